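"""Whale localization by crossing bearings from a moving vessel.

A two-element towed array gives the conical angle between the tow axis and
the arriving click — an unsigned bearing in [0, 180] degrees with a
port/starboard ambiguity.  As the vessel moves past a (near-stationary)
whale, successive bearings sweep; crossing them yields two candidate
positions, one on each side of the track.  The side whose bearing rays
intersect most coherently (lowest RMS point-to-ray residual) is chosen, and
that point's perpendicular distance to the track line is the distance-sampling
observation.

All geometry is planar (km grid); headings and ray angles are measured in
degrees counter-clockwise from the +x axis.  Port is the vessel's left, i.e.
heading + bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NoFixError(RuntimeError):
    """Raised when a bearing set cannot yield a well-conditioned fix."""


@dataclass
class VesselTrack:
    samples: pd.DataFrame  # t_s, x_km, y_km, heading_deg

    def __post_init__(self):
        t = self.samples["t_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("track times must be strictly increasing")
        if not np.all(np.isfinite(self.samples[["x_km", "y_km"]].to_numpy())):
            raise ValueError("track coordinates must be finite")

    def interpolate(self, t):
        """Vessel position and heading at arbitrary times (linear interp)."""
        t = np.asarray(t, dtype=float)
        s = self.samples
        x = np.interp(t, s["t_s"], s["x_km"])
        y = np.interp(t, s["t_s"], s["y_km"])
        h = np.interp(t, s["t_s"], s["heading_deg"])
        return x, y, h

    def to_csv(self, path):
        self.samples.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VesselTrack":
        return cls(pd.read_csv(path))


@dataclass
class BearingSeries:
    whale_id: str
    samples: pd.DataFrame  # t_s, bearing_deg (unsigned, relative to heading)

    def __post_init__(self):
        b = self.samples["bearing_deg"].to_numpy()
        if len(b) and (np.any(b < 0) or np.any(b > 180)):
            raise ValueError("bearings must lie in [0, 180] degrees")

    def to_frame(self) -> pd.DataFrame:
        df = self.samples.copy()
        df.insert(0, "whale_id", self.whale_id)
        df["side_unknown"] = 1
        return df

    @classmethod
    def read_csv(cls, path) -> list:
        """Read a bearings CSV (whale_id, t_s, bearing_deg) into series."""
        df = pd.read_csv(path)
        return [cls(str(wid), grp[["t_s", "bearing_deg"]].reset_index(drop=True))
                for wid, grp in df.groupby("whale_id", sort=True)]


@dataclass
class WhaleFix:
    whale_id: str
    position_port: tuple
    position_starboard: tuple
    residual_port: float
    residual_starboard: float
    chosen_side: str
    perp_distance_km: float

    @property
    def position(self) -> tuple:
        return (self.position_port if self.chosen_side == "port"
                else self.position_starboard)


def _least_squares_ray_point(anchors: np.ndarray, angles_deg: np.ndarray):
    """Point minimising the sum of squared perpendicular distances to the
    lines through ``anchors`` with directions ``angles_deg``; returns the
    point and the RMS residual."""
    u = np.column_stack([np.cos(np.radians(angles_deg)),
                         np.sin(np.radians(angles_deg))])
    # projector onto each line's normal: P_i = I - u_i u_i^T
    M = np.zeros((2, 2))
    rhs = np.zeros(2)
    for a, ui in zip(anchors, u):
        P = np.eye(2) - np.outer(ui, ui)
        M += P
        rhs += P @ a
    if np.linalg.cond(M) > 1e10:
        raise NoFixError("bearing rays are (near-)parallel; normal system degenerate")
    p = np.linalg.solve(M, rhs)
    d = p - anchors
    resid = d - (d * u).sum(axis=1, keepdims=True) * u
    return p, float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def perpendicular_distance(point, track_segment) -> float:
    """Orthogonal distance (km) from a point to the infinite line through a
    track segment ((x1, y1), (x2, y2))."""
    (x1, y1), (x2, y2) = track_segment
    dx, dy = x2 - x1, y2 - y1
    norm = np.hypot(dx, dy)
    if norm < 1e-12:
        raise ValueError("zero-length track segment")
    px, py = point
    return float(abs(dx * (py - y1) - dy * (px - x1)) / norm)


def cross_bearings(track: VesselTrack, bearings: BearingSeries,
                   min_aperture_deg: float = 15.0,
                   min_bearings: int = 2) -> WhaleFix:
    """Localize one whale from its bearing series.

    For each side hypothesis the bearing rays (anchored at the vessel
    position at each bearing's time, direction heading +/- bearing) are
    intersected by least squares; the side with the lower RMS residual is
    chosen and its perpendicular distance to the track line reported.
    """
    s = bearings.samples
    if len(s) < min_bearings:
        raise NoFixError(f"need at least {min_bearings} bearings, got {len(s)}")
    b = s["bearing_deg"].to_numpy(dtype=float)
    aperture = float(b.max() - b.min())
    if aperture < min_aperture_deg:
        raise NoFixError(
            f"bearing aperture {aperture:.1f} deg below minimum {min_aperture_deg} deg")

    t = s["t_s"].to_numpy(dtype=float)
    xv, yv, hv = track.interpolate(t)
    anchors = np.column_stack([xv, yv])

    p_port, r_port = _least_squares_ray_point(anchors, hv + b)
    p_stbd, r_stbd = _least_squares_ray_point(anchors, hv - b)
    side = "port" if r_port <= r_stbd else "starboard"
    chosen = p_port if side == "port" else p_stbd

    seg = ((float(xv[0]), float(yv[0])), (float(xv[-1]), float(yv[-1])))
    perp = perpendicular_distance(tuple(chosen), seg)
    return WhaleFix(bearings.whale_id, tuple(p_port), tuple(p_stbd),
                    r_port, r_stbd, side, perp)


def localize_all(track: VesselTrack, bearing_sets,
                 min_aperture_deg: float = 15.0) -> pd.DataFrame:
    """Cross bearings for every whale; skip (and record) unfixable ones."""
    rows = []
    for bs in bearing_sets:
        try:
            fx = cross_bearings(track, bs, min_aperture_deg=min_aperture_deg)
        except NoFixError as err:
            rows.append({"whale_id": bs.whale_id, "fixed": False,
                         "reason": str(err)})
            continue
        rows.append({"whale_id": bs.whale_id, "fixed": True,
                     "x_km": fx.position[0], "y_km": fx.position[1],
                     "side": fx.chosen_side,
                     "residual_km": min(fx.residual_port, fx.residual_starboard),
                     "perp_km": fx.perp_distance_km, "reason": ""})
    return pd.DataFrame(rows)


def surface_assumption_bias(depth_m: float, true_perp_km: float) -> float:
    """Fractional over-estimation of perpendicular distance when a whale at
    depth z is assumed to be at the surface: (sqrt(x^2 + z^2) - x) / x at the
    beam.  Small for the depths and ranges of a sperm whale survey."""
    if depth_m < 0:
        raise ValueError("depth must be non-negative")
    if true_perp_km <= 0:
        raise ValueError("true perpendicular distance must be positive")
    z = depth_m / 1000.0
    return float((np.hypot(true_perp_km, z) - true_perp_km) / true_perp_km)
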