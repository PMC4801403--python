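"""Dive-cycle segmentation and vocal-phase extraction from biologging tags.

A sperm whale tag record is a time series of depth and clicking state.  The
whales' foraging behaviour is stereotyped: a silent descent, a long
echolocation period at depth (regular "usual" clicks), a silent ascent, and a
surface inter-dive interval (IDI).  The whale is acoustically available to a
towed-hydrophone survey only during the echolocation period, so the quantities
that matter downstream are the durations of the echolocating phase (t_e) and
of the full silent stretch between successive echolocation periods
(t_ne = silent ascent + IDI + next silent descent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Depth (m) separating foraging dives from surface behaviour.  Tagged whales
#: start clicking at 61-452 m, so any threshold well below that and well above
#: surface swell works; 100 m is the default and is exposed everywhere.
DEFAULT_DIVE_THRESHOLD_M = 100.0


@dataclass
class TagSeries:
    """Time-indexed depth and clicking state for one tagged whale."""

    whale_id: str
    samples: pd.DataFrame  # columns: t_s, depth_m, clicking (0/1)
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        t = self.samples["t_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("tag sample times must be strictly increasing")
        if len(t) and (self.samples["depth_m"] < 0).any():
            raise ValueError("depths must be non-negative")

    def to_csv(self, path):
        self.samples.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, whale_id: str | None = None) -> "TagSeries":
        df = pd.read_csv(path)
        return cls(whale_id or str(path), df[["t_s", "depth_m", "clicking"]])


@dataclass
class DiveCycle:
    """One foraging dive plus the following inter-dive interval."""

    dive_start: float
    dive_end: float
    echo_start: float | None
    echo_end: float | None
    idi_end: float
    complete: bool

    @property
    def has_echo(self) -> bool:
        return self.echo_start is not None and self.echo_end is not None and \
            self.echo_end > self.echo_start

    @property
    def echo_duration_min(self) -> float:
        return (self.echo_end - self.echo_start) / 60.0 if self.has_echo else 0.0


@dataclass
class PhaseDurationSet:
    """Paired samples of echolocating (t_e) and silent (t_ne) durations, minutes."""

    t_e: np.ndarray
    t_ne: np.ndarray

    def __post_init__(self):
        self.t_e = np.asarray(self.t_e, dtype=float)
        self.t_ne = np.asarray(self.t_ne, dtype=float)
        if np.any(self.t_e <= 0) or np.any(self.t_ne < 0):
            raise ValueError("phase durations must be positive")

    def to_csv(self, path, whale_id: str = "pooled"):
        rows = [{"whale_id": whale_id, "phase": "echo", "duration_min": d} for d in self.t_e]
        rows += [{"whale_id": whale_id, "phase": "silent", "duration_min": d} for d in self.t_ne]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhaseDurationSet":
        df = pd.read_csv(path)
        return cls(df.loc[df["phase"] == "echo", "duration_min"].to_numpy(),
                   df.loc[df["phase"] == "silent", "duration_min"].to_numpy())

    @classmethod
    def pool(cls, sets) -> "PhaseDurationSet":
        """Pool several whales' phase sets per-cycle (each cycle counts once)."""
        return cls(np.concatenate([s.t_e for s in sets]),
                   np.concatenate([s.t_ne for s in sets]))


def segment_dive_cycles(series: TagSeries,
                        dive_threshold_m: float = DEFAULT_DIVE_THRESHOLD_M):
    """Split a tag record into dive cycles.

    A dive is a maximal excursion deeper than ``dive_threshold_m``; its
    echolocation period spans the first to the last clicking sample within the
    dive.  Each cycle pairs a dive with the following surface interval and is
    flagged ``complete`` only when the start of the next dive was recorded.
    """
    df = series.samples
    if df.empty:
        raise ValueError("empty tag series")
    t = df["t_s"].to_numpy(dtype=float)
    deep = df["depth_m"].to_numpy(dtype=float) > dive_threshold_m
    clicking = df["clicking"].to_numpy().astype(bool)

    edges = np.flatnonzero(np.diff(deep.astype(np.int8)))
    starts = [int(i) + 1 for i in edges if not deep[i]]
    ends = [int(i) for i in edges if deep[i]]
    if deep[0]:
        starts = [0] + starts
    if deep[-1]:
        ends = ends + [len(deep) - 1]

    cycles: list[DiveCycle] = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        clk = np.flatnonzero(clicking[s:e + 1])
        echo_start = float(t[s + clk[0]]) if clk.size else None
        # end-exclusive: the first non-clicking sample bounds the echo period,
        # so discrete-grid duration errors stay below one sample interval
        echo_end = (float(t[min(s + clk[-1] + 1, len(t) - 1)])
                    if clk.size else None)
        complete = k + 1 < len(starts)
        idi_end = float(t[starts[k + 1]]) if complete else float(t[-1])
        cycles.append(DiveCycle(float(t[s]), float(t[e]), echo_start, echo_end,
                                idi_end, complete))
    return cycles


def extract_phase_durations(cycles, exclude_first: bool = True,
                            require_complete: bool = True) -> PhaseDurationSet:
    """Build t_e / t_ne samples from segmented dive cycles.

    ``exclude_first`` drops the first cycle after tagging (tag-reaction bias);
    ``require_complete`` drops incomplete cycles and dives without an
    echolocation period.  t_ne spans the end of one dive's clicking to the
    start of the next dive's clicking, i.e. silent ascent + IDI + next descent
    — the stretch over which the whale is acoustically unavailable.
    """
    indexed = list(enumerate(cycles))
    if exclude_first:
        indexed = indexed[1:]
    usable = [(i, c) for i, c in indexed
              if c.has_echo and (c.complete or not require_complete)]
    if len(usable) < 2:
        raise ValueError("need at least two usable dive cycles to derive t_ne")

    t_e = np.array([c.echo_duration_min for _, c in usable])
    t_ne = []
    for i, c in usable:
        # the silent stretch after cycle i is fully observed as soon as the
        # *next* dive's clicking starts, whether or not that cycle is usable
        if i + 1 < len(cycles):
            nxt = cycles[i + 1]
            if nxt.echo_start is not None and c.echo_end is not None:
                gap = (nxt.echo_start - c.echo_end) / 60.0
                if gap > 0:
                    t_ne.append(gap)
    if len(t_ne) < 1:
        raise ValueError("not enough usable cycles after exclusions")
    return PhaseDurationSet(t_e, np.asarray(t_ne))


def phase_histograms(phase_set: PhaseDurationSet, bin_min: float = 1.0):
    """Normalised duration histograms in ``bin_min``-minute bins.

    Returns a dict ``{"echo": (edges, probs), "silent": (edges, probs)}``;
    probabilities sum to one per phase.
    """
    if phase_set.t_e.size == 0 or phase_set.t_ne.size == 0:
        raise ValueError("empty phase-duration set")
    out = {}
    for name, vals in (("echo", phase_set.t_e), ("silent", phase_set.t_ne)):
        hi = np.ceil(vals.max() / bin_min) * bin_min
        edges = np.arange(0.0, hi + bin_min, bin_min)
        counts, edges = np.histogram(vals, bins=edges)
        out[name] = (edges, counts / counts.sum())
    return out


def time_budget(phase_set: PhaseDurationSet) -> float:
    """Fraction of total time spent echolocating: sum t_e / (sum t_e + sum t_ne)."""
    tot_e = float(np.sum(phase_set.t_e))
    tot_ne = float(np.sum(phase_set.t_ne))
    if tot_e + tot_ne == 0:
        raise ValueError("empty phase-duration set")
    return tot_e / (tot_e + tot_ne)
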