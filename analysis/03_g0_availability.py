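#!/usr/bin/env python
"""Monte Carlo g(0) at the survey's operating point (ESHW 4.168 km, speed
11.8 km/h), from both the simulated-tag empirical distributions and the
calibrated parametric phase model, with the exponential-phase closed form
as a sanity anchor."""

import json
from pathlib import Path

import numpy as np

from strikewatch import g0 as g0m
from strikewatch import tags as tg
from strikewatch.survey_constants import CANARY_SURVEY as C

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg_kw = dict(eshw_km=C["mu_hat_km"], speed_kmh=C["speed_kmh"],
                  n_runs=2000, seed=2016)

    param = g0m.LognormalMixturePhases()
    est_param = g0m.simulate_g0(g0m.G0SimConfig(phase_source=param, **cfg_kw))

    phases = tg.PhaseDurationSet.from_csv(OUT / "phase_durations.csv")
    emp = g0m.EmpiricalPhases.from_phase_set(phases)
    est_emp = g0m.simulate_g0(g0m.G0SimConfig(phase_source=emp, **cfg_kw))

    window = est_param.window_min
    anchor = g0m.analytic_g0_exponential(param.mean_echo, param.mean_silent,
                                         window)

    out = {
        "window_min": window,
        "parametric": est_param.to_dict(),
        "empirical_from_tags": est_emp.to_dict(),
        "exponential_closed_form": anchor,
    }
    (OUT / "g0.json").write_text(json.dumps(out, indent=2) + "\n")

    print(f"detection window: {window:.1f} min")
    print(f"g(0) parametric phases: {est_param.g0_mean:.3f} "
          f"(sd {est_param.g0_sd:.3f}, "
          f"MC se {est_param.g0_sd / np.sqrt(2000):.4f})")
    print(f"g(0) empirical phases:  {est_emp.g0_mean:.3f} "
          f"(sd {est_emp.g0_sd:.3f})")
    print(f"exponential-phase closed form (same means): {anchor:.3f} — "
          "higher because the memoryless silent phase lacks the rest-tail "
          "mass concentration")
    print(f"wrote {OUT / 'g0.json'}")


if __name__ == "__main__":
    main()
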