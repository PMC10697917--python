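"""Compare the passive-model prediction with the synthetic measurement.

Puts the model sweep for the 151 cm / 58 kg patient next to the pipeline
summary of that patient's synthetic trial and reports per-metric
differences and the qualitative pattern-agreement flags.  The two routes
are independent: the measurement side goes truth -> sensors -> pipeline,
the model side is pure mechanics, so only pattern-level agreement is
expected (magnitudes differ because passive muscle stiffness is not
personalised).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hiptension.trials import METRICS, PatientSummary

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sweep = pd.read_csv(RESULTS / "passive_sweep.csv")
    measured = PatientSummary.from_json(RESULTS / "summary_series-4.json")

    res = sweep.resultant_N.to_numpy()
    g = sweep.gamma_deg.to_numpy()
    imin = int(np.argmin(res))
    model = {
        "max_force_N": float(res[int(np.argmin(g))]),
        "min_force_N": float(res[imin]),
        "gamma_at_min_deg": float(g[imin]),
        "force_at_90_N": float(np.interp(90.0, g, res)),
    }
    table = pd.DataFrame({
        "metric": list(METRICS),
        "model": [model[m] for m in METRICS],
        "measured_mean": [measured.mean(m) for m in METRICS],
    })
    table["difference"] = table.model - table.measured_mean
    table.to_csv(RESULTS / "model_vs_measured.csv", index=False,
                 float_format="%.2f")
    print(table.to_string(index=False))

    p = sweep.posterior_N.to_numpy()
    s = -sweep.inferior_N.to_numpy()
    agreement = {
        "u_shaped_resultant": bool(res[0] > res[imin] < res[-1]),
        "minimum_in_10_50_deg": bool(10 < g[imin] < 50),
        "posterior_rises_with_flexion": bool(p[-1] > p[0]),
        "superior_falls_with_flexion": bool(s[-1] < s[0]),
    }
    (RESULTS / "pattern_agreement.json").write_text(
        json.dumps(agreement, indent=2))
    print("\npattern agreement with the measured behaviour:")
    for k, v in agreement.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
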