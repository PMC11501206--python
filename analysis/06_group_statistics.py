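#!/usr/bin/env python
"""Published contingency values and calibration of the statistics battery.

Recomputes the published percentages and Fisher tests from their printed
numerators/denominators, and calibrates the ROUT outlier-removal false
flag rate on clean Gaussian samples.  Writes results/group_statistics.json.
"""

import json
from pathlib import Path

import numpy as np

from epiphen.stats import fisher_exact, proportion_pct, rout_outliers

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = {
        "pid_pct_male": proportion_pct(17, 120),
        "pid_pct_female": proportion_pct(108, 154),
        "nonconvulsive_pct_cre_neg": proportion_pct(2, 11),
        "nonconvulsive_pct_cre_pos": proportion_pct(4, 14),
        "fisher_p_pid_sex": fisher_exact([[108, 46], [17, 103]]),
        "fisher_p_first_seizure_severity": fisher_exact([[2, 9], [4, 10]]),
    }
    print("postictal depression: females 108/154 ="
          f" {out['pid_pct_female']}%, males 17/120 = {out['pid_pct_male']}%,"
          f" Fisher p = {out['fisher_p_pid_sex']:.2e}")
    print("non-convulsive first seizure: 2/11 ="
          f" {out['nonconvulsive_pct_cre_neg']}% vs 4/14 ="
          f" {out['nonconvulsive_pct_cre_pos']}%, Fisher p ="
          f" {out['fisher_p_first_seizure_severity']:.3f}")

    rng = np.random.default_rng(8)
    flagged = total = 0
    for _ in range(2000):
        r = rout_outliers(rng.standard_normal(20), q=0.01)
        flagged += r["outliers"].size
        total += 20
    out["rout_false_flag_rate_pct"] = 100 * flagged / total
    print(f"ROUT (Q=1%) false-flag rate on clean normals: "
          f"{out['rout_false_flag_rate_pct']:.2f}%")
    OUT.mkdir(exist_ok=True)
    (OUT / "group_statistics.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
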