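#!/usr/bin/env python
"""Validate SE-duration recovery and postictal-depression scoring.

Generates status-epilepticus recordings with randomized continuous-phase
lengths and exact step-down truth, and chronic seizures followed by
suppressions of known scale, then checks how well the episode metrics
recover the truth.  Writes results/se_pid_validation.json.
"""

import json
from pathlib import Path

from epiphen.validation import pid_suite, se_suite

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    se = se_suite(n_episodes=5, seed=2)
    print(f"SE duration error over {se['n_episodes']} episodes: "
          f"mean {se['mean_abs_error_min']:.2f} min, "
          f"max {se['max_abs_error_min']:.2f} min")
    pid = pid_suite(seeds_per_scale=2, seed=3)
    print(f"PID classification accuracy vs suppression-scale truth: "
          f"{pid['accuracy']:.2f} ({pid['n_cases']} cases)")
    OUT.mkdir(exist_ok=True)
    (OUT / "se_pid_validation.json").write_text(
        json.dumps({**se, **pid}, indent=2))


if __name__ == "__main__":
    main()
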