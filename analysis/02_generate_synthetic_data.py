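#!/usr/bin/env python
"""Generate the synthetic calibration corpus.

Fourteen training time courses (58 points) plus four hold-out sets, with
15% multiplicative lognormal noise, written as tidy CSV.
"""

import sys
from pathlib import Path

from enoskit import Model
from enoskit.synthetic import (DEFAULT_VALIDATION_DESIGN, corrupt_all,
                               generate_truth, total_points,
                               write_timecourse_csv)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_data"
SEED = 1
SIGMA = 0.15


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    model = Model()
    train = generate_truth(model=model)
    val = generate_truth(design=DEFAULT_VALIDATION_DESIGN, model=model,
                         id_prefix="val")
    noisy_train = corrupt_all(train, SIGMA, SEED)
    noisy_val = corrupt_all(val, SIGMA, SEED + 1)
    write_timecourse_csv(noisy_train, OUT / "training.csv")
    write_timecourse_csv(noisy_val, OUT / "validation.csv")
    print(f"training: {len(noisy_train)} datasets, "
          f"{total_points(noisy_train)} points -> {OUT/'training.csv'}")
    print(f"validation: {len(noisy_val)} datasets, "
          f"{total_points(noisy_val)} points -> {OUT/'validation.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
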