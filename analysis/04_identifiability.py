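#!/usr/bin/env python
"""Pairwise-correlation identifiability screen of the candidate fit set.

Builds the local sensitivity matrix of the normalized training outputs
with respect to log10 of each candidate parameter, computes pairwise
Pearson correlations, and flags pairs with |r| >= 0.9 as a-priori
unidentifiable (one member of each pair is then fixed before fitting).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from enoskit import Model
from enoskit.identifiability import (classify, select_fit_parameters,
                                     sensitivity_matrix)
from enoskit.synthetic import generate_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "identifiability"
CANDIDATES = ("k_dephos_R2", "k_int_VR2", "k_dp_Src", "k_dp_Akt",
              "k_deg_IP3", "k_off_Ca2C", "k_clear_NO", "k_cat_sGC",
              "k_on_Arg", "k_off_Arg")


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    model = Model()
    data = tuple(generate_truth(model=model))
    S = sensitivity_matrix(model.network.params, CANDIDATES, data, model)
    report = classify(S, CANDIDATES, threshold=0.9)
    report.table().round(3).to_csv(OUT / "correlations.csv")
    print("unidentifiable pairs (|r| >= 0.9):")
    for a, b, r in report.unidentifiable_pairs:
        print(f"  {a} ~ {b}: r = {r:+.3f}")
    st = {n: float(np.std(S[:, i])) for i, n in enumerate(CANDIDATES)}
    fit_set = select_fit_parameters(list(CANDIDATES), report, st)
    print(f"identifiable fit set ({len(fit_set)}): {fit_set}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
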