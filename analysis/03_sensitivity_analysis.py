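#!/usr/bin/env python
"""eFAST global sensitivity of the three outputs to one parameter group.

Desk-scale run: one module group at a time (default: the eNOS catalysis
group), scalar output = 30-min AUC of Ca2+, NO and cGMP at tumor-level
VEGF.  Parameters with a significant total-order index >= 0.1 are the
candidate perturbation targets; >= 0.2 marks them influential for fitting.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from enoskit import Model, StimulusCondition
from enoskit.efast import (EfastDesign, efast_indices, efast_sample,
                           select_influential)
from enoskit.screen import auc, SCREEN_OUTPUTS

OUT = Path(__file__).resolve().parents[1] / "results" / "sensitivity"
GROUP = sys.argv[1] if len(sys.argv) > 1 else "enos_cat"
SEED = 1


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    model = Model()
    params = model.network.params
    names = tuple(n for n in params.group(GROUP)
                  if params.meta(n).perturbable)
    design = EfastDesign.around_baseline(
        {n: params[n] for n in names}, M=4, Ns=129, Nr=3)
    sample = efast_sample(design, seed=SEED)
    cond = StimulusCondition(vegf_nM=0.389, duration_min=30.0)

    tables = []
    for output in SCREEN_OUTPUTS:
        Y = np.empty((design.n_params, design.Nr, design.Ns))
        for i in range(design.n_params):
            for r in range(design.Nr):
                for k in range(design.Ns):
                    row = sample.X[i, r, k]
                    p = params.with_values(
                        **{n: row[j] for j, n in enumerate(names)})
                    try:
                        Y[i, r, k] = auc(model.simulate(cond, p), output)
                    except Exception:
                        Y[i, r, k] = np.nan
        rep = efast_indices(Y, sample)
        t = rep.table()
        t["output"] = output
        tables.append(t)
        hits = select_influential(rep, cutoff=0.1)
        print(f"{output}: influential (S_Ti >= 0.1): {hits}")
    pd.concat(tables).to_csv(OUT / f"efast_{GROUP}.csv", index=False)
    print(f"wrote {OUT / f'efast_{GROUP}.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
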