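#!/usr/bin/env python
"""Simulate eNOS signalling at the four literature VEGF doses.

Doses: healthy-tissue 0.0003 nM, tumor-range 0.008 and 0.389 nM, and the
common experimental dose 1.1 nM (30 ng/mL).  Writes normalized trajectories
of nine readouts and a dose summary, and prints how the dose contrast fades
from the receptor down to cGMP.
"""

import sys
from pathlib import Path

from enoskit.pipeline import RunConfig, run_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "dose_response"


def main() -> int:
    result = run_scenario(RunConfig(scenario="dose_response",
                                    out_dir=str(OUT), seed=1))
    summary = result["summary"].set_index("vegf_nM")
    print(summary.round(4))
    pk = summary["peak_pR2_over_R2"]
    cg = summary["auc30_cGMP"]
    rd_pk = abs(pk[0.389] - pk[1.1]) / max(pk[0.389], pk[1.1])
    rd_cg = abs(cg[0.389] - cg[1.1]) / max(cg[0.389], cg[1.1])
    print(f"\npeak pR2/R2 relative difference (0.389 vs 1.1 nM): "
          f"{rd_pk:.1%}")
    print(f"cGMP AUC relative difference  (0.389 vs 1.1 nM): {rd_cg:.1%}")
    print("Input-level differences are progressively lost downstream: "
          "cGMP is robust to the VEGF dose.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
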