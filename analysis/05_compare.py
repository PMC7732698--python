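#!/usr/bin/env python
"""Rigidification and shift statistics between the two ensembles.

Quantifies what "rigidification" means operationally: the rigidified
ensemble (4× force constant, minimum shifted +3°) should show a σ ratio of
0.5, a +3° mean shift and a visibly reduced distribution overlap relative
to the baseline. The printed affinity constants of the maturation pair
(1.02×10¹⁰ vs 1.44×10⁷ M⁻¹, a ≥700-fold gain) give the biochemical scale of
the change these statistics accompany.

Writes results/05_comparison.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fabdyn import AnalysisConfig, AngleSeries, affinity_fold_change, compare_ensembles
from fabdyn.pipeline import report_for_series

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = AnalysisConfig()
    reports = {}
    for path in sorted(FIXTURES.glob("*_elbow_series.npy")):
        name = path.stem.replace("_elbow_series", "")
        reports[name] = {"elbow": report_for_series(
            AngleSeries(np.load(path), dt_ps=1.0, name="elbow"), cfg)}
    cmp_ = compare_ensembles(reports["baseline"], reports["rigidified"], cfg)
    df = cmp_.as_frame()
    df["affinity_fold_change_context"] = affinity_fold_change()
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "05_comparison.csv")
    print(df.to_string())
    print(f"\nwrote {RESULTS / '05_comparison.csv'}")
    print("sd ratio ~0.5 and reduced overlap = the rigidification signature; "
          "the mean shift tracks the moved minimum.")


if __name__ == "__main__":
    main()
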