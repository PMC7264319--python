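#!/usr/bin/env python
"""Run the full 7-selector x 4-classifier grid on the strong-effect cohort.

Uses 10-fold lesion-level cross-validation on all lesions, plus the size
subgroups (small <= 10 mm with 10-fold CV, large > 10 mm with
leave-one-out). Candidate feature counts k in {5, 10, 20}; ranking
forests use 60 trees, classifier forests 200, and the FSV ranker runs 4
reweighting iterations — sizes chosen so the whole grid finishes on one
CPU. Writes per-subgroup grid tables and AUC heatmaps under results/.
"""

import sys
import time
import warnings
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from bmradiomics import CVPlan, render_grid, train_eval_cell  # noqa: E402
from bmradiomics.evaluation import (  # noqa: E402
    CLASSIFIER_ORDER,
    SELECTOR_ORDER,
    ClassifierParams,
    GridReport,
)
from bmradiomics.pipeline import load_features_csv  # noqa: E402

SETTINGS = dict(
    k_grid=[5, 10, 20],
    selector_kwargs={"n_trees": 60, "n_iter": 4},
    classifier_params=ClassifierParams(rf_trees=200),
)


def evaluate_grid(table, plan, subgroup):
    cells = {}
    for s in SELECTOR_ORDER:
        for c in CLASSIFIER_ORDER:
            t0 = time.time()
            cells[(s, c)] = train_eval_cell(table, s, c, plan, seed=7, **SETTINGS)
            print(
                f"  [{subgroup}] {s:>9} x {c:<8} AUC {cells[(s, c)].auc:5.1f} "
                f"k={cells[(s, c)].optimal_k:<2} ({time.time() - t0:.0f}s)",
                flush=True,
            )
    return GridReport(cells=cells, subgroup=subgroup)


def main():
    warnings.filterwarnings("ignore")
    table = load_features_csv(ROOT / "scratch" / "features_strong.csv")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    t0 = time.time()

    reports = {"all": evaluate_grid(table, CVPlan("kfold", k=10, seed=101), "all")}
    small_rows = np.nonzero(table.diameters_mm <= 10.0)[0]
    large_rows = np.nonzero(table.diameters_mm > 10.0)[0]
    reports["small"] = evaluate_grid(
        table.subset(rows=small_rows), CVPlan("kfold", k=10, seed=101), "small"
    )
    reports["large"] = evaluate_grid(
        table.subset(rows=large_rows), CVPlan("loo", seed=101), "large"
    )

    for name, rep in reports.items():
        rep.to_dataframe().to_csv(out / f"grid_{name}.csv", index=False, float_format="%.4g")
        render_grid(rep, out / f"auc_{name}.csv", out / f"auc_{name}.png")
        best = rep.to_dataframe().sort_values("auc", ascending=False).iloc[0]
        print(f"\n=== {name} lesions ({len(rep.cells)} cells) ===")
        print(rep.auc_matrix().round(1).to_string())
        print(f"best: {best['selector']} selection + {best['classifier']} "
              f"classification, k={best['optimal_k']}, AUC {best['auc']:.1f}")
    print(f"\ngrid evaluation finished in {(time.time() - t0) / 60:.1f} min -> {out}")


if __name__ == "__main__":
    main()
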