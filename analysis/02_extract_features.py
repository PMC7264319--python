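#!/usr/bin/env python
"""Preprocess every lesion and extract the 1209-feature table.

Reads the cohort manifests written by 01_generate_cohort.py, applies the
fixed chain (bias correction -> crop -> z-score normalisation), extracts
the full radiomic descriptor per lesion, and writes
scratch/features_{strong,null}.csv plus a JSON sidecar with the
extraction parameters.
"""

import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from bmradiomics import extract_cohort, read_manifest  # noqa: E402
from bmradiomics.features import ExtractionParams  # noqa: E402
from bmradiomics.pipeline import write_features_csv  # noqa: E402


def main():
    params = ExtractionParams()
    for name in ("strong", "null"):
        manifest = ROOT / "scratch" / "cohorts" / name / "manifest.csv"
        records = read_manifest(manifest)
        t0 = time.time()
        df = extract_cohort(records, params=params)
        out = ROOT / "scratch" / f"features_{name}.csv"
        write_features_csv(df, out, params)
        print(
            f"{name:>7}: {df.shape[0]} lesions x {df.shape[1] - 4} features "
            f"in {time.time() - t0:.0f}s -> {out}"
        )


if __name__ == "__main__":
    main()
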