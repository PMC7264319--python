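"""End-to-end driver: manifest I/O, run configuration, and `run_all`.

A run is described by a single JSON-serialisable :class:`RunConfig`; all
randomness flows from one root seed through named substreams (cohort,
folds, permutations, classifiers) so a rerun with the same config is
bit-identical at the CSV level.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    CLASSIFIER_ORDER,
    SELECTOR_ORDER,
    ClassifierParams,
    CVPlan,
    permutation_test,
    render_grid,
    run_grid,
    subgroup_grids,
)
from .features import META_COLUMNS, ExtractionParams, extract_cohort
from .selection import CohortTable
from .synthetic import CohortConfig, LesionRecord, generate_cohort

__all__ = ["RunConfig", "read_manifest", "write_features_csv", "load_features_csv", "run_all"]

MANIFEST_COLUMNS = ("lesion_id", "patient_id", "label", "diameter_mm", "volume_path", "mask_path")


def read_manifest(path) -> list[LesionRecord]:
    """Read and validate a cohort manifest CSV.

    Rejects missing header columns, duplicate lesion ids, labels outside
    {0, 1}, sub-threshold diameters and missing volume/mask files, naming
    the offending row and column.
    """
    path = Path(path)
    records: list[LesionRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: manifest missing columns {missing}")
        for row_no, row in enumerate(reader, start=2):
            lid = row["lesion_id"]
            if lid in seen:
                raise ValueError(f"{path} row {row_no}: duplicate lesion_id {lid!r}")
            seen.add(lid)
            try:
                label = int(row["label"])
            except ValueError:
                raise ValueError(
                    f"{path} row {row_no}: label {row['label']!r} is not an integer"
                ) from None
            if label not in (0, 1):
                raise ValueError(f"{path} row {row_no}: label must be 0 or 1, got {label}")
            try:
                rec = LesionRecord(
                    lesion_id=lid,
                    patient_id=row["patient_id"],
                    label=label,
                    diameter_mm=float(row["diameter_mm"]),
                    volume_path=row["volume_path"],
                    mask_path=row["mask_path"],
                )
            except ValueError as err:
                raise ValueError(f"{path} row {row_no}: {err}") from None
            for col in ("volume_path", "mask_path"):
                p = row[col]
                if p and not Path(p).exists():
                    raise ValueError(f"{path} row {row_no}, column {col}: file not found {p!r}")
            records.append(rec)
    return records


def write_features_csv(df: pd.DataFrame, path, params: ExtractionParams | None = None) -> None:
    """Write the lesion x feature table plus a JSON parameter sidecar."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    if params is not None:
        sidecar = path.with_suffix(".params.json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_levels": params.n_levels,
                    "n_bins": params.n_bins,
                    "base_sigma": params.base_sigma,
                    "offsets": [list(o) for o in params.offsets],
                },
                indent=2,
            )
        )


def load_features_csv(path) -> CohortTable:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    return CohortTable.from_dataframe(df)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, serialisable as one JSON doc."""

    out_dir: str = "results/run"
    manifest: str | None = None  # None: generate a synthetic cohort
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    extraction: dict = field(default_factory=dict)  # ExtractionParams overrides
    bias_fwhm_mm: float = 60.0
    margin_voxels: int = 2
    apply_bias_correction: bool = True
    selectors: tuple = SELECTOR_ORDER
    classifiers: tuple = CLASSIFIER_ORDER
    k_grid: tuple = tuple(range(2, 51))
    cv_k: int = 10
    grouping: str = "lesion"
    subgroup_threshold_mm: float = 10.0
    run_subgroups: bool = True
    n_permutations: int = 0  # 0 disables the permutation stage
    permutation_cell: tuple = ("rf", "rf")
    selector_kwargs: dict = field(default_factory=dict)
    classifier_params: dict = field(default_factory=dict)  # ClassifierParams overrides

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("selectors", "classifiers", "k_grid", "permutation_cell"):
            d[key] = list(d[key])
        return json.dumps(d, indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _substream(seed: int, name: str) -> int:
    """Stable named substream below 2**31 derived from the root seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_all(config: RunConfig) -> dict:
    """Generate (optionally) -> preprocess -> extract -> evaluate.

    Writes, under ``config.out_dir``: the resolved config, the feature
    table, per-subgroup grid CSVs and heatmaps, a fold-audit CSV, and a
    permutation JSON when requested. Returns the in-memory reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    from . import __version__

    (out / "run.log").write_text(
        f"bmradiomics {__version__}\nconfig_hash {config.config_hash}\n"
        f"root_seed {config.seed}\n"
        + "".join(
            f"seed.{name} {_substream(config.seed, name)}\n"
            for name in ("cohort", "folds", "classifiers", "permutations")
        )
    )

    stage = "generate"
    try:
        if config.manifest is None:
            cohort_cfg = CohortConfig(
                seed=_substream(config.seed, "cohort"), **config.cohort
            )
            records = generate_cohort(cohort_cfg, out_dir=out / "cohort")
        else:
            records = read_manifest(config.manifest)

        stage = "extract"
        params = ExtractionParams(**config.extraction)
        df = extract_cohort(
            records,
            params=params,
            bias_fwhm_mm=config.bias_fwhm_mm,
            margin_voxels=config.margin_voxels,
            apply_bias_correction=config.apply_bias_correction,
        )
        write_features_csv(df, out / "features.csv", params)
        table = CohortTable.from_dataframe(df)

        stage = "evaluate"
        plan = CVPlan(
            "kfold", k=config.cv_k, grouping=config.grouping,
            seed=_substream(config.seed, "folds"),
        )
        clf_params = ClassifierParams(**config.classifier_params)
        reports = {}
        reports["all"] = run_grid(
            table,
            plan,
            selectors=config.selectors,
            classifiers=config.classifiers,
            k_grid=config.k_grid,
            seed=_substream(config.seed, "classifiers"),
            selector_kwargs=config.selector_kwargs,
            classifier_params=clf_params,
        )
        if config.run_subgroups:
            reports.update(
                subgroup_grids(
                    table,
                    threshold_mm=config.subgroup_threshold_mm,
                    seed=_substream(config.seed, "classifiers"),
                    selectors=config.selectors,
                    classifiers=config.classifiers,
                    k_grid=config.k_grid,
                    kfold_k=config.cv_k,
                    grouping=config.grouping,
                    selector_kwargs=config.selector_kwargs,
                    classifier_params=clf_params,
                )
            )
        for name, rep in reports.items():
            rep.to_dataframe().to_csv(out / f"grid_{name}.csv", index=False, float_format="%.6g")
            render_grid(rep, out / f"auc_{name}.csv", out / f"auc_{name}.png")

        audit_rows = []
        for (s, c), cell in reports["all"].cells.items():
            for entry in cell.audit:
                audit_rows.append(
                    {
                        "selector": s,
                        "classifier": c,
                        "fold": entry["fold"],
                        "test_lesions": ";".join(entry["test_lesions"]),
                    }
                )
        pd.DataFrame(audit_rows).to_csv(out / "fold_audit.csv", index=False)

        result = {"reports": reports, "features": df, "config_hash": config.config_hash}
        if config.n_permutations > 0:
            stage = "permutation"
            sel, clf = config.permutation_cell
            perm = permutation_test(
                table,
                sel,
                clf,
                plan,
                n_permutations=config.n_permutations,
                seed=_substream(config.seed, "permutations"),
                k_grid=config.k_grid,
                observed=reports["all"].cells[(sel, clf)],
                selector_kwargs=config.selector_kwargs,
                classifier_params=clf_params,
            )
            (out / "permutation.json").write_text(
                json.dumps(
                    {
                        "selector": sel,
                        "classifier": clf,
                        "observed_auc": perm.observed_auc,
                        "n_permutations": perm.n_permutations,
                        "n_higher": perm.n_higher,
                        "p_value": perm.p_value,
                    },
                    indent=2,
                )
            )
            result["permutation"] = perm
        return result
    except FileNotFoundError as err:
        raise RuntimeError(f"[stage: {stage}] {err}") from err
    except ValueError as err:
        raise RuntimeError(f"[stage: {stage}] {err}") from err
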