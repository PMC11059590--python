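"""Readers, writers and the orchestrating pipeline.

Interchange formats: single-channel 8-bit PNG/TIFF for label masks, CSV
for every tabular stage, JSON for fitted artifacts. Floats are
serialized at fixed precision so reruns under the same seed diff clean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .morphometrics import aggregate_table, glomerulus_morphometrics
from .rps import CLASSIFIER_FEATURES, EarlyCutoffs, assign_classes, fit_early_cutoffs
from .stats import cohens_kappa, prognosis_filter, prognostic_table
from .types import CELL_COLUMNS, LabeledGlomerulus, validate_mask_codes

__all__ = [
    "PipelineConfig",
    "read_label_mask",
    "write_label_mask",
    "read_cells_table",
    "write_table",
    "run_pipeline",
]

log = logging.getLogger("glomkit")

FLOAT_FORMAT = "%.6g"

#: glomerulus index columns (written next to the mask files)
GLOM_INDEX_COLUMNS = ("patient_id", "glom_id", "lesion_type", "mask", "pixel_size_um")


def write_label_mask(path, mask: np.ndarray) -> None:
    """Write a label mask as single-channel 8-bit PNG or TIFF."""
    path = Path(path)
    validate_mask_codes(mask)
    arr = np.asarray(mask, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr, extension=".png")


def read_label_mask(path) -> np.ndarray:
    """Read and validate a single-channel label mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise IOError(f"empty mask file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # decoder errors surface as I/O errors
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"mask {path} must be single-channel, got shape {arr.shape}"
        )
    validate_mask_codes(arr)
    return arr.astype(np.uint8)


def read_cells_table(path) -> pd.DataFrame:
    """Read a cells CSV (``patient_id, glom_id, cell_type, row, col``)."""
    df = pd.read_csv(path)
    required = {"patient_id", "glom_id", *CELL_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cells table {path} is missing columns {sorted(missing)}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    """Write a CSV with a header row, stable column order and fixed
    float precision."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``gloms_path`` indexes the mask files (columns
    ``patient_id, glom_id, lesion_type, mask, pixel_size_um``);
    ``classes_path`` holds the reference (pathologist) classes used to
    fit the early cutoffs; ``cohort_path`` is the optional visits table
    enabling the prognosis stage.
    """

    out_dir: Path
    masks_dir: Path
    gloms_path: Path
    cells_path: Path
    classes_path: Path
    cohort_path: Optional[Path] = None
    feature: str = "mesangial_area_fraction"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("out_dir", "masks_dir", "gloms_path", "cells_path", "classes_path"):
            setattr(self, name, Path(getattr(self, name)))
        if self.cohort_path is not None:
            self.cohort_path = Path(self.cohort_path)
        if self.feature not in CLASSIFIER_FEATURES:
            raise ValueError(
                f"feature must be one of {CLASSIFIER_FEATURES}, got {self.feature!r}"
            )

    def validate_paths(self) -> None:
        for name in ("masks_dir", "gloms_path", "cells_path", "classes_path"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.cohort_path is not None and not self.cohort_path.exists():
            raise FileNotFoundError(f"cohort_path: {self.cohort_path}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: d[k] for k in (
            "out_dir", "masks_dir", "gloms_path", "cells_path", "classes_path",
            "cohort_path", "feature", "seed") if k in d}
        extra = {k: v for k, v in d.items() if k not in known}
        return cls(**known, extra=extra)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record, cause: Exception):
        super().__init__(f"stage {stage!r} failed on record {record!r}: {cause}")
        self.stage = stage
        self.record = record


def _glom_features(config: PipelineConfig) -> pd.DataFrame:
    gloms = pd.read_csv(config.gloms_path)
    cells = read_cells_table(config.cells_path)
    cells_by_glom = dict(tuple(cells.groupby(["patient_id", "glom_id"], sort=False)))
    rows = []
    for _, rec in gloms.iterrows():
        key = (rec["patient_id"], rec["glom_id"])
        try:
            mask = read_label_mask(config.masks_dir / rec["mask"])
            sub = cells_by_glom.get(key)
            cell_df = (sub[list(CELL_COLUMNS)].reset_index(drop=True)
                       if sub is not None else pd.DataFrame(columns=list(CELL_COLUMNS)))
            g = LabeledGlomerulus(
                mask=mask, cells=cell_df, lesion_type=rec["lesion_type"],
                pixel_size_um=float(rec.get("pixel_size_um", 0.25)),
            )
            m = glomerulus_morphometrics(g)
        except Exception as exc:
            raise PipelineStageError("morphometrics", key, exc) from exc
        row = {"patient_id": rec["patient_id"], "glom_id": rec["glom_id"],
               "lesion_type": rec["lesion_type"]}
        row.update(m.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run features -> aggregation -> cutoffs -> classes -> agreement
    (-> prognosis) and write every artifact under ``config.out_dir``.

    Returns a mapping of artifact names to paths. Identical config and
    seed produce byte-identical outputs.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    glom_features = _glom_features(config)
    counts["glomeruli"] = len(glom_features)
    log.info("morphometrics: %d glomeruli", len(glom_features))
    artifacts["glom_features"] = out / "glom_features.csv"
    write_table(artifacts["glom_features"], glom_features)

    patient_features = aggregate_table(glom_features)
    counts["patients"] = len(patient_features)
    counts["midsection_glomeruli"] = int(patient_features["n_midsection"].sum())
    log.info("aggregate: %d patients, %d midsection glomeruli",
             counts["patients"], counts["midsection_glomeruli"])
    artifacts["patient_features"] = out / "patient_features.csv"
    write_table(artifacts["patient_features"], patient_features)

    ref = pd.read_csv(config.classes_path)
    if not {"patient_id", "rps_class"} <= set(ref.columns):
        raise PipelineStageError("classify", config.classes_path,
                                 ValueError("classes table needs patient_id, rps_class"))
    ref = ref.set_index("patient_id")["rps_class"]
    merged = patient_features.set_index("patient_id")
    common = merged.index.intersection(ref.index)
    early = ref.loc[common][ref.loc[common].isin(["I", "IIa", "IIb"])]
    try:
        cuts = fit_early_cutoffs(
            merged.loc[early.index], early.tolist(), config.feature,
        )
    except Exception as exc:
        raise PipelineStageError("classify.fit", config.feature, exc) from exc
    counts["early_fit_patients"] = cuts.n
    artifacts["cutoffs"] = out / "cutoffs.json"
    artifacts["cutoffs"].write_text(json.dumps(cuts.to_dict(), indent=2, sort_keys=True) + "\n")

    predicted = assign_classes(merged, cuts)
    classes_df = pd.DataFrame({
        "patient_id": merged.index,
        "rps_class": [c if c is not None else "unclassifiable" for c in predicted],
    })
    counts["classified"] = int((classes_df["rps_class"] != "unclassifiable").sum())
    artifacts["classes"] = out / "classes.csv"
    write_table(artifacts["classes"], classes_df)

    both = classes_df.set_index("patient_id")["rps_class"]
    pairing = pd.DataFrame({"pred": both, "ref": ref}).dropna()
    pairing = pairing[pairing["pred"] != "unclassifiable"]
    agreement = cohens_kappa(pairing["pred"].tolist(), pairing["ref"].tolist())
    artifacts["agreement"] = out / "agreement.json"
    artifacts["agreement"].write_text(json.dumps({
        "kappa": agreement.kappa,
        "observed_agreement": agreement.observed_agreement,
        "expected_agreement": agreement.expected_agreement,
        "n": agreement.n,
    }, indent=2, sort_keys=True) + "\n")
    counts["agreement_pairs"] = agreement.n

    if config.cohort_path is not None:
        visits = pd.read_csv(config.cohort_path)
        filtered, report = prognosis_filter(visits)
        counts["prognosis_retained"] = report.n_retained
        counts["prognosis_excluded_followup"] = report.n_excluded_followup
        counts["prognosis_excluded_baseline_egfr"] = report.n_excluded_baseline_egfr
        pred_series = both[both != "unclassifiable"]
        table = prognostic_table(pred_series, filtered, classes2=ref)
        artifacts["prognosis"] = out / "prognosis.csv"
        write_table(artifacts["prognosis"], table)

    run_log = {
        "seed": config.seed,
        "glomkit_version": __version__,
        "feature": config.feature,
        "counts": counts,
    }
    artifacts["run_log"] = out / "run_log.json"
    artifacts["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    return artifacts
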