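"""ROC-derived mesangial cutoffs and the rule-based RPS class assignment.

Decision order: percent GS > 50 -> class IV; else any KW lesion ->
class III; else the chosen mesangial feature against two ordinal
cutoffs -> I / IIa / IIb. Patients with GS% exactly 50 fall through to
the KW test (strict ">"). Early-class patients without a midsection
feature are explicitly unclassifiable (None), never silently defaulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .types import EARLY_CLASSES, RPSClass

__all__ = [
    "CLASSIFIER_FEATURES",
    "ROCResult",
    "EarlyCutoffs",
    "roc_curve",
    "optimal_cutoff",
    "fit_early_cutoffs",
    "assign_class",
    "assign_classes",
]

#: the three mesangium-related features eligible for early-class cutoffs
CLASSIFIER_FEATURES = (
    "mesangial_area_um2",
    "mesangial_area_fraction",
    "mesangial_area_per_mesangial_cell",
)


@dataclass(frozen=True)
class ROCResult:
    """ROC sweep: thresholds descending, TPR/FPR non-decreasing along it.

    A score >= threshold predicts positive; the leading +inf sentinel
    gives the (0, 0) corner.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Full ROC sweep and trapezoidal AUC for binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError(
            f"roc_curve requires both classes; labels contain only {present.tolist()}"
        )
    fpr, tpr, thr = skm.roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr))
    )


def optimal_cutoff(roc: ROCResult) -> float:
    """Threshold maximizing Youden's J = TPR - FPR, ties broken toward
    the smallest threshold."""
    j = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    j_max = j[finite].max()
    candidates = roc.thresholds[finite & (j >= j_max - 1e-12)]
    return float(candidates.min())


@dataclass(frozen=True)
class EarlyCutoffs:
    """Fitted ordinal cutoffs separating classes I / IIa / IIb on one
    mesangial feature (a patient at or above a cutoff is in the higher
    class)."""

    feature_name: str
    cutoff_I_vs_II: float
    cutoff_IIa_vs_IIb: float
    auc_I_vs_II: float
    auc_IIa_vs_IIb: float
    n: int

    def __post_init__(self) -> None:
        if self.feature_name not in CLASSIFIER_FEATURES:
            raise ValueError(
                f"feature_name must be one of {CLASSIFIER_FEATURES}, got {self.feature_name!r}"
            )
        if self.cutoff_I_vs_II > self.cutoff_IIa_vs_IIb:
            raise ValueError("cutoffs must be ordered: cutoff_I_vs_II <= cutoff_IIa_vs_IIb")

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "cutoff_I_vs_II": self.cutoff_I_vs_II,
            "cutoff_IIa_vs_IIb": self.cutoff_IIa_vs_IIb,
            "auc_I_vs_II": self.auc_I_vs_II,
            "auc_IIa_vs_IIb": self.auc_IIa_vs_IIb,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EarlyCutoffs":
        return cls(**{k: d[k] for k in (
            "feature_name", "cutoff_I_vs_II", "cutoff_IIa_vs_IIb",
            "auc_I_vs_II", "auc_IIa_vs_IIb", "n")})


def _feature_values(features, name: str) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[name].to_numpy(dtype=float)
    vals = []
    for f in features:
        vals.append(float(_get_feature(f, name)))
    return np.asarray(vals)


def _get_feature(f, name: str) -> float:
    if isinstance(f, (pd.Series, dict)):
        return f[name]
    return getattr(f, name)


def fit_early_cutoffs(features, pathologist_classes: Sequence, feature_name: str,
                      split: str = "one_vs_rest") -> EarlyCutoffs:
    """Fit the two ordinal cutoffs from early-class patients.

    *features* is a PatientFeatures sequence, DataFrame or mapping
    sequence restricted to pathologist classes I/IIa/IIb. The default
    ``one_vs_rest`` split fits (I | IIa+IIb) and (I+IIa | IIb); the
    ``adjacent`` variant fits (I | IIa) and (IIa | IIb) on the pair
    subsets. Patients with a missing (NaN) feature are dropped with a
    warning. Cutoffs violating ordinality are swapped with a warning.
    """
    if feature_name not in CLASSIFIER_FEATURES:
        raise ValueError(f"feature_name must be one of {CLASSIFIER_FEATURES}")
    if split not in ("one_vs_rest", "adjacent"):
        raise ValueError("split must be 'one_vs_rest' or 'adjacent'")
    classes = np.array([int(RPSClass.parse(c)) for c in pathologist_classes])
    if np.any(classes > int(RPSClass.IIb)):
        raise ValueError("fit_early_cutoffs accepts early classes (I, IIa, IIb) only")
    x = _feature_values(features, feature_name)
    if len(x) != len(classes):
        raise ValueError("features and classes must have equal length")
    ok = np.isfinite(x)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} patient(s) with a missing {feature_name} "
            "from cutoff fitting",
            stacklevel=2,
        )
        x, classes = x[ok], classes[ok]

    def _one_split(mask_neg, mask_pos, name: str):
        if not mask_pos.any() or not mask_neg.any():
            missing = "positive" if not mask_pos.any() else "negative"
            raise ValueError(f"split {name}: no patients on the {missing} side")
        sel = mask_neg | mask_pos
        roc = roc_curve(x[sel], mask_pos[sel].astype(int))
        return optimal_cutoff(roc), roc.auc

    e1, e2, e3 = (classes == int(c) for c in EARLY_CLASSES)
    if split == "one_vs_rest":
        c1, auc1 = _one_split(e1, e2 | e3, "I vs IIa+IIb")
        c2, auc2 = _one_split(e1 | e2, e3, "I+IIa vs IIb")
    else:
        c1, auc1 = _one_split(e1, e2, "I vs IIa")
        c2, auc2 = _one_split(e2, e3, "IIa vs IIb")
    for name, auc in (("I|II", auc1), ("IIa|IIb", auc2)):
        if auc < 0.55:
            warnings.warn(
                f"degenerate cutoff for split {name}: AUC {auc:.3f} is near chance",
                stacklevel=2,
            )
    if c1 > c2:
        warnings.warn(
            f"cutoffs violated ordinality ({c1:.4g} > {c2:.4g}); swapping",
            stacklevel=2,
        )
        c1, c2 = c2, c1
        auc1, auc2 = auc2, auc1
    return EarlyCutoffs(
        feature_name=feature_name,
        cutoff_I_vs_II=float(c1), cutoff_IIa_vs_IIb=float(c2),
        auc_I_vs_II=float(auc1), auc_IIa_vs_IIb=float(auc2),
        n=int(len(x)),
    )


def assign_class(f, cuts: EarlyCutoffs) -> Optional[RPSClass]:
    """Apply the decision tree to one patient's features.

    Returns None (unclassifiable) when the early-class branch is reached
    but the mesangial feature is missing.
    """
    percent_gs = float(_get_feature(f, "percent_GS"))
    if percent_gs > 50.0:
        return RPSClass.IV
    if bool(_get_feature(f, "has_KW")):
        return RPSClass.III
    value = float(_get_feature(f, cuts.feature_name))
    if not np.isfinite(value):
        return None
    if value < cuts.cutoff_I_vs_II:
        return RPSClass.I
    if value < cuts.cutoff_IIa_vs_IIb:
        return RPSClass.IIa
    return RPSClass.IIb


def assign_classes(features: pd.DataFrame, cuts: EarlyCutoffs) -> pd.Series:
    """Vectorized :func:`assign_class` over a patient-features table;
    unclassifiable rows get None."""
    out = [assign_class(row, cuts) for _, row in features.iterrows()]
    return pd.Series(
        [c.label if c is not None else None for c in out],
        index=features.index, name="rps_class",
    )
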