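"""Per-glomerulus and per-patient morphometric quantification.

Areas are pixel counts scaled by the squared pixel size; the glomerular
(tuft) area excludes the Bowman capsule ring. A glomerulus is
"midsection" when its three intrinsic cell types total at least 50
cells; per-patient intraglomerular means are taken over midsection
KW/NOA glomeruli only, while percent-type denominators include every
glomerulus of the patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CELL_TYPES, LESION_TYPES, MESANGIAL, TUFT, LabeledGlomerulus

__all__ = [
    "GlomerulusMorphometrics",
    "PatientFeatures",
    "MILD_EXPANSION_CUTOFF",
    "MIDSECTION_MIN_CELLS",
    "glomerulus_morphometrics",
    "is_midsection",
    "flag_mild_mesangial_expansion",
    "patient_aggregate",
    "aggregate_table",
    "compare_groups",
]

#: minimum total intrinsic cells for a midsection profile
MIDSECTION_MIN_CELLS = 50

#: mesangial area fraction below which expansion is "mild"
MILD_EXPANSION_CUTOFF = 0.2596

#: fields of GlomerulusMorphometrics averaged per patient
_MEAN_FIELDS = (
    "glomerular_area_um2", "mesangial_area_um2", "mesangial_area_fraction",
    "mesangial_cells", "endothelial_cells", "podocytes",
    "mesangial_area_per_mesangial_cell",
    "mesangial_cell_density", "endothelial_cell_density", "podocyte_density",
    "mesangial_cell_ratio", "endothelial_cell_ratio", "podocyte_ratio",
)


@dataclass(frozen=True)
class GlomerulusMorphometrics:
    """Quantities measured on one glomerulus.

    Densities are cells per μm² of tuft; ratios are per-type fractions of
    all intrinsic cells. Undefined ratios (zero mesangial cells, zero
    total cells) are NaN.
    """

    glomerular_area_um2: float
    mesangial_area_um2: float
    mesangial_area_fraction: float
    mesangial_cells: int
    endothelial_cells: int
    podocytes: int
    mesangial_area_per_mesangial_cell: float
    mesangial_cell_density: float
    endothelial_cell_density: float
    podocyte_density: float
    mesangial_cell_ratio: float
    endothelial_cell_ratio: float
    podocyte_ratio: float

    @property
    def total_cells(self) -> int:
        return self.mesangial_cells + self.endothelial_cells + self.podocytes

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class PatientFeatures:
    """Patient-level aggregate: percent glomeruli types over all glomeruli
    plus midsection-mean intraglomerular features (NaN when the patient
    has no midsection KW/NOA glomerulus)."""

    n_glomeruli: int
    percent_GS: float
    percent_SS: float
    percent_C: float
    percent_KW: float
    percent_NOA: float
    has_KW: bool
    n_midsection: int
    glomerular_area_um2: float
    mesangial_area_um2: float
    mesangial_area_fraction: float
    mesangial_cells: float
    endothelial_cells: float
    podocytes: float
    mesangial_area_per_mesangial_cell: float
    mesangial_cell_density: float
    endothelial_cell_density: float
    podocyte_density: float
    mesangial_cell_ratio: float
    endothelial_cell_ratio: float
    podocyte_ratio: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def glomerulus_morphometrics(g: LabeledGlomerulus) -> GlomerulusMorphometrics:
    """Measure areas, counts, densities and ratios on one labeled glomerulus."""
    if g.pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(g.mask)
    tuft_px = int(np.count_nonzero((mask == TUFT) | (mask == MESANGIAL)))
    if tuft_px == 0:
        raise ValueError("glomerulus has an empty tuft region")
    mes_px = int(np.count_nonzero(mask == MESANGIAL))
    px_area = g.pixel_size_um**2
    glom_area = tuft_px * px_area
    mes_area = mes_px * px_area

    counts = g.cell_counts()
    m, e, p = (counts[t] for t in CELL_TYPES)
    total = m + e + p
    return GlomerulusMorphometrics(
        glomerular_area_um2=glom_area,
        mesangial_area_um2=mes_area,
        mesangial_area_fraction=mes_px / tuft_px,
        mesangial_cells=m,
        endothelial_cells=e,
        podocytes=p,
        mesangial_area_per_mesangial_cell=mes_area / m if m > 0 else math.nan,
        mesangial_cell_density=m / glom_area,
        endothelial_cell_density=e / glom_area,
        podocyte_density=p / glom_area,
        mesangial_cell_ratio=m / total if total > 0 else math.nan,
        endothelial_cell_ratio=e / total if total > 0 else math.nan,
        podocyte_ratio=p / total if total > 0 else math.nan,
    )


def is_midsection(g, threshold: int = MIDSECTION_MIN_CELLS) -> bool:
    """True when the glomerulus carries at least *threshold* intrinsic cells.

    Accepts a :class:`LabeledGlomerulus` or a
    :class:`GlomerulusMorphometrics`.
    """
    if isinstance(g, GlomerulusMorphometrics):
        return g.total_cells >= threshold
    return sum(g.cell_counts().values()) >= threshold


def flag_mild_mesangial_expansion(mf: float, cutoff: float = MILD_EXPANSION_CUTOFF) -> bool:
    """True when the mesangial area fraction is strictly below the cutoff."""
    if not 0 <= mf <= 1:
        raise ValueError(f"mesangial area fraction must be in [0, 1], got {mf}")
    return mf < cutoff


def patient_aggregate(
    glomeruli: Sequence[tuple[LabeledGlomerulus, GlomerulusMorphometrics]],
) -> PatientFeatures:
    """Aggregate one patient's glomeruli into percent types and
    midsection-mean intraglomerular features.

    Percents are computed over *all* glomeruli; intraglomerular means only
    over midsection KW/NOA glomeruli (glomeruli weighted equally). When
    that subset is empty, every mean is NaN.
    """
    if len(glomeruli) == 0:
        raise ValueError("patient_aggregate requires at least one glomerulus")
    lesions = [g.lesion_type for g, _ in glomeruli]
    rows = []
    for (g, m) in glomeruli:
        row = m.to_dict()
        row["lesion_type"] = g.lesion_type
        rows.append(row)
    return _aggregate_rows(pd.DataFrame(rows), lesions)


def _aggregate_rows(df: pd.DataFrame, lesions: Sequence[str]) -> PatientFeatures:
    n = len(df)
    counts = pd.Series(lesions).value_counts()
    pct = {t: 100.0 * int(counts.get(t, 0)) / n for t in LESION_TYPES}

    total_cells = df["mesangial_cells"] + df["endothelial_cells"] + df["podocytes"]
    mid = df[df["lesion_type"].isin(["KW", "NOA"]) & (total_cells >= MIDSECTION_MIN_CELLS)]
    if len(mid) > 0:
        means = {f: float(np.nanmean(mid[f].to_numpy(dtype=float))) for f in _MEAN_FIELDS}
    else:
        means = {f: math.nan for f in _MEAN_FIELDS}
    return PatientFeatures(
        n_glomeruli=n,
        percent_GS=pct["GS"], percent_SS=pct["SS"], percent_C=pct["C"],
        percent_KW=pct["KW"], percent_NOA=pct["NOA"],
        has_KW=pct["KW"] > 0,
        n_midsection=len(mid),
        **means,
    )


def aggregate_table(glom_features: pd.DataFrame) -> pd.DataFrame:
    """Per-patient aggregation of a glomerulus-features table.

    Expects one row per glomerulus with at least ``patient_id``,
    ``lesion_type`` and the morphometric columns; returns one row per
    patient with a leading ``patient_id`` column.
    """
    required = {"patient_id", "lesion_type"} | set(_MEAN_FIELDS)
    missing = required - set(glom_features.columns)
    if missing:
        raise ValueError(f"glomerulus feature table is missing columns {sorted(missing)}")
    out = []
    for pid, grp in glom_features.groupby("patient_id", sort=True):
        feats = _aggregate_rows(grp, grp["lesion_type"].tolist())
        row = {"patient_id": pid}
        row.update(feats.to_dict())
        out.append(row)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    test: str


def compare_groups(values_by_group: Mapping, test: str = "mann_whitney") -> GroupComparison:
    """Rank-based inter-group comparison.

    ``mann_whitney`` expects exactly two groups (U statistic of the first
    group; exact p for small tie-free samples, normal approximation with
    tie correction otherwise). ``kruskal_wallis`` accepts two or more.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("compare_groups requires at least two groups")
    if any(g.size == 0 for g in groups.values()):
        raise ValueError("every group must be non-empty")
    samples = list(groups.values())
    if test == "mann_whitney":
        if len(samples) != 2:
            raise ValueError(
                f"mann_whitney compares exactly two groups, got {len(samples)}; "
                "use kruskal_wallis for more"
            )
        method = "exact" if max(s.size for s in samples) <= 20 else "asymptotic"
        try:
            res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided", method=method)
        except ValueError:
            # exact method rejects ties; fall back to the tie-corrected normal
            res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                   method="asymptotic")
        return GroupComparison(float(res.statistic), float(res.pvalue), test)
    if test == "kruskal_wallis":
        res = sps.kruskal(*samples)
        return GroupComparison(float(res.statistic), float(res.pvalue), test)
    raise ValueError(f"unknown test {test!r}; expected 'mann_whitney' or 'kruskal_wallis'")
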