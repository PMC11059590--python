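"""Synthetic input generators.

Everything downstream — morphometry, classification, evaluation and the
prognostic statistics — can be exercised on data produced here: labeled
glomerulus images with planted mesangial fractions and cell counts,
label "predictions" with a controlled confusion structure, mask
perturbations with a predictable Dice, and clinical cohorts with
class-dependent eGFR slopes, proteinuria levels and ESRD events.

All generators are deterministic under a fixed seed; randomness flows
from a single ``numpy.random.default_rng`` (or ``SeedSequence`` spawn
for per-glomerulus streams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    BACKGROUND,
    CAPSULE,
    CELL_COLUMNS,
    CELL_TYPES,
    LESION_TYPES,
    MESANGIAL,
    RPS_LABELS,
    TUFT,
    LabeledGlomerulus,
)

__all__ = [
    "InfeasibleSpecError",
    "GlomerulusSpec",
    "ConfusionSpec",
    "CohortSpec",
    "Cohort",
    "generate_glomerulus",
    "generate_prediction_labels",
    "perturb_mask",
    "generate_cohort",
    "generate_patient_glomeruli",
]


class InfeasibleSpecError(ValueError):
    """A generator spec that cannot be realized (target fraction >= 1,
    more cells than placeable sites, ...)."""


# ---------------------------------------------------------------------------
# glomerulus images
# ---------------------------------------------------------------------------

#: default per-lesion mesangial fraction targets and cell counts at a
#: reference tuft radius of 60 px; counts scale with tuft area.
_DEFAULT_MF = {"NOA": 0.25, "KW": 0.45, "SS": 0.35, "C": 0.30, "GS": 0.55}
_DEFAULT_CELLS_R60 = {
    "NOA": {"mesangial": 30, "endothelial": 30, "podocyte": 35},
    "KW": {"mesangial": 55, "endothelial": 32, "podocyte": 18},
    "SS": {"mesangial": 40, "endothelial": 28, "podocyte": 24},
    "C": {"mesangial": 35, "endothelial": 25, "podocyte": 22},
    "GS": {"mesangial": 45, "endothelial": 15, "podocyte": 8},
}


@dataclass(frozen=True)
class GlomerulusSpec:
    """Recipe for one synthetic glomerulus image."""

    lesion_type: str
    tuft_radius_px: int
    mesangial_fraction_target: float
    cell_counts: Mapping[str, int]
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(
                f"unknown lesion type {self.lesion_type!r}; expected one of {LESION_TYPES}"
            )
        if not (isinstance(self.tuft_radius_px, (int, np.integer)) and self.tuft_radius_px > 0):
            raise ValueError("tuft_radius_px must be a positive integer")
        if not 0 <= self.mesangial_fraction_target:
            raise ValueError("mesangial_fraction_target must be non-negative")
        if self.mesangial_fraction_target >= 1:
            raise InfeasibleSpecError(
                f"mesangial_fraction_target must be < 1, got {self.mesangial_fraction_target}"
            )
        if set(self.cell_counts) != set(CELL_TYPES):
            raise ValueError(f"cell_counts keys must be exactly {set(CELL_TYPES)}")
        if any(c < 0 for c in self.cell_counts.values()):
            raise ValueError("cell counts must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def default(cls, lesion_type: str, tuft_radius_px: int = 60,
                pixel_size_um: float = 0.25) -> "GlomerulusSpec":
        """Lesion-typical spec: KW draws carry more mesangium and fewer
        podocytes than an NOA draw at the same radius."""
        scale = (tuft_radius_px / 60.0) ** 2
        counts = {
            t: max(0, int(round(n * scale)))
            for t, n in _DEFAULT_CELLS_R60[lesion_type].items()
        }
        return cls(
            lesion_type=lesion_type,
            tuft_radius_px=tuft_radius_px,
            mesangial_fraction_target=_DEFAULT_MF[lesion_type],
            cell_counts=counts,
            pixel_size_um=pixel_size_um,
        )


def _grow_mesangium(tuft: np.ndarray, target_px: int, rng: np.random.Generator,
                    nodular: bool, center: tuple[int, int], radius: int) -> np.ndarray:
    """Union of irregular blobs inside *tuft* with exactly *target_px* pixels."""
    mes = np.zeros_like(tuft, dtype=bool)
    if target_px <= 0:
        return mes
    tuft_idx = np.flatnonzero(tuft)

    def _add_seed() -> None:
        free = np.flatnonzero(tuft & ~mes)
        if free.size == 0:
            return
        pick = free[rng.integers(free.size)]
        mes.flat[pick] = True

    if nodular:
        # plant a compact nodule off-center (Kimmelstiel-Wilson-like)
        rn = max(2, int(round(0.55 * math.sqrt(target_px / math.pi))))
        ang = rng.uniform(0, 2 * math.pi)
        off = radius * 0.45
        ny = int(round(center[0] + off * math.sin(ang)))
        nx = int(round(center[1] + off * math.cos(ang)))
        yy, xx = np.ogrid[: tuft.shape[0], : tuft.shape[1]]
        nod = (yy - ny) ** 2 + (xx - nx) ** 2 <= rn**2
        mes |= nod & tuft

    n_seeds = 3 if not nodular else 2
    for _ in range(n_seeds):
        _add_seed()

    struct = ndimage.generate_binary_structure(2, 2)
    while mes.sum() < target_px:
        ring = ndimage.binary_dilation(mes, structure=struct) & tuft & ~mes
        ring_idx = np.flatnonzero(ring)
        if ring_idx.size == 0:
            before = mes.sum()
            _add_seed()
            if mes.sum() == before:  # tuft saturated (cannot happen for target < tuft)
                break
            continue
        deficit = int(target_px - mes.sum())
        if ring_idx.size <= deficit:
            # keep boundaries irregular: accept a random ~70% subset, but
            # always at least one pixel so growth progresses
            keep = ring_idx[rng.random(ring_idx.size) < 0.7]
            if keep.size == 0:
                keep = ring_idx[[rng.integers(ring_idx.size)]]
            if keep.size > deficit:
                keep = rng.choice(keep, size=deficit, replace=False)
            mes.flat[keep] = True
        else:
            keep = rng.choice(ring_idx, size=deficit, replace=False)
            mes.flat[keep] = True
    assert int(mes.sum()) == target_px
    return mes


def _place_cells(mask: np.ndarray, counts: Mapping[str, int], rng: np.random.Generator,
                 min_sep: float = 2.0, max_tries: int = 300) -> pd.DataFrame:
    """Rejection-sample cell centroids on tuft pixels, pairwise distance >= min_sep."""
    domain = np.argwhere((mask == TUFT) | (mask == MESANGIAL))
    total = int(sum(counts.values()))
    if total == 0:
        return pd.DataFrame(columns=list(CELL_COLUMNS))
    # hexagonal packing at spacing 2 uses ~3.46 px^2 per centre; require slack
    if domain.shape[0] < 4 * total:
        raise InfeasibleSpecError(
            f"cannot place {total} cells with {min_sep} px separation on a "
            f"{domain.shape[0]}-pixel tuft"
        )
    placed: list[tuple[str, int, int]] = []
    pts = np.empty((0, 2), dtype=float)
    sep2 = min_sep**2
    for cell_type in CELL_TYPES:
        for _ in range(counts[cell_type]):
            for attempt in range(max_tries):
                r, c = domain[rng.integers(domain.shape[0])]
                if pts.size == 0 or np.min(np.sum((pts - (r, c)) ** 2, axis=1)) >= sep2:
                    placed.append((cell_type, int(r), int(c)))
                    pts = np.vstack([pts, (r, c)])
                    break
            else:
                raise InfeasibleSpecError(
                    f"failed to place cell {len(placed) + 1}/{total} after "
                    f"{max_tries} attempts; spec too dense"
                )
    return pd.DataFrame(placed, columns=list(CELL_COLUMNS))


def generate_glomerulus(spec: GlomerulusSpec, seed: int) -> LabeledGlomerulus:
    """Render one labeled glomerulus: disc tuft, annular Bowman capsule,
    blob-grown mesangium hitting the target pixel fraction exactly, and
    point cells rejection-sampled inside the tuft.
    """
    rng = np.random.default_rng(seed)
    r = spec.tuft_radius_px
    ring = max(2, r // 15)
    margin = 2
    n = 2 * (r + ring + margin) + 1
    cy = cx = n // 2

    yy, xx = np.ogrid[:n, :n]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = np.zeros((n, n), dtype=np.uint8)
    mask[d2 <= (r + ring) ** 2] = CAPSULE
    tuft = d2 <= r**2
    mask[tuft] = TUFT

    tuft_px = int(tuft.sum())
    target_px = int(round(spec.mesangial_fraction_target * tuft_px))
    mes = _grow_mesangium(
        tuft, target_px, rng,
        nodular=(spec.lesion_type == "KW"),
        center=(cy, cx), radius=r,
    )
    mask[mes] = MESANGIAL

    cells = _place_cells(mask, spec.cell_counts, rng)
    return LabeledGlomerulus(
        mask=mask, cells=cells, lesion_type=spec.lesion_type,
        pixel_size_um=spec.pixel_size_um,
    )


def perturb_mask(mask: np.ndarray, flip_fraction: float, seed: int,
                 target_code: int = MESANGIAL, fill_code: int = TUFT) -> np.ndarray:
    """Toggle ``round(flip_fraction * n)`` pixels of the target class
    against an equal-size border dilation.

    The perturbed class keeps its pixel count, so the Dice of the target
    class against the original is ``1 - flip_fraction`` up to rounding.
    """
    if not 0 <= flip_fraction <= 1:
        raise ValueError("flip_fraction must be in [0, 1]")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rng = np.random.default_rng(seed)
    member = mask == target_code
    n = int(member.sum())
    k = int(round(flip_fraction * n))
    out = mask.copy()
    if k == 0:
        return out
    # remove k target pixels
    idx = np.flatnonzero(member)
    drop = rng.choice(idx, size=k, replace=False)
    out.flat[drop] = fill_code
    # add k pixels from the dilation border (dilate further if needed)
    struct = ndimage.generate_binary_structure(2, 2)
    grown = member
    while True:
        grown = ndimage.binary_dilation(grown, structure=struct)
        ring = grown & ~member
        if ring.sum() >= k or ring.sum() == ring.size - n:
            break
    ring_idx = np.flatnonzero(ring)
    add = rng.choice(ring_idx, size=min(k, ring_idx.size), replace=False)
    out.flat[add] = target_code
    return out


# ---------------------------------------------------------------------------
# label predictions with planted confusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic true -> predicted transition matrix."""

    class_set: tuple
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_set", tuple(self.class_set))
        m = np.asarray(self.rate_matrix, dtype=float)
        object.__setattr__(self, "rate_matrix", m)
        k = len(self.class_set)
        if m.shape != (k, k):
            raise ValueError(f"rate_matrix must be {k}x{k}, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("rate_matrix entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every rate_matrix row must sum to 1 within 1e-9")

    @classmethod
    def identity(cls, class_set: Sequence) -> "ConfusionSpec":
        return cls(tuple(class_set), np.eye(len(class_set)))

    @classmethod
    def uniform_error(cls, class_set: Sequence, recall: float) -> "ConfusionSpec":
        """Diagonal *recall*, off-diagonal mass split evenly."""
        k = len(class_set)
        off = (1.0 - recall) / (k - 1) if k > 1 else 0.0
        m = np.full((k, k), off)
        np.fill_diagonal(m, recall if k > 1 else 1.0)
        return cls(tuple(class_set), m)


def generate_prediction_labels(true_types: Sequence, spec: ConfusionSpec, seed: int) -> list:
    """Draw one predicted label per true label from the matching matrix row."""
    rng = np.random.default_rng(seed)
    index = {c: i for i, c in enumerate(spec.class_set)}
    try:
        rows = np.array([index[t] for t in true_types], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; not in class_set {spec.class_set}") from None
    if rows.size == 0:
        return []
    cum = np.cumsum(spec.rate_matrix, axis=1)
    u = rng.random(rows.size)
    cols = np.array([np.searchsorted(cum[r], x, side="right") for r, x in zip(rows, u)])
    cols = np.minimum(cols, len(spec.class_set) - 1)
    return [spec.class_set[c] for c in cols]


# ---------------------------------------------------------------------------
# clinical cohorts
# ---------------------------------------------------------------------------


def _monotone(seq, direction: str) -> bool:
    d = np.diff(np.asarray(seq, dtype=float))
    return bool(np.all(d <= 1e-12)) if direction == "dec" else bool(np.all(d >= -1e-12))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated patient cohort.

    Per-class tuples are ordered (I, IIa, IIb, III, IV). Planted eGFR-slope
    locations must be non-increasing, podocyte locations non-increasing and
    mesangial locations non-decreasing across classes. Defaults plant
    class-wise slope and time-averaged-proteinuria levels on the reported
    clinical scale, with classes separated enough for parameter-recovery
    experiments.
    """

    n_patients: int
    class_probs: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    # morphometric feature locations per class
    mf_loc: tuple = (0.12, 0.22, 0.32, 0.42, 0.50)
    mf_scale: float = 0.03
    mes_area_loc: tuple = (800.0, 1400.0, 2200.0, 3000.0, 3600.0)
    mes_area_scale: float = 150.0
    mes_cells_loc: tuple = (25.0, 35.0, 45.0, 55.0, 60.0)
    podocytes_loc: tuple = (35.0, 30.0, 25.0, 18.0, 14.0)
    endothelial_loc: float = 30.0
    cell_scale: float = 3.0
    # clinical trajectories
    egfr_slope_loc: tuple = (-1.89, -2.5, -4.5, -11.6, -13.75)
    egfr_slope_scale: tuple = (0.8, 0.9, 1.2, 2.0, 2.5)
    tap_loc: tuple = (0.73, 1.41, 1.60, 3.92, 5.08)
    tap_sigma: float = 0.3
    baseline_egfr_loc: tuple = (95.0, 85.0, 75.0, 60.0, 45.0)
    baseline_egfr_scale: float = 8.0
    visit_interval_years: tuple = (0.25, 0.5)
    followup_years: tuple = (1.5, 3.5)
    egfr_noise_sd: float = 1.5
    proteinuria_noise_sigma: float = 0.15
    n_glomeruli: tuple = (8, 15)
    #: spread of glomerulus-level features around the patient mean, as a
    #: fraction of the patient value (intra-patient correlation is not
    #: reported anywhere; exposed rather than assumed)
    intra_patient_sd_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0):
            raise ValueError("class_probs must be a non-negative 5-vector")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1 within 1e-9")
        if not _monotone(self.egfr_slope_loc, "dec"):
            raise ValueError("planted eGFR-slope locations must be non-increasing I->IV")
        if not _monotone(self.podocytes_loc, "dec"):
            raise ValueError("planted podocyte locations must be non-increasing I->IV")
        if not _monotone(self.mes_cells_loc, "inc") or not _monotone(self.mf_loc, "inc"):
            raise ValueError("planted mesangial locations must be non-decreasing I->IV")


@dataclass
class Cohort:
    """Simulated cohort: per-patient feature rows and a long visits table."""

    patients: pd.DataFrame
    visits: pd.DataFrame


#: patients-table columns written by generate_cohort
PATIENT_COLUMNS = (
    "patient_id", "true_class", "n_glomeruli",
    "percent_GS", "percent_SS", "percent_C", "percent_KW", "percent_NOA",
    "has_KW", "n_midsection",
    "mesangial_area_um2", "mesangial_area_fraction",
    "mesangial_area_per_mesangial_cell",
    "mesangial_cells", "endothelial_cells", "podocytes",
    "baseline_egfr", "planted_egfr_slope",
)

VISIT_COLUMNS = (
    "patient_id", "time_years", "egfr", "proteinuria_g24h",
    "dialysis", "transplant", "esrd_flag",
)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort: each patient carries a planted RPS class,
    class-conditional morphometric features and a visit series whose
    noiseless trend slope equals the planted eGFR slope.
    """
    rng = np.random.default_rng(spec.seed)
    cls_idx = rng.choice(5, size=spec.n_patients, p=np.asarray(spec.class_probs))

    patient_rows = []
    visit_rows = []
    for i in range(spec.n_patients):
        c = int(cls_idx[i])
        pid = f"P{i:04d}"

        # percent glomeruli types consistent with the planted class
        if c == 4:  # IV: GS > 50%
            pgs = rng.uniform(52.0, 90.0)
            pkw = rng.uniform(0.0, 0.3 * (100.0 - pgs))
        elif c == 3:  # III: KW present, GS <= 50%
            pgs = rng.uniform(5.0, 45.0)
            pkw = rng.uniform(5.0, 30.0)
        else:  # early: no KW, GS <= 50%
            pgs = rng.uniform(0.0, 25.0)
            pkw = 0.0
        pss = rng.uniform(0.0, 5.0)
        pc = rng.uniform(0.0, 2.0)
        rest = 100.0 - pgs - pkw
        if pss + pc > rest:
            shrink = rest / (pss + pc + 1e-12)
            pss, pc = pss * shrink * 0.5, pc * shrink * 0.5
        pnoa = 100.0 - pgs - pkw - pss - pc

        mf = float(np.clip(rng.normal(spec.mf_loc[c], spec.mf_scale), 0.01, 0.95))
        mes_area = float(max(50.0, rng.normal(spec.mes_area_loc[c], spec.mes_area_scale)))
        mcells = float(max(1.0, rng.normal(spec.mes_cells_loc[c], spec.cell_scale)))
        ecells = float(max(0.0, rng.normal(spec.endothelial_loc, spec.cell_scale)))
        pcells = float(max(0.0, rng.normal(spec.podocytes_loc[c], spec.cell_scale)))

        slope = float(rng.normal(spec.egfr_slope_loc[c], spec.egfr_slope_scale[c]))
        baseline = float(np.clip(rng.normal(spec.baseline_egfr_loc[c], spec.baseline_egfr_scale), 20.0, 130.0))
        n_glom = int(rng.integers(spec.n_glomeruli[0], spec.n_glomeruli[1] + 1))

        patient_rows.append((
            pid, RPS_LABELS[c], n_glom,
            pgs, pss, pc, pkw, pnoa,
            pkw > 0, n_glom,  # cohort-level features are already midsection means
            mes_area, mf, mes_area / mcells,
            mcells, ecells, pcells,
            baseline, slope,
        ))

        # visit schedule: baseline plus jittered 3-6 month intervals
        followup = rng.uniform(*spec.followup_years)
        times = [0.0]
        while times[-1] + spec.visit_interval_years[0] <= followup:
            times.append(times[-1] + rng.uniform(*spec.visit_interval_years))
        times = np.asarray(times)
        trend = baseline + slope * times
        egfr = np.maximum(2.0, trend + (rng.normal(0.0, spec.egfr_noise_sd, times.size)
                                        if spec.egfr_noise_sd > 0 else 0.0))
        p0 = spec.tap_loc[c] * math.exp(rng.normal(0.0, spec.tap_sigma))
        prot = p0 * np.exp(rng.normal(0.0, spec.proteinuria_noise_sigma, times.size)
                           if spec.proteinuria_noise_sigma > 0 else np.zeros(times.size))
        for t, e, p in zip(times, egfr, prot):
            visit_rows.append((pid, float(t), float(e), float(p), 0, 0, int(e < 15.0)))

    patients = pd.DataFrame(patient_rows, columns=list(PATIENT_COLUMNS))
    visits = pd.DataFrame(visit_rows, columns=list(VISIT_COLUMNS))
    return Cohort(patients=patients, visits=visits)


# lesion-type draw probabilities per planted class (I, IIa, IIb, III, IV)
_CLASS_TYPE_PROBS = {
    0: {"GS": 0.08, "SS": 0.02, "C": 0.01, "KW": 0.0, "NOA": 0.89},
    1: {"GS": 0.10, "SS": 0.03, "C": 0.01, "KW": 0.0, "NOA": 0.86},
    2: {"GS": 0.15, "SS": 0.03, "C": 0.01, "KW": 0.0, "NOA": 0.81},
    3: {"GS": 0.20, "SS": 0.03, "C": 0.01, "KW": 0.30, "NOA": 0.46},
    4: {"GS": 0.75, "SS": 0.02, "C": 0.01, "KW": 0.07, "NOA": 0.15},
}


def generate_patient_glomeruli(rps_class, n_glomeruli: int, seed: int,
                               tuft_radius_px: int = 40,
                               pixel_size_um: float = 0.25,
                               mf_loc: Sequence[float] = (0.12, 0.22, 0.32, 0.42, 0.50),
                               intra_patient_sd: float = 0.03) -> list[LabeledGlomerulus]:
    """Image-level counterpart of :func:`generate_cohort`: draw a patient's
    glomeruli with class-conditional lesion types and mesangial fractions.

    KW/NOA glomeruli inherit the patient class's mesangial-fraction
    location so that patient aggregation recovers the planted separation.
    """
    from .types import RPSClass

    c = int(RPSClass.parse(rps_class)) - 1
    if n_glomeruli < 1:
        raise ValueError("n_glomeruli must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    probs = _CLASS_TYPE_PROBS[c]
    types = rng.choice(list(probs), size=n_glomeruli, p=list(probs.values()))
    # class IV must satisfy percent GS > 50, class III must carry a KW lesion
    if c == 4 and (types == "GS").mean() <= 0.5:
        need = int(np.floor(n_glomeruli / 2)) + 1
        types[:need] = "GS"
    if c == 3 and not np.any(types == "KW"):
        types[0] = "KW"

    gloms = []
    child_seeds = ss.spawn(n_glomeruli)
    for t, child in zip(types, child_seeds):
        # cells are points, so counts need not scale with the canvas:
        # keep the full per-lesion templates so KW/NOA draws stay above
        # the 50-cell midsection threshold at any radius
        base = GlomerulusSpec(
            lesion_type=str(t), tuft_radius_px=tuft_radius_px,
            mesangial_fraction_target=_DEFAULT_MF[str(t)],
            cell_counts=dict(_DEFAULT_CELLS_R60[str(t)]),
            pixel_size_um=pixel_size_um,
        )
        mf = base.mesangial_fraction_target
        if t in ("KW", "NOA"):
            mf = float(np.clip(rng.normal(mf_loc[c], intra_patient_sd), 0.01, 0.9))
        spec = GlomerulusSpec(
            lesion_type=str(t), tuft_radius_px=tuft_radius_px,
            mesangial_fraction_target=mf, cell_counts=dict(base.cell_counts),
            pixel_size_um=pixel_size_um,
        )
        gloms.append(generate_glomerulus(spec, int(child.generate_state(1)[0])))
    return gloms
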