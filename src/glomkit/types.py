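"""Shared domain types and constants.

Label masks use the integer code set ``{0, 1, 2, 3}``:

=====  =====================
code   meaning
=====  =====================
0      background
1      Bowman capsule ring
2      glomerular tuft tissue
3      mesangial region
=====  =====================

The mesangial region is always a subset of the tuft, so "glomerular
(tuft) area" is the pixel count of codes ``{2, 3}``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: label-mask codes
BACKGROUND = 0
CAPSULE = 1
TUFT = 2
MESANGIAL = 3
MASK_CODES = (BACKGROUND, CAPSULE, TUFT, MESANGIAL)

#: glomerulus lesion types: global sclerosis, segmental sclerosis,
#: crescent, Kimmelstiel-Wilson nodule, none-of-the-above
LESION_TYPES = ("GS", "SS", "C", "KW", "NOA")

#: intrinsic glomerular cell types
CELL_TYPES = ("mesangial", "endothelial", "podocyte")

#: cells table column layout
CELL_COLUMNS = ("cell_type", "row", "col")


class RPSClass(enum.IntEnum):
    """Ordinal RPS lesion class, I < IIa < IIb < III < IV."""

    I = 1
    IIa = 2
    IIb = 3
    III = 4
    IV = 5

    @property
    def label(self) -> str:
        return self.name

    @classmethod
    def parse(cls, value) -> "RPSClass":
        """Coerce a label (``"IIa"``), ordinal (``2``) or member to a member."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        try:
            return cls[str(value)]
        except KeyError:
            raise ValueError(
                f"unknown RPS class {value!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


RPS_LABELS = tuple(m.name for m in RPSClass)
EARLY_CLASSES = (RPSClass.I, RPSClass.IIa, RPSClass.IIb)


@dataclass
class LabeledGlomerulus:
    """One glomerulus: label mask, cell-instance table and lesion tag.

    ``cells`` is a DataFrame with columns ``cell_type, row, col``;
    centroids are 0-based pixel coordinates inside the tuft.
    """

    mask: np.ndarray
    cells: pd.DataFrame
    lesion_type: str
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(
                f"unknown lesion type {self.lesion_type!r}; "
                f"expected one of {LESION_TYPES}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not isinstance(self.cells, pd.DataFrame):
            self.cells = pd.DataFrame(self.cells, columns=list(CELL_COLUMNS))

    def cell_counts(self) -> dict[str, int]:
        """Number of cells per intrinsic type (absent types count 0)."""
        vc = self.cells["cell_type"].value_counts()
        return {t: int(vc.get(t, 0)) for t in CELL_TYPES}


def validate_mask_codes(mask: np.ndarray) -> None:
    """Raise if *mask* contains codes outside {0, 1, 2, 3}."""
    codes = np.unique(np.asarray(mask))
    bad = sorted(int(c) for c in codes if c not in MASK_CODES)
    if bad:
        raise ValueError(f"mask contains unknown label codes {bad}; allowed {list(MASK_CODES)}")


@dataclass
class ClinicalTrajectory:
    """Longitudinal eGFR / proteinuria visits for one patient.

    Times are years from biopsy; the first visit is the baseline at t=0.
    ``proteinuria`` may contain NaN for visits without a measurement.
    """

    patient_id: str
    times: np.ndarray
    egfr: np.ndarray
    proteinuria: np.ndarray
    dialysis: np.ndarray = field(default=None)  # type: ignore[assignment]
    transplant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.egfr = np.asarray(self.egfr, dtype=float)
        self.proteinuria = np.asarray(self.proteinuria, dtype=float)
        n = len(self.times)
        if self.dialysis is None:
            self.dialysis = np.zeros(n, dtype=bool)
        if self.transplant is None:
            self.transplant = np.zeros(n, dtype=bool)
        self.dialysis = np.asarray(self.dialysis, dtype=bool)
        self.transplant = np.asarray(self.transplant, dtype=bool)
        if not (len(self.egfr) == len(self.proteinuria) == len(self.dialysis) == len(self.transplant) == n):
            raise ValueError("visit arrays must have equal length")
        if n == 0:
            raise ValueError("trajectory must contain at least one visit")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("visit times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError("first visit must be the baseline at time 0")
        if np.any(self.egfr <= 0):
            raise ValueError("eGFR values must be positive")

    @property
    def baseline_egfr(self) -> float:
        return float(self.egfr[0])

    @property
    def baseline_proteinuria(self) -> float:
        return float(self.proteinuria[0])

    @property
    def followup_years(self) -> float:
        return float(self.times[-1] - self.times[0])

    @classmethod
    def from_frame(cls, patient_id: str, frame: pd.DataFrame) -> "ClinicalTrajectory":
        """Build from a visits table slice (columns ``time_years, egfr, proteinuria_g24h``
        and optional ``dialysis, transplant``)."""
        frame = frame.sort_values("time_years")
        return cls(
            patient_id=str(patient_id),
            times=frame["time_years"].to_numpy(),
            egfr=frame["egfr"].to_numpy(),
            proteinuria=frame["proteinuria_g24h"].to_numpy(),
            dialysis=frame["dialysis"].to_numpy() if "dialysis" in frame else None,
            transplant=frame["transplant"].to_numpy() if "transplant" in frame else None,
        )
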