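"""Reading and writing DCE-MRI series, region masks, and cohort tables.

All volumes are NIfTI-1 (via nibabel) on a single shared voxel grid; no
resampling or registration is performed here — masks must already live on
the series' grid.  Cohort tables are plain CSV with the column schema in
:data:`COHORT_COLUMNS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    EmptyRegionError,
    GridMismatchError,
    InvalidSpecError,
    PhaseCountError,
)

logger = logging.getLogger("bpequant")

#: Acquisition times (seconds) of the precontrast phase and the four
#: postcontrast phases: first postcontrast at 120 s, then every 90 s.
DEFAULT_PHASE_TIMES: tuple[float, ...] = (0.0, 120.0, 210.0, 300.0, 390.0)

#: Study group labels: women below the 20% lifetime-risk threshold,
#: high-risk women without a BRCA1/2 mutation, and BRCA1/2 carriers.
GROUPS: tuple[str, ...] = ("nonhigh", "high_nonbrca", "brca")

#: The six per-subject quantitative BPE measurements (percent units).
MEASURE_COLUMNS: tuple[str, ...] = (
    "pe_fgt",
    "pe_breast",
    "ser_fgt",
    "ser_breast",
    "ier",
    "der",
)

#: Cohort CSV schema: identifier, group label, clinical covariates,
#: radiologist FGT/BPE grades (ordinal 1-4), then the six measurements.
COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "group",
    "age",
    "bmi",
    "menopausal",
    "hormone_tx",
    "fgt_level",
    "bpe_category",
) + MEASURE_COLUMNS


@dataclass(frozen=True)
class DceSeries:
    """A 4-D dynamic contrast-enhanced series.

    Parameters
    ----------
    signal
        Non-negative intensities, shape ``(x, y, z, n_phases)``; phase 0 is
        the precontrast acquisition.
    phase_times
        Acquisition time of each phase in seconds, strictly increasing,
        starting at 0.
    voxel_spacing
        Voxel size in mm.
    """

    signal: np.ndarray
    phase_times: tuple[float, ...]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 4:
            raise GridMismatchError(f"signal must be 4-D, got shape {sig.shape}")
        times = tuple(float(t) for t in self.phase_times)
        if sig.shape[3] != len(times):
            raise GridMismatchError(
                f"{sig.shape[3]} phases but {len(times)} phase times"
            )
        if len(times) < 2:
            raise PhaseCountError("a DCE series needs at least 2 phases")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidSpecError(f"phase_times must be strictly increasing: {times}")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "phase_times", times)
        object.__setattr__(
            self, "voxel_spacing", tuple(float(s) for s in self.voxel_spacing)
        )

    @property
    def n_phases(self) -> int:
        return self.signal.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass(frozen=True)
class RegionMasks:
    """Co-registered binary breast and FGT masks; FGT is nested in breast."""

    breast: np.ndarray
    fgt: np.ndarray

    def __post_init__(self):
        breast = np.asarray(self.breast, dtype=bool)
        fgt = np.asarray(self.fgt, dtype=bool)
        if breast.shape != fgt.shape or breast.ndim != 3:
            raise GridMismatchError(
                f"mask grids differ: breast {breast.shape}, fgt {fgt.shape}"
            )
        if not breast.any():
            raise EmptyRegionError("breast mask is empty")
        if not fgt.any():
            raise EmptyRegionError("FGT mask is empty")
        if (fgt & ~breast).any():
            raise InvalidSpecError(
                "FGT mask extends outside the breast mask; "
                "use read_masks(..., repair=True) or intersect beforehand"
            )
        object.__setattr__(self, "breast", breast)
        object.__setattr__(self, "fgt", fgt)


def read_series(
    paths: str | Path | Sequence[str | Path],
    phase_times: Sequence[float] | None = None,
) -> DceSeries:
    """Load a DCE series from one 4-D NIfTI or an ordered list of 3-D NIfTIs.

    Negative intensities are clipped to zero with a logged warning.  When
    ``phase_times`` is omitted the protocol default
    :data:`DEFAULT_PHASE_TIMES` is used if the phase count matches.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    imgs = [nib.load(str(p)) for p in paths]
    vols: list[np.ndarray] = []
    for img in imgs:
        arr = np.asanyarray(img.dataobj, dtype=float)
        if arr.ndim == 4:
            vols.extend(arr[..., i] for i in range(arr.shape[3]))
        elif arr.ndim == 3:
            vols.append(arr)
        else:
            raise GridMismatchError(f"expected 3-D or 4-D volume, got {arr.ndim}-D")
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise GridMismatchError(f"phase volumes have mismatched grids: {sorted(shapes)}")
    if len(vols) < 2:
        raise PhaseCountError(f"need >= 2 phases, got {len(vols)}")
    sig = np.stack(vols, axis=-1)
    n_neg = int((sig < 0).sum())
    if n_neg:
        logger.warning("clipping %d negative intensities to 0", n_neg)
        sig = np.clip(sig, 0.0, None)
    if phase_times is None:
        if len(vols) != len(DEFAULT_PHASE_TIMES):
            raise InvalidSpecError(
                f"{len(vols)} phases: supply phase_times explicitly "
                f"(default covers {len(DEFAULT_PHASE_TIMES)})"
            )
        phase_times = DEFAULT_PHASE_TIMES
    zooms = imgs[0].header.get_zooms()[:3]
    return DceSeries(sig, tuple(phase_times), tuple(float(z) for z in zooms))


def write_series(series: DceSeries, path: str | Path) -> None:
    """Write the series as one 4-D NIfTI with voxel spacing in the header."""
    affine = np.diag(list(series.voxel_spacing) + [1.0])
    img = nib.Nifti1Image(series.signal.astype(np.float64), affine)
    img.header.set_zooms(series.voxel_spacing + (1.0,))
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, path: str | Path, voxel_spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_masks(
    breast_path: str | Path,
    fgt_path: str | Path,
    series: DceSeries,
    repair: bool = False,
) -> RegionMasks:
    """Load breast and FGT masks and validate them against the series grid.

    With ``repair=True`` any FGT voxel outside the breast is intersected
    away (logged); otherwise nesting violations raise.
    """
    breast = np.asanyarray(nib.load(str(breast_path)).dataobj) > 0
    fgt = np.asanyarray(nib.load(str(fgt_path)).dataobj) > 0
    if breast.shape != series.grid_shape or fgt.shape != series.grid_shape:
        raise GridMismatchError(
            f"mask grids {breast.shape}/{fgt.shape} do not match "
            f"series grid {series.grid_shape}"
        )
    stray = fgt & ~breast
    if stray.any() and repair:
        logger.warning(
            "intersecting %d FGT voxels outside the breast mask", int(stray.sum())
        )
        fgt = fgt & breast
    return RegionMasks(breast, fgt)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV and validate the schema and value ranges."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "bpe_category"]
    if missing:
        raise InvalidSpecError(f"cohort table missing columns: {missing}")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise InvalidSpecError(f"unknown group labels: {sorted(bad_groups)}")
    if not df["fgt_level"].isin([1, 2, 3, 4]).all():
        raise InvalidSpecError("fgt_level must be in {1,2,3,4}")
    if (df["age"] <= 0).any() or (df["bmi"] <= 0).any():
        raise InvalidSpecError("age and bmi must be positive")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)
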