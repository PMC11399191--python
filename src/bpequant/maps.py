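"""Voxelwise PE / SER enhancement maps and region-fraction BPE summaries.

Definitions
-----------
At a voxel with precontrast signal ``S_pre``, early-phase signal
``S_early`` and delayed-phase signal ``S_delayed``:

    PE  = 100 * (S_early - S_pre) / S_pre          (percent enhancement)
    SER = (S_early - S_pre) / (S_delayed - S_pre)  (signal enhancement ratio)

PE is defined wherever ``S_pre`` exceeds a small epsilon; SER only on
*enhancing* voxels — those whose PE reaches the voxel threshold — with a
positive delayed-enhancement denominator.  The four region measurements
are volume fractions: the percent of region voxels (FGT mask or whole
breast mask) whose PE exceeds the PE threshold (default 30%), and whose
SER exceeds the SER threshold (default 0.90), respectively.  Voxels with
undefined PE or SER count in the denominator only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, GridMismatchError, InvalidSpecError, PhaseIndexError
from .io import DceSeries, RegionMasks
from .kinetics import ier_der, principal_timecourse


@dataclass(frozen=True)
class ThresholdConfig:
    """Voxel thresholds and numerical guards for BPE quantification.

    pe_threshold : percent; a voxel is *enhancing* when PE >= this.
    ser_threshold : ratio; an enhancing voxel shows plateau/washout
        kinetics when SER >= this.
    epsilon : signal-units guard on divisions; ``None`` means
        1e-6 x the median precontrast signal of each series.
    ser_denominator : "region" counts SER-positive voxels against all
        region voxels; "enhancing" against enhancing region voxels only.
    summary : "fraction" is the volume-fraction summary; "median" is an
        alternative that reports the median map value over enhancing
        region voxels.
    """

    pe_threshold: float = 30.0
    ser_threshold: float = 0.90
    epsilon: float | None = None
    ser_denominator: str = "region"
    summary: str = "fraction"

    def __post_init__(self):
        if self.pe_threshold <= 0 or self.ser_threshold <= 0:
            raise InvalidSpecError("thresholds must be positive")
        if self.ser_denominator not in ("region", "enhancing"):
            raise InvalidSpecError("ser_denominator must be 'region' or 'enhancing'")
        if self.summary not in ("fraction", "median"):
            raise InvalidSpecError("summary must be 'fraction' or 'median'")

    def resolve_epsilon(self, series: DceSeries) -> float:
        if self.epsilon is not None:
            return float(self.epsilon)
        med = float(np.median(series.signal[..., 0]))
        return 1e-6 * med if med > 0 else 1e-12


@dataclass(frozen=True)
class EnhancementMaps:
    """PE map (percent, NaN where undefined), SER map with validity mask,
    and the phase indices they were computed from."""

    pe: np.ndarray
    ser: np.ndarray
    ser_valid: np.ndarray
    early_phase_index: int
    delayed_phase_index: int


@dataclass(frozen=True)
class BpeMeasures:
    """The six per-subject quantitative BPE values, all in percent."""

    pe_fgt: float
    pe_breast: float
    ser_fgt: float
    ser_breast: float
    ier: float
    der: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pe_fgt": self.pe_fgt, "pe_breast": self.pe_breast,
            "ser_fgt": self.ser_fgt, "ser_breast": self.ser_breast,
            "ier": self.ier, "der": self.der,
        }


def _check_phase(series: DceSeries, idx: int, name: str) -> int:
    idx = int(idx)
    if not 1 <= idx <= series.n_phases - 1:
        raise PhaseIndexError(
            f"{name} phase index {idx} out of range [1, {series.n_phases - 1}]"
        )
    return idx


def compute_pe_map(
    series: DceSeries, early_phase_index: int = 1, epsilon: float | None = None
) -> np.ndarray:
    """Percent-enhancement map at the early phase; NaN where the
    precontrast signal is below epsilon.  Negative PE is preserved."""
    e = _check_phase(series, early_phase_index, "early")
    eps = ThresholdConfig(epsilon=epsilon).resolve_epsilon(series)
    s_pre = series.signal[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = 100.0 * (series.signal[..., e] - s_pre) / s_pre
    pe = np.where(s_pre > eps, pe, np.nan)
    return pe


def compute_ser_map(
    series: DceSeries,
    early_phase_index: int = 1,
    delayed_phase_index: int | None = None,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Signal-enhancement-ratio map and its validity mask.

    SER is evaluated only on enhancing voxels (PE >= cfg.pe_threshold)
    with precontrast signal and delayed enhancement above epsilon;
    everywhere else the map is NaN and the validity mask False.
    """
    e = _check_phase(series, early_phase_index, "early")
    d = series.n_phases - 1 if delayed_phase_index is None else int(delayed_phase_index)
    d = _check_phase(series, d, "delayed")
    if e >= d:
        raise PhaseIndexError(f"early phase {e} must precede delayed phase {d}")
    eps = cfg.resolve_epsilon(series)
    s_pre = series.signal[..., 0]
    num = series.signal[..., e] - s_pre
    den = series.signal[..., d] - s_pre
    pe = compute_pe_map(series, e, epsilon=eps)
    valid = (s_pre > eps) & (den > eps) & np.isfinite(pe) & (pe >= cfg.pe_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        ser = np.where(valid, num / den, np.nan)
    return ser, valid


def compute_enhancement_maps(
    series: DceSeries,
    early_phase_index: int = 1,
    delayed_phase_index: int | None = None,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> EnhancementMaps:
    e = _check_phase(series, early_phase_index, "early")
    d = series.n_phases - 1 if delayed_phase_index is None else int(delayed_phase_index)
    pe = compute_pe_map(series, e, epsilon=cfg.epsilon)
    ser, valid = compute_ser_map(series, e, d, cfg)
    return EnhancementMaps(pe, ser, valid, e, d)


def _region_summary(maps: EnhancementMaps, region: np.ndarray, cfg: ThresholdConfig
                    ) -> tuple[float, float]:
    n = int(region.sum())
    if n == 0:
        raise EmptyRegionError("region mask is empty")
    pe = maps.pe[region]
    ser = maps.ser[region]
    valid = maps.ser_valid[region]
    enhancing = np.isfinite(pe) & (pe >= cfg.pe_threshold)
    ser_hit = valid & np.isfinite(ser) & (ser >= cfg.ser_threshold)
    if cfg.summary == "median":
        pe_val = float(np.median(pe[enhancing])) if enhancing.any() else 0.0
        ser_val = float(np.median(ser[ser_hit])) if ser_hit.any() else 0.0
        return pe_val, ser_val
    pe_frac = 100.0 * enhancing.sum() / n
    ser_den = int(enhancing.sum()) if cfg.ser_denominator == "enhancing" else n
    ser_frac = 100.0 * ser_hit.sum() / ser_den if ser_den else 0.0
    return float(pe_frac), float(ser_frac)


def summarize_regions(
    maps: EnhancementMaps, masks: RegionMasks, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[float, float, float, float]:
    """(PE_FGT, PE_Breast, SER_FGT, SER_Breast) in percent."""
    if maps.pe.shape != masks.breast.shape:
        raise GridMismatchError(
            f"map grid {maps.pe.shape} does not match mask grid {masks.breast.shape}"
        )
    pe_fgt, ser_fgt = _region_summary(maps, masks.fgt, cfg)
    pe_breast, ser_breast = _region_summary(maps, masks.breast, cfg)
    return pe_fgt, pe_breast, ser_fgt, ser_breast


def quantify_subject(
    series: DceSeries,
    masks: RegionMasks,
    cfg: ThresholdConfig = ThresholdConfig(),
    early_phase_index: int = 1,
    delayed_phase_index: int | None = None,
) -> BpeMeasures:
    """All six BPE measurements for one subject: the four region
    fractions plus IER/DER from the principal FGT kinetic eigenvector."""
    maps = compute_enhancement_maps(series, early_phase_index, delayed_phase_index, cfg)
    pe_fgt, pe_breast, ser_fgt, ser_breast = summarize_regions(maps, masks, cfg)
    eig = principal_timecourse(series, masks.fgt)
    ier, der = ier_der(eig, series.phase_times)
    return BpeMeasures(pe_fgt, pe_breast, ser_fgt, ser_breast, ier, der)


def threshold_phase_sweep(
    subjects: Sequence[tuple[DceSeries, RegionMasks]],
    groups: Sequence[str],
    thresholds: Sequence[float] = tuple(range(10, 100, 10)),
    early_phases: Sequence[int] = (1,),
    delayed_phases: Sequence[int] | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
    cfg: ThresholdConfig = ThresholdConfig(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sensitivity sweep over PE thresholds and phase choices.

    For every grid point (pe_threshold, early phase, delayed phase) the
    four region measures are recomputed per subject and each group pair
    is compared per measure with a two-sided Mann-Whitney U-test.  The
    returned tidy table (one row per grid point x measure x comparison)
    reports *unadjusted* p-values with the reference significance level
    recorded in the ``alpha_ref`` column; it is the data behind a
    Manhattan-style profile plot.
    """
    from .stats import mann_whitney  # local import: stats also imports nothing here

    if len(subjects) != len(groups):
        raise InvalidSpecError("one group label per subject required")
    thresholds = [float(t) for t in thresholds]
    if not thresholds or any(t <= 0 for t in thresholds):
        raise InvalidSpecError("thresholds must be a non-empty positive list")
    if not early_phases:
        raise InvalidSpecError("early_phases must be non-empty")
    n_phases = subjects[0][0].n_phases
    if delayed_phases is None:
        delayed_phases = [n_phases - 1]
    groups = list(groups)
    if comparisons is None:
        uniq = sorted(set(groups))
        comparisons = list(itertools.combinations(uniq, 2))
    measure_names = ("pe_fgt", "pe_breast", "ser_fgt", "ser_breast")
    rows = []
    for thr, e, d in itertools.product(thresholds, early_phases, delayed_phases):
        if e >= d:
            continue
        point_cfg = ThresholdConfig(
            pe_threshold=thr, ser_threshold=cfg.ser_threshold, epsilon=cfg.epsilon,
            ser_denominator=cfg.ser_denominator, summary=cfg.summary,
        )
        vals = np.array(
            [
                summarize_regions(
                    compute_enhancement_maps(s, e, d, point_cfg), m, point_cfg
                )
                for s, m in subjects
            ]
        )
        for (ga, gb), (j, meas) in itertools.product(
            comparisons, enumerate(measure_names)
        ):
            xa = vals[[g == ga for g in groups], j]
            xb = vals[[g == gb for g in groups], j]
            res = mann_whitney(xa, xb)
            rows.append(
                {"pe_threshold": thr, "early_phase": e, "delayed_phase": d,
                 "measure": meas, "comparison": f"{ga}_vs_{gb}",
                 "p_unadjusted": res.p, "alpha_ref": alpha}
            )
    return pd.DataFrame(rows)
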