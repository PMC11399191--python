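"""Principal kinetic eigenvector of FGT voxel time courses; IER and DER.

The time courses of all FGT voxels with positive precontrast signal are
stacked into an ``n_voxels x n_phases`` matrix and decomposed *without
mean-centering*: the leading right singular vector of the raw matrix is
a time course on the signal scale, so its precontrast component is a
meaningful baseline and the ratios against it are percent enhancements.
(Mean-centering would subtract the baseline and leave a near-zero
precontrast component, making those ratios ill-defined; the uncentered
convention is therefore deliberate and isolated here so it can be
swapped.)  The sign is fixed so the precontrast component is positive.

IER (initial enhancement ratio) is the percent increase of the
eigenvector at the 120-s early postcontrast phase over precontrast; DER
(delayed enhancement ratio) the same at the 390-s delayed phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError

logger = logging.getLogger("bpequant")


@dataclass(frozen=True)
class KineticEigenvector:
    """Leading uncentered principal component of the FGT time courses.

    ``timecourse`` has unit Euclidean norm and positive precontrast
    component; ``eigenvalue`` is the squared leading singular value and
    ``variance_fraction`` its share of the total squared norm.
    """

    timecourse: np.ndarray
    eigenvalue: float
    variance_fraction: float
    n_voxels_used: int


def principal_timecourse(series, fgt_mask: np.ndarray) -> KineticEigenvector:
    """Leading right singular vector of the uncentered FGT voxel matrix.

    Voxels with non-positive precontrast signal are excluded.  Raises
    :class:`InsufficientDataError` when fewer valid voxels than phases
    remain and :class:`DegenerateDataError` on an all-zero matrix.
    """
    mask = np.asarray(fgt_mask, dtype=bool)
    x = series.signal[mask]  # (n_voxels, n_phases)
    x = x[x[:, 0] > 0]
    n, p = x.shape
    if n < p:
        raise InsufficientDataError(
            f"{n} valid FGT voxels but {p} phases; need n >= p"
        )
    # p x p second-moment matrix: cheap regardless of voxel count
    m = x.T @ x
    total = float(np.trace(m))
    if total <= 0:
        raise DegenerateDataError("all-zero voxel matrix")
    evals, evecs = np.linalg.eigh(m)
    lead = float(evals[-1])
    v = evecs[:, -1]
    # orient: positive precontrast component, ties resolved by positive sum
    if v[0] < 0 or (v[0] == 0 and v.sum() < 0):
        v = -v
    return KineticEigenvector(
        timecourse=v,
        eigenvalue=lead,
        variance_fraction=lead / total,
        n_voxels_used=n,
    )


def ier_der(
    eig: KineticEigenvector,
    phase_times: Sequence[float],
    early_time: float = 120.0,
    delayed_time: float = 390.0,
    eps: float = 1e-12,
) -> tuple[float, float]:
    """(IER, DER) in percent from an oriented kinetic eigenvector.

    The phases nearest to ``early_time`` and ``delayed_time`` are used;
    a note is logged when no exact match exists.
    """
    v = np.asarray(eig.timecourse, dtype=float)
    times = np.asarray(phase_times, dtype=float)
    if v.shape[0] != times.shape[0]:
        raise DegenerateDataError(
            f"eigenvector length {v.shape[0]} != {times.shape[0]} phases"
        )
    if v[0] <= eps:
        raise DegenerateDataError("precontrast eigenvector component is not positive")
    e = int(np.argmin(np.abs(times - early_time)))
    d = int(np.argmin(np.abs(times - delayed_time)))
    for want, got in ((early_time, times[e]), (delayed_time, times[d])):
        if got != want:
            logger.info("no %.0f-s phase; using nearest at %.0f s", want, got)
    ier = 100.0 * (v[e] - v[0]) / v[0]
    der = 100.0 * (v[d] - v[0]) / v[0]
    return float(ier), float(der)
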