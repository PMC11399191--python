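"""Synthetic DCE-MRI phantoms and cohorts with known ground truth.

The phantom emulates the three voxel populations that matter for BPE
quantification — fat, non-enhancing fibroglandular tissue (FGT), and
enhancing FGT with persistent / plateau / washout kinetics — using a
piecewise-linear wash-in model:

    S(t) = S0 * (1 + a * w(t)),   w(0) = 0,  w(t_early) = 1,
    w(t) = 1 + b * (t - t_early)  for t > t_early,

so ``a`` is the fractional early uptake (PE/100 at the early phase) and
``b`` (1/s) is the late slope: b < 0 washout, b = 0 plateau, b > 0
persistent.  Additive Gaussian noise stands in for acquisition noise.
The analytic percent-enhancement and signal-enhancement-ratio of every
voxel are stored alongside the series so downstream map computations can
be checked against a closed form.

The cohort generator draws a three-group study population (nonhigh-risk,
high-risk non-BRCA, BRCA) whose covariates (age, BMI, menopausal status,
hormonal-treatment history, FGT level) are confounded with group the way
a screening cohort is, and whose six BPE measurements follow a
user-specified linear model on those covariates plus group effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .io import (
    DEFAULT_PHASE_TIMES,
    GROUPS,
    MEASURE_COLUMNS,
    DceSeries,
    RegionMasks,
    validate_cohort,
)

# --------------------------------------------------------------------------
# Phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueClass:
    """One voxel population of the phantom.

    ``uptake`` is the fractional signal increase at the early phase
    (PE/100); ``slope`` the late wash-in slope b in 1/s.
    """

    label: str
    volume_fraction: float
    s0: float
    uptake: float
    slope: float = 0.0
    is_fgt: bool = False


def default_tissue_classes() -> tuple[TissueClass, ...]:
    """Fat plus non-enhancing and enhancing FGT (persistent and washout).

    The washout class's slope is set so its early/delayed enhancement
    ratio is 1.25 — the plateau/washout regime a 0.90 SER voxel threshold
    is designed to isolate; the persistent class has SER well below 0.9.
    """
    t_early, t_delayed = 120.0, 390.0
    dt = t_delayed - t_early
    return (
        TissueClass("fat", 0.50, s0=400.0, uptake=0.05),
        TissueClass("fgt_nonenhancing", 0.25, s0=250.0, uptake=0.10, is_fgt=True),
        # persistent: SER = 1 / (1 + b*dt) = 0.5
        TissueClass(
            "fgt_persistent", 0.15, s0=250.0, uptake=0.50, slope=1.0 / dt, is_fgt=True
        ),
        # washout: SER = 1 / (1 + b*dt) = 1.25
        TissueClass(
            "fgt_washout", 0.10, s0=250.0, uptake=0.60, slope=-0.2 / dt, is_fgt=True
        ),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a DCE phantom."""

    grid_shape: tuple[int, int, int] = (16, 16, 8)
    phase_times: tuple[float, ...] = DEFAULT_PHASE_TIMES
    tissue_classes: tuple[TissueClass, ...] = field(default_factory=default_tissue_classes)
    noise_sd: float = 0.0
    seed: int = 0
    scatter: bool = False  # scatter classes voxelwise instead of contiguous slabs

    def validate(self) -> None:
        times = tuple(float(t) for t in self.phase_times)
        if len(times) < 2 or times[0] != 0.0:
            raise InvalidSpecError("phase_times must start at 0 with >= 2 phases")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidSpecError("phase_times must be strictly increasing")
        total = sum(c.volume_fraction for c in self.tissue_classes)
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(f"volume fractions sum to {total}, not 1")
        for c in self.tissue_classes:
            if c.s0 <= 0:
                raise InvalidSpecError(f"class {c.label}: S0 must be > 0")
            if c.uptake < 0:
                raise InvalidSpecError(f"class {c.label}: uptake must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not any(c.is_fgt for c in self.tissue_classes):
            raise InvalidSpecError("at least one tissue class must be FGT")


@dataclass(frozen=True)
class PhantomTruth:
    """Noise-free per-voxel ground truth of a generated phantom."""

    true_pe_map: np.ndarray  # percent, at the early phase
    true_ser_map: np.ndarray  # ratio; NaN where no uptake
    class_label_map: np.ndarray  # int index into spec.tissue_classes
    population_curves: dict[str, np.ndarray]  # label -> noise-free time course


def washin_weight(t: np.ndarray, slope: float, t_early: float) -> np.ndarray:
    """Piecewise-linear wash-in: 0 at t=0, 1 at t_early, slope after."""
    t = np.asarray(t, dtype=float)
    return np.where(t <= t_early, t / t_early, 1.0 + slope * (t - t_early))


def generate_phantom(spec: PhantomSpec) -> tuple[DceSeries, RegionMasks, PhantomTruth]:
    """Generate a phantom series, its masks, and analytic ground truth.

    The breast mask covers the whole grid; the FGT mask covers the voxels
    of classes flagged ``is_fgt`` (hence FGT is nested in breast by
    construction).  Identical spec and seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    n_vox = int(np.prod(shape))
    times = np.asarray(spec.phase_times, dtype=float)
    t_early = times[1]

    # voxel counts per class: floor then distribute the remainder
    fracs = np.array([c.volume_fraction for c in spec.tissue_classes])
    counts = np.floor(fracs * n_vox).astype(int)
    for i in np.argsort(-(fracs * n_vox - counts))[: n_vox - counts.sum()]:
        counts[i] += 1

    labels_flat = np.repeat(np.arange(len(spec.tissue_classes)), counts)
    if spec.scatter:
        labels_flat = rng.permutation(labels_flat)
    label_map = labels_flat.reshape(shape)

    s0 = np.array([c.s0 for c in spec.tissue_classes])
    uptake = np.array([c.uptake for c in spec.tissue_classes])
    w = np.stack(
        [washin_weight(times, c.slope, t_early) for c in spec.tissue_classes]
    )  # (n_classes, n_phases)
    curves = s0[:, None] * (1.0 + uptake[:, None] * w)

    signal = curves[labels_flat].reshape(shape + (len(times),))
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        signal = np.clip(signal, 0.0, None)

    fgt_classes = np.array([c.is_fgt for c in spec.tissue_classes])
    fgt = fgt_classes[label_map]
    masks = RegionMasks(np.ones(shape, dtype=bool), fgt)

    true_pe = 100.0 * uptake[label_map]
    w_early = w[:, np.flatnonzero(times == t_early)[0]]
    w_late = w[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ser_by_class = np.where(
            (uptake > 0) & (w_late > 0), w_early / w_late, np.nan
        )
    truth = PhantomTruth(
        true_pe_map=true_pe,
        true_ser_map=ser_by_class[label_map],
        class_label_map=label_map,
        population_curves={
            c.label: curves[i] for i, c in enumerate(spec.tissue_classes)
        },
    )
    series = DceSeries(signal, tuple(times))
    return series, masks, truth


def class_ier_der(cls: TissueClass, phase_times: Sequence[float] = DEFAULT_PHASE_TIMES,
                  early_time: float = 120.0, delayed_time: float = 390.0) -> tuple[float, float]:
    """Analytic (IER, DER) in percent of one tissue class's population curve."""
    times = np.asarray(phase_times, dtype=float)
    w = washin_weight(times, cls.slope, times[1])
    curve = cls.s0 * (1.0 + cls.uptake * w)
    e = int(np.argmin(np.abs(times - early_time)))
    d = int(np.argmin(np.abs(times - delayed_time)))
    return (
        100.0 * (curve[e] - curve[0]) / curve[0],
        100.0 * (curve[d] - curve[0]) / curve[0],
    )


def phantom_for_ier_der(ier: float, der: float, **kwargs) -> PhantomSpec:
    """A two-class FGT phantom whose enhancing class has the given analytic
    (IER, DER) in percent: uptake = IER/100, slope chosen so the delayed
    weight equals DER/IER."""
    if ier <= 0:
        raise InvalidSpecError("ier must be > 0")
    t_early, t_delayed = 120.0, 390.0
    a = ier / 100.0
    b = (der / ier - 1.0) / (t_delayed - t_early)
    classes = (
        TissueClass("fat", 0.2, s0=400.0, uptake=0.02),
        TissueClass("fgt_enhancing", 0.8, s0=250.0, uptake=a, slope=b, is_fgt=True),
    )
    return PhantomSpec(tissue_classes=classes, **kwargs)


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupCovariates:
    """Per-group covariate distribution: truncated normals for age/BMI,
    Bernoulli for the binaries, categorical over FGT levels 1-4."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    p_postmenopausal: float
    p_hormone_tx: float
    fgt_probs: tuple[float, float, float, float]
    age_range: tuple[float, float] = (21.0, 90.0)
    bmi_range: tuple[float, float] = (16.0, 50.0)


@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a synthetic three-group cohort.

    ``bpe_model`` maps each measure to a coefficient dict with keys
    ``intercept, age, bmi, menopausal, hormone_tx, fgt_level, sd`` and
    optional per-group offsets ``group:<label>`` (relative to zero).
    """

    n_per_group: Mapping[str, int]
    covariates: Mapping[str, GroupCovariates]
    bpe_model: Mapping[str, Mapping[str, float]]
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise InvalidSpecError(f"unknown group label {g!r}")
            if n < 1:
                raise InvalidSpecError(f"n_per_group[{g!r}] must be >= 1")
        if not set(self.n_per_group) <= set(self.covariates):
            raise InvalidSpecError("covariates must cover every sampled group")
        known = {"intercept", "age", "bmi", "menopausal", "hormone_tx", "fgt_level", "sd"}
        for m, coefs in self.bpe_model.items():
            if m not in MEASURE_COLUMNS:
                raise InvalidSpecError(f"unknown measure {m!r} in bpe_model")
            if coefs.get("sd", 0.0) < 0:
                raise InvalidSpecError(f"{m}: noise sd must be >= 0")
            for k in coefs:
                if k in known:
                    continue
                if k.startswith("group:") and k.split(":", 1)[1] in GROUPS:
                    continue
                raise InvalidSpecError(f"{m}: unknown coefficient {k!r}")
        missing = set(MEASURE_COLUMNS) - set(self.bpe_model)
        if missing:
            raise InvalidSpecError(f"bpe_model missing measures: {sorted(missing)}")


#: Covariate distributions anchored to the study cohort's summaries:
#: nonhigh-risk women are older and mostly postmenopausal with lower FGT
#: levels; BRCA carriers are youngest with slightly higher BMI.
DEFAULT_COVARIATES: dict[str, GroupCovariates] = {
    "high_nonbrca": GroupCovariates(46, 11, 24.5, 4.0, 0.338, 0.241,
                                    (0.023, 0.268, 0.381, 0.328)),
    "nonhigh": GroupCovariates(56, 12, 24.5, 4.0, 0.732, 0.324,
                               (0.056, 0.380, 0.451, 0.113)),
    "brca": GroupCovariates(41, 12, 25.5, 4.5, 0.448, 0.321,
                            (0.061, 0.333, 0.370, 0.236)),
}

#: Cohort sizes of the study population.
DEFAULT_N_PER_GROUP: dict[str, int] = {
    "high_nonbrca": 299,
    "nonhigh": 71,
    "brca": 165,
}


def default_bpe_model() -> dict[str, dict[str, float]]:
    """Linear BPE model anchored to the study's group medians and the
    directions of its covariate associations: enhancement fractions fall
    with age and menopause and rise with FGT level; the high-risk
    non-BRCA group sits above the other two on PE/IER/DER and below them
    on SER_FGT."""
    return {
        "pe_fgt": {"intercept": 9.0, "age": -0.06, "fgt_level": 2.2,
                   "menopausal": -2.0, "group:nonhigh": -2.0, "group:brca": -2.1,
                   "sd": 6.0},
        "pe_breast": {"intercept": 1.2, "age": -0.012, "fgt_level": 0.55,
                      "menopausal": -0.5, "group:nonhigh": -0.8, "group:brca": -0.6,
                      "sd": 1.4},
        "ser_fgt": {"intercept": 8.5, "age": 0.01, "fgt_level": 0.3,
                    "group:nonhigh": 2.8, "group:brca": 1.9, "sd": 4.0},
        "ser_breast": {"intercept": 0.6, "fgt_level": 0.25, "sd": 1.0},
        "ier": {"intercept": 34.0, "age": -0.15, "fgt_level": 3.0,
                "menopausal": -4.0, "group:nonhigh": -7.0, "group:brca": -5.3,
                "sd": 18.0},
        "der": {"intercept": 90.0, "age": -0.3, "fgt_level": 6.0,
                "menopausal": -8.0, "group:nonhigh": -17.0, "group:brca": -11.7,
                "sd": 40.0},
    }


def null_bpe_model(sd: float = 5.0) -> dict[str, dict[str, float]]:
    """All effects zero — the null cohort used for type-I-error calibration."""
    return {m: {"intercept": 10.0, "sd": sd} for m in MEASURE_COLUMNS}


def default_cohort_spec(seed: int = 0, n_per_group: Mapping[str, int] | None = None,
                        bpe_model: Mapping[str, Mapping[str, float]] | None = None,
                        ) -> CohortSimSpec:
    return CohortSimSpec(
        n_per_group=dict(n_per_group or DEFAULT_N_PER_GROUP),
        covariates=dict(DEFAULT_COVARIATES),
        bpe_model=bpe_model or default_bpe_model(),
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (ranges here are wide, so cheap)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw one subject row per subject; identical spec + seed give an
    identical table.  BPE measures other than IER/DER are clipped to
    [0, 100] (they are volume fractions in percent)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in GROUPS:
        if g not in spec.n_per_group:
            continue
        n = spec.n_per_group[g]
        cov = spec.covariates[g]
        age = _truncated_normal(rng, cov.age_mean, cov.age_sd, *cov.age_range, size=n)
        bmi = _truncated_normal(rng, cov.bmi_mean, cov.bmi_sd, *cov.bmi_range, size=n)
        meno = (rng.random(n) < cov.p_postmenopausal).astype(int)
        horm = (rng.random(n) < cov.p_hormone_tx).astype(int)
        probs = np.asarray(cov.fgt_probs, dtype=float)
        fgt = rng.choice(np.arange(1, 5), size=n, p=probs / probs.sum())
        df = pd.DataFrame(
            {"group": g, "age": np.round(age, 1), "bmi": np.round(bmi, 1),
             "menopausal": meno, "hormone_tx": horm, "fgt_level": fgt}
        )
        for m in MEASURE_COLUMNS:
            c = spec.bpe_model[m]
            y = (
                c.get("intercept", 0.0)
                + c.get("age", 0.0) * df["age"]
                + c.get("bmi", 0.0) * df["bmi"]
                + c.get("menopausal", 0.0) * df["menopausal"]
                + c.get("hormone_tx", 0.0) * df["hormone_tx"]
                + c.get("fgt_level", 0.0) * df["fgt_level"]
                + c.get(f"group:{g}", 0.0)
                + rng.normal(0.0, c.get("sd", 0.0), n)
            )
            if m in ("pe_fgt", "pe_breast", "ser_fgt", "ser_breast"):
                y = np.clip(y, 0.0, 100.0)
            df[m] = y
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "id", [f"s{i:04d}" for i in range(len(out))])
    # radiologist BPE grade: a coarse ordinal proxy driven by pe_breast
    q = out["pe_breast"].rank(pct=True)
    out.insert(8, "bpe_category", np.minimum(4, 1 + (q * 4).astype(int)))
    return validate_cohort(out)


def confounded_cohort_spec(seed: int = 0, n_treated: int = 500,
                           n_control: int = 2000) -> CohortSimSpec:
    """Two-group cohort for propensity-matching simulations: the treated
    (nonhigh-risk) group is older, more often postmenopausal, slightly
    more often on hormonal treatment and lower in FGT level than the
    high-risk non-BRCA controls — the directions of the study cohort's
    confounding — at half the study's shift magnitudes so the groups
    retain common propensity support.  BPE (pe_breast) is driven purely
    by the confounders, with zero group effect: any unmatched group
    difference is confounding by construction.

    The default sizes give a matched sample large enough that the
    |SMD| < 0.1 balance convention reflects matching quality rather than
    sampling noise: the SMD of n matched pairs fluctuates with sd of
    order sqrt(2(1-rho)/n), where rho is the within-pair covariate
    correlation induced by matching, and certifying five covariates
    simultaneously below 0.1 needs that sd well under 0.05 — hence
    hundreds of pairs, not the study's 71.
    """
    cov = {
        "high_nonbrca": GroupCovariates(46, 11, 24.5, 4.0, 0.34, 0.24,
                                        (0.023, 0.268, 0.381, 0.328)),
        "nonhigh": GroupCovariates(51, 11, 24.5, 4.0, 0.54, 0.30,
                                   (0.040, 0.330, 0.420, 0.210)),
    }
    model = null_bpe_model(sd=4.0)
    model["pe_breast"] = {"intercept": 4.0, "age": -0.04, "menopausal": -0.8,
                          "fgt_level": 0.6, "sd": 1.5}
    return CohortSimSpec(
        n_per_group={"high_nonbrca": n_control, "nonhigh": n_treated},
        covariates=cov, bpe_model=model, seed=seed,
    )


def shifted_cohort_spec(measure: str, shift: float, seed: int = 0,
                        n_per_group: Mapping[str, int] | None = None,
                        sd: float = 5.0) -> CohortSimSpec:
    """Null cohort plus a pure group shift on one measure for the
    high-risk non-BRCA group — the programmed-effect cohort used in
    power and sweep checks."""
    model = null_bpe_model(sd=sd)
    model[measure] = dict(model[measure], **{"group:high_nonbrca": shift})
    return default_cohort_spec(seed=seed, n_per_group=n_per_group, bpe_model=model)
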