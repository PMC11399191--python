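# bpequant

Quantitative **background parenchymal enhancement (BPE)** analysis for
breast DCE-MRI, with the cohort statistics used to compare BPE between
breast-cancer screening risk groups (nonhigh-risk, high-risk non-*BRCA*,
and *BRCA1/2* carriers).

BPE — contrast uptake of normal fibroglandular tissue (FGT) — is usually
graded qualitatively by radiologists. This package implements a fully
quantitative alternative for a standard screening protocol (one
precontrast acquisition plus four postcontrast phases at 120, 210, 300
and 390 s) and the statistical battery needed to analyse it at cohort
scale. It is aimed at imaging scientists who have co-registered breast
and FGT segmentation masks and want reproducible per-subject BPE numbers
and group comparisons.

## The six measurements

At a voxel with precontrast signal S_pre, early-phase signal S_early and
delayed-phase signal S_delayed:

    PE  = 100 · (S_early − S_pre) / S_pre
    SER = (S_early − S_pre) / (S_delayed − S_pre)

PE captures wash-in strength; SER near or above 1 indicates
plateau/washout kinetics. Per subject:

* **PE_FGT, PE_Breast** — percent of FGT-mask / breast-mask voxels with
  PE ≥ 30% (the voxel enhancement threshold).
* **SER_FGT, SER_Breast** — percent of region voxels that enhance *and*
  have SER ≥ 0.90.
* **IER, DER** — the FGT voxel time courses are stacked into an
  n_voxels × n_phases matrix and decomposed by uncentered PCA; the
  leading right singular vector v is a representative kinetic time
  course, and IER = 100·(v₁₂₀ₛ − v₀)/v₀, DER = 100·(v₃₉₀ₛ − v₀)/v₀.

Cohort statistics: two-sided Mann–Whitney U-tests (exact enumeration for
small samples, tie-corrected normal approximation otherwise) over the
six-measure family with Bonferroni correction at FWER 0.1; chi-squared
tests of group characteristics (Yates correction on 2×2 tables);
univariate/multivariable OLS of BPE on clinical factors; and 1:1
greedy nearest-neighbour propensity-score matching on age, BMI,
menopausal status, hormonal treatment and FGT level, with standardized
mean difference (SMD) balance diagnostics.

Because no image data ships with the package, a synthetic-data module
generates DCE phantoms with analytic ground-truth PE/SER maps and
three-group cohorts with realistic covariate confounding; every pipeline
stage is tested against these.

## Worked example

```python
import bpequant as bq

# a DCE phantom: fat + non-enhancing FGT + persistent and washout FGT
series, masks, truth = bq.generate_phantom(bq.PhantomSpec(noise_sd=5.0, seed=1))
m = bq.quantify_subject(series, masks)
print(m.as_dict())
# {'pe_fgt': 50.0, 'pe_breast': 25.0, 'ser_fgt': 20.0, 'ser_breast': 10.0,
#  'ier': 35.9, 'der': 52.0}
```

Half of the phantom's FGT voxels are programmed to enhance ≥ 30%, so
PE_FGT = 50.0%; the washout class (SER 1.25) occupies 20% of the FGT,
so SER_FGT = 20.0%; IER/DER reflect the eigenvector of the mixed FGT
kinetics.

```python
cohort = bq.generate_cohort(bq.default_cohort_spec(seed=1))  # 535 subjects
for r in bq.compare_groups(cohort, ("high_nonbrca", "nonhigh")):
    print(f"{r.measure:<10} {r.median_a:6.1f} vs {r.median_b:6.1f}"
          f"   adj p = {r.p_adjusted:.3g}  {'*' if r.significant else ''}")
# pe_fgt       12.6 vs    7.7   adj p = 3.07e-05  *
# pe_breast     2.1 vs    1.1   adj p = 2.35e-05  *
# ser_fgt      10.1 vs   13.2   adj p = 8.41e-05  *
# ser_breast    1.3 vs    1.1   adj p = 1
# ier          31.4 vs   16.9   adj p = 1.98e-07  *
# der          88.2 vs   56.7   adj p = 1.08e-05  *

match = bq.propensity_match(cohort, "nonhigh", "high_nonbrca", seed=1)
print(len(match.pairs), match.smd_before["age"], match.smd_after["age"])
# 71 pairs; age SMD 0.88 before matching, 0.12 after
```

The synthetic cohort is confounded the way the screening population is —
nonhigh-risk women are older, mostly postmenopausal and lower in FGT
level — and the programmed group effects give the high-risk non-BRCA
group higher PE/IER/DER and lower SER_FGT, which the comparison
recovers. Adjusted p-values are min(1, 6·p) over the six-measure family.

The same stages are available from the shell:

```bash
bpequant simulate --out-dir run --seed 1
bpequant compare --cohort run/cohort.csv --pair high_nonbrca:nonhigh --out run/cmp.csv
bpequant match   --cohort run/cohort.csv --treated nonhigh --control high_nonbrca
bpequant sweep   --out run/sweep.csv          # threshold/phase sensitivity grid
bpequant report  --cohort run/cohort.csv --out run/report.csv
```

Every command writes a `provenance.json` (config + package versions +
seed); re-running with the same seed reproduces outputs byte-for-byte.

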