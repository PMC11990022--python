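# Methods

## The structural model behind the SPINA indices

The SPINA Carb approach treats fasting glucose and insulin as the
steady state of a closed feedback loop: beta cells secrete insulin at a
rate GBeta·G/(d_β + G) that saturates in glucose, insulin is cleared
exponentially, and glucose — produced hepatically at a constant rate P₀ —
is cleared both insulin-independently and through an insulin-dependent
pathway whose gain GR saturates in insulin at the receptor.  Setting both
balance equations to zero and solving for the two structural parameters
given the *observed* fasting pair (G∞, I∞) yields

    GBeta = β_I · I∞ · (d_β + G∞) / (α_I · G∞)                  [mol/s]
    GR    = (α_G·P₀ − β_G·G∞) · (d_R + I∞) / (β_G·G∞·G_E·I∞)    [mol/s]
    DI    = GBeta[pmol/s] · GR[mol/s]                           [dimensionless]

SPINA-DI, the static disposition index, is the loop gain of the system:
it stays roughly constant while rising secretion compensates falling
sensitivity, and drops when compensation fails.  By convention GBeta is
reported in pmol/s and GR in mol/s; DI is their numerical product on
those scales.

### Physiological constants

| constant | value | meaning |
|---|---|---|
| P₀ | 150 µmol/s | hepatic glucose production at rest |
| α_G | 0.11 L⁻¹ | reciprocal glucose distribution volume |
| β_G | 7.1·10⁻⁴ s⁻¹ | glucose clearance exponent |
| α_I | 0.2 L⁻¹ | reciprocal insulin distribution volume |
| β_I | 3.4·10⁻³ s⁻¹ | insulin clearance exponent |
| d_β | 7 mmol/L | half-saturation of glucose-stimulated secretion |
| d_R | 1.6 nmol/L | half-saturation of insulin at its receptor |
| G_E | 50 s/mol | insulin effector gain |

These describe a standard adult at rest and are exposed as a
`SpinaConstants` dataclass so alternates can be tested.  Two consistency
checks support the transcription: a healthy fasting pair (5 mmol/L,
60 pmol/L) lands *inside* all three reference bands simultaneously
(GBeta 2.45 pmol/s, GR 2.02 mol/s, DI 4.94), and the indices evaluated at
each arm's median inputs land within a few percent of that arm's reported
median indices.  The test suite additionally verifies the closed forms
against numerical root-finding of the raw balance equations (1e-9
relative on a 20-point grid), so algebra and model cannot drift apart.

The GR formula is only defined while α_G·P₀ > β_G·G∞, i.e. fasting
glucose below ≈ 23 mmol/L; beyond that (and at zero insulin) GR and DI
are reported as not evaluable with the panel flag mechanism rather than
as negative numbers.

## HOMA, QUICKI and units

The classic HOMA formulas are used (not the HOMA2 computer model): they
reproduce the reciprocal and logarithmic identities that the published
group medians satisfy (1/3.47 = 0.29, 1/log₁₀(405·3.47) = 0.32, …), which
the updated model would not.  All HOMA/QUICKI formulas are defined on
conventional units; internally the package stores glucose in mmol/L and
insulin in pmol/L and converts on the fly.  Glucose conversion uses
exactly 18.0 mg/dL per mmol/L (consistent with the printed pair
126 mg/dL ↔ 7.0 mmol/L).  The insulin conversion factor defaults to
6.945 pmol/L per µIU/mL; some laboratories use 6.00, so the factor is a
parameter of every formula that needs it.  Because QUICKI =
1/log₁₀(405·HOMA-IR) whatever that factor, subject orderings by QUICKI
and HOMA-IR are exact mirror images, and for odd cohorts the median
QUICKI equals QUICKI of the median HOMA-IR — the mechanism behind the
cross-table consistency checks.

Reference-range boundaries follow the printed notation: one-sided ranges
("<2.5", ">0.4") are strict, two-sided ranges ("4.01–7.65") closed.
Values are retained at full precision; two decimals are a display
convention only.

## Screening, clusters, strata

Diabetes: HbA1c > 6.5 % (strict, "exceeded") OR fasting glucose
≥ 7.0 mmol/L (closed).  Subjects on antidiabetic medication count as
diabetic by default (`medication_implies_diabetes=True`), since
treated-to-target subjects would otherwise escape the laboratory
criteria; the flag can be turned off.

The simplified endotype clustering is a fixed-precedence decision list:
beta-cell antibody positive → SAID; age at diagnosis ≥ 65 y → MARD;
BMI ≥ 30 kg/m² → MOD; HOMA-IR ≥ 5.0 → SIRD; else SIDD.  The age and BMI
thresholds are the conventional boundaries of the age-related and
obesity-related clusters; the HOMA-IR threshold for "severe
insulin-resistant" is this package's own default — the simplified scheme's
source does not fix one — and all three live in an editable
`ClusterRules` table.  Missing age at diagnosis falls back to current
age (a conservative choice that can only promote toward MARD).

Haptoglobin ≤ 209.8 mg/dL is the *low* stratum (the boundary belongs to
low, matching how the strata are tabulated); CRP ≤ 5 mg/dL low.  Missing
markers yield an `unknown` stratum rather than an error.

## Statistics

* Normality is checked with the Lilliefors variant of the
  Kolmogorov–Smirnov test (parameters estimated from the sample), the
  appropriate form when no reference parameters are stated; variance
  homogeneity with a two-sided F-test; both at α = 0.05.  A t-test is
  used only when both samples pass both gates, otherwise the
  Mann–Whitney U test.  Samples smaller than 4 cannot establish
  normality and take the nonparametric path.
* Mann–Whitney: exact null distribution for combined n ≤ 12 without
  ties; otherwise the normal approximation with tie and continuity
  corrections.  Two identical or fully tied samples give p = 1.  The
  exact branch is verified against brute-force enumeration of all rank
  assignments.
* 2×2 tables use the Pearson chi-squared test *with* Yates continuity
  correction: on the prevalence table (17/78 vs 2/47) the corrected test
  gives p = 0.039 — the tabulated value — while the uncorrected test
  gives ≈ 0.020, which identifies the original software default.  (The
  running text of the source analysis prints 0.0039 for the same
  comparison where its table prints 0.039; recomputation supports the
  table.  The package reproduces the table value and flags the prose
  value as a likely typo — it does not try to match both.)  A zero
  margin yields statistic 0 and p = 1 with a warning.
* Quartiles use the linear-interpolation convention (the common
  statistical-software default).  Descriptives render as mean ± SEM,
  median (Q1–Q3) or count (%) depending on the distribution check.
* p-values ≥ 10⁻⁴ are formatted with two significant digits (trailing
  zeros preserved), smaller ones as "<0.0001"; the formatter is
  idempotent under parse-and-reformat.
* No multiple-testing correction and no regression modelling, matching
  the analysis design this package implements.

## Sample size

Matched case-control designs are powered through the discordant-pair
(McNemar) framework.  With exposure probabilities p₁ (cases) and p₀
(controls) and within-pair correlation φ, the discordant probabilities
are p₁₀ = p₁(1−p₀) − c and p₀₁ = (1−p₁)p₀ − c with
c = φ·√(p₁(1−p₁)p₀(1−p₀)), and the pair requirement is

    m = [z₁₋α/₂·√(p₁₀+p₀₁) + z₁₋β·√(p₁₀+p₀₁−(p₁₀−p₀₁)²)]² / (p₁₀−p₀₁)²,

rounded up; controls are ⌈m/ratio⌉.  φ defaults to 0 (independent pair
members): with α = 0.05, power 0.90, p₁ = 0.434, p₀ = 0.164 and a 2:1
ratio this gives an unrounded requirement of 61.41 and the published
62 cases / 31 controls, which validates the independence reading of the
design; a nonzero φ is exposed as a parameter.

## Synthetic cohort generator

The generator emulates two arms with the published summary structure so
that the full pipeline is testable without patient data:

* **Fasting insulin** — log-normal per arm (the printed IQRs are strongly
  right-skewed), non-diabetic log-medians ln 90 (cases) and ln 70
  (controls) with log-SDs 0.92 / 0.72, diabetics shifted up by ~0.5 on
  the log scale.
* **Fasting glucose** — normal with a diabetic mixture tail: non-diabetics
  N(5.05, 0.60) cases / N(4.95, 0.55) controls clipped below 7.0 mmol/L,
  diabetics N(6.4, 1.1).
* **HbA1c** — affine in glucose (slope 1.12, intercept −0.23, SD 0.25),
  chosen so non-diabetic and diabetic medians sit near 5.4 % and 6.8 %;
  non-diabetics are truncated at 6.5 % so the screening rules fire
  coherently, and untreated diabetics whose draw would escape both
  criteria are lifted just above the HbA1c bound.  The control arm omits
  HbA1c (as in the emulated data), so control diabetes rests on glucose
  and medication.
* **BMI** — normal (31.5 ± 6.7 cases, 27.0 ± 6.0 controls), diabetics
  +2 kg/m².
* **Haptoglobin** — gamma (shape 11, scale 18.5 mg/dL in cases), +55 mg/dL
  under antidiabetic treatment; this puts ~46 % of cases above the
  209.8 mg/dL cut-off and reproduces the untreated stratum's median/IQR.
  A Gaussian copula links haptoglobin to insulin with Spearman ρ = 0.2 —
  the real correlation is unreported; the default is a weak positive
  assumption exposed in the configuration.
* **Diabetes** — Bernoulli 18 % (cases) / 4 % (controls); 70 % of case-arm
  diabetics treated (all control diabetics), with per-drug probabilities
  dominated by metformin.  Because diabetics skew heavier, the
  obesity-related cluster (MOD) emerges as the modal endotype among
  diabetics without being assigned directly.
* **Severity** (cases only; controls zero, Hurley absent) — Hurley
  categorical (0.20/0.45/0.35), SAHS ≈ round N(7, 2.8), lesion counts
  Poisson/negative-binomial matched to the published medians.

What the generator does **not** model: any joint structure beyond the
insulin–haptoglobin copula and the diabetes conditioning (e.g. severity
is independent of metabolic state, whereas treated patients in the real
data had higher Hurley stages), assay error, and the real cohort's full
joint distribution — only printed marginals were targets.  Passing
calibration tests therefore show that the pipeline recovers the intended
distributions, not that the generator replicates the patients.

A single `numpy` `default_rng` stream per cohort makes generation
deterministic; the seed is recorded in the cohort provenance, and
identical seeds produce byte-identical CSVs.

## Problem sizes and tolerances in the test suite

Calibration recovery is asserted at n = 10,000 per arm (medians and IQR
endpoints within 10 % of their targets; prevalence 18 ± 3 points); the
type-I error of the adaptive pipeline is estimated from 2,000 seeded
null cohorts at n = 50 per arm and required to lie in 0.05 ± 0.02;
identity-type invariants (HOMA reciprocity, QUICKI ordering) run on
10,000 random samples at 1e-12; the SPINA closed form must match
equilibrium root-finding to 1e-9 relative.  These sizes were chosen so
the whole suite runs in well under a minute while keeping Monte-Carlo
noise far from the asserted bands.

## Known limitations

Fasting (static) function tests only; no OGTT/clamp dynamics.  The
simplified cluster rules are a transcription target — exact thresholds in
the originating clustering scheme may differ, which is why they are an
editable table.  Cohort-level medians of a real, non-deposited dataset
are not reproducible by construction; the package's validation rests on
in-table identities, closed-form ground truths and property suites.
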