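# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices, and the known limitations of the `nmrgwas` pipeline.

## The two-stage ratio GWAS

**Traits.** A spectrum sampled on a uniform ppm grid is reduced to
uniform half-open bins [left, left + w); the bin value is the mean of
the grid intensities inside the bin, which is invariant to grid density
(any constant factor is later absorbed by the log transform and by
ratios).  Bin labels are left edges rounded to 3 decimals.  Intensities
are log₁₀-transformed (non-positive values become missing), then a
single per-bin pass sets values more than 3 bin-SDs from the bin mean to
missing; the bin mean and SD are computed once from the pre-filter
values, not iteratively.  Bins intersecting the water region
(4.6–5 ppm) are excluded outright.  A ratio trait between two bins is
the difference of the already-cleaned log values — no re-derivation from
raw intensities and no second outlier pass.

**Alignment.** Because no internal reference compound is assumed, each
spectrum is rigidly shifted (integer grid steps, no warping) so that the
maximum inside the lactate window (1.30–1.42 ppm) lands on the canonical
apex at 1.37 ppm.  A spectrum whose window maximum does not rise above a
signal-presence threshold (default: 5× the median absolute intensity,
and strictly positive) raises an alignment failure naming the subject.

**Association model.** Every test is ordinary least squares of the trait
on (intercept, minor-allele dosage, age, sex); the dosage slope's
two-sided P comes from the t distribution on n − 4 df.  Complete-case
restriction is per (SNP, trait) pair, so n varies across results.
Dosages count observed minor alleles, oriented per SNP by observed
frequency (ties at 50% keep the B allele).  SNP QC applies strict
inequalities: call rate > 0.95, MAF > 0.01, Hardy–Weinberg χ² P > 10⁻⁶
(1-df goodness of fit; the threshold is insensitive to using the exact
test instead).  No genomic control, relatedness adjustment, or
imputation is applied.  P values are clamped at the smallest positive
normal double (≈2.2e-308) instead of underflowing: ratio scans genuinely
reach the 1e-94 scale.

**Feature selection.** The pseudo-spectrum records, per bin, the minimum
P over all SNPs and the SNP attaining it (ties break by position, then
id).  A genuine spectral signal spans several adjacent bins associated
with the same SNP, so maximal runs of adjacent (one-bin-distance)
same-lead-SNP bins are collapsed to the single lowest-P bin (ties toward
lower ppm).  No numeric "comparable strength" tolerance is applied for
run membership — strict same-lead adjacency is the simplest reading and
is idempotent.  The k strongest representatives (default 500; the
desk-scale presets use 50) go to stage 2.

**p-gain.** For a ratio tested against a SNP, p-gain =
min(P_num, P_den)/P_ratio, using both constituents' single-bin P values
for the same SNP — taken from the stage-1 table and computed on the fly
if a constituent was never scanned.  p-gain > 1 exactly when the ratio
improves on its best constituent.

**Multiple testing and the adaptive family.** The significance threshold
is α/(SNPs × traits) with traits = pairs + single bins, mirroring the
two-stage accounting (e.g. 500·499/2 + 8,600 = 133,350 at cohort scale).
One property of this construction deserves honesty: the ratio family is
formed *adaptively* from stage-1 winners of the same data, so the
correction bounds each test's error but not the family-wise rate.  If
two effectively independent noise bins are both selected with the same
lead SNP and opposite-sign slopes (each |t| ≈ 4), their difference trait
reaches |t| ≈ (|t₁|+|t₂|)/√2 ≈ 6 against that SNP — P ≈ 10⁻⁹, below a
desk-scale threshold of ~10⁻⁷.  The expected number of such same-lead
collisions among k selected bins over M SNPs is ≈ k(k−1)/(2M):
negligible when M ≫ k² (the cohort-scale regime, 0.19 expected
collisions at k = 500, M = 655,658) but ≈ 6 per run at the desk scale
the simulations use (k = 50, M = 200).  The null-cohort acceptance test
records this: at desk scale most no-effect runs show at least one
"significant" ratio, driven entirely by this mechanism (stage-1 P values
themselves are uniform, which the suite verifies separately).  Users
applying the pipeline with small SNP panels should either shrink k or
interpret ratio hits whose constituents share a lead SNP with weak
single-bin support as selection artifacts.  The MAF > 10% rule is a
reporting filter only; all QC-passed SNPs are tested.

## The synthetic cohort

The generator produces the four linked layers a real study would have,
from one seed via named substreams (bit-identical reruns).

* **Genotypes.** Independent biallelic SNPs in Hardy–Weinberg
  proportions (dosage ~ Binomial(2, MAF)), optional missingness;
  minor-allele orientation after drawing.
* **Concentrations.** log₁₀ C = base + Σ effect·dosage +
  age-slope·(age − 50) + sex-offset·sex + loading·F + N(0, σ).  Age is
  uniform on 25–74 years, sex balanced — a plausible population-cohort
  structure whose exact values do not matter to the math.  F is a single
  standard-normal "overall lipid level" factor per subject whose
  per-metabolite loadings make ratios variance-reducing: the minimal
  mechanism behind substrate–product ratio sharpening.
* **Spectra.** Sum of Lorentzian lines (standard solution-NMR lineshape;
  heavy tails deliberately exercise binning and the shoulder scenario),
  height ∝ concentration, with a per-subject, per-metabolite rigid
  shift jitter of SD 0.0005 ppm — below the bin width, which is what
  makes fixed-width binning the right compensation.  Broad Lorentzian
  humps with a per-subject log-normal scale emulate the
  lipid/macromolecule envelope; a very broad high-amplitude line at
  4.8 ppm stands in for residual water (it only needs to be destroyed by
  masking, not to be realistic); i.i.d. Gaussian noise per grid point.
  Narrow lines are evaluated within ±400 half-widths (truncating <1e-5
  of the tail), keeping rendering exactly linear in concentrations.
* **Platform readouts.** readout = C·exp(N(0, √log(1 + CV²))) so the
  multiplicative error has the stated CV; independent missingness.  The
  NMR platform's own noise/CV is not published for the modelled study,
  so the defaults (CV 3% clinical, 10% MS; additive spectral noise 0.5
  a.u. against peak intensities of 50–300) are asserted as plausible,
  not derived.

### Scenario presets (desk scale: 1,000 subjects, 200 SNPs, 0.003-ppm bins, k = 50)

* **fads1** — substrate–product pair: peaks at 2.801/2.017 ppm, one SNP
  (MAF 0.30) moving them ±0.05 log₁₀ per allele in opposite directions,
  equal shared-factor loadings (0.12).  The ratio cancels the factor:
  single-bin P ~1e-14/1e-8 vs ratio P ~1e-60.
* **gckr** — pleiotropy across regions: one SNP (MAF 0.414) raising a
  glucose-like metabolite (3.286 ppm, +0.04) and lowering a
  triglyceride-like one (1.370 ppm, −0.04) with unequal loadings
  (0.10/0.14).  The cross-region ratio integrates both effects; its best
  annotation is the glucose/triglyceride concentration quotient, not
  either single metabolite (whose correlations with the ratio are
  cancelled by the shared factor).
* **pyroxd2** — shoulder peak: a narrow genotype-dependent line
  (2.7585 ppm, half-width 0.0008, −0.14 log₁₀ per allele, MAF 0.343) on
  the flank of a broad genotype-independent resonance (2.740 ppm,
  half-width 0.010, amplitude = the scenario dial, default 50).  The
  peak-bin/neighbour-bin ratio divides out the background locally; as
  the background amplitude grows the single-bin association decays while
  the ratio's holds, so the ratio-minus-single −log₁₀P margin grows —
  the local-baseline-correction effect.
* **null** — the same spectral machinery with no genetic effects, for
  error-rate checks.

The triglyceride (gckr) or lactate (other presets) resonance at
1.370 ppm doubles as the alignment anchor, as a real plasma spectrum's
lactate doublet would.

### What the simulations do not emulate

No J-coupling/multiplet physics beyond fixed line offsets, no relaxation
or field-strength effects, no realistic plasma peak library, no
lipoprotein-subclass structure, no correlated SNPs (LD), no population
structure or relatedness.  Passing recovery tests therefore show the
pipeline's statistics behave as designed under the stated generative
model — not that real plasma spectra will yield these effect sizes.

## Numerical and engineering choices

* The scan assembles each trait's 4×4 normal equations as full-sample
  moments minus the (sparse) contribution of the trait's missing rows —
  algebraically exact, independent of chunking, and ~20× faster than
  re-reducing the matrix per SNP.  SNPs with missing dosages fall back
  to a general per-SNP path.  Agreement with the standalone fit is to
  1e-10 relative (summation order differs in the last ulps).
* Constant-trait/constant-dosage screens use relative floors
  (cancellation error scales with the raw second moments).
* Spearman correlations use average ranks for ties and
  pairwise-complete deletion per (metabolite, bin) pair, maximizing n;
  metabolites need ≥300 non-missing values (configurable) after their
  own 3-SD cleaning.
* Metabolite-ratio candidates for annotating ratio positions are the
  pairwise quotients of the cleaned panel, capped at 10⁴ pairs in
  deterministic order (the search space used by the modelled study is
  unstated).
* The ppm axis is stored ascending; display code may reverse it (NMR
  convention).  Bin count is ⌈range/width⌉ regardless of data.  The
  modelled study's "10,000 bins over 0–9 ppm at 0.001 ppm" is internally
  inconsistent (9/0.001 = 9,000), so range, width and exclusion regions
  are all configuration, never hard-coded counts.
* All randomness flows from one seed through named `SeedSequence`
  substreams per generator stage; identical config + seed reproduces
  byte-identical artifacts.

## Problem sizes used by the test suite

Scenario recovery runs 20 seeds per preset at the desk scale above
(~6 s per run); the shoulder-peak margin uses 10 seeds × 3 amplitudes
with direct fits at the planted positions; the null cohort uses 500
subjects.  The engine-vs-oracle and calibration checks use 100 random
problems and 1,000 permutations at n = 500.
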