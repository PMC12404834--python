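# Methods

## Model and assumptions

All estimation works from two-sample summary statistics: per SNP j, an
exposure association γ̂ⱼ ~ N(γⱼ, σ²_Xj) and an outcome association
Γ̂ⱼ ~ N(βγⱼ + αⱼ, σ²_Yj), independent across the two cohorts, with αⱼ the
horizontal-pleiotropy effect. The package treats the SEs as known (the
usual summary-data idealization) and binary-trait effects as log-odds per
allele. Identification rests on the standard instrumental-variable
assumptions; the estimators differ in how they relax them:

- **IVW** assumes αⱼ = 0 and strong instruments. Weak instruments
  attenuate it (the denominator Σγ̂² overstates Σγ² by Σσ²_X), and
  in-sample selection adds winner's-curse attenuation on top.
- **dIVW** subtracts σ²_Xj from each γ̂ⱼ², which restores consistency under
  many weak instruments and balanced pleiotropy. Its SE is the
  estimating-equation sandwich with per-SNP score variance
  [(γ̂ⱼ² − σ²_Xj)(σ²_Yj + β²σ²_Xj) + σ²_Xjσ²_Yj + 2β²σ⁴_Xj]/σ⁴_Yj; a
  Monte-Carlo test checks that the reported SE tracks the empirical SD
  within 10% at p = 1000 weak instruments. Validity is summarized by the
  condition measure κ̂ = [Σ(γ̂ⱼ² − σ²_Xj)/σ²_Xj]/√p, flagged below a floor
  of 20 (configurable) with a `WeakInstrumentWarning`.
- **RAPS** profiles out instrument strengths: β̂ maximizes −Σρ(tⱼ),
  tⱼ = (Γ̂ⱼ − βγ̂ⱼ)/√(σ²_Yj + β²σ²_Xj + τ²). The l2 loss gives the
  profile-score estimator; Huber (k = 1.345) and Tukey biweight
  (k = 4.685, the 95%-efficiency constants) bound the influence of
  pleiotropic outliers. With overdispersion on, τ² ≥ 0 solves
  Σ[ψ(tⱼ)tⱼ − δ_ρ]/s²ⱼ = 0 where δ_ρ = E[ψ(Z)Z] under Z ~ N(0,1)
  (closed form 2Φ(k) − 1 for Huber, quadrature for Tukey), alternated
  with the β step to convergence; τ² = 0 is reported when the equation is
  already non-positive at the boundary.

### Numerical choices

The RAPS optimizer starts from dIVW (consistent under weak instruments,
hence a good basin for the redescending Tukey objective), runs a bounded
scalar search (xatol 1e−12) with a safeguarded Newton polish, and falls
back to a grid scan over [−5, 5] (step 1e−3) if the local search pins a
bound. `converged` is honest: a gradient check must pass, otherwise the
estimate is returned with `converged=False` and no CI. SEs are
M-estimation sandwiches, 1×1 in β or 2×2 in (β, τ²), with central
finite-difference breads (step 1e−6·max(1, |θ|)).

Multivariable fits optimize the K-exposure objective (independent
exposure measurement errors assumed; a correlation matrix would be needed
for overlapping exposure cohorts, which is out of scope) by Nelder–Mead
from the WLS start plus a BFGS polish, and report the inverse observed
information as the covariance. Collinear exposures (design condition
number > 1e10) raise a singular-information error. An exposure whose
effect column is entirely zero is identified only through the variance
channel — a degenerate direction — so its coefficient is pinned at 0
(p-value 1, zero covariance row), which also makes adjustment for an
irrelevant mediator exactly vacuous. Bonferroni flags use 0.05/K, K the
number of exposures in the model.

## Profile curve and modes

`robust_profile` evaluates the τ² = 0 objective on a grid (default
[−2, 2], step 0.001 — generous for log-OR effects; configurable, and the
direction diagnostic below uses [−4, 4]) and refines every interior local
maximum by bounded optimization in its bracketing cells. `detect_modes`
filters by prominence (default 2 objective units, an LR-like scale —
drops to the higher neighboring valley, computed with the standard peak
machinery) and by pairwise separation (default 0.05), orders by objective,
and raises the direction flag when a multimodal curve has a mode within
the separation tolerance of zero. Marker SNPs at a mode are those with
|tⱼ| below 1.0 by default (no threshold is standard in the field; 1.0
keeps markers to clearly compatible instruments).

The reversed-direction signature deserves a note: with uniformly strong
instruments and a pure one-pathway truth, swapping exposure and outcome
produces a *single* mode near 1/β, not a zero peak. The near-zero peak
appears when the reversed "exposure" has its own genetics: instruments
re-selected on the swapped exposure then mix SNPs acting through the true
exposure (mode at 1/β) with SNPs acting on it directly (mode at 0). The
direction fixture therefore uses a spike-slab instrument architecture
(null spike sd 0.005, slab sd 0.4, 15% slab) plus balanced pleiotropy
τ = 0.05 as the outcome's own genetic background, and re-selects at
p < 1e−4 after swapping. This is the realistic setting for the
diagnostic; the test suite exercises it at fixed seeds.

## Bayesian model averaging

The sampler state is (β₁[, β₂], τ, per-SNP assignment ∈ {out, comp 1,
comp 2}). Per sweep: one inclusion flip (Hastings-corrected for the
component choice when adding), a random-walk update of each β with the
ordering β₁ < β₂ enforced by rejection, a τ update against the
half-normal(0.5) prior (vague on the log-odds scale), and, with two
components, one reassignment move. β priors are N(0, 10²). Step sizes
adapt toward an acceptance band of [0.15, 0.6] during burn-in only
(every 200 sweeps, ×1.4 / ×0.7) and are frozen afterward, so the
post-burn-in chain is a valid fixed-kernel MCMC and bit-reproducible from
its seed. Minimum model size is 2 per component (a one-SNP "component"
would be unfalsifiable). Defaults are 50,000 iterations with 10,000
burn-in — stable PPIs for p ≤ 100 at desk scale; the bundled analyses use
shorter, explicitly-passed chains. PPI is the post-burn-in inclusion
frequency; ESS uses the initial-positive-sequence autocorrelation
estimator.

`beside_dl` is this package's interpretation of a "DL" summary for
model-averaged MR: an inverse-variance fit on the PPI > 0.5 subset with a
DerSimonian–Laird between-SNP variance added to the weights. It is
labeled as an interpretation in its diagnostics metadata.

## Mediation

Total effect from a univariable estimator (default RAPS-Tukey), direct
effect as the exposure coefficient of the two-exposure multivariable fit,
indirect ≡ total − direct (exact identity by construction), proportion
mediated = indirect/total with a delta-method CI, suppressed when
|total| < 2·SE(total) because the ratio CI explodes near a null total.
The default indirect-effect SE is the independence approximation
√(SE²_total + SE²_direct), with a parametric bootstrap alternative; both
are surfaced when they disagree materially. Two mediator sources are
handled as two independent runs juxtaposed — no meta-analytic pooling.

## Drug-target proxy

`build_inhibition_exposure` stages: orient lead cis-eQTLs to the
expression-lowering allele (idempotent, expression-scale); harmonize with
the biomarker table; keep SNPs whose oriented biomarker point estimate is
strictly negative (inhibition should lower the biomarker — a sign test
with no significance requirement, matching the deliberately permissive
no-p-filter design for sparse cis instruments); LD-prune the joined set
(default r² < 0.001; 0.8 as the relaxed sensitivity preset). Stage counts
are logged and non-increasing. Multi-tissue inputs are pooled and
deduplicated keeping the smallest eQTL p per SNP (configurable to one
tissue). Downstream estimation goes through the ordinary harmonized-
dataset path, so a two-instrument dIVW — a supported, loudly-warned
small-p operation — still reports its condition measure.

## Synthetic-data generator

Pure functions of (config, seed). SEs follow the GWAS scaling
1/√(2n·maf(1 − maf)) with maf ~ U(0.1, 0.5). Defaults emulate the study
conditions the package targets: exposure cohort n_x = 30,000 (an
eQTLGen-scale blood eQTL study), outcome effective n_y = 15,000 (a
~450k-participant biobank binary trait at a few percent prevalence has
roughly this effective size on the log-odds scale), instrument strengths
γ ~ N(0, 0.4²) (lead-cis-eQTL scale, mean per-SNP F in the hundreds —
"strong"), balanced pleiotropy τ = 0.01, correlated-pleiotropy fraction
π = 0.4 with confounder shift −0.6 (two well-separated pathways at
0.4 and −0.2 for β = 0.4), mediation chain θ_xm = 0.5, θ_my = 0.2,
θ_direct = 0.2 (total 0.3, indirect 0.1) with mediator-specific SNP
effects sd 0.1 for multivariable identifiability. Weak-instrument
fixtures set γ sd equal to σ_X (mean per-SNP F ≈ 2). Selection is either
on the shipped exposure estimates (same-sample; winner's curse present)
or an independent replicate (three-sample; absent). Binary outcomes are
generated directly on the log-odds summary scale; a tiny individual-level
logistic generator (n ≤ 20,000, statsmodels fit) exists solely to confirm
that scale convention.

Two idealizations matter for interpreting green tests. First,
`simulate_mediation` draws fresh outcome noise for each returned dataset,
so the total- and direct-effect errors are uncorrelated and the
independence-approximation indirect SE is exact under the generator; a
real analysis reusing one outcome GWAS induces positive correlation
between the two, making that SE conservative (over-covering). Second, the
generator has no LD among the estimation instruments (LD enters only the
drug-target cis fixture), no allele-frequency-dependent architecture, and
no sample overlap between exposure and outcome cohorts — passing recovery
tests demonstrate correctness of the estimators under their stated model,
not robustness to those real-data features.

## Problem sizes and tolerances in the test suite

Recovery batteries use p = 100 instruments with 500 replicates (bias
within 3 Monte-Carlo SEs; 95% CI coverage required in [0.92, 0.98];
type-I error in [0.03, 0.08]); the weak-instrument contrast uses p = 1000
with 500 replicates and the winner's-curse contrast p = 2000 with 300
paired replicates; sampler checks use 6,000–25,000 iterations. These
sizes give Monte-Carlo noise well inside the asserted bands while keeping
the whole suite at a few minutes on one CPU, and all replicate seeds are
fixed offsets from a base seed, so every run is deterministic.

## Known limitations

No LD-aware estimation (instruments are assumed independent after
clumping); no sample-overlap correction; no reversible-jump over the
number of BMA components (the user chooses 1 or 2); no colocalization or
pQTL support in the drug-target arm; palindromic-SNP handling relies on
allele frequencies and drops ambiguous rows rather than attempting strand
inference from LD; the observed-information covariance of the
multivariable fit slightly understates uncertainty for redescending
losses (a few percent on the SE at the fixture sizes tested).
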