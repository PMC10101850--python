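# Methods

## The molecular clock

Neutral SSNVs arrive at a roughly constant rate per cell division, so the
SSNV density of a clonal population (mutations per haploid basepair of the
analyzed genome) measures how much division history that population had
accumulated when it was founded. Two clocks are read per tumor:

- **MRCA density.** All clonal mutations — present in every tumor cell —
  predate the most recent common ancestor of the resected tumor. Counted
  per chromosome copy and per bp, they time the onset of the
  final clonal expansion.
- **ECA density.** A clonal chromosomal gain copies every mutation already
  on the gained allele. Mutations found clonally on ≥2 copies ("amplified
  clonal") therefore predate the gain, and their density per amplified-
  allele bp times the gain itself. Gains significantly younger (fewer
  amplified mutations) than the MRCA expectation define an earlier common
  ancestor.

### Clonal deconvolution

On a genomic class with copy number CN, B-allele count b and purity ρ,
clonal peaks sit at VAF = ρk/ζ, k ∈ {1, CN−b, b}, ζ = ρCN + 2(1−ρ).
Observed variant reads are binomial around the peaks; mixture weights over
the deduplicated peaks are estimated by EM (flat prior → MAP = MLE; 10
seeded Dirichlet restarts; validated against an exhaustive 0.01-step
simplex grid). Variants with VAF < ρ/ζ are discarded to keep subclonal
mutations out; by symmetry this removes half of the single-copy peak, so
its count is doubled: n₁ = 2·w₁·N. The b-allele peak count is also
doubled (n_b = 2·w_b·N, b > 1) by the published convention of the
framework this implements, although that peak lies above the cutoff; for b = CN−b the two
amplified peaks coincide and are fitted as one undoubled weight. The
per-copy clonal count of class *l* is
n_l = (n₁ + (CN−b)·n_{CN−b} + b·n_b)/CN.

Classes are formed by pooling all autosomal segments of equal (CN, b)
genome-wide (``merge_by="chrom"`` keeps chromosomes separate); segments
with CN > 4 or ≤ 10⁷ bp are excluded as statistically ambiguous. A CN
state missing from the caller is filled in when a candidate state matches
the measured coverage ratio within ±0.1 and BAF within ±0.05; ambiguous or
unmatched segments are dropped.

### False-positive correction

Incomplete sampling of a spatially structured tumor makes some subclonal
mutations look clonal. Following the primary/relapse-pair estimate that
~15% of apparently clonal calls are such artifacts, the MRCA count is
multiplied by (1 − FP), FP = 0.15 (configurable). The synthetic generator
plants the corresponding artifact fraction so the corrected estimator is
unbiased under its own assumptions.

### Pre-MRCA test

Under the null that a gain is coincident with the MRCA, the amplified
clonal count on a class of amplified length g_l follows a negative
binomial with size m_MRCA and success probability p = 1/(1 + g_l/g) —
mean m_MRCA·g_l/g, overdispersed to absorb mutation-rate heterogeneity
along the genome. One-sided P(X ≤ n_amp) is computed via the regularized
incomplete beta (stable to m ~ 10⁵); Holm correction at 0.01 per tumor.
Classes with amplified density *above* the MRCA density are excluded as
probable subclonal copy-number calls. ECA density pools amplified counts
over amplified-allele lengths of the significant classes, counting the b
and CN−b allele classes separately (so a 2+2 tetrasomy contributes its
segment length twice); a two-sided version of the same test checks each
contributing class for conformity with the pooled ECA. 95% CIs come from
1,000 bootstrap resamples of the genomic classes (percentile method).

### Classification and real time

Tumors split at 0.05 SSNVs/Mb of MRCA density (the upper border of the
early mode of the cohort bimodality); exactly-at-threshold is late. With a
daily diploid SSNV rate μλ (default calibration 3.2 ± 0.4/day) densities
convert to weeks post conception as t = 14 d + m̃·3.3×10⁹/(μλ/2); the
divisor 2 moves the diploid rate to the haploid density scale, and the
14-day offset reflects that somatic variants are called against the
zygote's genome but counted from gastrulation.

## Two-hit initiation model

Neural precursors expand exponentially (rates λ₁ > δ₁, λ₁ ≡ 1 fixes the
time unit to expansion-phase divisions) to a peak N(T), then either decay
(λ₂ < δ₂) or stay homeostatic (λ₂ = δ₂). A first oncogenic event
(probability μ₁ per division) reduces loss by 1/r; within such premalignant
clones a second event (μ₂, loss reduced by 1/s) founds the tumor if its
lineage survives, with ultimate survival ν₂ = 1 − δ/(sλ) at the respective
phase's rates. During fitting, s is not free: a target ν₂ is sampled and
s = max(1, δ₁/(λ₁(1−ν₂))), with ν₂ adjusted when the bound binds.

P_MRCA(t) combines three cases (both events before T; straddling T; both
after T). The after-peak cases are mean-field expressions in the expected
premalignant population M₁ (which grows exactly like N before the peak,
E[M₁(t)] = μ₁λ₁ t N(t), and at λ₂ − δ₂/r after it). The both-in-expansion
case is implemented as the same mean-field rate of surviving second hits,
1 − exp(−μ₁μ₂λ₁²ν₂E ∫₀ᵗ u N(u) du), which matches the explicit branching
simulator; a literature variant with a Luria–Delbrück correction factor
F = ∫₀¹ ν/(ν + z^α) dz, α = (δ₁ − sλ₁)/(δ₁ − λ₁), is available as
``case1_form="published"``. These mean-field forms are accurate while
P ≪ 1 — the regime of the observed incidence (~10⁻⁵) — and overshoot once
P = O(0.1), where heavy-tailed clone-size fluctuations matter; the
acceptance tests validate them in-domain against the Gillespie oracle.

The conditional first-event law weights first-hit times by expected clone
size at t₂: uniform (t₁/t₂) while the pool expands — the classical
Luria–Delbrück result — and an exponential-tilted closed form afterwards,
verified against direct numerical integration and the simulator. Event
times are sampled by inverse transform: x ~ U(0, 10⁻⁵) on P_MRCA for t₂
(draws beyond P_MRCA(t_max) are censored — no tumor), then y ~ U(0,1) on
P(t₁|t₂). Bisection refines roots to 10⁻⁶ time units; the ABC forward
path interpolates on 1024-point grids instead (error ≪ the Poisson noise
of the mutation counts).

## Growth model

Tumor growth is a supercritical birth–death process (λ_T ≡ 1, relative
loss δ_T/λ_T ∈ [0,1)) observed at N_end = 10⁹ cells. Neutral mutations
arise at μ per division (diploid genome) and drift as independent clones
with the geometric-with-extinction law P_{1,i}(t). The expected count in a
clone-size window is a single time integral (the clone-size sum is
geometric, hence analytic); adaptive quadrature serves the API, and a
cached fixed-order Gauss–Legendre rule (160 nodes) vectorizes all 0.05-
frequency bins for the ABC forward model. The observable tail carries
μ_eff = μ/(1 − δ_T/λ_T) — cumulative counts above f follow μ_eff(1/f − 1)
— so a single histogram identifies μ_eff and the founder ("clonal") count
n_clonal, not μ and δ_T/λ_T separately; the loss ratio is recovered as
1 − 2μ/μ_eff with the cohort-calibrated per-division rate μ (factor 2:
haploid rate vs diploid μ_eff), and the per-day division rate as
λ = (2m_MRCA + ln(10⁹)·μ_eff)/(2μ·(age + 250 d)), where 250 d approximates
embryogenesis after gastrulation. Uncertainties propagate to first order
with summed absolute terms.

Data preparation stratifies mutations by copy number (k ≤ 4, states with
≥ 10⁸ bp), classifies amplified clonal mutations by 95% binomial-quantile
windows at the state's mean coverage (overlapping windows resolve to the
higher multiplicity), merges them into the single-copy peak by multiplying
VAFs by l/k and replicating l times (the published convention — note for
CN=3, l=2 the merged entries land at 4/3 of the single-copy peak; the
identical rule is applied on the simulation side so the ABC comparison is
consistent), computes cumulative counts F_k(f) = #{VAF_k > f} on the
0.05 grid, and extrapolates to genome scale by Σg/g_k.

## ABC–SMC

A generic sequential sampler: generation 0 draws from the prior; each
later generation resamples, perturbs with a Gaussian kernel (2× weighted
covariance, internal coordinates log₁₀ for log-uniform priors), and
accepts below the median of the previous accepted distances, with
kernel-corrected importance weights. Stopping: ε ≤ target, generation cap,
or an exhausted attempt budget. Fully determined by one seed.

Costs: the initiation fit compares cumulative incidence counts of
simulated vs observed ECA/MRCA densities at the observed values, weighting
points below 0.2 SSNVs/Mb tenfold and penalizing deviation of the late-age
incidence from 10⁻⁵ (squared residual at scale 10⁻⁴ by default; the
un-squared literature variant is available); degenerate count
uncertainties are floored at one. The growth fit sums squared differences
of cumulative VAF counts per copy-number state, weighted by genome
fraction. Default priors are weakly informative over plausible ranges
(μ₁, μ₂ log-uniform 10⁻⁹–10⁻³; peak size log-uniform 10⁴–10⁹; loss ratios
uniform; μ log-uniform 0.1–100; r uniform 1–20) and overridable.

## Synthetic data

The generator inverts the timing analysis under the study conditions it
is tested at: purity 0.9, 80× coverage (scaled per-class by relative DNA
content), a near-triploid profile with whole-chromosome trisomies as the
candidate early event and two tetrasomic classes gained at the MRCA;
amplified clonal counts Poisson at the ECA density per gained allele
class, single-copy counts filling the per-copy MRCA density (0.06/Mb for
the late-MRCA conditions, 0.03/Mb single-event for early-MRCA) plus the
15% false-positive fraction, a subclonal tail from the expected birth–
death spectrum with Poisson noise, and binomial read sampling at Poisson
depth (floored at one read). Master seeds expand into independent child
streams via `numpy.random.SeedSequence`.

What it does *not* emulate: mapping artifacts, strand bias, germline
contamination, subclonal copy-number changes, regional mutation-rate
heterogeneity (the negative binomial's overdispersion is therefore
conservative on synthetic data), or spatial sampling beyond the global
false-positive fraction. Passing recovery tests show the estimators are
consistent under the model's own assumptions at realistic depth/purity —
not that those assumptions hold in any particular real tumor.

The two stochastic oracles are deliberately brute-force: a Gillespie
two-hit simulator on the deterministic precursor trajectory (explicit
clone bookkeeping, per-division second hits, Bernoulli ultimate survival)
and a lineage-tracking birth–death simulator for the spectrum. The latter
runs either to fixed size conditioned on non-extinction (the observable-
tumor ensemble; ~2–3% inflated near fixation relative to the mean-field
integral) or unconditioned to fixed time, whose ensemble mean equals the
integral exactly by the branching property — the unbiased oracle used in
the acceptance comparison, with the midpoint clone-size convention
[a−½, b+½] standing in for the discrete sum at small N_end.

## Problem sizes

Tests and the acceptance script run on reduced but statistically
meaningful sizes chosen once: 50 timing replicates per class, 10⁴
branching replicates for the closed-form checks (second hits kept rare,
μ₂ = 2.5×10⁻⁴, to stay in the mean-field domain), 500 birth–death
replicates at N_end = 10³, ABC at 64–100 particles and 8–12 generations
(the full-scale configuration, 1,000 particles / 25 generations / ε ≤
0.05, remains the default of ``ABCConfig``).

## Known limitations

- Losses, high-level amplifications (CN > 4) and structural variants are
  not timed; LOH segments are timed only through their remaining allele.
- The initiation closed forms are mean-field: fine for incidence-scale
  probabilities, biased upward when P_MRCA approaches O(0.1).
- The growth fit cannot separate μ from δ_T/λ_T on a single tumor (only
  μ_eff is identified); loss ratios require an external μ.
- Arm-level event annotation ships a minimal hg19 arm table for autosomes
  only.
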