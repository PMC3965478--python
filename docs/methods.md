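# Methods

## The model

A short tandem repeat (STR) locus is a length polymorphism; an individual's
genotype there is an unordered allele pair.  Capillary electrophoresis of a
PCR-amplified mixture yields, per locus, a set of peaks: fragment size
(base pairs) identifies the allele, height (RFU) measures amplified
quantity.  For a K-person mixture the data vector **d** of peak heights is
modeled as

μ = M · Σₖ wₖ · dose(gₖ)/2 · e^(−δ·size/100),  then stutter,
d ~ MVN(μ, Σ),   Σ = diag(σ²_floor + σ_scale · μ),

where gₖ is contributor k's allele pair (dose 0/1/2 per allele position),
W = (w₁…w_K) are mixture weights on the simplex, M is the combined allelic
fluorescence ("template mass", RFU scale), δ ≥ 0 is an exponential
degradation rate per 100 bp, and back stutter moves a fraction r of each
allele's expected height to the position one repeat shorter (total signal
conserved).  The affine-variance diagonal covariance captures
heteroscedastic PCR noise — variance grows with expected height — while
staying bounded away from zero for dropout scoring.  The likelihood is an
untruncated Gaussian (an approximation near zero heights; truncation is a
possible extension).

The allele grid at a locus is the union of observed peak positions, the
hypothesized genotype alleles and their back-stutter positions; the data
height is zero at unobserved grid positions, so a hypothesis that predicts
a peak that did not appear pays the dropout penalty.

### Priors

Genotype priors come from population allele frequencies with a co-ancestry
(θ) correction.  We use the unconditional Balding–Nichols genotype
probabilities (the Dirichlet sampling formula):

P(aᵢaᵢ) = pᵢ[θ + (1−θ)pᵢ],  P(aᵢaⱼ) = 2(1−θ)pᵢpⱼ,

which sum to exactly one over the genotype space, reduce to Hardy–Weinberg
at θ = 0, and enrich homozygotes for θ > 0.  (The superficially similar
NRC-II 4.10a/b expressions with the (1+θ)(1+2θ) denominator are
*conditional* match probabilities — they do not normalize over genotypes
and are therefore unusable as a prior; we deliberately do not use them.)
Default θ = 0.01.  Alleles absent from a frequency table (e.g. a called
stutter position) can be assigned a minimum frequency of 5/2N (fallback
0.001), logged when used.  Weights carry a flat Dirichlet prior; mass and
the optional nuisance parameters carry flat priors on the log scale.

## Inference

The sampler is Metropolis-within-Gibbs:

* **Genotypes** — each contributor's pair at each locus is redrawn from its
  exact full conditional, enumerated over the candidate pair support
  (likelihood × prior).  Additionally, one randomly chosen *pair* of
  contributors per locus per sweep is redrawn from its exact two-site
  conditional.  The joint update matters: with near-equal weights,
  single-site updates cannot re-pair alleles between contributors without
  passing through low-probability intermediates, and the weight chain then
  sits at the symmetric w = 1/K saddle.  The two-site enumeration lets a
  locus re-orient its pairing in one move.
* **Weights** — random-walk Metropolis in logit-simplex coordinates
  (Jacobian-corrected), so W stays on the simplex by construction.
* **Mass** — lognormal random walk (flat prior on log M).
* **Stutter, degradation, variance scale** — lognormal random-walk kernels
  exist but are *off by default*: stutter ratios and variance parameters
  are instrument/kit calibration constants in routine use, and freeing them
  on a single profile costs identifiability at desk scale.  They can be
  switched on per run.

Candidate genotype support defaults to pairs of the alleles observed at the
locus (plus any assumed contributor's alleles) — the standard
observed-allele support of quantitative mixture software; the full panel
range is available via `candidate_support="panel"`.  The restriction makes
the per-locus enumeration exact and fast, at the price that a posterior can
assign exactly zero to pairs involving unobserved alleles: a reference with
a dropped-out allele is reported as LR 0 at that locus rather than a small
positive value.  Validation statistics clamp such exclusionary bans at −30
for aggregation.

**Initialization**: genotypes from the prior, weights from a flat Dirichlet
draw (a deliberate symmetry breaker), M from the mean observed locus
height.  **Defaults**: 20,000 iterations, 5,000 burn-in (the bundled
experiments use 1,500/500, which the concordance checks show is converged
for clean two-person profiles).  **Label switching**: contributors are
reported in weight-ranked slots, applied *per posterior sample* (assumed
contributors pinned first), making the reported marginals invariant to
global relabeling.  **Determinism**: a single seed drives the whole run.

The contributor count K is assumed, not inferred, with an allele-count
suggestion utility and a convenience routine that runs K and K+1.
Inference never sees a reference genotype.

Per-profile variance estimation (`variance_scale=None`) runs a
method-of-moments pass over loci showing exactly two peaks in ≥ 60%
balance — treated as one contributor's heterozygote — regressing squared
deviations on mean height; it falls back to the configured defaults
(floor 100 RFU², scale 5 RFU) when no such loci exist.

### Exactness

For small problems the posterior is enumerable, and the sampler was checked
against brute-force enumeration: with weights and mass fixed, MCMC genotype
marginals on 2-contributor, ≤ 5-allele loci agree with exhaustive
enumeration within Monte-Carlo error.  On simulated near-balanced mixtures
the MCMC's per-locus major-genotype accuracy equals that of exact
enumeration with weights fixed at truth — the residual errors there are
posterior ambiguity, not sampler error (see Limitations).

## Match statistics

Locus LR = posterior(ref pair)/prior(ref pair); independent loci multiply;
log₁₀ LR is the ban.  A posterior of exactly zero at the reference reports
LR 0 (no smoothing), with the sample count available to judge resolution.
Classification uses a configurable ± 0.5 ban inconclusive band around zero.
Across multiple populations the smallest statistic is reported
(conservative).  LRs display at 3 significant figures, bans at 2 decimals;
full precision is kept internally.

The comparators: CPI calls alleles at per-dye analytical thresholds
(defaults 73/84/75/52 RFU for blue/green/yellow/red), restricts the
genotype prior to pairs of called alleles (0/1 inclusion likelihood,
renormalized), and uses the reciprocal of the inclusion probability
(Σ called frequencies)² as the locus LR; mCPI additionally requires every
called allele to reach the stochastic threshold of its injection time
(defaults 210/320/460 RFU at 2/5/10 s) or the locus is dropped.  A peak
exactly at a threshold is called (≥ convention, configurable).  θ enters
CPI through the restricted-prior sum (identical to (Σp)² at θ = 0, the
default, matching the usual manual arithmetic).  Stutter positions are not
filtered by the comparators — every supra-threshold peak is an allele
event — with a config option for pre-removal in sensitivity analyses.
Comparator locus LRs are ≥ 1 by construction; only the genotype model can
report negative weight of evidence.

## The simulator

The generator emulates 2–4-person PowerPlex-16-style 15-locus profiles:
per-allele expected heights from dose × weight × mass, exponential
degradation in size, 5% single-position back stutter (mass-conserving),
multiplicative lognormal noise with unit mean and configurable cv
(default 0.1), and a 10 RFU detection floor.  Fragment sizes are
`offset + repeats × repeat_unit`, with microvariants ("9.3") contributing
their extra bases.  Default total mass 3,000 RFU keeps a 10% minor
contributor's alleles (~150 RFU) above the analytical thresholds but below
the 5 s stochastic threshold — the regime where the three methods diverge.
Two-person mixture weights are drawn uniformly on (0.1, 0.9).  The bundled
allele-frequency table is *synthetic* (Dirichlet draws with a unimodal
concentration profile), standing in for confidential casework databases.

What the simulator does **not** emulate: baseline noise peaks, pull-up and
bleed-through artifacts, forward stutter, off-ladder alleles, locus-specific
amplification efficiency (configurable but defaulting to balanced), or
inter-locus degradation beyond the single exponential.  Experiments passing
on these data therefore demonstrate internal consistency of model and
method — not performance on real casework signal artifacts.

## Validation procedures

* **Specificity** — inferred evidence genotypes are compared against
  references sampled from the θ-corrected priors; the report aggregates the
  noncontributor ban distribution (mean/min/max/sd, tail counts above
  0–3 ban, false-positive rate), with bans clamped at −30.  Because of the
  observed-allele support, most noncontributors are outright excluded
  (LR 0) rather than merely disfavored, so the clamp binds often.
* **Precision** — within-group standard deviation of duplicate-run bans:
  each pair contributes the ML (ddof = 0) variance about its own mean, so a
  pair differing by d contributes d²/4; the report is the square root of
  the mean within-pair variance.  (A duplicate pair (10.0, 10.2) gives
  exactly 0.1.)
* **Uniformity** — one-sample Kolmogorov–Smirnov tests against
  Uniform(lower, upper), exact for n ≤ 50, asymptotic above; used both for
  ban distributions over mixture ensembles and for inferred mixture
  weights, and calibrated under the null (≈ 5% rejections at α = 0.05 over
  200 seeded repetitions).
* **Concordance** — replicate runs are compared by symmetrized,
  support-union KL divergence (base 10; lightly smoothed so a pair one
  replicate never visited stays finite) per locus and contributor, with a
  0.05 ban default tolerance, plus a 0.05 weight-mean check.  Chain-length
  settings are exempt from the settings-equality precondition so an
  under-run chain can be compared against a converged one and flagged.

## Numerical choices

Log-space throughout; conditional enumeration subtracts the max before
exponentiation.  Genotype distributions validate to Σ = 1 ± 1e-9.
Combined LRs with a zero locus report ban = −∞, clamped only inside
validation aggregation.  Ties in posterior modes break by canonical pair
order; ties across populations break by name.  Empty loci are skipped
(flag, not an exception) and contribute no information.

## Known limitations

* Near-balanced mixtures (weights within a few percent of equal) are
  intrinsically ambiguous about which contributor carries which pair: with
  peak-height cv 0.1, the per-allele discriminability of the two
  assignments is Δw/(2·cv·w̄) regardless of template amount.  Exact
  enumeration shows per-locus major-genotype accuracy dropping toward
  chance as w → 0.5; ensemble-level "major-contributor mode equals truth"
  rates therefore plateau around ~90% when weights span 0.1–0.9, rising
  above 95% once the major weight exceeds ~0.55.
* Observed-allele support precludes partial credit for dropped-out alleles
  (LR exactly 0 instead of small); use `candidate_support="panel"` where
  that matters and the locus is small enough to enumerate.
* The affine variance model cannot match purely multiplicative noise at
  both tail ends of the height range; it is a deliberate, minimal
  heteroscedastic form.
* Loci are treated as independent (no linkage), and a single θ describes
  substructure.
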