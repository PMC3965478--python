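# pgmix — probabilistic genotyping of forensic STR mixtures

Forensic DNA evidence is frequently a *mixture*: biological material from
two or more people, amplified at a panel of short tandem repeat (STR) loci
and read out as electropherogram (EPG) peaks whose sizes encode alleles and
whose heights (in RFU) encode DNA quantity.  Human review collapses those
quantitative peaks into all-or-none "allele" calls with thresholds and
computes an inclusion statistic; quantitative modeling instead infers each
contributor's genotype *up to probability* from the full peak pattern and
reports a likelihood ratio.  `pgmix` implements both routes, plus the
simulation and validation machinery needed to compare them, for analysts
and statisticians studying mixture interpretation methods.

## What it computes

**Quantitative model.** For peak-height data **d** at a locus with K
contributors holding allele pairs g₁…g_K, mixture weights W (summing to 1)
and template mass M, the model builds the mean pattern

μ = M · Σₖ wₖ · gₖ/2,

adjusted for single-exponential degradation in fragment size and one-repeat
back stutter, and scores the data with a multivariate normal likelihood
N(d; μ, Σ) whose diagonal covariance grows with expected height
(σ²ᵢ = floor + scale·μᵢ).  Bayes' theorem combines this likelihood with
population genotype priors (Balding–Nichols θ-corrected); a
Metropolis-within-Gibbs MCMC sampler (exact enumeration of each genotype's
full conditional, logit-simplex walk for W, lognormal walk for M) returns
per-contributor genotype posterior distributions.  The match statistic for
a reference genotype is the likelihood ratio

LR = Pr(g_ref | d) / Pr(g_ref),

multiplied across independent loci; log₁₀ LR is the weight of evidence in
"ban".

**Threshold comparators.** CPI (combined probability of inclusion, a.k.a.
RMNE) calls every peak above a per-dye analytical threshold an allele and
uses (Σ called allele frequencies)² per locus, reciprocal as a locus LR.
mCPI additionally drops any locus where a called allele falls below the
per-injection-time stochastic threshold — often discarding the statistic
entirely.

**Simulation & validation.** A synthetic-EPG generator (PowerPlex-16-like
15-locus panel, stutter, degradation, lognormal peak noise, 10 RFU
detection floor) provides ground truth for specificity, precision,
sensitivity-uniformity (Kolmogorov–Smirnov) and parameter-recovery
experiments.

## Worked example

The classic two-contributor illustration: a locus shows peaks of about
600/600/300/300 RFU at alleles 7, 14, 10, 12 — a 7,14 major with twice the
DNA of a 10,12 minor.

```python
from pgmix import *

panel = default_panel()
freqs = synthetic_frequency_table(panel, seed=1)

major = ContributorProfile("major", {"PentaE": GenotypePair.make("PentaE", "7", "14")})
minor = ContributorProfile("minor", {"PentaE": GenotypePair.make("PentaE", "10", "12")})
spec = MixtureSpec([major, minor], weights=[2/3, 1/3], total_mass=1800,
                   stutter_rate=0.0, cv=0.02, panel=panel)
peaks = simulate_profile(spec, rng=21)

settings = InferenceSettings(n_contributors=2, iterations=3000, burn_in=1000,
                             seed=4, stutter_rate=0.0, variance_scale=5.0)
result = infer(peaks, settings, freqs, panel)
post = result.posteriors["PentaE"][1]          # minor contributor
print(result.weight_mean.round(2))             # [0.67 0.33]
print(post.mode(), round(post.prob(post.mode()), 2))
# PentaE:10,12 1.0
```

The minor contributor's posterior concentrates essentially all its mass on
the 10,12 pair: the peak-height pattern resolves the mixture.  The same
data pushed through the threshold comparators spread the posterior over all
ten pairs of the four called alleles (CPI locus LR ≈ 4) or, at a 5 s
injection where the 300 RFU peaks sit below the 320 RFU stochastic
threshold, drop the locus from mCPI altogether.

A command-line surface wraps the same pipeline:

```bash
pgmix simulate --seed 7 --out mix.csv
pgmix infer --peaks mix.csv --frequencies mix_freqs.csv \
            --contributors 2 --seed 2 --out inference.json
pgmix match --inference inference.json --references mix_truth.csv \
            --frequencies mix_freqs.csv --out report.json
pgmix cpi   --peaks mix.csv --references mix_truth.csv \
            --frequencies mix_freqs.csv --out cpi.json
```

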