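"""Reliability experiments: specificity, precision, sensitivity, uniformity.

Reusable desk-scale versions of the standard probabilistic-genotyping
validation battery:

* specificity — compare inferred evidence genotypes against randomly
  generated noncontributor references and measure how often a positive
  weight of evidence occurs by chance (the false-positive rate);
* precision — within-group standard deviation of the ban over duplicate
  MCMC runs on the same data;
* sensitivity/accuracy — over an ensemble of mixtures with uniformly
  distributed weights, match statistics for true contributors should span
  their range roughly uniformly; a one-sample Kolmogorov-Smirnov test
  quantifies the comparison;
* recovery — simulate mixtures with known ground truth, infer, and check
  that mixture weights and major-contributor genotypes are recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .match import genotype_match
from .mcmc import InferenceResult, InferenceSettings, infer
from .panel import Panel
from .population import (
    GenotypeDistribution,
    build_prior_distribution,
    PopulationFrequencyTable,
)
from .simulate import (
    apply_detection_floor,
    MixtureSpec,
    PeakTable,
    random_mixture,
    simulate_profile,
)
from .thresholds import call_alleles, inclusion_match, ThresholdConfig

logger = logging.getLogger(__name__)

#: aggregation floor for exclusionary ban values
BAN_CLAMP = -30.0


@dataclass
class SpecificityReport:
    """Noncontributor log(LR) distribution summary."""

    n_comparisons: int
    mean_ban: float
    min_ban: float
    max_ban: float
    sd_ban: float
    tail_counts: dict[int, int]  # count of ban > threshold, thresholds 0..3
    false_positive_rate: float
    seed: int

    def __post_init__(self) -> None:
        counts = [self.tail_counts[t] for t in sorted(self.tail_counts)]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise InputError("tail counts must be non-increasing in threshold")


def specificity_experiment(
    evidence_genotypes: Sequence[Mapping[str, GenotypeDistribution]],
    freqs: PopulationFrequencyTable,
    theta: float,
    n_random: int,
    seed: int,
    ban_clamp: float = BAN_CLAMP,
) -> SpecificityReport:
    """Compare evidence genotypes with random noncontributor references.

    For each inferred evidence genotype, *n_random* references are drawn
    from the co-ancestry-corrected population priors; each comparison's
    combined ban is the sum of per-locus log10 posterior/prior ratios.
    Bans below *ban_clamp* (including the -inf from a zero posterior) are
    clamped there for aggregation; clamping is logged.  Seeded and
    reproducible.
    """
    if n_random < 1:
        raise InputError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    all_bans: list[np.ndarray] = []
    for evidence in evidence_genotypes:
        bans = np.zeros(n_random)
        for locus, posterior in evidence.items():
            prior = build_prior_distribution(locus, freqs, theta)
            pairs = prior.support
            pv = np.array([prior.mass[p] for p in pairs])
            qv = np.array([posterior.prob(p) for p in pairs])
            with np.errstate(divide="ignore"):
                log_lr = np.where(qv > 0, np.log10(np.maximum(qv, 1e-300) / pv), -np.inf)
            idx = rng.choice(len(pairs), size=n_random, p=pv / pv.sum())
            bans += log_lr[idx]
        all_bans.append(bans)
    bans = np.concatenate(all_bans)
    n_clamped = int(np.sum(bans < ban_clamp))
    if n_clamped:
        logger.info(
            "clamped %d of %d noncontributor ban values at %.1f",
            n_clamped,
            bans.size,
            ban_clamp,
        )
    bans = np.maximum(bans, ban_clamp)
    tail = {t: int(np.sum(bans > t)) for t in (0, 1, 2, 3)}
    return SpecificityReport(
        n_comparisons=int(bans.size),
        mean_ban=float(bans.mean()),
        min_ban=float(bans.min()),
        max_ban=float(bans.max()),
        sd_ban=float(bans.std()),
        tail_counts=tail,
        false_positive_rate=tail[0] / bans.size,
        seed=seed,
    )


@dataclass
class PrecisionReport:
    n_pairs: int
    within_group_sd: float


def precision_within_group_sd(
    pairs: Sequence[tuple[float, float]]
) -> PrecisionReport:
    """Within-group standard deviation of duplicate-run ban values.

    Each replicate pair contributes the variance of its two values about
    their own mean (maximum-likelihood form, so a duplicate pair differing
    by d contributes d^2/4); the reported figure is the square root of the
    mean within-pair variance.  Identical pairs give exactly 0.
    """
    if not pairs:
        raise InputError("no replicate pairs given")
    d = np.array([a - b for a, b in pairs], dtype=float)
    return PrecisionReport(
        n_pairs=len(pairs),
        within_group_sd=float(np.sqrt(np.mean(d * d / 4.0))),
    )


def ks_uniformity(
    bans: Sequence[float], lower: float, upper: float
) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against Uniform(lower, upper).

    Uses the exact small-sample distribution for n <= 50 and the asymptotic
    Kolmogorov distribution otherwise.  Returns (KS statistic, p-value).
    """
    vals = np.asarray(bans, dtype=float)
    if vals.size < 5:
        raise InputError("need at least 5 values for the KS test")
    if upper <= lower:
        raise InputError("degenerate range: upper must exceed lower")
    method = "exact" if vals.size <= 50 else "asymp"
    res = stats.kstest(
        vals, stats.uniform(loc=lower, scale=upper - lower).cdf, method=method
    )
    return float(res.statistic), float(res.pvalue)


def weight_uniformity(
    weights: Sequence[float], lower: float = 0.0, upper: float = 1.0
) -> tuple[float, float]:
    """KS test of inferred mixture weights against Uniform(lower, upper)."""
    return ks_uniformity(weights, lower, upper)


@dataclass
class RecoveryExperiment:
    """Simulated mixtures with known truth plus their inference results."""

    specs: list[MixtureSpec]
    peaks: list[PeakTable]
    results: list[InferenceResult]
    duplicates: list[InferenceResult]
    priors: dict[str, GenotypeDistribution]
    freqs: PopulationFrequencyTable
    theta: float
    seed: int

    def true_major_weights(self) -> np.ndarray:
        return np.array([max(s.weights) for s in self.specs])

    def inferred_major_weights(self) -> np.ndarray:
        # contributors are reported in decreasing posterior-weight order
        return np.array([r.weight_mean[0] for r in self.results])

    def weight_correlation(self) -> float:
        """Pearson r between true and posterior-mean major weights."""
        return float(
            np.corrcoef(self.true_major_weights(), self.inferred_major_weights())[0, 1]
        )

    def major_mode_accuracy(self) -> float:
        """Fraction of loci where the inferred major contributor's posterior
        mode equals the true major contributor's genotype."""
        hits = total = 0
        for spec, result in zip(self.specs, self.results):
            major = int(np.argmax(spec.weights))
            truth = spec.contributors[major].genotypes
            for locus, dists in result.posteriors.items():
                total += 1
                hits += dists[0].mode() == truth[locus]
        return hits / total if total else float("nan")

    def contributor_matches(
        self, thresholds: ThresholdConfig | None = None
    ) -> pd.DataFrame:
        """Match statistics for every true contributor by all three methods.

        Columns: mixture, contributor, weight, genotype_ban, cpi_ban,
        mcpi_ban, cpi_class, mcpi_class.  The genotype-model comparison
        aligns each true contributor with the inferred contributor of
        matching weight rank.
        """
        thresholds = thresholds or ThresholdConfig()
        # called stutter peaks can carry labels unseen in the database; the
        # standard minimum-frequency floor keeps the inclusion arithmetic
        # defined for them
        freqs = self.freqs.with_rare_allele_floor()
        rows = []
        for i, (spec, peaks, result) in enumerate(
            zip(self.specs, self.peaks, self.results)
        ):
            calls = call_alleles(peaks, thresholds)
            rank = np.argsort(-np.asarray(spec.weights))
            for slot, k in enumerate(rank):
                profile = spec.contributors[k]
                gm = genotype_match(
                    result.genotype(slot),
                    self.priors,
                    profile,
                    population=self.freqs.population_name,
                    sample=peaks.sample_name,
                )
                cpi = inclusion_match(calls, profile, freqs, 0.0, "cpi")
                mcpi = inclusion_match(calls, profile, freqs, 0.0, "mcpi")
                rows.append(
                    {
                        "mixture": i,
                        "contributor": profile.sample_name,
                        "weight": spec.weights[k],
                        "genotype_ban": gm.log10_lr_ban,
                        "cpi_ban": cpi.log10_lr_ban,
                        "mcpi_ban": mcpi.log10_lr_ban,
                        "cpi_class": cpi.classification,
                        "mcpi_class": mcpi.classification,
                    }
                )
        return pd.DataFrame(rows)

    def precision_pairs(self) -> list[tuple[float, float]]:
        """Ban pairs for the major contributor from duplicate runs."""
        pairs = []
        for spec, result, dup in zip(self.specs, self.results, self.duplicates):
            major = int(np.argmax(spec.weights))
            profile = spec.contributors[major]
            bans = []
            for r in (result, dup):
                gm = genotype_match(
                    r.genotype(0), self.priors, profile,
                    population=self.freqs.population_name,
                )
                bans.append(gm.log10_lr_ban)
            pairs.append((bans[0], bans[1]))
        return pairs


def mixture_recovery_experiment(
    freqs: PopulationFrequencyTable,
    panel: Panel,
    n_mixtures: int = 20,
    seed: int = 0,
    n_contributors: int = 2,
    cv: float = 0.1,
    theta: float = 0.01,
    iterations: int = 1500,
    burn_in: int = 500,
    duplicates: bool = True,
    variance_scale: float | None = 5.0,
    **spec_kwargs,
) -> RecoveryExperiment:
    """Simulate mixtures with weights spanning 10-90%, infer, and package
    everything needed for recovery, specificity, precision and method-
    comparison checks.  Fully determined by *seed*.
    """
    rng = np.random.default_rng(seed)
    priors = {
        locus: build_prior_distribution(locus, freqs, theta)
        for locus in panel.locus_names
    }
    specs, tables, results, dups = [], [], [], []
    for i in range(n_mixtures):
        spec = random_mixture(
            freqs,
            panel,
            n_contributors=n_contributors,
            theta=theta,
            rng=rng,
            cv=cv,
            **spec_kwargs,
        )
        peaks = apply_detection_floor(simulate_profile(spec, rng=rng))
        settings = InferenceSettings(
            n_contributors=n_contributors,
            iterations=iterations,
            burn_in=burn_in,
            seed=int(rng.integers(2**31 - 1)),
            theta=theta,
            stutter_rate=spec.stutter_rate,
            degradation_rate=spec.degradation_rate,
            variance_scale=variance_scale,
        )
        result = infer(peaks, settings, freqs, panel)
        specs.append(spec)
        tables.append(peaks)
        results.append(result)
        if duplicates:
            dup_settings = replace(settings, seed=int(rng.integers(2**31 - 1)))
            dups.append(infer(peaks, dup_settings, freqs, panel))
    return RecoveryExperiment(
        specs=specs,
        peaks=tables,
        results=results,
        duplicates=dups,
        priors=priors,
        freqs=freqs,
        theta=theta,
        seed=seed,
    )
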