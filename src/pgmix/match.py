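"""Likelihood-ratio match statistics from genotype distributions.

The LR at one locus is the ratio of posterior to prior genotype
probability, evaluated at the reference's allele pair.  Independent locus
LRs multiply into the combined match statistic; its base-10 logarithm (the
"ban") expresses identification information additively.  A positive ban
supports a match, a negative ban does not, and values inside a small band
around zero are inconclusive.  Unlike the threshold-based comparators, the
genotype-model LR can fall below 1 and so can quantify exclusionary
support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import InputError
from .population import GenotypeDistribution, GenotypePair
from .simulate import ContributorProfile

#: half-width (ban) of the default inconclusive zone around log(LR) = 0
DEFAULT_INCONCLUSIVE_BAND = 0.5


@dataclass
class MatchResult:
    """Per-locus and combined LR for one evidence/reference comparison."""

    sample: str
    reference: str
    population: str
    method: str
    per_locus_lr: dict[str, float]
    combined_lr: float
    log10_lr_ban: float
    classification: str
    locus_status: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_locus_lr and not math.isnan(self.combined_lr):
            product = 1.0
            for lr in self.per_locus_lr.values():
                product *= lr
            if product > 0 and self.combined_lr > 0:
                if abs(product - self.combined_lr) > 1e-9 * max(product, self.combined_lr):
                    raise InputError(
                        "combined LR does not equal the product of locus LRs"
                    )

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "reference": self.reference,
            "population": self.population,
            "method": self.method,
            "per_locus_lr": dict(self.per_locus_lr),
            "combined_lr": self.combined_lr,
            "log10_lr_ban": self.log10_lr_ban,
            "classification": self.classification,
            "locus_status": dict(self.locus_status),
            "metadata": dict(self.metadata),
        }

    def sentence(self) -> str:
        """Plain-language report statement for an inclusionary result."""
        if not math.isfinite(self.combined_lr):
            return "No match statistic could be computed."
        return (
            f"A match between the evidence and reference is "
            f"{self.combined_lr:.3g} times more probable than coincidence."
        )


def locus_lr(
    posterior: GenotypeDistribution,
    prior: GenotypeDistribution,
    ref: GenotypePair,
) -> float:
    """LR at one locus: posterior(ref) / prior(ref).

    Equals 1 when the posterior matches the prior (no information) and 0
    when the posterior assigns the reference pair no mass; a zero prior is
    an error (the LR is undefined there).
    """
    p_prior = prior.prob(ref)
    if p_prior <= 0.0:
        raise InputError(f"reference pair {ref} has zero prior; LR undefined")
    return posterior.prob(ref) / p_prior


def combine_loci(locus_lrs: Mapping[str, float]) -> tuple[float, float]:
    """Product of independent locus LRs and its base-10 log (ban).

    A zero locus LR drives the combined LR to 0 and the ban to -inf,
    reported as exclusionary support rather than an error.
    """
    if not locus_lrs:
        raise InputError("no locus LRs to combine")
    ban = 0.0
    for locus, lr in locus_lrs.items():
        if lr < 0:
            raise InputError(f"negative LR at {locus}")
        if lr == 0.0:
            return 0.0, float("-inf")
        ban += math.log10(lr)
    return 10.0 ** ban, ban


def classify_log_lr(
    ban: float, inconclusive_band: float = DEFAULT_INCONCLUSIVE_BAND
) -> str:
    """include / exclude / inconclusive from the weight of evidence."""
    if inconclusive_band < 0:
        raise InputError("inconclusive band must be >= 0")
    if ban > inconclusive_band:
        return "include"
    if ban < -inconclusive_band:
        return "exclude"
    return "inconclusive"


def genotype_match(
    posteriors: Mapping[str, GenotypeDistribution],
    priors: Mapping[str, GenotypeDistribution],
    reference: ContributorProfile,
    population: str = "",
    sample: str = "",
    inconclusive_band: float = DEFAULT_INCONCLUSIVE_BAND,
    metadata: dict | None = None,
) -> MatchResult:
    """Full genotype-model match: per-locus LRs, combined LR, classification.

    Loci present in both the posterior map and the reference are used; the
    posterior of a locus with no data should simply be absent (such loci
    contribute no information).
    """
    per_locus: dict[str, float] = {}
    for locus, posterior in posteriors.items():
        if locus not in reference.genotypes:
            continue
        per_locus[locus] = locus_lr(
            posterior, priors[locus], reference.genotypes[locus]
        )
    if not per_locus:
        raise InputError("no loci shared between posterior and reference")
    combined, ban = combine_loci(per_locus)
    return MatchResult(
        sample=sample,
        reference=reference.sample_name,
        population=population,
        method="genotype-model",
        per_locus_lr=per_locus,
        combined_lr=combined,
        log10_lr_ban=ban,
        classification=classify_log_lr(ban, inconclusive_band),
        metadata=metadata or {},
    )


def min_over_populations(results: Sequence[MatchResult]) -> MatchResult:
    """The conservative (smallest combined LR) result across populations.

    Ties break by population name order.  All inputs must concern the same
    sample and reference.
    """
    if not results:
        raise InputError("no results given")
    first = results[0]
    for r in results[1:]:
        if (r.sample, r.reference) != (first.sample, first.reference):
            raise InputError("results mix different samples or references")
    return min(results, key=lambda r: (r.combined_lr, r.population))

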