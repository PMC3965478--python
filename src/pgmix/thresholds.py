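"""Threshold-based manual interpretation: allele calling, CPI and mCPI.

The manual comparator methods reduce quantitative peak data to all-or-none
allele events.  An analytical threshold (per dye channel) separates
putative alleles from baseline noise; a higher stochastic threshold (per
capillary injection time) marks calls whose heterozygote sister allele
might have dropped out.

* CPI (combined probability of inclusion, also called RMNE): if every
  reference allele at a locus is called, the locus inclusion probability is
  the squared sum of called-allele frequencies; its reciprocal acts as a
  locus LR, multiplied across loci.
* mCPI additionally drops any locus where some called allele falls below
  the stochastic threshold; dropping loci can leave no statistic at all
  (an inconclusive result).

Default thresholds follow a casework configuration: analytical 73/84/75/52
RFU for blue/green/yellow/red dyes, stochastic 210/320/460 RFU for 2/5/10 s
injections.  Peaks exactly at a threshold are called (>= convention,
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import InputError
from .match import MatchResult, combine_loci
from .population import (
    GenotypeDistribution,
    GenotypePair,
    enumerate_pairs,
    genotype_prior,
    PopulationFrequencyTable,
)
from .simulate import ContributorProfile, PeakTable

DEFAULT_ANALYTICAL_BY_DYE = {"blue": 73.0, "green": 84.0, "yellow": 75.0, "red": 52.0}
DEFAULT_STOCHASTIC_BY_INJECTION = {2: 210.0, 5: 320.0, 10: 460.0}


@dataclass
class ThresholdConfig:
    """Analytical (per dye) and stochastic (per injection time) RFU levels."""

    analytical_by_dye: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTICAL_BY_DYE)
    )
    stochastic_by_injection: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STOCHASTIC_BY_INJECTION)
    )
    strict_above: bool = False  # True: call only peaks strictly above

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.analytical_by_dye.values()):
            raise InputError("analytical thresholds must be positive")
        if any(v <= 0 for v in self.stochastic_by_injection.values()):
            raise InputError("stochastic thresholds must be positive")

    def analytical(self, dye: str) -> float:
        if dye not in self.analytical_by_dye:
            raise InputError(f"no analytical threshold for dye {dye!r}")
        return self.analytical_by_dye[dye]

    def stochastic(self, injection_s: int) -> float:
        key = int(injection_s)
        if key not in self.stochastic_by_injection:
            raise InputError(f"no stochastic threshold for injection {injection_s}s")
        return self.stochastic_by_injection[key]


class AlleleCall(NamedTuple):
    allele: str
    height_rfu: float
    above_stochastic: bool


AlleleCallSet = dict[str, list[AlleleCall]]


def call_alleles(peaks: PeakTable, cfg: ThresholdConfig) -> AlleleCallSet:
    """Reduce peaks to called allele events, with stochastic marking.

    A peak is called when its height reaches the analytical threshold of
    its dye; each call is additionally marked by whether it reaches the
    stochastic threshold of its injection time.
    """
    calls: AlleleCallSet = {}
    for _, row in peaks.data.iterrows():
        at = cfg.analytical(row["dye"])
        st = cfg.stochastic(row["injection_s"])
        h = float(row["height_rfu"])
        passed = h > at if cfg.strict_above else h >= at
        if passed:
            above = h > st if cfg.strict_above else h >= st
            calls.setdefault(row["locus"], []).append(
                AlleleCall(str(row["allele"]), h, above)
            )
    return calls


def inclusion_posterior(
    calls: list[AlleleCall],
    prior: GenotypeDistribution,
    stochastic_only: bool = False,
) -> GenotypeDistribution | None:
    """Prior restricted to pairs of called alleles and renormalized.

    The inclusion likelihood is 1 for every pair formed from the called
    alleles (only those above the stochastic threshold when
    *stochastic_only*) and 0 otherwise; multiplying the prior by this 0/1
    likelihood and renormalizing gives the inclusion posterior.  Returns
    ``None`` (locus inconclusive flag) when the usable call set is empty.
    """
    usable = [c for c in calls if c.above_stochastic] if stochastic_only else calls
    if not usable:
        return None
    alleles = sorted({c.allele for c in usable})
    pairs = enumerate_pairs(alleles, prior.locus)
    weights = {}
    for pair in pairs:
        p = prior.prob(pair)
        if p == 0.0:
            raise InputError(
                f"called pair {pair} missing from the prior's allele universe"
            )
        weights[pair] = p
    return GenotypeDistribution.from_weights(prior.locus, weights)


def cpi_locus_probability(
    calls: list[AlleleCall],
    locus: str,
    freqs: PopulationFrequencyTable,
    theta: float = 0.0,
) -> float:
    """Locus inclusion probability: the chance a random person is included.

    With theta = 0 this is the textbook (sum of called allele
    frequencies)^2; with theta > 0 it is the sum of co-ancestry-corrected
    pair priors over the pairs of called alleles (the two agree exactly at
    theta = 0).
    """
    if not calls:
        raise InputError(f"no calls at {locus}")
    alleles = sorted({c.allele for c in calls})
    if theta == 0.0:
        total = sum(freqs.frequency(locus, a) for a in alleles)
        return min(total * total, 1.0)
    pairs = enumerate_pairs(alleles, locus)
    return min(sum(genotype_prior(p, freqs, theta) for p in pairs), 1.0)


def mcpi_locus_usable(calls: list[AlleleCall]) -> bool:
    """True iff every called allele also reaches the stochastic threshold."""
    return bool(calls) and all(c.above_stochastic for c in calls)


def inclusion_match(
    calls: AlleleCallSet,
    reference: ContributorProfile,
    freqs: PopulationFrequencyTable,
    theta: float = 0.0,
    method: str = "cpi",
) -> MatchResult:
    """CPI or mCPI match statistic for a reference against called alleles.

    Per locus: the reference is excluded when any of its alleles is
    uncalled; otherwise the locus LR is the reciprocal of the inclusion
    probability.  mCPI additionally drops loci with sub-stochastic calls.
    The combined LR is the product over used loci; with no usable locus the
    result is inconclusive with no statistic.  The comparator methods never
    produce a locus LR below 1.
    """
    if method not in ("cpi", "mcpi"):
        raise InputError(f"method must be 'cpi' or 'mcpi', got {method!r}")
    per_locus_lr: dict[str, float] = {}
    locus_status: dict[str, str] = {}
    excluded = False
    for locus, pair in reference.genotypes.items():
        locus_calls = calls.get(locus, [])
        if not locus_calls:
            locus_status[locus] = "no_calls"
            continue
        called = {c.allele for c in locus_calls}
        if any(a not in called for a in pair.alleles):
            locus_status[locus] = "excluded"
            excluded = True
            continue
        if method == "mcpi" and not mcpi_locus_usable(locus_calls):
            locus_status[locus] = "dropped_stochastic"
            continue
        lr = 1.0 / cpi_locus_probability(locus_calls, locus, freqs, theta)
        per_locus_lr[locus] = lr
        locus_status[locus] = "used"

    if excluded:
        classification = "exclude"
        combined, ban = 0.0, float("-inf")
    elif not per_locus_lr:
        classification = "inconclusive"
        combined, ban = float("nan"), float("nan")
    else:
        combined, ban = combine_loci(per_locus_lr)
        classification = "include"
    return MatchResult(
        sample="",
        reference=reference.sample_name,
        population=freqs.population_name,
        method=method,
        per_locus_lr=per_locus_lr,
        combined_lr=combined,
        log10_lr_ban=ban,
        classification=classification,
        locus_status=locus_status,
    )
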