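"""Allele and genotype spaces, population frequencies, and genotype priors.

An STR locus is a length polymorphism: alleles are named by their repeat
count, including microvariants such as "9.3" (nine full repeats plus three
bases).  A genotype at a locus is an unordered pair of alleles.  Given n
alleles there are n(n+1)/2 unordered pairs: n homozygotes and n(n-1)/2
heterozygotes.

Genotype priors come from population allele frequencies.  With co-ancestry
coefficient theta = 0 the priors are the Hardy-Weinberg values p_i^2 and
2 p_i p_j.  For theta > 0 we use the Balding-Nichols genotype probabilities
(the Dirichlet sampling formula), which inflate homozygote probabilities to
account for population substructure:

    P(a_i, a_i) = p_i [t + (1-t) p_i]
    P(a_i, a_j) = 2 (1-t) p_i p_j

These sum to one over all pairs whenever the allele frequencies sum to one.
(The related NRC-II 4.10a/b expressions with the (1+t)(1+2t) denominator
are *conditional* match probabilities — the chance a second sampled person
repeats an already-seen genotype — and do not normalize over the genotype
space, so they are not usable as a prior.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

#: default co-ancestry coefficient used for genotype priors
DEFAULT_THETA = 0.01

#: fallback minimum allele frequency when no database size is known
DEFAULT_MIN_FREQUENCY = 0.001


def allele_sort_key(label: str) -> tuple:
    """Ordering key for allele labels: numeric when parseable, lexical otherwise.

    Handles microvariants ("9.3" sorts between 9 and 10); non-numeric labels
    (e.g. "X") sort after all numeric ones.
    """
    try:
        return (0, float(label), str(label))
    except ValueError:
        return (1, 0.0, str(label))


def validate_theta(theta: float) -> float:
    if not 0.0 <= theta < 0.5:
        raise InputError(f"co-ancestry theta must be in [0, 0.5), got {theta}")
    return float(theta)


@dataclass(frozen=True, order=True)
class GenotypePair:
    """An unordered allele pair at a locus, stored canonically sorted."""

    locus: str
    a1: str
    a2: str

    @classmethod
    def make(cls, locus: str, a: str, b: str) -> "GenotypePair":
        a, b = str(a), str(b)
        if allele_sort_key(b) < allele_sort_key(a):
            a, b = b, a
        return cls(locus, a, b)

    @property
    def is_homozygote(self) -> bool:
        return self.a1 == self.a2

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.a1, self.a2)

    def dose(self, allele: str) -> int:
        """Number of copies of *allele* carried by this genotype (0, 1 or 2)."""
        return (self.a1 == allele) + (self.a2 == allele)

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.locus}:{self.a1},{self.a2}"


@dataclass
class PopulationFrequencyTable:
    """Per-locus allele frequencies for one named population.

    ``frequencies`` maps locus -> {allele label -> frequency}.  Frequencies
    must lie in (0, 1] and sum to at most 1 (a remainder for unobserved rare
    alleles is permitted).  ``min_frequency``, when set, substitutes for
    alleles absent from a locus table (the standard 5/2N floor) instead of
    raising; lookups that use it are logged.
    """

    population_name: str
    frequencies: dict[str, dict[str, float]]
    min_frequency: float | None = None
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise InputError("frequency table has no loci")
        for locus, table in self.frequencies.items():
            if not table:
                raise InputError(f"locus {locus} has no alleles")
            total = 0.0
            for allele, f in table.items():
                if not 0.0 < f <= 1.0:
                    raise InputError(
                        f"frequency of {locus} allele {allele} out of (0,1]: {f}"
                    )
                total += f
            if total > 1.0 + 1e-6:
                raise InputError(
                    f"frequencies at locus {locus} sum to {total:.6f} > 1"
                )

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    def alleles(self, locus: str) -> list[str]:
        """Allele labels at *locus*, in canonical order."""
        if locus not in self.frequencies:
            raise InputError(f"locus {locus} not in frequency table")
        return sorted(self.frequencies[locus], key=allele_sort_key)

    def frequency(self, locus: str, allele: str) -> float:
        if locus not in self.frequencies:
            raise InputError(f"locus {locus} not in frequency table")
        table = self.frequencies[locus]
        allele = str(allele)
        if allele in table:
            return table[allele]
        if self.min_frequency is not None:
            if (locus, allele) not in self._warned:
                self._warned.add((locus, allele))
                logger.warning(
                    "allele %s not in %s database at %s; substituting "
                    "minimum frequency %g",
                    allele,
                    self.population_name,
                    locus,
                    self.min_frequency,
                )
            return self.min_frequency
        raise InputError(
            f"allele {allele} not in {self.population_name} database at {locus}"
        )

    def with_rare_allele_floor(
        self, database_size: int | None = None
    ) -> "PopulationFrequencyTable":
        """Copy of the table with a minimum frequency for unseen alleles.

        The floor is 5/(2N) for a database of N individuals, or 0.001 when
        no size is given.
        """
        floor = (
            5.0 / (2.0 * database_size)
            if database_size
            else DEFAULT_MIN_FREQUENCY
        )
        return PopulationFrequencyTable(
            self.population_name, self.frequencies, min_frequency=floor
        )


@dataclass
class GenotypeDistribution:
    """A probability mass over unordered allele pairs at one locus.

    Represents priors, threshold-restricted inclusion posteriors, and
    MCMC-inferred posteriors uniformly.
    """

    locus: str
    mass: dict[GenotypePair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mass:
            raise InputError(f"empty genotype distribution at {self.locus}")
        total = 0.0
        for pair, p in self.mass.items():
            if p < 0:
                raise InputError(f"negative probability at {pair}: {p}")
            if pair.locus != self.locus:
                raise InputError(
                    f"pair {pair} does not belong to locus {self.locus}"
                )
            total += p
        if abs(total - 1.0) > 1e-9:
            raise InputError(
                f"genotype distribution at {self.locus} sums to {total!r}, not 1"
            )

    @classmethod
    def from_weights(
        cls, locus: str, weights: Mapping[GenotypePair, float]
    ) -> "GenotypeDistribution":
        """Normalize nonnegative weights into a distribution."""
        total = sum(weights.values())
        if total <= 0:
            raise InputError(f"cannot normalize zero mass at {locus}")
        return cls(locus, {p: w / total for p, w in weights.items() if w > 0})

    @property
    def support(self) -> list[GenotypePair]:
        return list(self.mass)

    def prob(self, pair: GenotypePair) -> float:
        """Probability of *pair*; 0 when outside the support."""
        return self.mass.get(pair, 0.0)

    def mode(self) -> GenotypePair:
        """Most probable pair (ties broken by canonical pair order)."""
        return min(self.mass, key=lambda p: (-self.mass[p], p))


def enumerate_pairs(
    alleles: Iterable[str], locus: str = ""
) -> list[GenotypePair]:
    """All n(n+1)/2 unordered allele pairs, in deterministic canonical order.

    n homozygotes and n(n-1)/2 heterozygotes.
    """
    labels = [str(a) for a in alleles]
    if not labels:
        raise InputError("allele list is empty")
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate alleles in list: {labels}")
    labels = sorted(labels, key=allele_sort_key)
    pairs = []
    for i, a in enumerate(labels):
        for b in labels[i:]:
            pairs.append(GenotypePair(locus, a, b))
    return pairs


def genotype_prior(
    pair: GenotypePair,
    freqs: PopulationFrequencyTable,
    theta: float = DEFAULT_THETA,
) -> float:
    """Balding-Nichols prior probability of an allele pair.

    Reduces to Hardy-Weinberg (p^2 / 2 p_i p_j) at theta = 0.  Summed over
    all pairs of the full allele set the priors total one.
    """
    theta = validate_theta(theta)
    p1 = freqs.frequency(pair.locus, pair.a1)
    if pair.is_homozygote:
        return p1 * (theta + (1.0 - theta) * p1)
    p2 = freqs.frequency(pair.locus, pair.a2)
    return 2.0 * (1.0 - theta) * p1 * p2


def build_prior_distribution(
    locus: str,
    freqs: PopulationFrequencyTable,
    theta: float = DEFAULT_THETA,
) -> GenotypeDistribution:
    """Genotype prior over all pairs of the locus allele list.

    The mass is renormalized so it sums to exactly one even when the allele
    frequencies leave a small rare-allele remainder.
    """
    alleles = freqs.alleles(locus)
    pairs = enumerate_pairs(alleles, locus)
    weights = {p: genotype_prior(p, freqs, theta) for p in pairs}
    return GenotypeDistribution.from_weights(locus, weights)


def sample_random_genotype(
    freqs: PopulationFrequencyTable,
    theta: float,
    locus: str,
    rng: np.random.Generator | int,
) -> GenotypePair:
    """Draw one allele pair from the genotype prior at *locus*.

    Emulates generating a random reference by selecting alleles in
    proportion to their population prevalence (with co-ancestry
    correction).  ``rng`` may be a seed or a Generator; identical seeds
    give identical draws.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    prior = build_prior_distribution(locus, freqs, theta)
    pairs = prior.support
    probs = np.array([prior.mass[p] for p in pairs])
    idx = rng.choice(len(pairs), p=probs / probs.sum())
    return pairs[idx]


def sample_random_profile(
    freqs: PopulationFrequencyTable,
    theta: float,
    loci: Iterable[str],
    rng: np.random.Generator | int,
) -> dict[str, GenotypePair]:
    """Random genotypes at every listed locus (loci independent)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return {locus: sample_random_genotype(freqs, theta, locus, rng) for locus in loci}


def genotype_kl(p: GenotypeDistribution, q: GenotypeDistribution) -> float:
    """Kullback-Leibler divergence KL(p || q) in base-10 (ban) units.

    Nonnegative, zero iff p = q; requires support(p) a subset of support(q).
    Used to check concordance of replicate inference runs.
    """
    kl = 0.0
    for pair, pp in p.mass.items():
        if pp == 0.0:
            continue
        qq = q.prob(pair)
        if qq == 0.0:
            raise InputError(
                f"support violation: {pair} has p={pp} but q=0"
            )
        kl += pp * math.log10(pp / qq)
    return max(kl, 0.0)
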