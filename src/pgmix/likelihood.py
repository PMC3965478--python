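"""Quantitative peak-pattern likelihood for mixture genotype hypotheses.

Given hypothesized contributor genotypes G, mixture weights W and template
mass M, a mean peak pattern mu is constructed as a weighted sum of the
contributor allele-pair doses, adjusted for size-dependent degradation and
back stutter.  The observed peak-height vector d is then scored with a
multivariate normal density whose covariance is diagonal with variance
affine in the expected height:

    var(position) = variance_floor + variance_scale * mu(position)

This heteroscedastic form captures the growth of PCR peak-height variance
with signal intensity while keeping every variance bounded away from zero.
The allele grid at a locus is the union of observed peak positions, the
hypothesized genotype alleles and their back-stutter positions; data height
is taken as 0 at unobserved grid positions, so hypotheses that predict
peaks that did not appear are penalized (dropout scoring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .panel import Panel, stutter_allele
from .population import (
    GenotypeDistribution,
    GenotypePair,
    allele_sort_key,
)

LOG_2PI = math.log(2.0 * math.pi)

#: default per-peak variance parameters (RFU^2 floor, RFU per unit mean)
DEFAULT_VARIANCE_FLOOR = 100.0
DEFAULT_VARIANCE_SCALE = 5.0


@dataclass
class ModelParameters:
    """Continuous parameters of the peak-pattern model.

    weights: mixture weights W (simplex over contributors);
    mass: combined allelic fluorescence intensity M (RFU scale);
    stutter_rate, degradation_rate: artifact model as in the simulator;
    variance_floor / variance_scale: diagonal covariance parameters.
    """

    weights: Sequence[float]
    mass: float
    stutter_rate: float = 0.05
    degradation_rate: float = 0.0
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    variance_scale: float = DEFAULT_VARIANCE_SCALE

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not len(w) or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise InputError(f"weights must be a positive simplex: {w}")
        if self.mass <= 0:
            raise InputError("mass must be positive")
        if not 0.0 <= self.stutter_rate < 0.3:
            raise InputError(f"stutter_rate out of [0, 0.3): {self.stutter_rate}")
        if self.degradation_rate < 0:
            raise InputError("degradation_rate must be >= 0")
        if self.variance_floor <= 0 or self.variance_scale <= 0:
            raise InputError("variance parameters must be positive")

    @property
    def n_contributors(self) -> int:
        return len(self.weights)


def _pattern_grid(
    observed: Mapping[str, float],
    genotypes: Sequence[GenotypePair],
    include_stutter: bool = True,
) -> list[str]:
    """Allele grid: observed positions, hypothesized alleles, their stutter."""
    positions = set(observed)
    for pair in genotypes:
        for allele in pair.alleles:
            positions.add(allele)
            if include_stutter:
                positions.add(stutter_allele(allele))
    return sorted(positions, key=allele_sort_key)


def unit_pattern(
    pair: GenotypePair,
    grid: Sequence[str],
    panel: Panel,
    stutter_rate: float,
    degradation_rate: float,
) -> np.ndarray:
    """Expected pattern of one genotype per unit (mass x weight).

    Dose/2 at each allele position, degraded by fragment size, with a
    stutter fraction moved one repeat down.  Multiplying by M * w_k and
    summing over contributors gives the locus mean pattern.
    """
    geom = panel.geometry(pair.locus)
    index = {a: i for i, a in enumerate(grid)}
    out = np.zeros(len(grid))
    for allele in pair.alleles:
        decay = math.exp(-degradation_rate * geom.size_bp(allele) / 100.0)
        h = 0.5 * decay
        out[index[allele]] += (1.0 - stutter_rate) * h
        if stutter_rate > 0.0:
            pos = stutter_allele(allele)
            if pos in index:
                out[index[pos]] += stutter_rate * h
    return out


def mean_pattern(
    genotypes: Sequence[GenotypePair],
    params: ModelParameters,
    panel: Panel,
    grid: Sequence[str] | None = None,
) -> dict[str, float]:
    """Expected peak heights for a genotype hypothesis.

    Linear in mass; invariant under permutation of equal-weight
    contributors.  Returns a map grid position -> expected RFU.
    """
    if len(genotypes) != params.n_contributors:
        raise InputError(
            f"{len(genotypes)} genotypes for {params.n_contributors} weights"
        )
    if grid is None:
        grid = _pattern_grid({}, genotypes, include_stutter=params.stutter_rate > 0)
    mu = np.zeros(len(grid))
    for pair, w in zip(genotypes, params.weights):
        mu += params.mass * w * unit_pattern(
            pair, grid, panel, params.stutter_rate, params.degradation_rate
        )
    return dict(zip(grid, mu))


def gaussian_loglik(
    data: np.ndarray, mu: np.ndarray, floor: float, scale: float
) -> float:
    """Diagonal-MVN log density of *data* at mean *mu*."""
    var = floor + scale * mu
    resid = data - mu
    return float(-0.5 * np.sum(LOG_2PI + np.log(var) + resid * resid / var))


def log_likelihood(
    observed: Mapping[str, float],
    genotypes: Sequence[GenotypePair],
    params: ModelParameters,
    panel: Panel,
) -> float | None:
    """MVN log-likelihood of observed peaks under a genotype hypothesis.

    *observed* maps allele label -> height (RFU) at one locus.  Returns
    ``None`` for an empty locus (flagged skip, not an exception); summing
    the returned values across loci gives the profile log-likelihood.
    """
    if not observed:
        return None
    grid = _pattern_grid(observed, genotypes, include_stutter=params.stutter_rate > 0)
    data = np.array([observed.get(a, 0.0) for a in grid])
    mu_map = mean_pattern(genotypes, params, panel, grid)
    mu = np.array([mu_map[a] for a in grid])
    return gaussian_loglik(data, mu, params.variance_floor, params.variance_scale)


def joint_log_posterior(
    peaks_by_locus: Mapping[str, Mapping[str, float]],
    genotypes_by_locus: Mapping[str, Sequence[GenotypePair]],
    params: ModelParameters,
    priors: Mapping[str, Sequence[GenotypeDistribution]],
    panel: Panel,
) -> float:
    """Unnormalized joint log posterior of a full genotype configuration.

    Sum over loci of the data log-likelihood plus the log prior of each
    contributor's hypothesized pair (flat prior over the continuous
    parameters, contributing an additive constant).  A zero-prior pair
    yields -inf: the hypothesis is rejected outright.
    """
    total = 0.0
    for locus, genotypes in genotypes_by_locus.items():
        ll = log_likelihood(peaks_by_locus.get(locus, {}), genotypes, params, panel)
        if ll is not None:
            total += ll
        for pair, prior in zip(genotypes, priors[locus]):
            p = prior.prob(pair)
            if p <= 0.0:
                return -math.inf
            total += math.log(p)
    return total


def estimate_variance_params(
    peaks_by_locus: Mapping[str, Mapping[str, float]],
    floor: float = DEFAULT_VARIANCE_FLOOR,
) -> tuple[float, float]:
    """Method-of-moments variance_scale from heterozygote peak balance.

    Loci showing exactly two peaks in reasonable balance (minimum 60%
    heterozygote balance, the usual single-genotype screen) are treated as
    one contributor's heterozygote whose two heights are replicate draws
    around a shared mean; squared deviations regressed through the origin
    on the mean (after removing the floor) estimate variance_scale.  Falls
    back to the configured default when no such loci exist or the estimate
    degenerates.
    """
    means, sqdev = [], []
    for heights in peaks_by_locus.values():
        vals = list(heights.values())
        if len(vals) == 2 and min(vals) >= 0.6 * max(vals):
            m = 0.5 * (vals[0] + vals[1])
            means.append(m)
            sqdev.append((vals[0] - m) ** 2 + (vals[1] - m) ** 2)
    if not means:
        return floor, DEFAULT_VARIANCE_SCALE
    means_a = np.asarray(means)
    excess = np.asarray(sqdev) - floor
    scale = float(np.sum(excess * means_a) / np.sum(means_a * means_a))
    if not np.isfinite(scale) or scale <= 0:
        return floor, DEFAULT_VARIANCE_SCALE
    return floor, scale
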