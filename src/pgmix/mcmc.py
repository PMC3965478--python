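"""Posterior inference over mixture genotypes by Markov chain Monte Carlo.

The sampler is Metropolis-within-Gibbs:

* each contributor's allele pair at each locus is redrawn from its exact
  full conditional, enumerated over the candidate pair support
  (likelihood x population prior) — discrete enumeration makes small cases
  exactly checkable against brute force;
* mixture weights take a random-walk step in logit-simplex coordinates;
* template mass (and optionally stutter, degradation and variance scale)
  take lognormal random-walk steps.

Inference is objective: only the peak data, the population priors and the
settings enter; no reference genotype is consulted.  The candidate pair
support at a locus defaults to pairs of the alleles observed there (plus
any assumed contributor's alleles), the standard observed-allele support of
quantitative mixture models; the full panel allele range is available as an
option for small loci.

Contributor labels are exchangeable under the model; for reporting,
contributors are ordered by posterior mean mixture weight (largest first),
with assumed contributors pinned to their given slots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .likelihood import (
    DEFAULT_VARIANCE_FLOOR,
    DEFAULT_VARIANCE_SCALE,
    LOG_2PI,
    estimate_variance_params,
    unit_pattern,
)
from .panel import Panel, stutter_allele
from .population import (
    GenotypeDistribution,
    GenotypePair,
    allele_sort_key,
    enumerate_pairs,
    genotype_prior,
    PopulationFrequencyTable,
)
from .simulate import ContributorProfile, PeakTable

logger = logging.getLogger(__name__)


@dataclass
class InferenceSettings:
    """Settings for one MCMC interpretation request.

    ``n_contributors`` is assumed, not inferred (see
    :func:`suggest_contributor_count` for an allele-count heuristic and
    :func:`infer_multi_k` for testing K and K+1).  ``variance_scale=None``
    triggers a per-profile method-of-moments estimate.  ``fix_weights`` /
    ``fix_mass`` freeze those coordinates (used by exactness checks).
    """

    n_contributors: int
    iterations: int = 20000
    burn_in: int = 5000
    seed: int = 0
    theta: float = 0.01
    population: str | None = None
    assumed_contributors: list[ContributorProfile] = field(default_factory=list)
    fix_weights: Sequence[float] | None = None
    fix_mass: float | None = None
    stutter_rate: float = 0.05
    degradation_rate: float = 0.0
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    variance_scale: float | None = None
    sample_stutter: bool = False
    sample_degradation: bool = False
    sample_variance: bool = False
    candidate_support: str = "observed"
    weight_step: float = 0.25
    mass_step: float = 0.08
    nuisance_step: float = 0.15

    def __post_init__(self) -> None:
        if self.n_contributors < 1:
            raise InputError("need at least one contributor")
        if not 0 <= self.burn_in < self.iterations:
            raise InputError("require 0 <= burn_in < iterations")
        if len(self.assumed_contributors) > self.n_contributors:
            raise InputError("more assumed contributors than contributors")
        if self.candidate_support not in ("observed", "panel"):
            raise InputError(
                f"candidate_support must be 'observed' or 'panel', "
                f"got {self.candidate_support!r}"
            )


class _LocusEngine:
    """Precomputed per-locus quantities for fast conditional enumeration."""

    def __init__(
        self,
        locus: str,
        observed: Mapping[str, float],
        panel: Panel,
        freqs: PopulationFrequencyTable,
        settings: InferenceSettings,
    ) -> None:
        self.locus = locus
        self.observed = dict(observed)
        candidates = set(observed)
        for profile in settings.assumed_contributors:
            if locus in profile.genotypes:
                candidates.update(profile.genotypes[locus].alleles)
        if settings.candidate_support == "panel":
            candidates.update(panel.geometry(locus).alleles)
        if not candidates:
            raise InputError(f"no candidate alleles at {locus}")
        self.candidates = sorted(candidates, key=allele_sort_key)
        self.pairs = enumerate_pairs(self.candidates, locus)
        self.pair_index = {p: i for i, p in enumerate(self.pairs)}
        self.log_prior = np.log(
            [genotype_prior(p, freqs, settings.theta) for p in self.pairs]
        )
        grid = set(self.candidates)
        if settings.stutter_rate > 0 or settings.sample_stutter:
            grid.update(stutter_allele(a) for a in self.candidates)
        self.grid = sorted(grid, key=allele_sort_key)
        self.data = np.array([self.observed.get(a, 0.0) for a in self.grid])
        self.panel = panel
        self.rebuild_patterns(settings.stutter_rate, settings.degradation_rate)

    def rebuild_patterns(self, stutter_rate: float, degradation_rate: float) -> None:
        """Unit patterns (pair x grid) for the current artifact parameters."""
        self.patterns = np.array(
            [
                unit_pattern(p, self.grid, self.panel, stutter_rate, degradation_rate)
                for p in self.pairs
            ]
        )

    def loglik_rows(self, means: np.ndarray, floor: float, scale: float) -> np.ndarray:
        """Row-wise diagonal-MVN log density of the data at candidate means."""
        var = floor + scale * means
        resid = self.data - means
        return -0.5 * np.sum(LOG_2PI + np.log(var) + resid * resid / var, axis=-1)


@dataclass
class MCMCState:
    """Mutable chain state: genotype indices, weights, mass, nuisance, caches."""

    engines: dict[str, _LocusEngine]
    settings: InferenceSettings
    rng: np.random.Generator
    genotype_idx: dict[str, np.ndarray]  # locus -> index per contributor
    stacks: dict[str, np.ndarray]        # locus -> (K, n_grid) unit patterns
    weights: np.ndarray
    mass: float
    stutter_rate: float
    degradation_rate: float
    variance_floor: float
    variance_scale: float
    n_fixed: int = 0                      # leading contributors held fixed
    accept: dict[str, list[int]] = field(
        default_factory=lambda: {"weights": [0, 0], "mass": [0, 0], "nuisance": [0, 0]}
    )

    def locus_loglik(self, locus: str, weights=None, mass=None) -> float:
        eng = self.engines[locus]
        w = self.weights if weights is None else weights
        m = self.mass if mass is None else mass
        mu = m * (w @ self.stacks[locus])
        return float(eng.loglik_rows(mu, self.variance_floor, self.variance_scale))

    def total_loglik(self, weights=None, mass=None) -> float:
        return sum(
            self.locus_loglik(locus, weights, mass) for locus in self.engines
        )


def gibbs_update_genotype(state: MCMCState, k: int, locus: str) -> None:
    """Redraw contributor *k*'s pair at *locus* from its full conditional.

    The conditional is enumerated over the candidate pair support,
    proportional to likelihood x prior; other coordinates are unchanged.
    Under a flat likelihood the conditional equals the prior.
    """
    eng = state.engines[locus]
    stack = state.stacks[locus]
    w = state.weights
    rest = w @ stack - w[k] * stack[k]
    means = state.mass * (rest[None, :] + w[k] * eng.patterns)
    logp = (
        eng.loglik_rows(means, state.variance_floor, state.variance_scale)
        + eng.log_prior
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    idx = state.rng.choice(len(probs), p=probs)
    state.genotype_idx[locus][k] = idx
    stack[k] = eng.patterns[idx]


def gibbs_update_pair(state: MCMCState, j: int, k: int, locus: str) -> None:
    """Jointly redraw contributors *j* and *k* at *locus* from their exact
    two-site conditional (enumerated over all pair combinations).

    Single-site updates mix poorly over the pairing of alleles between
    contributors when the weights are near-equal (any re-pairing must pass
    through a low-probability intermediate); the joint update lets a locus
    re-orient its pairing in one move, which in turn lets the weight chain
    escape the symmetric mode.
    """
    eng = state.engines[locus]
    stack = state.stacks[locus]
    w = state.weights
    rest = w @ stack - w[j] * stack[j] - w[k] * stack[k]
    a = w[j] * eng.patterns  # (n, g)
    b = w[k] * eng.patterns
    means = state.mass * (rest[None, None, :] + a[:, None, :] + b[None, :, :])
    logp = (
        eng.loglik_rows(means, state.variance_floor, state.variance_scale)
        + eng.log_prior[:, None]
        + eng.log_prior[None, :]
    )
    flat = logp.ravel()
    flat = flat - flat.max()
    probs = np.exp(flat)
    probs /= probs.sum()
    idx = state.rng.choice(len(probs), p=probs)
    n = len(eng.pairs)
    ij, ik = divmod(idx, n)
    state.genotype_idx[locus][j] = ij
    state.genotype_idx[locus][k] = ik
    stack[j] = eng.patterns[ij]
    stack[k] = eng.patterns[ik]


def update_weights_mass(state: MCMCState) -> None:
    """Metropolis steps for mixture weights (logit-simplex random walk) and
    mass (lognormal random walk); both leave the joint posterior invariant.

    A zero-length proposal is always accepted.  Weights stay on the simplex
    and mass stays positive by construction of the transforms.
    """
    settings = state.settings
    K = len(state.weights)
    if settings.fix_weights is None and K > 1:
        z = np.log(state.weights[:-1]) - math.log(state.weights[-1])
        z_new = z + settings.weight_step * state.rng.standard_normal(K - 1)
        expz = np.exp(np.append(z_new, 0.0))
        w_new = expz / expz.sum()
        # flat Dirichlet prior; Jacobian of the logit transform is prod(w)
        log_alpha = (
            state.total_loglik(weights=w_new)
            - state.total_loglik()
            + float(np.sum(np.log(w_new)) - np.sum(np.log(state.weights)))
        )
        state.accept["weights"][1] += 1
        if math.log(state.rng.uniform()) < log_alpha:
            state.weights = w_new
            state.accept["weights"][0] += 1
    if settings.fix_mass is None:
        m_new = state.mass * math.exp(
            settings.mass_step * state.rng.standard_normal()
        )
        # flat prior on log(mass): Jacobian cancels
        log_alpha = state.total_loglik(mass=m_new) - state.total_loglik()
        state.accept["mass"][1] += 1
        if math.log(state.rng.uniform()) < log_alpha:
            state.mass = m_new
            state.accept["mass"][0] += 1


def _update_nuisance(state: MCMCState) -> None:
    """Optional lognormal random-walk updates for stutter, degradation and
    variance scale (flat priors on the log scale within their bounds)."""
    settings = state.settings
    proposals = []
    if settings.sample_stutter:
        proposals.append("stutter_rate")
    if settings.sample_degradation:
        proposals.append("degradation_rate")
    if settings.sample_variance:
        proposals.append("variance_scale")
    for name in proposals:
        current = getattr(state, name)
        if current <= 0:
            current = 1e-3
        new = current * math.exp(
            settings.nuisance_step * state.rng.standard_normal()
        )
        if name == "stutter_rate" and new >= 0.3:
            continue
        old_ll = state.total_loglik()
        old_val = getattr(state, name)
        setattr(state, name, new)
        if name in ("stutter_rate", "degradation_rate"):
            for eng in state.engines.values():
                eng.rebuild_patterns(state.stutter_rate, state.degradation_rate)
            _rebuild_stacks(state)
        new_ll = state.total_loglik()
        state.accept["nuisance"][1] += 1
        if math.log(state.rng.uniform()) < new_ll - old_ll:
            state.accept["nuisance"][0] += 1
        else:
            setattr(state, name, old_val)
            if name in ("stutter_rate", "degradation_rate"):
                for eng in state.engines.values():
                    eng.rebuild_patterns(state.stutter_rate, state.degradation_rate)
                _rebuild_stacks(state)


def _rebuild_stacks(state: MCMCState) -> None:
    for locus, eng in state.engines.items():
        idx = state.genotype_idx[locus]
        state.stacks[locus] = eng.patterns[idx].copy()


@dataclass
class InferenceResult:
    """Posterior summaries from one MCMC run.

    ``posteriors[locus][k]`` is contributor k's genotype posterior at the
    locus (contributors ordered by posterior mean weight, assumed
    contributors first).  Weight and mass summaries come from post-burn-in
    samples.
    """

    posteriors: dict[str, list[GenotypeDistribution]]
    weight_mean: np.ndarray
    weight_sd: np.ndarray
    weight_samples: np.ndarray
    mass_mean: float
    mass_sd: float
    diagnostics: dict
    settings: InferenceSettings
    seed: int

    @property
    def n_contributors(self) -> int:
        return len(self.weight_mean)

    def genotype(self, contributor: int) -> dict[str, GenotypeDistribution]:
        """Per-locus genotype posterior of one contributor."""
        return {
            locus: dists[contributor] for locus, dists in self.posteriors.items()
        }


def infer(
    peaks: PeakTable,
    settings: InferenceSettings,
    freqs: PopulationFrequencyTable,
    panel: Panel,
) -> InferenceResult:
    """Run the MCMC sampler on one evidence profile.

    Deterministic given ``settings.seed``.  Loci with no peaks are skipped
    (they contribute no information and are absent from the result).
    Assumed contributors are held fixed at their known pairs.
    """
    if len(peaks) == 0:
        raise InputError("empty peak table")
    if freqs.min_frequency is None:
        freqs = freqs.with_rare_allele_floor()
    rng = np.random.default_rng(settings.seed)

    peaks_by_locus = {
        locus: peaks.locus_peaks(locus)
        for locus in peaks.loci
        if peaks.locus_peaks(locus)
    }
    if not peaks_by_locus:
        raise InputError("no loci with peaks")

    floor = settings.variance_floor
    scale = settings.variance_scale
    if scale is None:
        floor, scale = estimate_variance_params(peaks_by_locus, floor)

    engines = {
        locus: _LocusEngine(locus, obs, panel, freqs, settings)
        for locus, obs in peaks_by_locus.items()
    }
    for locus, eng in engines.items():
        bound = math.ceil(len(eng.observed) / 2)
        if settings.n_contributors < bound:
            logger.warning(
                "locus %s shows %d alleles but only %d contributors assumed; "
                "the model must explain the extras via stutter or noise",
                locus,
                len(eng.observed),
                settings.n_contributors,
            )

    K = settings.n_contributors
    n_fixed = len(settings.assumed_contributors)
    genotype_idx: dict[str, np.ndarray] = {}
    stacks: dict[str, np.ndarray] = {}
    for locus, eng in engines.items():
        idx = np.zeros(K, dtype=int)
        for k in range(K):
            if k < n_fixed:
                pair = settings.assumed_contributors[k].genotypes[locus]
                if pair not in eng.pair_index:
                    raise InputError(
                        f"assumed genotype {pair} outside candidate support"
                    )
                idx[k] = eng.pair_index[pair]
            else:
                prior = np.exp(eng.log_prior - eng.log_prior.max())
                idx[k] = rng.choice(len(eng.pairs), p=prior / prior.sum())
        genotype_idx[locus] = idx
        stacks[locus] = eng.patterns[idx].copy()

    if settings.fix_weights is not None:
        weights = np.asarray(settings.fix_weights, dtype=float)
        if len(weights) != K or abs(weights.sum() - 1.0) > 1e-9:
            raise InputError("fix_weights must be a length-K simplex")
    else:
        # random start breaks the symmetric-weight saddle for near-equal truth
        weights = rng.dirichlet(np.ones(K))
    if settings.fix_mass is not None:
        mass = float(settings.fix_mass)
    else:
        totals = [sum(obs.values()) for obs in peaks_by_locus.values()]
        mass = max(float(np.mean(totals)), 1.0)

    state = MCMCState(
        engines=engines,
        settings=settings,
        rng=rng,
        genotype_idx=genotype_idx,
        stacks=stacks,
        weights=weights,
        mass=mass,
        stutter_rate=settings.stutter_rate,
        degradation_rate=settings.degradation_rate,
        variance_floor=floor,
        variance_scale=scale,
        n_fixed=n_fixed,
    )

    n_kept = settings.iterations - settings.burn_in
    counts = {
        locus: np.zeros((K, len(eng.pairs))) for locus, eng in engines.items()
    }
    weight_samples = np.empty((n_kept, K))
    mass_samples = np.empty(n_kept)

    free_idx = list(range(n_fixed, K))
    for it in range(settings.iterations):
        for locus in engines:
            for k in free_idx:
                gibbs_update_genotype(state, k, locus)
            if len(free_idx) >= 2:
                j, k = rng.choice(free_idx, size=2, replace=False)
                gibbs_update_pair(state, int(j), int(k), locus)
        update_weights_mass(state)
        if (
            settings.sample_stutter
            or settings.sample_degradation
            or settings.sample_variance
        ):
            _update_nuisance(state)
        if it >= settings.burn_in:
            j = it - settings.burn_in
            # label switching: contributors are reported in weight-ranked
            # slots (assumed contributors pinned first), applied per sample
            # so the marginals are invariant to global relabeling
            order = np.concatenate(
                [
                    np.arange(n_fixed),
                    n_fixed + np.argsort(-state.weights[n_fixed:], kind="stable"),
                ]
            )
            for locus in engines:
                counts[locus][
                    np.arange(K), state.genotype_idx[locus][order]
                ] += 1
            weight_samples[j] = state.weights[order]
            mass_samples[j] = state.mass

    posteriors: dict[str, list[GenotypeDistribution]] = {}
    for locus, eng in engines.items():
        dists = []
        for k in range(K):
            c = counts[locus][k]
            weights_map = {
                eng.pairs[i]: c[i] / n_kept for i in range(len(eng.pairs)) if c[i] > 0
            }
            dists.append(GenotypeDistribution.from_weights(locus, weights_map))
        posteriors[locus] = dists

    ordered_w = weight_samples
    diagnostics = {
        "acceptance": {
            name: (a / t if t else None) for name, (a, t) in state.accept.items()
        },
        "n_kept": n_kept,
        "variance_floor": floor,
        "variance_scale": scale,
        "loci": list(engines),
    }
    return InferenceResult(
        posteriors=posteriors,
        weight_mean=ordered_w.mean(axis=0),
        weight_sd=ordered_w.std(axis=0),
        weight_samples=ordered_w,
        mass_mean=float(mass_samples.mean()),
        mass_sd=float(mass_samples.std()),
        diagnostics=diagnostics,
        settings=settings,
        seed=settings.seed,
    )


def suggest_contributor_count(peaks: PeakTable) -> int:
    """Minimum contributor count consistent with the peak data.

    ceil(max over loci of distinct alleles / 2) — the usual allele-count
    bound used when visually estimating contributor number.
    """
    best = 1
    for locus in peaks.loci:
        n = len(peaks.locus_peaks(locus))
        best = max(best, math.ceil(n / 2))
    return best


def infer_multi_k(
    peaks: PeakTable,
    settings: InferenceSettings,
    freqs: PopulationFrequencyTable,
    panel: Panel,
) -> dict[int, InferenceResult]:
    """Run inference at K and K+1 contributors and report both.

    Convenience for ambiguous contributor numbers; the caller compares the
    two results.
    """
    out = {}
    for k in (settings.n_contributors, settings.n_contributors + 1):
        out[k] = infer(peaks, replace(settings, n_contributors=k), freqs, panel)
    return out


@dataclass
class ConcordanceReport:
    """Replicate-run comparison: flagged loci and overall pass/fail."""

    passed: bool
    flagged: list[str]
    kl_by_locus: dict[str, float]
    weight_delta: float


def check_concordance(
    run1: InferenceResult,
    run2: InferenceResult,
    tolerance: float = 0.05,
) -> ConcordanceReport:
    """Compare two independent runs on the same data and settings.

    Flags any (locus, contributor) whose genotype marginals differ by more
    than *tolerance* ban of (symmetrized, support-union) KL divergence, or
    weight means differing by more than 0.05.  Runs must share settings
    except for the seed and the chain length (so an under-run chain can be
    compared against a converged one and flagged).
    """
    s1 = replace(run1.settings, seed=0, iterations=1, burn_in=0)
    s2 = replace(run2.settings, seed=0, iterations=1, burn_in=0)
    if s1 != s2:
        raise InputError("concordance check requires identical settings")
    flagged = []
    kl_by_locus: dict[str, float] = {}
    for locus in run1.posteriors:
        worst = 0.0
        if locus not in run2.posteriors:
            flagged.append(locus)
            continue
        for k in range(run1.n_contributors):
            p = run1.posteriors[locus][k]
            q = run2.posteriors[locus][k]
            worst = max(worst, _sym_kl(p, q))
        kl_by_locus[locus] = worst
        if worst > tolerance:
            flagged.append(locus)
    weight_delta = float(np.max(np.abs(run1.weight_mean - run2.weight_mean)))
    passed = not flagged and weight_delta <= 0.05
    return ConcordanceReport(passed, flagged, kl_by_locus, weight_delta)


def _sym_kl(
    p: GenotypeDistribution, q: GenotypeDistribution, eps: float = 1e-6
) -> float:
    """Symmetrized KL (ban) over the union support with light smoothing.

    Smoothing keeps the statistic finite when one replicate visited a pair
    the other never sampled; large values still flag discordance.
    """
    support = set(p.mass) | set(q.mass)
    pv = np.array([p.prob(s) + eps for s in support])
    qv = np.array([q.prob(s) + eps for s in support])
    pv /= pv.sum()
    qv /= qv.sum()
    kl_pq = float(np.sum(pv * np.log10(pv / qv)))
    kl_qp = float(np.sum(qv * np.log10(qv / pv)))
    return 0.5 * (kl_pq + kl_qp)


def enumerate_posterior(
    observed: Mapping[str, float],
    locus: str,
    weights: Sequence[float],
    mass: float,
    freqs: PopulationFrequencyTable,
    panel: Panel,
    settings: InferenceSettings,
) -> list[GenotypeDistribution]:
    """Brute-force genotype posterior at one locus with fixed weights/mass.

    Enumerates every combination of candidate pairs across contributors and
    normalizes likelihood x prior exactly.  Only feasible for small
    problems; serves as a reference for the sampler.
    """
    from itertools import product

    from .likelihood import ModelParameters, log_likelihood

    eng = _LocusEngine(locus, observed, panel, freqs, settings)
    params = ModelParameters(
        weights=list(weights),
        mass=mass,
        stutter_rate=settings.stutter_rate,
        degradation_rate=settings.degradation_rate,
        variance_floor=settings.variance_floor,
        variance_scale=settings.variance_scale or DEFAULT_VARIANCE_SCALE,
    )
    K = len(weights)
    combos = list(product(range(len(eng.pairs)), repeat=K))
    logp = np.empty(len(combos))
    for i, combo in enumerate(combos):
        genotypes = [eng.pairs[c] for c in combo]
        ll = log_likelihood(observed, genotypes, params, panel)
        logp[i] = (ll if ll is not None else 0.0) + sum(
            eng.log_prior[c] for c in combo
        )
    logp -= logp.max()
    post = np.exp(logp)
    post /= post.sum()
    out = []
    for k in range(K):
        marg = np.zeros(len(eng.pairs))
        for i, combo in enumerate(combos):
            marg[combo[k]] += post[i]
        out.append(
            GenotypeDistribution.from_weights(
                locus, {eng.pairs[i]: marg[i] for i in range(len(eng.pairs)) if marg[i] > 0}
            )
        )
    return out
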