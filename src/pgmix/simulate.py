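"""Synthetic quantitative STR electropherogram (EPG) peak data.

Generates mixture peak tables with known ground truth: contributor genotype
doses scaled by mixture weight and template mass, single-position back
stutter, exponential size-dependent degradation, multiplicative lognormal
peak-height noise, and a detection floor.

Conventions (shared with the likelihood model so that simulated data and
modeled mean patterns agree exactly at zero noise):

* expected base height of allele a:
  ``total_mass * sum_k w_k * dose_k(a)/2 * exp(-degradation_rate * size_a / 100)``
* stutter moves a ``stutter_rate`` fraction of each base height to the
  position one repeat shorter, so total signal is conserved;
* noise multiplies each peak by a lognormal factor with unit mean and the
  requested coefficient of variation (cv = 0 reproduces the closed-form
  pattern bit for bit).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .panel import Panel, default_panel, stutter_allele
from .population import GenotypePair, allele_sort_key

logger = logging.getLogger(__name__)

#: instrument baseline noise level; peaks below it carry no usable signal
DETECTION_FLOOR_RFU = 10.0

PEAK_COLUMNS = [
    "sample",
    "locus",
    "dye",
    "allele",
    "size_bp",
    "height_rfu",
    "injection_s",
]


@dataclass
class ContributorProfile:
    """A single contributor: one genotype per locus."""

    sample_name: str
    genotypes: dict[str, GenotypePair]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise InputError(f"profile {self.sample_name} has no loci")
        for locus, pair in self.genotypes.items():
            if pair.locus != locus:
                raise InputError(
                    f"genotype {pair} filed under locus {locus}"
                )


@dataclass
class MixtureSpec:
    """Ground-truth description of a simulated mixture.

    ``total_mass`` is the combined allelic fluorescence per locus on the RFU
    scale (a scalar, or a per-locus map for locus-specific amplification).
    Defaults reflect a routine casework-like sample: 5% back stutter, no
    degradation, 10% peak-height coefficient of variation, 5 s injection.
    """

    contributors: list[ContributorProfile]
    weights: Sequence[float]
    total_mass: float | Mapping[str, float] = 3000.0
    stutter_rate: float = 0.05
    degradation_rate: float = 0.0
    cv: float = 0.1
    injection_s: int = 5
    panel: Panel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.contributors) != len(w):
            raise InputError(
                f"{len(self.contributors)} contributors but {len(w)} weights"
            )
        if not len(w) or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise InputError(f"weights must be positive and sum to 1: {w}")
        if not 0.0 <= self.stutter_rate < 0.3:
            raise InputError(f"stutter_rate out of [0, 0.3): {self.stutter_rate}")
        if self.degradation_rate < 0:
            raise InputError("degradation_rate must be >= 0")
        if self.cv < 0:
            raise InputError("cv must be >= 0")

    def locus_mass(self, locus: str) -> float:
        if isinstance(self.total_mass, Mapping):
            return float(self.total_mass[locus])
        return float(self.total_mass)

    @property
    def loci(self) -> list[str]:
        return list(self.contributors[0].genotypes)


@dataclass
class PeakTable:
    """Quantitative EPG data: labeled peaks with size, height, dye, injection.

    Thin wrapper over a pandas DataFrame with columns
    ``sample, locus, dye, allele, size_bp, height_rfu, injection_s``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"peak table missing columns: {missing}")
        self.data = self.data[PEAK_COLUMNS].reset_index(drop=True)
        self.data["allele"] = self.data["allele"].astype(str)
        if (self.data["height_rfu"] < 0).any():
            bad = self.data.index[self.data["height_rfu"] < 0].tolist()
            raise InputError(f"negative peak heights at rows {bad}")
        dup = self.data.duplicated(subset=["sample", "locus", "allele"])
        if dup.any():
            rows = self.data.loc[dup, ["locus", "allele"]].values.tolist()
            raise InputError(f"duplicate (locus, allele) peaks: {rows}")

    @property
    def sample_name(self) -> str:
        names = self.data["sample"].unique()
        return str(names[0]) if len(names) else ""

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.data["locus"]))

    def locus_peaks(self, locus: str) -> dict[str, float]:
        """Map allele label -> height (RFU) at *locus* (empty when absent)."""
        rows = self.data[self.data["locus"] == locus]
        return dict(zip(rows["allele"], rows["height_rfu"]))

    def __len__(self) -> int:
        return len(self.data)


def expected_locus_heights(
    spec: MixtureSpec, locus: str
) -> dict[str, float]:
    """Closed-form expected peak heights at *locus* (no noise, no floor)."""
    geom = spec.panel.geometry(locus)
    mass = spec.locus_mass(locus)
    base: dict[str, float] = {}
    for profile, w in zip(spec.contributors, spec.weights):
        if locus not in profile.genotypes:
            raise InputError(
                f"contributor {profile.sample_name} lacks a genotype at {locus}"
            )
        pair = profile.genotypes[locus]
        for allele in pair.alleles:
            decay = math.exp(
                -spec.degradation_rate * geom.size_bp(allele) / 100.0
            )
            base[allele] = base.get(allele, 0.0) + mass * w * decay / 2.0
    if spec.stutter_rate == 0.0:
        return base
    heights: dict[str, float] = {}
    for allele, h in base.items():
        heights[allele] = heights.get(allele, 0.0) + (1.0 - spec.stutter_rate) * h
        pos = stutter_allele(allele)
        heights[pos] = heights.get(pos, 0.0) + spec.stutter_rate * h
    return heights


def _noise_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation *cv*."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def simulate_locus_peaks(
    spec: MixtureSpec,
    locus: str,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Simulated peak rows for one locus (heights jittered unless cv = 0)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    geom = spec.panel.geometry(locus)
    expected = expected_locus_heights(spec, locus)
    alleles = sorted(expected, key=allele_sort_key)
    means = np.array([expected[a] for a in alleles])
    heights = means * _noise_factors(len(means), spec.cv, rng)
    sample = "+".join(c.sample_name for c in spec.contributors)
    return pd.DataFrame(
        {
            "sample": sample,
            "locus": locus,
            "dye": geom.dye,
            "allele": alleles,
            "size_bp": [geom.size_bp(a) for a in alleles],
            "height_rfu": heights,
            "injection_s": spec.injection_s,
        }
    )


def simulate_profile(
    spec: MixtureSpec,
    loci: Iterable[str] | None = None,
    rng: np.random.Generator | int = 0,
) -> PeakTable:
    """Simulate a whole multi-locus profile; one seed governs the run."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    loci = list(loci) if loci is not None else spec.loci
    if not loci:
        raise InputError("empty locus list")
    frames = [simulate_locus_peaks(spec, locus, rng) for locus in loci]
    return PeakTable(pd.concat(frames, ignore_index=True))


def apply_detection_floor(
    peaks: PeakTable, floor_rfu: float = DETECTION_FLOOR_RFU
) -> PeakTable:
    """Drop peaks below the baseline noise level; other rows are unchanged.

    Loci emptied entirely by the floor are flagged with a warning (they are
    degenerate for downstream interpretation).
    """
    if floor_rfu < 0:
        raise InputError("detection floor must be >= 0")
    kept = peaks.data[peaks.data["height_rfu"] >= floor_rfu]
    emptied = sorted(set(peaks.loci) - set(kept["locus"]))
    if emptied:
        logger.warning(
            "detection floor %.1f RFU removed every peak at loci: %s",
            floor_rfu,
            ", ".join(emptied),
        )
    return PeakTable(kept.reset_index(drop=True))


def random_mixture(
    freqs,
    panel: Panel | None = None,
    n_contributors: int = 2,
    weights: Sequence[float] | None = None,
    theta: float = 0.01,
    rng: np.random.Generator | int = 0,
    **spec_kwargs,
) -> MixtureSpec:
    """Draw contributor genotypes from the population and build a MixtureSpec.

    When *weights* is omitted the first weight is drawn uniformly on
    (0.1, 0.9) for two contributors, or from a flat Dirichlet otherwise,
    emulating casework mixtures whose weights span 10-90%.
    """
    from .population import sample_random_profile

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    panel = panel or default_panel()
    loci = panel.locus_names
    contributors = [
        ContributorProfile(
            f"C{i + 1}", sample_random_profile(freqs, theta, loci, rng)
        )
        for i in range(n_contributors)
    ]
    if weights is None:
        if n_contributors == 1:
            weights = [1.0]
        elif n_contributors == 2:
            w1 = rng.uniform(0.1, 0.9)
            weights = [w1, 1.0 - w1]
        else:
            weights = rng.dirichlet(np.ones(n_contributors)).tolist()
    return MixtureSpec(
        contributors=contributors,
        weights=list(weights),
        panel=panel,
        **spec_kwargs,
    )
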