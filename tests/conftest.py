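import pytest

from pgmix import (
    ContributorProfile,
    default_panel,
    GenotypePair,
    MixtureSpec,
    PopulationFrequencyTable,
    synthetic_frequency_table,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def freqs(panel):
    return synthetic_frequency_table(panel, seed=1)


@pytest.fixture()
def two_allele_freqs():
    return PopulationFrequencyTable(
        "TOY", {"L1": {"10": 0.5, "11": 0.5}}
    )


@pytest.fixture()
def three_allele_freqs():
    return PopulationFrequencyTable(
        "TOY", {"L1": {"10": 0.2, "11": 0.3, "12": 0.5}}
    )


# The worked-example locus: a 20-allele Penta E-like marker typed from a
# two-person mixture of a 7,14 major and a 10,12 minor.  The printed prior
# column over the ten pairs of called alleles {7, 10, 12, 14} (percent).
TABLE_PRIORS_PCT = {
    ("7", "7"): 4.3,
    ("7", "10"): 3.3,
    ("7", "12"): 7.1,
    ("7", "14"): 1.9,
    ("10", "10"): 0.6,
    ("10", "12"): 2.7,
    ("10", "14"): 0.7,
    ("12", "12"): 2.9,
    ("12", "14"): 1.6,
    ("14", "14"): 0.2,
}


@pytest.fixture(scope="session")
def worked_example_prior():
    """The worked-example prior as a (locus, mass-map) over ten pairs.

    The ten printed pair priors sum to 25.3%; the remaining genotype mass
    sits on pairs involving uncalled alleles, folded here into a single
    sink pair so the distribution normalizes without altering any
    restricted-posterior arithmetic.
    """
    from pgmix import GenotypeDistribution

    mass = {
        GenotypePair.make("PentaE", a, b): p / 100.0
        for (a, b), p in TABLE_PRIORS_PCT.items()
    }
    sink = GenotypePair.make("PentaE", "5", "5")
    mass[sink] = 1.0 - sum(mass.values())
    return GenotypeDistribution("PentaE", mass)


def mixture_profiles(panel, genotype_map):
    """Helper: build single-locus contributor profiles from label pairs."""
    return [
        ContributorProfile(
            name, {locus: GenotypePair.make(locus, a, b) for locus, (a, b) in g.items()}
        )
        for name, g in genotype_map.items()
    ]


@pytest.fixture()
def pentae_mixture(panel):
    """Fig-1-like Penta E mixture: 7,14 major (2/3) and 10,12 minor (1/3)."""
    profiles = mixture_profiles(
        panel,
        {
            "major": {"PentaE": ("7", "14")},
            "minor": {"PentaE": ("10", "12")},
        },
    )
    return MixtureSpec(
        contributors=profiles,
        weights=[2.0 / 3.0, 1.0 / 3.0],
        total_mass=1800.0,
        stutter_rate=0.0,
        degradation_rate=0.0,
        cv=0.0,
        injection_s=5,
        panel=panel,
    )
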