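"""STR panel geometry: loci, dyes, repeat units, allele ranges, fragment sizes.

A bundled PowerPlex-16-like 15-locus panel ships with the package; any panel
can be loaded from a YAML/JSON description file with the same structure.
Fragment sizes are synthesized as ``offset_bp + repeats * repeat_unit`` with
microvariant labels like "9.3" contributing nine full repeats plus three
bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError
from .population import PopulationFrequencyTable, allele_sort_key


@dataclass(frozen=True)
class LocusGeometry:
    name: str
    dye: str
    repeat_unit: int
    offset_bp: float
    alleles: tuple[str, ...]

    def size_bp(self, allele: str) -> float:
        """Fragment size of *allele* in base pairs."""
        whole, frac = _split_label(allele)
        return self.offset_bp + whole * self.repeat_unit + frac


def _split_label(allele: str) -> tuple[int, int]:
    """Split an allele label into (full repeats, extra bases)."""
    text = str(allele)
    try:
        if "." in text:
            whole, frac = text.split(".", 1)
            return int(whole), int(frac)
        return int(text), 0
    except ValueError as exc:
        raise InputError(f"cannot parse allele label {text!r}") from exc


def stutter_allele(allele: str) -> str:
    """Label of the back-stutter position, one repeat shorter."""
    whole, frac = _split_label(allele)
    if whole < 1:
        raise InputError(f"no stutter position below allele {allele!r}")
    return f"{whole - 1}.{frac}" if frac else str(whole - 1)


@dataclass
class Panel:
    """A typing panel: named loci with dye, repeat unit, sizes and alleles."""

    name: str
    loci: dict[str, LocusGeometry]

    def __post_init__(self) -> None:
        if not self.loci:
            raise InputError("panel has no loci")

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    def geometry(self, locus: str) -> LocusGeometry:
        if locus not in self.loci:
            raise InputError(f"locus {locus} not in panel {self.name}")
        return self.loci[locus]

    def dye(self, locus: str) -> str:
        return self.geometry(locus).dye

    def size_bp(self, locus: str, allele: str) -> float:
        return self.geometry(locus).size_bp(allele)

    @classmethod
    def from_dict(cls, spec: dict) -> "Panel":
        try:
            loci = {}
            for name, entry in spec["loci"].items():
                loci[name] = LocusGeometry(
                    name=name,
                    dye=str(entry["dye"]),
                    repeat_unit=int(entry["repeat_unit"]),
                    offset_bp=float(entry["offset_bp"]),
                    alleles=tuple(str(a) for a in entry["alleles"]),
                )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"malformed panel description: {exc}") from exc
        return cls(name=str(spec.get("name", "unnamed")), loci=loci)

    @classmethod
    def from_file(cls, path: str | Path) -> "Panel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_panel() -> Panel:
    """The bundled PowerPlex-16-like 15-locus panel."""
    text = (
        resources.files("pgmix").joinpath("data/powerplex16.yaml").read_text()
    )
    return Panel.from_dict(yaml.safe_load(text))


def synthetic_frequency_table(
    panel: Panel,
    population_name: str = "SYNTHETIC",
    seed: int | np.random.Generator = 0,
    concentration: float = 4.0,
) -> PopulationFrequencyTable:
    """Generate a synthetic population allele-frequency table for *panel*.

    Frequencies at each locus are drawn from a Dirichlet whose concentration
    is highest for central alleles, mimicking the unimodal allele-frequency
    spectra of real STR databases.  The result is a stand-in for a casework
    population database (which is confidential); it is reproducible from the
    seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    freqs: dict[str, dict[str, float]] = {}
    for name, geom in panel.loci.items():
        labels = sorted(geom.alleles, key=allele_sort_key)
        n = len(labels)
        # triangular concentration profile peaking mid-range
        centre = (n - 1) / 2.0
        alpha = concentration * (1.0 - 0.8 * np.abs(np.arange(n) - centre) / max(centre, 1.0))
        alpha = np.clip(alpha, 0.2, None)
        p = rng.dirichlet(alpha)
        p = np.clip(p, 1e-4, None)
        p = p / p.sum()
        freqs[name] = {a: float(f) for a, f in zip(labels, p)}
    return PopulationFrequencyTable(population_name, freqs)
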