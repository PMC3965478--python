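"""Readers, writers, run configuration and provenance.

Formats (all UTF-8, comma-separated with a required header, "." decimal,
locus names uppercased on ingest is NOT applied — locus names are taken
verbatim so they match the panel description):

* peak table CSV: ``sample,locus,dye,allele,size_bp,height_rfu,injection_s``
  (JSON mirror: a list of row objects with identical field names);
* population frequency CSV: ``population,locus,allele,frequency``;
* reference genotype CSV: ``sample,locus,allele1,allele2``;
* match report JSON: validated against a pydantic schema, with config hash
  and seed provenance embedded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pydantic
import yaml

from .errors import DataFormatError
from .match import MatchResult
from .mcmc import InferenceResult
from .population import GenotypePair, PopulationFrequencyTable
from .simulate import ContributorProfile, PEAK_COLUMNS, PeakTable

logger = logging.getLogger(__name__)


def setup_logging(level: str = "INFO", logfile: str | None = None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------- peak tables

def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak table from CSV or JSON (by file suffix).

    Malformed rows are reported with their line numbers; negative heights,
    duplicate (locus, allele) entries and schema mismatches are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() == ".json":
            with open(path, encoding="utf-8") as fh:
                rows = json.load(fh)
            frame = pd.DataFrame(rows)
        else:
            frame = pd.read_csv(path, dtype={"allele": str})
    except (ValueError, OSError) as exc:
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in PEAK_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    bad = frame.index[pd.to_numeric(frame["height_rfu"], errors="coerce").isna()]
    if len(bad):
        raise DataFormatError(
            f"{path}: non-numeric height_rfu at data rows {list(bad + 2)}"
        )
    neg = frame.index[frame["height_rfu"].astype(float) < 0]
    if len(neg):
        raise DataFormatError(
            f"{path}: negative height_rfu at data rows {list(neg + 2)}"
        )
    try:
        return PeakTable(frame)
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_peak_table(peaks: PeakTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = peaks.data.to_dict(orient="records")
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        peaks.data.to_csv(path, index=False)


# ------------------------------------------------------------- frequencies

def read_frequencies(
    path: str | Path, population: str | None = None
) -> PopulationFrequencyTable:
    """Read one population's allele frequencies from CSV.

    The file may hold several populations; *population* selects one.  With
    a single population in the file the argument may be omitted.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"allele": str})
    required = ["population", "locus", "allele", "frequency"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    names = sorted(frame["population"].unique())
    if population is None:
        if len(names) != 1:
            raise DataFormatError(
                f"{path} holds populations {names}; specify one"
            )
        population = names[0]
    elif population not in names:
        raise DataFormatError(f"population {population!r} not in {path}: {names}")
    sub = frame[frame["population"] == population]
    freqs: dict[str, dict[str, float]] = {}
    for _, row in sub.iterrows():
        freqs.setdefault(row["locus"], {})[str(row["allele"])] = float(
            row["frequency"]
        )
    try:
        return PopulationFrequencyTable(str(population), freqs)
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_frequencies(freqs: PopulationFrequencyTable, path: str | Path) -> None:
    rows = [
        {
            "population": freqs.population_name,
            "locus": locus,
            "allele": allele,
            "frequency": f,
        }
        for locus, table in freqs.frequencies.items()
        for allele, f in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -------------------------------------------------------------- references

def read_references(path: str | Path) -> list[ContributorProfile]:
    """Read reference genotype profiles from CSV."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"allele1": str, "allele2": str})
    required = ["sample", "locus", "allele1", "allele2"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    profiles: dict[str, dict[str, GenotypePair]] = {}
    for _, row in frame.iterrows():
        pair = GenotypePair.make(row["locus"], row["allele1"], row["allele2"])
        profiles.setdefault(str(row["sample"]), {})[row["locus"]] = pair
    try:
        return [
            ContributorProfile(name, genotypes)
            for name, genotypes in profiles.items()
        ]
    except Exception as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_references(
    profiles: list[ContributorProfile], path: str | Path
) -> None:
    rows = [
        {
            "sample": p.sample_name,
            "locus": locus,
            "allele1": pair.a1,
            "allele2": pair.a2,
        }
        for p in profiles
        for locus, pair in p.genotypes.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------- match reports

class _MatchReportSchema(pydantic.BaseModel):
    """Bundled schema for the match-report JSON."""

    sample: str
    reference: str
    population: str
    method: str
    per_locus_lr: dict[str, float]
    combined_lr: float | None
    log10_lr_ban: float | None
    classification: str
    locus_status: dict[str, str] = {}
    metadata: dict = {}


def validate_match_report(payload: dict) -> None:
    """Raise DataFormatError if *payload* does not satisfy the schema."""
    try:
        _MatchReportSchema.model_validate(payload)
    except pydantic.ValidationError as exc:
        raise DataFormatError(f"invalid match report: {exc}") from exc


def write_match_report(result: MatchResult, path: str | Path) -> None:
    """Serialize a match result (JSON) with provenance intact."""
    payload = result.to_dict()
    for key in ("combined_lr", "log10_lr_ban"):
        if not np.isfinite(payload[key]):
            payload[key] = None
    validate_match_report(payload)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def write_genotype_distributions(
    result: InferenceResult, path: str | Path, sample: str = ""
) -> None:
    """Inferred posteriors as CSV:
    ``sample,contributor,locus,allele1,allele2,probability``."""
    rows = []
    for locus, dists in result.posteriors.items():
        for k, dist in enumerate(dists):
            for pair, p in sorted(dist.mass.items()):
                rows.append(
                    {
                        "sample": sample,
                        "contributor": k + 1,
                        "locus": locus,
                        "allele1": pair.a1,
                        "allele2": pair.a2,
                        "probability": p,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def inference_to_json(result: InferenceResult) -> dict:
    """JSON-ready summary of an inference run (posteriors, weights, seed)."""
    return {
        "seed": result.seed,
        "weights": {
            "mean": result.weight_mean.tolist(),
            "sd": result.weight_sd.tolist(),
        },
        "mass": {"mean": result.mass_mean, "sd": result.mass_sd},
        "diagnostics": {
            k: v for k, v in result.diagnostics.items() if k != "acceptance"
        }
        | {"acceptance": result.diagnostics.get("acceptance", {})},
        "posteriors": {
            locus: [
                {f"{p.a1},{p.a2}": prob for p, prob in sorted(d.mass.items())}
                for d in dists
            ]
            for locus, dists in result.posteriors.items()
        },
    }


def write_inference_json(
    result: InferenceResult, path: str | Path, extra: dict | None = None
) -> None:
    payload = inference_to_json(result)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_inference_posteriors(path: str | Path):
    """Load per-contributor genotype posteriors from an inference JSON.

    Returns (posteriors, payload) where posteriors maps
    locus -> list of GenotypeDistribution (one per contributor).
    """
    from .population import GenotypeDistribution

    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
        posteriors = {}
        for locus, dists in payload["posteriors"].items():
            out = []
            for mass in dists:
                pairs = {}
                for key, prob in mass.items():
                    a1, a2 = key.split(",")
                    pairs[GenotypePair.make(locus, a1, a2)] = float(prob)
                out.append(GenotypeDistribution.from_weights(locus, pairs))
            posteriors[locus] = out
    except (KeyError, ValueError) as exc:
        raise DataFormatError(f"cannot parse inference JSON {path}: {exc}") from exc
    return posteriors, payload


# ---------------------------------------------------------------- run config

class ThresholdSection(pydantic.BaseModel):
    analytical_by_dye: dict[str, float] = {
        "blue": 73.0,
        "green": 84.0,
        "yellow": 75.0,
        "red": 52.0,
    }
    stochastic_by_injection: dict[int, float] = {2: 210.0, 5: 320.0, 10: 460.0}


class McmcSection(pydantic.BaseModel):
    iterations: int = 20000
    burn_in: int = 5000
    theta: float = 0.01


class ModelSection(pydantic.BaseModel):
    stutter_rate: float = 0.05
    degradation_rate: float = 0.0
    variance_floor: float = 100.0
    variance_scale: float | None = None


class RunConfig(pydantic.BaseModel):
    """Structured configuration for a pipeline run (YAML or JSON)."""

    panel_path: str | None = None
    frequency_path: str | None = None
    thresholds: ThresholdSection = ThresholdSection()
    model: ModelSection = ModelSection()
    mcmc: McmcSection = McmcSection()
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise DataFormatError(f"no such config file: {path}")
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        try:
            cfg = cls.model_validate(payload or {})
        except pydantic.ValidationError as exc:
            raise DataFormatError(f"invalid config {path}: {exc}") from exc
        for attr in ("panel_path", "frequency_path"):
            value = getattr(cfg, attr)
            if value is not None and not Path(value).exists():
                raise DataFormatError(f"{attr} does not exist: {value}")
        return cfg

    def config_hash(self) -> str:
        """Short stable hash of the configuration, for provenance."""
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
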