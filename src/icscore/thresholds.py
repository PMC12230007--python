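"""Cutoff configuration for the intrinsic-capacity scorers.

Two kinds of cutoffs feed the scoring rules:

* **Fixed cutoffs** with established literature values (handgrip strength by
  sex, the BMI band, Timed Up and Go, one-leg stance, three-month weight
  loss, the GDS-15 depression bands, and the composite classification bands).
  These ship as defaults and can be overridden from configuration.
* **Tabular norms** that are inherently population-specific: the senior
  fitness test chair-stand and sit-and-reach norms (age band x sex) and the
  education-adjusted MoCA screening cutoffs.  No defaults are hard-coded for
  these; they must be supplied by configuration.  A clearly labelled
  synthetic example table ships with the package for demonstration and
  testing.

The configuration format is a single YAML (or JSON) document with keys
``fixed``, ``norms`` and ``moca``; see ``docs/column_dictionary.md`` for the
schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
import yaml

__all__ = [
    "FixedCutoffs",
    "NormBand",
    "NormTable",
    "MocaCutoffs",
    "ThresholdConfig",
    "ConfigError",
    "LookupError_",
    "load_threshold_config",
    "example_threshold_config",
    "lookup_chair_stand_min",
    "lookup_sit_reach_range",
    "lookup_moca_cutoff",
]


class ConfigError(ValueError):
    """Raised when a threshold configuration is malformed or inconsistent."""


class LookupError_(KeyError):
    """Raised when a norm or cutoff lookup has no matching entry."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class FixedCutoffs:
    """Scalar cutoffs for the scoring rules, with literature defaults.

    Units: handgrip in kgf, BMI in kg/m^2, times in seconds, weight loss in
    kg, GDS-15 and composite values in points.
    """

    hgs_male_min: float = 27.0
    hgs_female_min: float = 16.0
    bmi_low: float = 22.0
    bmi_high: float = 27.0
    tug_max: float = 10.0
    balance_min: float = 20.0  # pass requires balance strictly greater
    weight_loss_kg: float = 3.0
    gds_band_edges: tuple[int, int] = (5, 10)
    composite_low_max: float = 4.0
    composite_moderate_max: float = 8.0

    def __post_init__(self) -> None:
        if self.hgs_male_min <= 0 or self.hgs_female_min <= 0:
            raise ConfigError("handgrip cutoffs must be positive")
        if not self.bmi_low < self.bmi_high:
            raise ConfigError("bmi_low < bmi_high is required")
        lo, hi = self.gds_band_edges
        if not (0 <= lo < hi <= 15):
            raise ConfigError(
                "gds_band_edges must be strictly increasing within 0..15"
            )
        if not self.composite_low_max < self.composite_moderate_max < 10:
            raise ConfigError(
                "composite_low_max < composite_moderate_max < 10 is required"
            )


@dataclass(frozen=True)
class NormBand:
    """One row of the functional-fitness norm table: an age band for one sex."""

    sex: str  # "F" or "M"
    age_min: int
    age_max: int
    chair_stand_min: int
    sit_reach_min: float
    sit_reach_max: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ConfigError(f"norm band sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_min > self.age_max:
            raise ConfigError("norm band age_min must not exceed age_max")
        if self.chair_stand_min < 0:
            raise ConfigError("chair_stand_min must be non-negative")
        if self.sit_reach_min > self.sit_reach_max:
            raise ConfigError("sit_reach_min must not exceed sit_reach_max")

    def matches(self, sex: str, age: float) -> bool:
        # closed interval on both ends; bands must not overlap
        return self.sex == sex and self.age_min <= age <= self.age_max


@dataclass(frozen=True)
class NormTable:
    """Age- and sex-specific chair-stand and sit-and-reach norms."""

    entries: tuple[NormBand, ...] = ()

    def __post_init__(self) -> None:
        for a in self.entries:
            for b in self.entries:
                if a is not b and a.sex == b.sex:
                    if a.age_min <= b.age_max and b.age_min <= a.age_max:
                        raise ConfigError(
                            f"overlapping norm bands for sex {a.sex}: "
                            f"{a.age_min}-{a.age_max} and {b.age_min}-{b.age_max}"
                        )

    def find(self, sex: str, age: float) -> NormBand:
        for band in self.entries:
            if band.matches(sex, age):
                return band
        raise LookupError_(
            f"no norm band covers sex={sex!r}, age={age:g}"
        )


@dataclass(frozen=True)
class MocaCutoffs:
    """Education-adjusted MoCA screening cutoffs, matched by exact band label."""

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for band, cutoff in self.entries.items():
            if not 0 <= cutoff <= 30:
                raise ConfigError(
                    f"MoCA cutoff for band {band!r} must lie in 0..30, got {cutoff}"
                )

    def find(self, education: str) -> int:
        try:
            return self.entries[education]
        except KeyError:
            raise LookupError_(
                f"no MoCA cutoff for education band {education!r}"
            ) from None


@dataclass(frozen=True)
class ThresholdConfig:
    """The full cutoff triple consumed by the scorers."""

    fixed: FixedCutoffs = field(default_factory=FixedCutoffs)
    norms: NormTable = field(default_factory=NormTable)
    moca: MocaCutoffs = field(default_factory=MocaCutoffs)


def lookup_chair_stand_min(table: NormTable, sex: str, age: float) -> int:
    """Minimum chair-stand repetitions counted as a pass for (sex, age)."""
    return table.find(sex, age).chair_stand_min


def lookup_sit_reach_range(table: NormTable, sex: str, age: float) -> tuple[float, float]:
    """Recommended sit-and-reach range (cm, inclusive ends) for (sex, age)."""
    band = table.find(sex, age)
    return (band.sit_reach_min, band.sit_reach_max)


def lookup_moca_cutoff(table: MocaCutoffs, education: str) -> int:
    """Education-adjusted MoCA cutoff; scores at or above it pass."""
    return table.find(education)


_FIXED_FIELDS = {
    "hgs_male_min", "hgs_female_min", "bmi_low", "bmi_high", "tug_max",
    "balance_min", "weight_loss_kg", "gds_band_edges",
    "composite_low_max", "composite_moderate_max",
}
_NORM_FIELDS = {
    "sex", "age_min", "age_max", "chair_stand_min",
    "sit_reach_min", "sit_reach_max",
}


def _build(doc: dict | None) -> ThresholdConfig:
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigError("threshold config must be a mapping")
    unknown = set(doc) - {"fixed", "norms", "moca"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    fixed_doc = doc.get("fixed") or {}
    if not isinstance(fixed_doc, dict):
        raise ConfigError("'fixed' must be a mapping")
    bad = set(fixed_doc) - _FIXED_FIELDS
    if bad:
        raise ConfigError(f"unknown fixed-cutoff keys: {sorted(bad)}")
    if "gds_band_edges" in fixed_doc:
        edges = fixed_doc["gds_band_edges"]
        if not (isinstance(edges, (list, tuple)) and len(edges) == 2):
            raise ConfigError("gds_band_edges must be a pair of integers")
        fixed_doc = {**fixed_doc, "gds_band_edges": (int(edges[0]), int(edges[1]))}
    fixed = FixedCutoffs(**fixed_doc)

    rows = doc.get("norms") or []
    if not isinstance(rows, list):
        raise ConfigError("'norms' must be a list of rows")
    bands = []
    for i, row in enumerate(rows):
        if not isinstance(row, dict):
            raise ConfigError(f"norms[{i}] must be a mapping")
        bad = set(row) - _NORM_FIELDS
        if bad:
            raise ConfigError(f"norms[{i}]: unknown keys {sorted(bad)}")
        missing = _NORM_FIELDS - set(row)
        if missing:
            raise ConfigError(f"norms[{i}]: missing keys {sorted(missing)}")
        bands.append(NormBand(
            sex=str(row["sex"]),
            age_min=int(row["age_min"]),
            age_max=int(row["age_max"]),
            chair_stand_min=int(row["chair_stand_min"]),
            sit_reach_min=float(row["sit_reach_min"]),
            sit_reach_max=float(row["sit_reach_max"]),
        ))
    norms = NormTable(entries=tuple(bands))

    moca_rows = doc.get("moca") or []
    if isinstance(moca_rows, dict):
        entries = {str(k): int(v) for k, v in moca_rows.items()}
    elif isinstance(moca_rows, list):
        entries = {}
        for i, row in enumerate(moca_rows):
            if not isinstance(row, dict) or set(row) != {"education_band", "cutoff"}:
                raise ConfigError(
                    f"moca[{i}] must have keys 'education_band' and 'cutoff'"
                )
            band = str(row["education_band"])
            if band in entries:
                raise ConfigError(f"duplicate MoCA education band {band!r}")
            entries[band] = int(row["cutoff"])
    else:
        raise ConfigError("'moca' must be a list of rows or a mapping")
    moca = MocaCutoffs(entries=entries)

    return ThresholdConfig(fixed=fixed, norms=norms, moca=moca)


def load_threshold_config(path: str | Path) -> ThresholdConfig:
    """Load and validate a threshold configuration from a YAML/JSON file.

    An empty file yields all default fixed cutoffs with empty norm and MoCA
    tables.  Raises :class:`ConfigError` naming the offending key or rule.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return _build(doc)


def dump_threshold_config(config: ThresholdConfig) -> dict:
    """Serialise a ThresholdConfig to a plain dict (round-trips via _build)."""
    return {
        "fixed": {**asdict(config.fixed),
                  "gds_band_edges": list(config.fixed.gds_band_edges)},
        "norms": [asdict(b) for b in config.norms.entries],
        "moca": dict(config.moca.entries),
    }


def threshold_config_from_dict(doc: dict | None) -> ThresholdConfig:
    """Build a ThresholdConfig from an already-parsed mapping."""
    return _build(doc)


def example_threshold_config() -> ThresholdConfig:
    """The synthetic example configuration shipped with the package.

    Its chair-stand / sit-and-reach norms and MoCA cutoffs are illustrative
    stand-ins for population norm tables, not published values.
    """
    with resources.files("icscore.data").joinpath(
        "synthetic_example_thresholds.yaml"
    ).open("r", encoding="utf-8") as fh:
        return _build(yaml.safe_load(fh))
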