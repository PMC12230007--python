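"""Longitudinal cohort tables: a documented CSV dialect, validation, scoring.

The interchange format is long-format CSV, UTF-8, comma-separated, header
row, "." decimal separator, empty string for missing.  One row is one
participant at one timepoint; ``timepoint`` is coded 0 (baseline) or
1 (follow-up).  Sex is coded ``F``/``M``; boolean flags are ``0``/``1``.
Secondary outcome columns beyond the core assessment battery are declared
through :class:`VariableSpec` (continuous, continuous-skewed, ordinal with
an ordered level list, or binary).  See ``docs/column_dictionary.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Mapping

import pandas as pd

from .scoring import AssessmentRecord, score_record
from .thresholds import ThresholdConfig

__all__ = [
    "VariableSpec",
    "CohortTable",
    "IntegrityError",
    "CORE_COLUMNS",
    "SCORE_COLUMNS",
    "read_cohort",
    "write_cohort",
    "score_cohort",
    "write_scored",
]

VarType = Literal["continuous", "continuous-skewed", "ordinal", "binary"]

# core assessment columns and their pandas dtypes
CORE_COLUMNS: dict[str, str] = {
    "participant_id": "str",
    "timepoint": "Int64",
    "age": "Float64",
    "sex": "str",
    "education": "str",
    "hgs": "Float64",
    "bmi": "Float64",
    "weight_loss_3mo": "Float64",
    "appetite_loss": "Int64",
    "wears_glasses": "Int64",
    "vision_difficulty": "Int64",
    "uses_hearing_aid": "Int64",
    "hearing_difficulty": "Int64",
    "tug": "Float64",
    "chair_stand": "Int64",
    "sit_reach": "Float64",
    "balance": "Float64",
    "gds15": "Int64",
    "moca": "Int64",
}

_BOOL_COLUMNS = (
    "appetite_loss", "wears_glasses", "vision_difficulty",
    "uses_hearing_aid", "hearing_difficulty",
)

SCORE_COLUMNS = (
    "sensory", "psychological", "cognitive", "vitality", "locomotion",
    "composite", "category",
)


class IntegrityError(ValueError):
    """Raised when a cohort file violates the table invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one analysis variable: its measurement type and levels."""

    name: str
    vtype: VarType
    levels: tuple[str, ...] | None = None  # ordered, for ordinal variables

    def __post_init__(self) -> None:
        if self.vtype == "ordinal" and not self.levels:
            raise ValueError(f"ordinal variable {self.name!r} needs an ordered level list")
        if self.vtype != "ordinal" and self.levels:
            raise ValueError(f"levels only apply to ordinal variables ({self.name!r})")


@dataclass
class CohortTable:
    """A validated long-format cohort: one row per participant x timepoint."""

    df: pd.DataFrame
    variables: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["participant_id", "timepoint"])
        if dup.any():
            pid = df.loc[dup, "participant_id"].iloc[0]
            tp = df.loc[dup, "timepoint"].iloc[0]
            raise IntegrityError(f"duplicate row for ({pid!r}, timepoint {tp})")
        base = set(df.loc[df["timepoint"] == 0, "participant_id"])
        follow = set(df.loc[df["timepoint"] == 1, "participant_id"])
        orphans = follow - base
        if orphans:
            raise IntegrityError(
                f"follow-up without baseline for {sorted(orphans)!r}"
            )
        for spec in self.variables.values():
            if spec.name not in df.columns:
                raise IntegrityError(f"declared variable {spec.name!r} not in table")
            if spec.vtype == "ordinal":
                observed = set(df[spec.name].dropna().astype(str))
                extra = observed - set(spec.levels)
                if extra:
                    raise IntegrityError(
                        f"{spec.name!r}: observed levels {sorted(extra)} not declared"
                    )

    # -- convenience views -------------------------------------------------
    @property
    def n_enrolled(self) -> int:
        return int((self.df["timepoint"] == 0).sum())

    @property
    def n_complete(self) -> int:
        ids = self.df.groupby("participant_id")["timepoint"].nunique()
        return int((ids == 2).sum())

    def baseline(self) -> pd.DataFrame:
        return self.df[self.df["timepoint"] == 0]

    def followup(self) -> pd.DataFrame:
        return self.df[self.df["timepoint"] == 1]

    def iter_records(self) -> Iterator[AssessmentRecord]:
        """Yield each row as an AssessmentRecord (missing cells pass as NaN)."""
        for _, row in self.df.iterrows():
            yield _row_to_record(row)


def _row_to_record(row: pd.Series) -> AssessmentRecord:
    def f(col):  # nullable scalar -> float or nan
        v = row[col]
        return float("nan") if pd.isna(v) else float(v)

    def i(col):
        v = row[col]
        return float("nan") if pd.isna(v) else int(v)

    def b(col):
        v = row[col]
        return None if pd.isna(v) else bool(v)

    return AssessmentRecord(
        participant_id=str(row["participant_id"]),
        timepoint=int(row["timepoint"]),
        age=f("age"),
        sex=str(row["sex"]),
        education=str(row["education"]),
        hgs=f("hgs"),
        bmi=f("bmi"),
        weight_loss_3mo=f("weight_loss_3mo"),
        appetite_loss=b("appetite_loss"),
        wears_glasses=b("wears_glasses"),
        vision_difficulty=b("vision_difficulty"),
        uses_hearing_aid=b("uses_hearing_aid"),
        hearing_difficulty=b("hearing_difficulty"),
        tug=f("tug"),
        chair_stand=i("chair_stand"),
        sit_reach=f("sit_reach"),
        balance=f("balance"),
        gds15=i("gds15"),
        moca=i("moca"),
    )


def read_cohort(
    path: str | Path,
    variables: Mapping[str, VariableSpec] | None = None,
) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    ``variables`` declares any secondary outcome columns beyond the core
    battery.  Raises :class:`IntegrityError` for duplicate
    (participant, timepoint) rows or follow-up rows without a baseline, and
    a ``ValueError`` naming the column for unparseable cells.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype="str", keep_default_na=False)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path.name}: missing required columns {missing}")
    df = df.replace("", pd.NA)
    out = pd.DataFrame()
    for col, dtype in CORE_COLUMNS.items():
        if dtype == "str":
            out[col] = df[col].astype("string")
        else:
            try:
                # astype (not to_numeric): exact round-trip float parsing
                out[col] = df[col].astype(dtype)
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"{path.name}: column {col!r} has an unparseable cell: {exc}"
                ) from exc
    for col in _BOOL_COLUMNS:
        bad = out[col].dropna().isin([0, 1])
        if not bad.all():
            raise ValueError(f"{path.name}: column {col!r} must be coded 0/1")
    variables = dict(variables or {})
    for name, spec in variables.items():
        if name not in df.columns:
            raise IntegrityError(f"{path.name}: declared variable {name!r} absent")
        if spec.vtype == "ordinal":
            out[name] = df[name].astype("string")
        elif spec.vtype == "binary":
            out[name] = df[name].astype("Int64")
        else:
            out[name] = df[name].astype("Float64")
    # carry through any score columns already present (scored files re-read)
    for col in SCORE_COLUMNS:
        if col in df.columns:
            if col == "category":
                out[col] = df[col].astype("string")
            else:
                out[col] = df[col].astype("Float64")
    return CohortTable(df=out, variables=variables)


def write_cohort(path: str | Path, table: CohortTable) -> None:
    """Write a cohort to the documented CSV dialect (round-trip stable)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, na_rep="")


def score_cohort(table: CohortTable, config: ThresholdConfig) -> CohortTable:
    """Score every row of a cohort, appending the seven score columns.

    Rows missing raw values raise; dropout is represented by absent
    follow-up rows, which simply contribute no scored row.
    """
    scored = table.df.copy()
    results: dict[str, list] = {c: [] for c in SCORE_COLUMNS}
    for record in table.iter_records():
        domains, comp = score_record(record, config)
        results["sensory"].append(domains.sensory)
        results["psychological"].append(domains.psychological)
        results["cognitive"].append(domains.cognitive)
        results["vitality"].append(domains.vitality)
        results["locomotion"].append(domains.locomotion)
        results["composite"].append(comp.score)
        results["category"].append(comp.category)
    for col in SCORE_COLUMNS:
        dtype = "string" if col == "category" else "Float64"
        scored[col] = pd.Series(results[col], index=scored.index, dtype=dtype)
    variables = dict(table.variables)
    variables.setdefault(
        "category", VariableSpec("category", "ordinal", ("low", "moderate", "high"))
    )
    return CohortTable(df=scored, variables=variables)


def write_scored(path: str | Path, table: CohortTable) -> None:
    """Write a scored cohort; re-reading reproduces all score columns exactly."""
    for col in SCORE_COLUMNS:
        if col not in table.df.columns:
            raise ValueError(f"table has no score column {col!r}; run score_cohort first")
    write_cohort(path, table)
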