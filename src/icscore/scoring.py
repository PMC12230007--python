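"""Intrinsic-capacity scoring: five domain scorers, composite, classifier.

Intrinsic capacity (IC) is the WHO composite of an individual's physical and
mental capacities, partitioned here into five domains — vitality, sensory,
locomotion, psychological, cognitive — each worth up to 2 points, summed
without weighting to a 0-10 composite:

    IC = locomotion (2) + vitality (2) + cognition (2) + psychological (2)
         + sensory (2)

The vitality and locomotion domains are themselves sums of four half-point
sub-rules; the sensory domain sums two one-point sub-rules (vision,
hearing); the psychological domain bands the GDS-15 total; the cognitive
domain thresholds the MoCA total at an education-adjusted cutoff.  The
composite classifies as low (0-4), moderate (5-8) or high (9-10) capacity.

Boundary conventions (the printed rules leave a few points on a continuous
scale undefined; these are this package's resolutions, applied uniformly):

* TUG exactly at the cutoff (10 s) scores 0 (tie-to-fail, matching the
  "over 10 s" zero rule).
* One-leg balance passes only strictly above 20 s, so times in (20, 21) s
  pass; the printed rules are stated on whole seconds.
* Handgrip at the sex cutoff passes (>= 27 kgf men, >= 16 kgf women).
* MoCA exactly at the education cutoff passes (single-threshold step).
* A sensory sub-score is 1 only with neither reported difficulty nor a
  corrective device; any impairment indicator (difficulty or device,
  in any combination) scores 0.
* Half-point composites falling between the printed integer class bands
  resolve downward: low < 5 <= moderate < 9 <= high.

All sub-scores are exact multiples of 0.5 and are accumulated as integer
half-points internally, so equality tests against the half-point grid are
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .thresholds import FixedCutoffs, MocaCutoffs, NormTable, ThresholdConfig

__all__ = [
    "AssessmentRecord",
    "DomainScores",
    "CompositeIC",
    "InputError",
    "MissingValueError",
    "score_vitality",
    "score_sensory",
    "score_locomotion",
    "score_psychological",
    "score_cognition",
    "composite",
    "classify_composite",
    "score_record",
    "CATEGORIES",
]

CATEGORIES = ("low", "moderate", "high")


class InputError(ValueError):
    """Raised for out-of-range or unrecognised scorer inputs."""


class MissingValueError(ValueError):
    """Raised when a record lacks a raw value required for scoring."""


@dataclass(frozen=True)
class AssessmentRecord:
    """One participant's raw assessment at one timepoint.

    Units: age years; hgs kgf; bmi kg/m^2; weight_loss_3mo kg over the last
    three months; tug and balance seconds; chair_stand repetitions;
    sit_reach centimetres (may be negative); gds15 0..15; moca 0..30.
    Timepoint is 0 (baseline) or 1 (follow-up).
    """

    participant_id: str
    timepoint: int
    age: float
    sex: str
    education: str
    hgs: float
    bmi: float
    weight_loss_3mo: float
    appetite_loss: bool
    wears_glasses: bool
    vision_difficulty: bool
    uses_hearing_aid: bool
    hearing_difficulty: bool
    tug: float
    chair_stand: int
    sit_reach: float
    balance: float
    gds15: int
    moca: int

    def __post_init__(self) -> None:
        # Missing values are permitted here (a record may be partially
        # observed); completeness is enforced by score_record, which names
        # the missing field.  Invariants apply only to present values.
        if self.timepoint not in (0, 1):
            raise InputError(f"timepoint must be 0 or 1, got {self.timepoint!r}")
        if self.sex not in ("F", "M"):
            raise InputError(f"sex must be 'F' or 'M', got {self.sex!r}")
        checks = [
            (self.age, lambda v: v >= 60, "age >= 60"),
            (self.hgs, lambda v: v >= 0, "hgs >= 0"),
            (self.bmi, lambda v: v > 0, "bmi > 0"),
            (self.weight_loss_3mo, lambda v: v >= 0, "weight_loss_3mo >= 0"),
            (self.tug, lambda v: v > 0, "tug > 0"),
            (self.chair_stand, lambda v: v >= 0, "chair_stand >= 0"),
            (self.balance, lambda v: v >= 0, "balance >= 0"),
            (self.gds15, lambda v: 0 <= v <= 15, "gds15 in 0..15"),
            (self.moca, lambda v: 0 <= v <= 30, "moca in 0..30"),
        ]
        for value, ok, rule in checks:
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            if not ok(value):
                raise InputError(f"invariant violated: {rule}")


@dataclass(frozen=True)
class DomainScores:
    """The five per-domain scores, each on its own half- or whole-point grid."""

    sensory: float
    psychological: float
    cognitive: float
    vitality: float
    locomotion: float

    _SETS = {
        "sensory": (0, 1, 2),
        "psychological": (0, 1, 2),
        "cognitive": (0, 2),
        "vitality": (0, 0.5, 1, 1.5, 2),
        "locomotion": (0, 0.5, 1, 1.5, 2),
    }

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in self._SETS[f.name]:
                raise InputError(
                    f"{f.name} score {v!r} not in allowed set {self._SETS[f.name]}"
                )

    def total(self) -> float:
        # accumulate in half-points so the sum sits exactly on the 0.5 grid
        halves = sum(
            int(round(2 * getattr(self, f.name))) for f in fields(self)
        )
        return halves / 2


@dataclass(frozen=True)
class CompositeIC:
    """The 0-10 composite score and its low/moderate/high class."""

    score: float
    category: str


def _half(passes: int) -> float:
    return passes * 0.5


def score_vitality(
    hgs: float,
    sex: str,
    bmi: float,
    weight_loss_3mo: float,
    appetite_loss: bool,
    cutoffs: FixedCutoffs | None = None,
) -> float:
    """Vitality domain: handgrip + BMI + weight loss + appetite, 0.5 each.

    Pass rules: handgrip at or above the sex cutoff; BMI inside the
    [bmi_low, bmi_high] band (inclusive); less than 3 kg lost in the last
    three months; no reported appetite loss.
    """
    cutoffs = cutoffs or FixedCutoffs()
    if sex == "M":
        hgs_min = cutoffs.hgs_male_min
    elif sex == "F":
        hgs_min = cutoffs.hgs_female_min
    else:
        raise InputError(f"sex must be 'F' or 'M', got {sex!r}")
    passes = (
        (hgs >= hgs_min)
        + (cutoffs.bmi_low <= bmi <= cutoffs.bmi_high)
        + (weight_loss_3mo < cutoffs.weight_loss_kg)
        + (not appetite_loss)
    )
    return _half(passes)


def score_sensory(
    wears_glasses: bool,
    vision_difficulty: bool,
    uses_hearing_aid: bool,
    hearing_difficulty: bool,
) -> float:
    """Sensory domain: vision and hearing self-report, 1 point each.

    A sub-score is 1 only when neither a difficulty nor a corrective device
    is reported; any impairment indicator scores 0.
    """
    vision = int(not vision_difficulty and not wears_glasses)
    hearing = int(not hearing_difficulty and not uses_hearing_aid)
    return float(vision + hearing)


def score_locomotion(
    tug: float,
    chair_stand: int,
    sit_reach: float,
    balance: float,
    age: float,
    sex: str,
    cutoffs: FixedCutoffs | None = None,
    norms: NormTable | None = None,
) -> float:
    """Locomotion domain: TUG + chair stand + sit-and-reach + balance, 0.5 each.

    Pass rules: TUG strictly under 10 s; repetitions at or above the
    age/sex norm; reach inside the age/sex range (inclusive); one-leg
    stance held strictly longer than 20 s.  Norm lookups must resolve for
    (sex, age); a missing band propagates as a lookup error.
    """
    cutoffs = cutoffs or FixedCutoffs()
    if norms is None:
        norms = NormTable()
    band = norms.find(sex, age)
    passes = (
        (tug < cutoffs.tug_max)
        + (chair_stand >= band.chair_stand_min)
        + (band.sit_reach_min <= sit_reach <= band.sit_reach_max)
        + (balance > cutoffs.balance_min)
    )
    return _half(passes)


def score_psychological(gds15: int, cutoffs: FixedCutoffs | None = None) -> float:
    """Psychological domain from the GDS-15 total: 0-5 -> 2, 6-10 -> 1, 11-15 -> 0."""
    cutoffs = cutoffs or FixedCutoffs()
    if not 0 <= gds15 <= 15:
        raise InputError(f"gds15 must lie in 0..15, got {gds15}")
    lo, hi = cutoffs.gds_band_edges
    if gds15 <= lo:
        return 2.0
    if gds15 <= hi:
        return 1.0
    return 0.0


def score_cognition(moca: int, education: str, moca_cutoffs: MocaCutoffs) -> float:
    """Cognitive domain: MoCA at or above the education-adjusted cutoff -> 2, else 0."""
    cutoff = moca_cutoffs.find(education)
    return 2.0 if moca >= cutoff else 0.0


def classify_composite(score: float, cutoffs: FixedCutoffs | None = None) -> str:
    """Classify a 0-10 composite as low, moderate or high capacity.

    Bands: low below 5, moderate from 5 up to (not including) 9, high from 9.
    Half-point scores in the gaps of the printed integer bands (4.5, 8.5)
    resolve to the lower class.
    """
    cutoffs = cutoffs or FixedCutoffs()
    if not (isinstance(score, (int, float)) and math.isfinite(score)):
        raise InputError(f"composite score must be finite, got {score!r}")
    if not 0 <= score <= 10:
        raise InputError(f"composite score must lie in 0..10, got {score}")
    if score < cutoffs.composite_low_max + 1:
        return "low"
    if score < cutoffs.composite_moderate_max + 1:
        return "moderate"
    return "high"


def composite(domains: DomainScores, cutoffs: FixedCutoffs | None = None) -> CompositeIC:
    """Sum the five domain scores and classify the result."""
    score = domains.total()
    return CompositeIC(score=score, category=classify_composite(score, cutoffs))


_RAW_FIELDS = (
    "age", "sex", "education", "hgs", "bmi", "weight_loss_3mo",
    "appetite_loss", "wears_glasses", "vision_difficulty",
    "uses_hearing_aid", "hearing_difficulty", "tug", "chair_stand",
    "sit_reach", "balance", "gds15", "moca",
)


def score_record(
    record: AssessmentRecord, config: ThresholdConfig
) -> tuple[DomainScores, CompositeIC]:
    """Score one complete assessment record through all five domains.

    Missing raw values are a hard error (scoring requires the full battery;
    no imputation), raised as :class:`MissingValueError` naming the field.
    """
    for name in _RAW_FIELDS:
        value = getattr(record, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingValueError(
                f"record {record.participant_id!r} is missing {name!r}"
            )
    domains = DomainScores(
        sensory=score_sensory(
            record.wears_glasses, record.vision_difficulty,
            record.uses_hearing_aid, record.hearing_difficulty,
        ),
        psychological=score_psychological(record.gds15, config.fixed),
        cognitive=score_cognition(record.moca, record.education, config.moca),
        vitality=score_vitality(
            record.hgs, record.sex, record.bmi, record.weight_loss_3mo,
            record.appetite_loss, config.fixed,
        ),
        locomotion=score_locomotion(
            record.tug, record.chair_stand, record.sit_reach, record.balance,
            record.age, record.sex, config.fixed, config.norms,
        ),
    )
    return domains, composite(domains, config.fixed)
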