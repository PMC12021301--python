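"""Operationalised Fried frailty phenotype.

Five binary components — slowness, weakness, weight loss, exhaustion and
low physical activity — are scored from a participant's measurements,
and the component count maps to a category: 0 components = robust,
1–2 = prefrail, >=3 = frail.

Boundary convention: the gait and grip cut-offs are strict ("below
0.8 m/s", "<27 kg / <15 kg" — a measurement exactly at the cut-off does
NOT flag), while weight loss and exhaustion are inclusive ("at least
5 kg", "at least 3 to 4 days a week").  Exhaustion flags when *either*
of the two depression-scale items reaches the frequency cut-off; low
activity flags when either self-reported walking difficulty is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd


class FrailtyError(ValueError):
    """Raised for invalid assessment inputs."""


class FrailtyCategory(str, Enum):
    ROBUST = "robust"
    PREFRAIL = "prefrail"
    FRAIL = "frail"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


COMPONENTS = ("slowness", "weakness", "weight_loss", "exhaustion", "low_activity")


@dataclass(frozen=True)
class ThresholdConfig:
    """Cut-offs for the five components.

    ``gait_speed_cutoff_m_s`` may be overridden per (sex, height) stratum
    via ``gait_cutoff_by_stratum`` for protocols that adjust the walk
    cut-off (e.g. short physical performance battery conventions); the
    default is a flat 0.8 m/s for everyone.
    """

    gait_speed_cutoff_m_s: float = 0.8
    grip_cutoff_kg: dict[str, float] = field(
        default_factory=lambda: {"male": 27.0, "female": 15.0}
    )
    weight_loss_cutoff_kg: float = 5.0
    exhaustion_days_per_week: int = 3
    gait_cutoff_by_stratum: dict[tuple[str, str], float] | None = None


DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass(frozen=True)
class ParticipantAssessment:
    """One participant's clinical measurements for phenotype scoring."""

    sex: str  # "male" | "female"
    gait_speed_m_s: float  # usual pace over a 3-m walk
    grip_kg: float  # handgrip dynamometry
    weight_loss_kg_6mo: float  # unintentional loss, previous 6 months
    exhaustion_q1: int  # days/week, "everything I did was an effort"
    exhaustion_q2: int  # days/week, "I could not get going"
    diff_walk_block: bool
    diff_climb_stairs: bool
    height_stratum: str | None = None  # optional, for stratified gait cut-offs

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise FrailtyError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.gait_speed_m_s < 0 or self.grip_kg < 0 or self.weight_loss_kg_6mo < 0:
            raise FrailtyError("measurements must be nonnegative")
        for q in (self.exhaustion_q1, self.exhaustion_q2):
            if not 0 <= int(q) <= 7:
                raise FrailtyError(f"exhaustion frequency {q} outside 0..7 days/week")


@dataclass(frozen=True)
class ComponentFlags:
    slowness: bool
    weakness: bool
    weight_loss: bool
    exhaustion: bool
    low_activity: bool

    @property
    def count(self) -> int:
        return sum(
            (self.slowness, self.weakness, self.weight_loss,
             self.exhaustion, self.low_activity)
        )


def score_components(
    a: ParticipantAssessment, thresholds: ThresholdConfig = DEFAULT_THRESHOLDS
) -> ComponentFlags:
    """Score the five phenotype components for one participant."""
    a.validate()
    gait_cut = thresholds.gait_speed_cutoff_m_s
    if thresholds.gait_cutoff_by_stratum and a.height_stratum is not None:
        gait_cut = thresholds.gait_cutoff_by_stratum.get(
            (a.sex, a.height_stratum), gait_cut
        )
    return ComponentFlags(
        slowness=a.gait_speed_m_s < gait_cut,
        weakness=a.grip_kg < thresholds.grip_cutoff_kg[a.sex],
        weight_loss=a.weight_loss_kg_6mo >= thresholds.weight_loss_cutoff_kg,
        exhaustion=max(a.exhaustion_q1, a.exhaustion_q2)
        >= thresholds.exhaustion_days_per_week,
        low_activity=a.diff_walk_block or a.diff_climb_stairs,
    )


def classify_frailty(flags: ComponentFlags) -> FrailtyCategory:
    """Map a component count to robust / prefrail / frail."""
    if flags.count >= 3:
        return FrailtyCategory.FRAIL
    if flags.count >= 1:
        return FrailtyCategory.PREFRAIL
    return FrailtyCategory.ROBUST


def cohort_frailty_table(
    cohort: list[ParticipantAssessment],
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
    ids: list | None = None,
) -> pd.DataFrame:
    """Score and classify a whole cohort.

    Returns a DataFrame with one row per participant: the five component
    flags, the component count and the category.  The index is ``ids``
    when given, else 0..n-1.
    """
    if not cohort:
        raise FrailtyError("cohort is empty")
    rows = []
    for a in cohort:
        f = score_components(a, thresholds)
        rows.append(
            {
                "slowness": f.slowness,
                "weakness": f.weakness,
                "weight_loss": f.weight_loss,
                "exhaustion": f.exhaustion,
                "low_activity": f.low_activity,
                "count": f.count,
                "category": classify_frailty(f).value,
            }
        )
    idx = pd.Index(ids if ids is not None else range(len(cohort)), name="id")
    if len(idx) != len(cohort):
        raise FrailtyError("ids length does not match cohort size")
    return pd.DataFrame(rows, index=idx)


def assessments_from_frame(df: pd.DataFrame) -> list[ParticipantAssessment]:
    """Build typed assessments from a cohort table (cohort CSV schema)."""
    return [
        ParticipantAssessment(
            sex=str(r.sex),
            gait_speed_m_s=float(r.gait_speed_m_s),
            grip_kg=float(r.grip_kg),
            weight_loss_kg_6mo=float(r.weight_loss_kg_6mo),
            exhaustion_q1=int(r.exhaustion_q1),
            exhaustion_q2=int(r.exhaustion_q2),
            diff_walk_block=bool(r.diff_walk_block),
            diff_climb_stairs=bool(r.diff_climb_stairs),
        )
        for r in df.itertuples()
    ]


def category_counts(table: pd.DataFrame) -> dict[str, int]:
    """Counts per category from a cohort frailty table (sums to n)."""
    c = table["category"].value_counts()
    return {cat.value: int(c.get(cat.value, 0)) for cat in FrailtyCategory}
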