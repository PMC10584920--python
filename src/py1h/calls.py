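"""QC and event calling for pY1H strain series.

A strain series is the unit of calling: one DNA-bait crossed with a TF-pair
strain and its two single-TF controls (2-AD design), or with both reciprocal
AD-orientation sub-series (1-AD design). Calling proceeds in three steps:

1. ``classify_activity`` quantizes each strain's reporter signal into an
   ordinal activity level (very_weak / weak / moderate / strong) by a robust
   z-score against the plate's empty-empty RS distribution.
2. ``qc_series`` rejects series with failed mating growth, non-uniform
   quadruplicates, or failed sequence confirmation.
3. ``call_event`` applies the calling rules: cooperative when the TF-pair
   strain is active (moderate/strong) but neither single is; antagonistic
   when a single is active but the pair is not; independent when the pair
   and at least one single are active; none when nothing is.

For the 1-AD design, the activity pattern across the two AD orientations
further resolves the binding modality (mutual cooperativity, recruitment,
sequestration, competition, independent); the 2-AD design can only separate
mutual cooperativity from sequestration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "ActivityLevel",
    "Event",
    "Modality",
    "StrainRecord",
    "StrainSeries",
    "InteractionCall",
    "classify_activity",
    "qc_series",
    "call_event",
    "classify_modality_1ad",
    "classify_modality_2ad",
    "call_screen",
]


class ActivityLevel(str, Enum):
    """Ordinal reporter activity relative to the empty-empty controls."""

    VERY_WEAK = "very_weak"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"

    @property
    def active(self) -> bool:
        """Moderate/strong counts as reporter activity for event calling."""
        return self in (ActivityLevel.MODERATE, ActivityLevel.STRONG)


class Event(str, Enum):
    COOPERATIVE = "cooperative"
    ANTAGONISTIC_TF1 = "antagonistic_TF1"
    ANTAGONISTIC_TF2 = "antagonistic_TF2"
    ANTAGONISTIC_MUTUAL = "antagonistic_mutual"
    INDEPENDENT = "independent"
    NONE = "none"
    INCONCLUSIVE = "inconclusive"


class Modality(str, Enum):
    MUTUAL_COOPERATIVITY = "mutual_cooperativity"
    RECRUITMENT_TF1_RECRUITS_TF2 = "recruitment_TF1_recruits_TF2"
    RECRUITMENT_TF2_RECRUITS_TF1 = "recruitment_TF2_recruits_TF1"
    SEQUESTRATION_OF_TF1 = "sequestration_of_TF1"
    SEQUESTRATION_OF_TF2 = "sequestration_of_TF2"
    COMPETITION = "competition"
    INDEPENDENT = "independent"
    SEQUESTRATION = "sequestration"
    INDISTINGUISHABLE = "indistinguishable"
    UNCLASSIFIED = "unclassified"


#: Default robust-z cut points between very_weak|weak, weak|moderate,
#: moderate|strong.
DEFAULT_THRESHOLDS = (2.0, 4.0, 8.0)

#: Consistency constant making the MAD comparable to a standard deviation
#: under normality.
_MAD_SCALE = 1.4826


def classify_activity(
    rs: float,
    empty_rs: np.ndarray,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    fallback_scale: float = 1e-9,
) -> tuple[ActivityLevel, float]:
    """Quantize a reporter signal into an activity level.

    The robust z-score is ``(rs - median(empty_rs)) / (1.4826 * MAD)``
    where the median/MAD are taken over the plate's empty-empty strain
    scores. A degenerate empty distribution (MAD = 0) falls back to an
    absolute epsilon scale with a warning.

    Returns the level and the underlying z.
    """
    empty_rs = np.asarray(empty_rs, dtype=float)
    empty_rs = empty_rs[np.isfinite(empty_rs)]
    if empty_rs.size < 3:
        raise ValueError("need >= 3 empty-empty reporter signals to estimate spread")
    med = float(np.median(empty_rs))
    mad = float(np.median(np.abs(empty_rs - med)))
    scale = _MAD_SCALE * mad
    if scale == 0.0:
        warnings.warn("degenerate empty-empty RS distribution (MAD = 0); using epsilon scale")
        scale = max(fallback_scale, abs(med) * fallback_scale)
    z = (rs - med) / scale
    t1, t2, t3 = thresholds
    if z < t1:
        level = ActivityLevel.VERY_WEAK
    elif z < t2:
        level = ActivityLevel.WEAK
    elif z < t3:
        level = ActivityLevel.MODERATE
    else:
        level = ActivityLevel.STRONG
    return level, float(z)


@dataclass(frozen=True)
class StrainRecord:
    """One strain's QC inputs and activity within a series."""

    level: ActivityLevel
    growth: bool = True
    uniform: bool = True
    n_colonies: int = 4
    sequence_confirmed: bool = True
    contaminated: bool = False
    z: float = np.nan


@dataclass
class StrainSeries:
    """A bait × TF-pair series: TF-pair strain plus single-TF controls.

    For the 1-AD design, ``orientation2`` carries the reciprocal
    AD-orientation sub-series (TF2-AD + TF1 with its singles) and the main
    records correspond to orientation 1 (TF1-AD + TF2).
    """

    bait: str
    pair_id: str
    design: str  # "1AD" | "2AD"
    pair: StrainRecord
    tf1: StrainRecord
    tf2: StrainRecord
    orientation2: "StrainSeries | None" = None
    require_sequence_confirmation: bool = False


@dataclass(frozen=True)
class InteractionCall:
    bait: str
    pair_id: str
    event: Event
    modality: Modality | None = None
    qc_reason: str = ""
    levels: tuple = field(default_factory=tuple)


def qc_series(series: StrainSeries) -> tuple[bool, str]:
    """Apply the series-level QC criteria.

    A series is inconclusive if any strain lacked growth on the mating
    selection plate, if fewer than 3/4 quadruplicate colonies were uniform
    for any strain, if sequence confirmation was required and failed, or if
    any strain is contaminated.

    Returns ``(passed, reason)`` with ``reason == ""`` on pass.
    """
    for name, rec in (("pair", series.pair), ("tf1", series.tf1), ("tf2", series.tf2)):
        if rec.contaminated:
            return False, f"contaminated:{name}"
        if not rec.growth:
            return False, f"no_growth:{name}"
        if not rec.uniform or rec.n_colonies < 3:
            return False, f"non_uniform:{name}"
        if series.require_sequence_confirmation and not rec.sequence_confirmed:
            return False, f"unconfirmed:{name}"
    if series.orientation2 is not None:
        ok, reason = qc_series(series.orientation2)
        if not ok:
            return False, f"orientation2:{reason}"
    return True, ""


def _event_from_levels(pair: ActivityLevel, tf1: ActivityLevel, tf2: ActivityLevel) -> Event:
    """Total map from an activity 3-tuple to an event (exhaustive by construction)."""
    p, a, b = pair.active, tf1.active, tf2.active
    if p and not a and not b:
        return Event.COOPERATIVE
    if not p and a and b:
        return Event.ANTAGONISTIC_MUTUAL
    if not p and a:
        return Event.ANTAGONISTIC_TF1
    if not p and b:
        return Event.ANTAGONISTIC_TF2
    if p:
        return Event.INDEPENDENT
    return Event.NONE


def call_event(series: StrainSeries) -> InteractionCall:
    """QC a series and call its interaction event.

    For 1-AD series with both orientations, the event is called from the
    orientation whose pattern shows a dependent event (cooperative first,
    then antagonistic), and the binding modality is resolved from the
    reciprocal-orientation activity pattern.
    """
    ok, reason = qc_series(series)
    levels = (series.pair.level, series.tf1.level, series.tf2.level)
    if not ok:
        return InteractionCall(series.bait, series.pair_id, Event.INCONCLUSIVE, qc_reason=reason, levels=levels)

    event = _event_from_levels(*levels)
    modality: Modality | None = None
    if series.design == "1AD":
        if series.orientation2 is None:
            warnings.warn(f"1-AD series {series.pair_id} missing reciprocal orientation")
            modality = Modality.UNCLASSIFIED
        else:
            o2 = series.orientation2
            event2 = _event_from_levels(o2.pair.level, o2.tf1.level, o2.tf2.level)
            # prefer the orientation showing a dependent event
            rank = {
                Event.COOPERATIVE: 0,
                Event.ANTAGONISTIC_TF1: 1,
                Event.ANTAGONISTIC_TF2: 1,
                Event.ANTAGONISTIC_MUTUAL: 1,
                Event.INDEPENDENT: 2,
                Event.NONE: 3,
            }
            if rank[event2] < rank[event]:
                event = event2
            pattern = (
                series.tf1.level.active,      # TF1-AD alone
                series.pair.level.active,     # TF1-AD + TF2
                o2.tf1.level.active,          # TF2-AD alone
                o2.pair.level.active,         # TF2-AD + TF1
            )
            modality = classify_modality_1ad(pattern)
    elif series.design == "2AD":
        modality = classify_modality_2ad(event)
    return InteractionCall(series.bait, series.pair_id, event, modality=modality, levels=levels)


#: Mechanism truth table for the 1-AD design. Keys are activity patterns
#: (TF1-AD alone, TF1-AD + TF2, TF2-AD alone, TF2-AD + TF1).
MODALITY_TABLE: dict[tuple[bool, bool, bool, bool], Modality] = {
    (False, True, False, True): Modality.MUTUAL_COOPERATIVITY,
    # TF1 binds DNA on its own and tethers AD-tagged TF2
    (True, True, False, True): Modality.RECRUITMENT_TF1_RECRUITS_TF2,
    (False, True, True, True): Modality.RECRUITMENT_TF2_RECRUITS_TF1,
    # TF2 pulls DNA-binding TF1 off the bait via a protein interaction
    (True, False, False, False): Modality.SEQUESTRATION_OF_TF1,
    (False, False, True, False): Modality.SEQUESTRATION_OF_TF2,
    # both bind alone; the winner of the site keeps its AD at the DNA
    (True, False, True, True): Modality.COMPETITION,   # TF2 outcompetes TF1
    (True, True, True, False): Modality.COMPETITION,   # TF1 outcompetes TF2
    (True, True, True, True): Modality.INDEPENDENT,
}


def classify_modality_1ad(pattern: tuple[bool, bool, bool, bool]) -> Modality:
    """Resolve the binding modality from the reciprocal-orientation pattern.

    ``pattern`` is the active/inactive 4-tuple (TF1-AD alone, TF1-AD + TF2,
    TF2-AD alone, TF2-AD + TF1). Patterns outside the mechanism truth table
    return ``UNCLASSIFIED``.
    """
    return MODALITY_TABLE.get(tuple(bool(x) for x in pattern), Modality.UNCLASSIFIED)


def classify_modality_2ad(event: Event) -> Modality:
    """The 2-AD design only separates mutual cooperativity from sequestration."""
    if event is Event.COOPERATIVE:
        return Modality.MUTUAL_COOPERATIVITY
    if event in (Event.ANTAGONISTIC_TF1, Event.ANTAGONISTIC_TF2, Event.ANTAGONISTIC_MUTUAL):
        return Modality.SEQUESTRATION
    return Modality.INDISTINGUISHABLE


def call_screen(
    scores,
    design: str = "2AD",
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
):
    """Call every series on a scored plate.

    Parameters
    ----------
    scores : DataFrame
        Output of :func:`py1h.scoring.score_plate` augmented with columns
        ``bait``, ``pair_id`` and ``strain_class`` in
        {"pair", "tf1_single", "tf2_single", "empty"}; 1-AD screens use the
        classes suffixed ``_o1`` / ``_o2`` for the two AD orientations.
    design : "1AD" | "2AD"

    Returns a DataFrame with one row per (bait, pair_id): event, modality,
    QC status and the supporting activity levels.
    """
    import pandas as pd

    # prefer the per-colony empty RS sample (stabler spread estimate than
    # the handful of strain-level aggregates) when the scorer provides it
    empty_rs = scores.attrs.get("empty_colony_rs")
    if empty_rs is None or len(empty_rs) < 3:
        empty_rs = scores.loc[scores["strain_class"] == "empty", "rs"].to_numpy(dtype=float)

    def record(row) -> StrainRecord:
        if row is None or not np.isfinite(row["rs"]):
            return StrainRecord(
                level=ActivityLevel.VERY_WEAK, growth=bool(row["growth"]) if row is not None and "growth" in row else True,
                uniform=False, n_colonies=0,
            )
        level, z = classify_activity(float(row["rs"]), empty_rs, thresholds)
        return StrainRecord(
            level=level,
            growth=bool(row.get("growth", True)),
            uniform=bool(row["uniform"]),
            n_colonies=int(row["n_colonies"]),
            z=z,
        )

    def pick(grp, cls):
        sub = grp[grp["strain_class"] == cls]
        return None if sub.empty else sub.iloc[0]

    rows = []
    for (bait, pair_id), grp in scores[scores["strain_class"] != "empty"].groupby(
        ["bait", "pair_id"], sort=False
    ):
        if design == "2AD":
            trio = [pick(grp, c) for c in ("pair", "tf1_single", "tf2_single")]
            if any(r is None for r in trio):
                rows.append((bait, pair_id, Event.INCONCLUSIVE.value, "", "missing_strain", "", "", ""))
                continue
            series = StrainSeries(
                bait=bait, pair_id=pair_id, design="2AD",
                pair=record(trio[0]), tf1=record(trio[1]), tf2=record(trio[2]),
            )
        else:
            o1 = [pick(grp, c) for c in ("pair_o1", "tf1_single_o1", "tf2_single_o1")]
            o2 = [pick(grp, c) for c in ("pair_o2", "tf1_single_o2", "tf2_single_o2")]
            if any(r is None for r in o1 + o2):
                rows.append((bait, pair_id, Event.INCONCLUSIVE.value, "", "missing_strain", "", "", ""))
                continue
            series = StrainSeries(
                bait=bait, pair_id=pair_id, design="1AD",
                pair=record(o1[0]), tf1=record(o1[1]), tf2=record(o1[2]),
                orientation2=StrainSeries(
                    bait=bait, pair_id=pair_id, design="1AD",
                    pair=record(o2[0]), tf1=record(o2[1]), tf2=record(o2[2]),
                ),
            )
        call = call_event(series)
        rows.append(
            (
                bait,
                pair_id,
                call.event.value,
                call.modality.value if call.modality else "",
                call.qc_reason,
                *(lv.value for lv in call.levels),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["bait", "pair_id", "event", "modality", "qc_reason",
                 "pair_level", "tf1_level", "tf2_level"],
    )
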