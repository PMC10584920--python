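"""Reporter signal scores and cooperativity/antagonism indices.

The unit of quantification is one colony: its area ``A`` (pixels) and mean
foreground intensity ``I`` (signal units per pixel) come from
:mod:`py1h.plates`. Per plate, the reporter signal of a strain is

    RS = agg[(I - I_min) * A] - AVG[(I - I_min) * A]_empty-empty

where ``I_min`` is the minimum non-zero colony intensity on the plate, the
aggregate runs over the strain's quadruplicate colonies, and the average
runs over all empty-empty control colonies (neither prey vector expresses a
TF). From the per-strain scores of a bait × TF-pair series the three
interaction indices follow:

    cooperativity = RS_pair - RS_TF1 - RS_TF2
    antagonism_1  = RS_TF1 - RS_pair
    antagonism_2  = RS_TF2 - RS_pair

Quadruplicates are aggregated by the median by default (robust to a single
bad colony); the mean is available, and with mean aggregation the mean RS
over the empty-empty strains on a plate is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateContext",
    "ReporterScore",
    "InteractionIndices",
    "plate_context",
    "reporter_signal",
    "indices",
    "score_plate",
]

#: strain_class label of the empty-empty control strains.
EMPTY_CLASS = "empty"

#: Quadruplicate uniformity rule: at least this many detected colonies ...
MIN_UNIFORM_COLONIES = 3
#: ... whose per-colony (I - I_min) * A coefficient of variation is at most this.
MAX_UNIFORM_CV = 0.5


@dataclass(frozen=True)
class PlateContext:
    """Per-plate normalization constants for the reporter signal.

    Attributes
    ----------
    i_min : float
        Minimum non-zero colony intensity on the plate (signal units).
    empty_baseline : float
        Mean of per-colony ``(I - i_min) * A`` over all empty-empty
        colonies (signal * pixel units).
    n_empty_colonies : int
        Number of empty-empty colonies the baseline averages over.
    """

    i_min: float
    empty_baseline: float
    n_empty_colonies: int


@dataclass(frozen=True)
class ReporterScore:
    """Reporter signal of one strain on one plate (signal * pixel units)."""

    strain: str
    rs: float
    n_colonies: int
    aggregation: str
    uniform: bool
    cv: float


@dataclass(frozen=True)
class InteractionIndices:
    cooperativity: float
    antagonism_1: float
    antagonism_2: float


def _colony_values(df: pd.DataFrame, i_min: float) -> np.ndarray:
    """Per-colony (I - i_min) * A over detected, unflagged colonies."""
    ok = (df["area"] > 0) & (df.get("flag", pd.Series("", index=df.index)).fillna("") == "")
    sub = df.loc[ok]
    return ((sub["intensity"] - i_min) * sub["area"]).to_numpy(dtype=float)


def plate_context(measurements: pd.DataFrame) -> PlateContext:
    """Compute ``I_min`` and the empty-empty baseline for one plate.

    Parameters
    ----------
    measurements : DataFrame
        One row per colony with at least columns ``strain``,
        ``strain_class``, ``area``, ``intensity`` (``flag`` optional).

    Raises
    ------
    ValueError
        ``"no_baseline"`` if the plate carries no empty-empty colony, or if
        no colony was detected at all.
    """
    detected = measurements[measurements["area"] > 0]
    if detected.empty:
        raise ValueError("no_baseline: no detected colony on plate")
    i_min = float(detected["intensity"].min())

    empties = measurements[measurements["strain_class"] == EMPTY_CLASS]
    vals = _colony_values(empties, i_min)
    if vals.size == 0:
        raise ValueError("no_baseline: no empty-empty colony on plate")
    return PlateContext(i_min=i_min, empty_baseline=float(vals.mean()), n_empty_colonies=int(vals.size))


def reporter_signal(
    quartet: pd.DataFrame,
    ctx: PlateContext,
    aggregation: str = "median",
) -> ReporterScore:
    """Aggregate one strain's quadruplicate into a reporter signal score.

    Undetected or flagged colonies are dropped before aggregation. The
    strain is "uniform" when at least 3 colonies were detected and the
    coefficient of variation of their per-colony values is at most 0.5.

    Raises
    ------
    ValueError
        If no usable colony remains (the caller should mark the series
        inconclusive).
    """
    if aggregation not in ("median", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    strain = str(quartet["strain"].iloc[0])
    vals = _colony_values(quartet, ctx.i_min)
    if vals.size == 0:
        raise ValueError(f"all colonies of strain {strain} missing or flagged")
    agg = float(np.median(vals) if aggregation == "median" else np.mean(vals))
    # uniformity on the raw signal mass I*A: the background-subtracted mass
    # has mean ~0 for baseline strains, which would make its CV meaningless
    ok = (quartet["area"] > 0) & (
        quartet.get("flag", pd.Series("", index=quartet.index)).fillna("") == ""
    )
    mass = (quartet.loc[ok, "intensity"] * quartet.loc[ok, "area"]).to_numpy(dtype=float)
    mean_mass = float(mass.mean())
    cv = float(mass.std() / abs(mean_mass)) if mean_mass != 0 else np.inf
    uniform = vals.size >= MIN_UNIFORM_COLONIES and cv <= MAX_UNIFORM_CV
    return ReporterScore(
        strain=strain,
        rs=agg - ctx.empty_baseline,
        n_colonies=int(vals.size),
        aggregation=aggregation,
        uniform=bool(uniform),
        cv=cv,
    )


def indices(rs_pair: float, rs_tf1: float, rs_tf2: float) -> InteractionIndices:
    """Cooperativity and antagonism indices from three reporter signals."""
    return InteractionIndices(
        cooperativity=rs_pair - rs_tf1 - rs_tf2,
        antagonism_1=rs_tf1 - rs_pair,
        antagonism_2=rs_tf2 - rs_pair,
    )


def score_plate(measurements: pd.DataFrame, aggregation: str = "median") -> pd.DataFrame:
    """Score every strain on one plate.

    Returns a DataFrame with one row per strain: ``strain``,
    ``strain_class``, ``rs``, ``n_colonies``, ``uniform``, ``cv``. Strains
    whose colonies are all missing/flagged get ``rs = NaN`` and
    ``n_colonies = 0``.
    """
    ctx = plate_context(measurements)
    empty_colony_rs = (
        _colony_values(measurements[measurements["strain_class"] == EMPTY_CLASS], ctx.i_min)
        - ctx.empty_baseline
    )
    rows = []
    for (strain, cls), grp in measurements.groupby(["strain", "strain_class"], sort=False):
        try:
            score = reporter_signal(grp, ctx, aggregation=aggregation)
            rows.append((strain, cls, score.rs, score.n_colonies, score.uniform, score.cv))
        except ValueError:
            rows.append((strain, cls, np.nan, 0, False, np.nan))
    out = pd.DataFrame(
        rows, columns=["strain", "strain_class", "rs", "n_colonies", "uniform", "cv"]
    )
    # per-colony empty-empty RS values: a larger sample than the strain
    # aggregates, useful as the reference spread for activity calling
    out.attrs["empty_colony_rs"] = empty_colony_rs
    return out
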