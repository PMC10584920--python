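"""End-to-end glue: plate image -> measurements -> scores -> calls."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calls, plates, scoring

__all__ = ["analyze_plate", "analyze_screen"]


def analyze_plate(
    image: np.ndarray,
    layout: pd.DataFrame,
    design: str = "2AD",
    invert: bool = False,
    aggregation: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify one readout plate and call its interaction events.

    ``layout`` maps grid positions to strains (columns ``row``, ``col``,
    ``strain``, ``strain_class``, plus ``bait`` and ``pair_id`` for the
    event-series bookkeeping). Returns ``(scores, calls)`` tables.
    """
    measured = plates.measure_plate(image, layout, invert=invert)
    laid = measured[~measured["strain_class"].isin(["absent", ""])]
    scores = scoring.score_plate(laid, aggregation=aggregation)
    attrs = dict(scores.attrs)
    meta_cols = [c for c in ("bait", "pair_id") if c in layout.columns]
    if meta_cols:
        meta = layout.drop_duplicates("strain")[["strain"] + meta_cols]
        scores = scores.merge(meta, on="strain", how="left")
        scores.attrs.update(attrs)  # pandas merge drops attrs
    if "bait" not in scores.columns:
        scores["bait"] = ""
    if "pair_id" not in scores.columns:
        scores["pair_id"] = scores["strain"]
    called = calls.call_screen(scores, design=design)
    return scores, called


def analyze_screen(
    plate_images: dict[str, np.ndarray],
    layouts: dict[str, pd.DataFrame],
    design: str = "2AD",
    **kwargs,
) -> pd.DataFrame:
    """Analyze one plate per bait and concatenate the calls."""
    out = []
    for bait, image in plate_images.items():
        _, called = analyze_plate(image, layouts[bait], design=design, **kwargs)
        out.append(called)
    return pd.concat(out, ignore_index=True)
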