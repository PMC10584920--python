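"""SWIM-seq strain confirmation: alignment filters and well/series decisions.

Strain identity is confirmed from barcoded, well-pooled amplicon sequencing
of the prey plasmids. Reads are aligned upstream (bwa mem or equivalent);
this module consumes the SAM records. A read survives filtering when it is
a primary alignment with an alignment score of at least 90% of the trimmed
read length and strictly fewer than 5% mismatches. Per well, each expected
target (TF ORF or empty vector) is confirmed when its surviving-read count
strictly exceeds that of every non-expected target; a TF-pair series is
sequence-confirmed when both TFs are confirmed in the TF1-TF2 well, TF1 and
the empty AD2u vector in the TF1-empty well, and TF2 and the empty pGADT7
vector in the TF2-empty well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pysam

__all__ = [
    "read_sam",
    "filter_records",
    "confirm_well",
    "confirm_series",
    "WellConfirmation",
    "SeriesConfirmation",
]

MIN_SCORE_FRACTION = 0.90
MAX_MISMATCH_FRACTION = 0.05


def read_sam(path: str, well_from_qname=None) -> pd.DataFrame:
    """Load alignment records from a SAM file into a record table.

    Columns: ``read_id``, ``well``, ``target``, ``primary``, ``score``
    (AS tag), ``mismatches`` (NM tag), ``read_length``. The well id is
    parsed from the query name; by default everything before the first
    ``:`` (override with ``well_from_qname``).
    """
    if well_from_qname is None:
        well_from_qname = lambda q: q.split(":", 1)[0]
    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            rows.append(
                (
                    rec.query_name,
                    well_from_qname(rec.query_name),
                    rec.reference_name,
                    not (rec.is_secondary or rec.is_supplementary),
                    float(rec.get_tag("AS")) if rec.has_tag("AS") else float("nan"),
                    int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    rec.query_length or (rec.infer_read_length() or 0),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "well", "target", "primary", "score", "mismatches", "read_length"],
    )


def filter_records(
    records: pd.DataFrame,
    min_score_fraction: float = MIN_SCORE_FRACTION,
    max_mismatch_fraction: float = MAX_MISMATCH_FRACTION,
) -> pd.DataFrame:
    """Keep primary alignments with score >= 90% of the read length and < 5% mismatches."""
    keep = (
        records["primary"]
        & (records["score"] >= min_score_fraction * records["read_length"])
        & (records["mismatches"] < max_mismatch_fraction * records["read_length"])
    )
    return records[keep]


@dataclass(frozen=True)
class WellConfirmation:
    well: str
    expected: tuple[str, ...]
    counts: dict = field(default_factory=dict)
    confirmed_targets: tuple[str, ...] = ()
    confirmed: bool = False

    @property
    def top_target(self) -> str | None:
        if not self.counts:
            return None
        return max(self.counts, key=lambda t: self.counts[t])


def confirm_well(surviving: pd.DataFrame, expected) -> WellConfirmation:
    """Decide whether a well's reads confirm its expected target(s).

    A target is confirmed when it has at least one surviving read and its
    count strictly exceeds the count of every non-expected target (ties
    with an unexpected target are unconfirmed). With a single expectation
    this is the strict-maximum rule; wells expecting both a TF and an empty
    vector evaluate each expectation over the same surviving reads.
    """
    expected = (expected,) if isinstance(expected, str) else tuple(expected)
    well = str(surviving["well"].iloc[0]) if len(surviving) else ""
    counts = surviving["target"].value_counts().to_dict()
    max_unexpected = max((c for t, c in counts.items() if t not in expected), default=0)
    confirmed_targets = tuple(
        t for t in expected if counts.get(t, 0) >= 1 and counts.get(t, 0) > max_unexpected
    )
    return WellConfirmation(
        well=well,
        expected=expected,
        counts=counts,
        confirmed_targets=confirmed_targets,
        confirmed=len(confirmed_targets) == len(expected),
    )


@dataclass(frozen=True)
class SeriesConfirmation:
    pair_id: str
    confirmed: bool
    reason: str = ""


def confirm_series(
    pair_id: str,
    pair_well: WellConfirmation | None,
    tf1_well: WellConfirmation | None,
    tf2_well: WellConfirmation | None,
    tf1: str,
    tf2: str,
    ad2u_vector: str = "AD2u_empty",
    pgadt7_vector: str = "pGADT7_empty",
) -> SeriesConfirmation:
    """Sequence-confirm a TF-pair series from its three wells.

    Requires TF1 and TF2 in the pair well, TF1 plus the empty AD2u vector
    in the TF1-empty well, and TF2 plus the empty pGADT7 vector in the
    TF2-empty well.
    """
    for name, conf in (("pair", pair_well), ("tf1", tf1_well), ("tf2", tf2_well)):
        if conf is None:
            return SeriesConfirmation(pair_id, False, f"missing_well:{name}")
    checks = [
        ("pair", pair_well, (tf1, tf2)),
        ("tf1", tf1_well, (tf1, ad2u_vector)),
        ("tf2", tf2_well, (tf2, pgadt7_vector)),
    ]
    for name, conf, targets in checks:
        for t in targets:
            if t not in conf.confirmed_targets:
                return SeriesConfirmation(pair_id, False, f"unconfirmed:{name}:{t}")
    return SeriesConfirmation(pair_id, True)
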