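"""Paralog comparison: percent identity, homology pair expansion, partner Jaccard.

Percent amino-acid identity comes from a global (Needleman-Wunsch, affine
gap) pairwise alignment under a configurable substitution matrix (BLOSUM62
by default); identity is the number of matched identical residues over the
full alignment length (gap columns included).

Known interacting TF-pairs are expanded by homology: for a known pair
(X, Y), every TF A with identity(A, X) above the cutoff and every B with
identity(B, Y) above it contributes candidate pairs (A, Y), (X, B) and
(A, B). The cutoff may be given directly or as a percentile of the
off-diagonal identity distribution.

Functional similarity between two paralogs is the Jaccard index of their
partner-relationship vectors: for each shared tested partner, two bits
(has >= 1 cooperative event, has >= 1 antagonistic event).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "percent_identity",
    "identity_matrix",
    "homology_expand",
    "partner_profiles",
    "partner_jaccard",
    "identity_bins",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


def _aligner(matrix_name: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = "global"
    return aligner


def percent_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
    denominator: str = "alignment",
) -> float:
    """Percent identity of a global pairwise alignment (0-100).

    ``denominator`` is the alignment length including gap columns
    ("alignment", default) or the shorter sequence length ("shorter").
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}")
    aln = _aligner(matrix, open_gap, extend_gap).align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    if denominator == "alignment":
        denom = aln.length
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * counts.identities / denom


def identity_matrix(sequences: dict[str, str], **kwargs) -> pd.DataFrame:
    """All-against-all percent identity (symmetric, diagonal 100)."""
    names = list(sequences)
    mat = pd.DataFrame(100.0, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pid = percent_identity(sequences[a], sequences[b], **kwargs)
            mat.loc[a, b] = mat.loc[b, a] = pid
    return mat


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def homology_expand(
    known_pairs: list[tuple[str, str]],
    identities: pd.DataFrame,
    cutoff: float | None = None,
    percentile: float | None = None,
) -> pd.DataFrame:
    """Expand known TF-pairs with homology-derived candidate pairs.

    Exactly one of ``cutoff`` (percent identity) or ``percentile``
    (quantile of the off-diagonal identities, e.g. 99.9) must be given.
    Returns unordered, deduplicated pairs with a ``provenance`` column
    ("known" wins over "homology") and the resolved ``cutoff`` as a frame
    attribute.
    """
    if (cutoff is None) == (percentile is None):
        raise ValueError("give exactly one of cutoff or percentile")
    if percentile is not None:
        if not 0 < percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        iu = np.triu_indices(len(identities), k=1)
        cutoff = float(np.percentile(identities.to_numpy()[iu], percentile))

    for x, y in known_pairs:
        if x not in identities.index or y not in identities.index:
            raise ValueError(f"identity matrix does not cover pair ({x}, {y})")

    def similar(tf: str) -> list[str]:
        col = identities[tf]
        return [str(t) for t in col.index[(col >= cutoff) & (col.index != tf)]]

    out: dict[tuple[str, str], str] = {}
    for x, y in known_pairs:
        out[_norm_pair(x, y)] = "known"
    for x, y in known_pairs:
        sim_x = similar(x)
        sim_y = similar(y)
        candidates = (
            [(a, y) for a in sim_x] + [(x, b) for b in sim_y] + [(a, b) for a in sim_x for b in sim_y]
        )
        for pair in candidates:
            key = _norm_pair(*pair)
            out.setdefault(key, "homology")
    df = pd.DataFrame(
        [(a, b, prov) for (a, b), prov in sorted(out.items())],
        columns=["tf_a", "tf_b", "provenance"],
    )
    df.attrs["cutoff"] = cutoff
    return df


def partner_profiles(
    calls: pd.DataFrame, tf_a: str, tf_b: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Binary partner-relationship vectors for two TFs over shared partners.

    ``calls`` has columns ``tf``, ``partner``, ``event`` with event in
    {"cooperative", "antagonistic"}. For each partner tested with both TFs
    (in any order), the vector carries two bits per partner: >= 1
    cooperative event, >= 1 antagonistic event.
    """
    def events_of(tf: str) -> pd.DataFrame:
        fwd = calls[calls["tf"] == tf][["partner", "event"]]
        rev = calls[calls["partner"] == tf][["tf", "event"]].rename(columns={"tf": "partner"})
        return pd.concat([fwd, rev], ignore_index=True)

    ev_a, ev_b = events_of(tf_a), events_of(tf_b)
    shared = sorted(set(ev_a["partner"]) & set(ev_b["partner"]))

    def vector(ev: pd.DataFrame) -> np.ndarray:
        bits = []
        for p in shared:
            sub = ev[ev["partner"] == p]["event"]
            bits.append(int((sub == "cooperative").any()))
            bits.append(int((sub == "antagonistic").any()))
        return np.array(bits, dtype=int)

    return vector(ev_a), vector(ev_b), shared


def partner_jaccard(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Jaccard index |AND| / |OR| of two binary vectors (NaN when OR empty)."""
    a = np.asarray(vec_a, dtype=bool)
    b = np.asarray(vec_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("partner vectors must have equal length")
    union = int((a | b).sum())
    if union == 0:
        return float("nan")
    return int((a & b).sum()) / union


def identity_bins(percent: float) -> str:
    """Identity class: low (<30), medium (30-50, closed), high (>50)."""
    if not 0 <= percent <= 100:
        raise ValueError("percent identity must lie in [0, 100]")
    if percent < 30:
        return "low"
    if percent <= 50:
        return "medium"
    return "high"
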