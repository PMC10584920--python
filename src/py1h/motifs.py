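"""PWM scanning with exact p-values, core-motif merging, co-binding.

Motif presence in a promoter is scored per window as the sum of log-odds

    score(w) = sum_i log2( PWM_i[w_i] / 0.25 )

against a uniform background. Scores are discretized on a fixed grid
(default 1e-4 bits per unit) so that the per-window score is an exact
integer sum; the p-value P(Score >= s) over all 4^k background words is
then computed by exact dynamic programming on that grid, and scanning and
p-value lookup agree to the granularity by construction.

Overlapping hits of one TF on one promoter are merged into non-overlapping
"core motifs": consecutive hits sharing >= 80% of nucleotides (relative to
the shorter hit) are grouped transitively; each group emits the n-way
intersection when it is at least 4 nt long, otherwise the group is reduced
one member at a time (keeping the contiguous (n-1)-run with the longest
intersection, ties to the leftmost) until an intersection of >= 4 nt — or a
single hit — remains. Two TFs co-bind a promoter when they have core motifs
within 10 nt edge-to-edge.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "CoreMotif",
    "read_pwm_file",
    "read_pwm_dir",
    "write_pwm_file",
    "filter_low_specificity",
    "scan",
    "score_to_pvalue",
    "merge_core_motifs",
    "pair_cobinding",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

#: Default score discretization granularity, in bits.
GRANULARITY = 1e-4

#: Default hit-reporting p-value cutoff.
DEFAULT_P_MAX = 1e-4

#: Sentinel integer score for windows containing an impossible base.
_NEG_INF = np.iinfo(np.int64).min // 4


@dataclass
class PWM:
    """Position-probability matrix over A, C, G, T with uniform background.

    ``matrix`` has shape (k, 4); each row sums to 1. Integer log-odds are
    precomputed at ``granularity`` bits per unit; zero-probability entries
    score minus infinity (the window is unmatchable).
    """

    name: str
    matrix: np.ndarray
    background: float = 0.25
    granularity: float = GRANULARITY
    _int_scores: np.ndarray = field(init=False, repr=False)
    _sf: "tuple[int, np.ndarray] | None" = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (k, 4) with k >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: position probabilities must sum to 1")
        ints = np.full(self.matrix.shape, _NEG_INF, dtype=np.int64)
        pos = self.matrix > 0.0
        lo = np.log2(self.matrix[pos] / self.background)
        ints[pos] = np.round(lo / self.granularity).astype(np.int64)
        self._int_scores = ints

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Best attainable score in bits (on the discretization grid)."""
        return float(self._int_scores.max(axis=1).sum() * self.granularity)

    def _survival(self) -> tuple[int, np.ndarray]:
        """Exact distribution of the integer score over uniform words.

        Returns ``(min_int, sf)`` where ``sf[j] = P(S >= min_int + j)``
        for the integer score S, counting only words with finite score.
        """
        if self._sf is not None:
            return self._sf
        ints = self._int_scores
        finite = ints > _NEG_INF
        dist = np.ones(1, dtype=float)
        cur_lo = 0
        cur_len = 1
        for r, f in zip(ints, finite):
            vals = r[f]
            new_lo = cur_lo + int(vals.min())
            new_len = cur_len + int(vals.max() - vals.min())
            new = np.zeros(new_len, dtype=float)
            for v in vals:
                shift = int(v) - int(vals.min())
                new[shift : shift + cur_len] += dist[:cur_len] * self.background
            dist = new
            cur_lo = new_lo
            cur_len = new_len
        sf = np.cumsum(dist[::-1])[::-1]
        self._sf = (cur_lo, sf)
        return self._sf

    def pvalue(self, score: float) -> float:
        """P(Score >= score) over uniform random words (exact DP)."""
        if score == -np.inf:
            return 1.0
        lo, sf = self._survival()
        s_int = int(round(score / self.granularity))
        idx = s_int - lo
        if idx < 0:
            # below the worst attainable finite score: every finite word qualifies
            return float(sf[0]) if sf.size else 0.0
        if idx >= sf.size:
            return 0.0
        return float(sf[idx])

    def score_threshold(self, p_max: float) -> int:
        """Smallest integer score whose p-value is at most ``p_max``.

        Windows scoring at or above the returned value (in granularity
        units) are exactly the windows with ``pvalue <= p_max``.
        """
        lo, sf = self._survival()
        passing = np.nonzero(sf <= p_max)[0]
        if passing.size == 0:
            return lo + sf.size  # unattainable: no score passes
        return lo + int(passing[0])


def read_pwm_file(path: str | os.PathLike) -> PWM:
    """Read a whitespace-delimited PWM: header ``>NAME`` then 4 rows (A,C,G,T) x k columns."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{path}: expected '>NAME' header line")
    name = lines[0][1:].strip()
    rows = [np.array(ln.split(), dtype=float) for ln in lines[1:5]]
    if len(rows) != 4 or len({r.size for r in rows}) != 1:
        raise ValueError(f"{path}: expected 4 equal-length probability rows")
    return PWM(name=name, matrix=np.vstack(rows).T)


def write_pwm_file(pwm: PWM, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for b in range(4):
            fh.write(" ".join(f"{v:.6f}" for v in pwm.matrix[:, b]) + "\n")


def read_pwm_dir(directory: str | os.PathLike) -> list[PWM]:
    return [
        read_pwm_file(os.path.join(directory, f))
        for f in sorted(os.listdir(directory))
        if f.endswith((".pwm", ".txt"))
    ]


def filter_low_specificity(pwm: PWM, min_max_probability: float = 0.8) -> bool:
    """Keep a PWM only if some position has a base probability >= 0.8.

    Matrices whose maximum probability is below the cutoff at every position
    carry little positional information and are dropped before scanning.
    Returns True to keep.
    """
    return bool((pwm.matrix.max(axis=1) >= min_max_probability).any())


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as int8 indices (N and unknowns -> -1)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(pwm: PWM, enc: np.ndarray) -> np.ndarray:
    """Integer score of every window of an encoded strand (|s|-k+1 values)."""
    k = pwm.k
    n = enc.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        col = enc[i : i + n]
        bad = col < 0
        safe = np.where(bad, 0, col)
        vals = pwm._int_scores[i, safe]
        scores += vals
        valid &= ~bad
        valid &= vals > _NEG_INF
    scores[~valid] = _NEG_INF
    return scores


def scan(
    pwm: PWM,
    sequence: str,
    promoter: str = "",
    both_strands: bool = True,
    p_max: float | None = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Scan a sequence with a PWM, reporting hits at ``p <= p_max``.

    Hit coordinates are 0-based half-open on the forward strand regardless
    of the matched strand; scores are in bits. Windows containing N are
    skipped. With ``p_max=None`` every finite-scoring window is reported.
    """
    enc = encode(sequence)
    n = len(sequence)
    rows: list[tuple] = []
    min_int = pwm.score_threshold(p_max) if p_max is not None else None
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        if strand == "+":
            strand_enc = enc
        else:
            rev = enc[::-1]
            strand_enc = np.where(rev >= 0, _COMPLEMENT[np.where(rev >= 0, rev, 0)], np.int8(-1))
        ints = _window_scores(pwm, strand_enc)
        passing = ints > _NEG_INF
        if min_int is not None:
            passing &= ints >= min_int
        for t in np.nonzero(passing)[0]:
            score = float(ints[t] * pwm.granularity)
            p = pwm.pvalue(score)
            if strand == "+":
                start = int(t)
            else:
                start = n - int(t) - pwm.k
            rows.append((pwm.name, promoter, start, start + pwm.k, strand, score, p))
    df = pd.DataFrame(rows, columns=["tf", "promoter", "start", "end", "strand", "score", "p"])
    return df.sort_values(["start", "strand"], kind="stable").reset_index(drop=True)


def score_to_pvalue(pwm: PWM, score: float) -> float:
    """Functional alias for :meth:`PWM.pvalue`."""
    return pwm.pvalue(score)


@dataclass(frozen=True)
class CoreMotif:
    """Merged non-overlapping binding-site interval of one TF on one promoter."""

    tf: str
    promoter: str
    start: int
    end: int
    members: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return self.end - self.start


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _intersection(members: list[tuple[int, int]]) -> tuple[int, int]:
    start = max(m[0] for m in members)
    end = min(m[1] for m in members)
    return start, end


def _emit_group(
    members: list[tuple[int, int]],
    out: list[tuple[tuple[int, int], tuple[tuple[int, int], ...]]],
    min_core: int,
) -> None:
    """Recursively reduce a group to cores of >= ``min_core`` nt."""
    start, end = _intersection(members)
    if end - start >= min_core:
        out.append(((start, end), tuple(members)))
        return
    if len(members) == 1:
        iv = members[0]
        if iv[1] - iv[0] >= min_core:
            out.append((iv, (iv,)))
        return
    # drop one end member: keep the contiguous (n-1)-run with the longest
    # intersection; ties go to the leftmost run
    left, right = members[:-1], members[1:]
    li = _intersection(left)
    ri = _intersection(right)
    if (li[1] - li[0]) >= (ri[1] - ri[0]):
        keep, dropped = left, members[-1]
    else:
        keep, dropped = right, members[0]
    _emit_group(keep, out, min_core)
    _emit_group([dropped], out, min_core)


def merge_core_motifs(
    hits: pd.DataFrame,
    min_core: int = 4,
    min_shared: float = 0.8,
) -> list[CoreMotif]:
    """Merge one TF's hits on one promoter into non-overlapping core motifs.

    ``hits`` needs columns ``start`` and ``end`` (``tf`` / ``promoter``
    optional, propagated to the output). Consecutive hits sharing at least
    ``min_shared`` of the shorter hit's nucleotides are grouped
    transitively; groups reduce to intersections of >= ``min_core`` nt as
    described in the module docstring. A final left-to-right sweep trims any
    residual overlap between emitted cores (cores shrinking below
    ``min_core`` are dropped), so the output is always pairwise
    non-overlapping.
    """
    if hits.empty:
        return []
    tf = str(hits["tf"].iloc[0]) if "tf" in hits else ""
    promoter = str(hits["promoter"].iloc[0]) if "promoter" in hits else ""
    ivs = sorted({(int(s), int(e)) for s, e in zip(hits["start"], hits["end"])})

    groups: list[list[tuple[int, int]]] = [[ivs[0]]]
    for iv in ivs[1:]:
        prev = groups[-1][-1]
        shorter = min(prev[1] - prev[0], iv[1] - iv[0])
        if shorter > 0 and _overlap(prev, iv) / shorter >= min_shared:
            groups[-1].append(iv)
        else:
            groups.append([iv])

    raw: list[tuple[tuple[int, int], tuple[tuple[int, int], ...]]] = []
    for grp in groups:
        _emit_group(grp, raw, min_core)

    raw.sort(key=lambda c: c[0])
    cores: list[CoreMotif] = []
    prev_end = -1
    for (start, end), members in raw:
        start = max(start, prev_end)
        if end - start >= min_core:
            cores.append(CoreMotif(tf=tf, promoter=promoter, start=start, end=end, members=members))
            prev_end = end
    return cores


def pair_cobinding(
    cores_a: list[CoreMotif],
    cores_b: list[CoreMotif],
    max_gap: int = 10,
) -> pd.DataFrame:
    """Report core-motif pairs of two TFs within ``max_gap`` nt of each other.

    The gap is edge-to-edge; overlapping cores count as gap 0. Cores must
    lie on the same promoter.
    """
    rows = []
    for a in cores_a:
        for b in cores_b:
            if a.promoter != b.promoter:
                continue
            gap = max(0, max(a.start, b.start) - min(a.end, b.end))
            if gap <= max_gap:
                rows.append((a.tf, b.tf, a.promoter, a.start, a.end, b.start, b.end, gap))
    return pd.DataFrame(
        rows,
        columns=["tf_a", "tf_b", "promoter", "start_a", "end_a", "start_b", "end_b", "gap"],
    )
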