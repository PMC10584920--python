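"""Degree-preserving network randomization and overlap statistics.

The pY1H result network is bipartite and directed: source nodes are TF-pair
strains (TF1-TF2), target nodes are promoters. Significance of overlap with
orthogonal evidence (ChIP-seq peaks, motif cores) is assessed against a
null of 10,000 degree-preserving randomizations, each obtained by 20,000
successful double-edge swaps; a swap exchanges the targets of two random
edges and is rejected when it would create a duplicate edge, so every
node's in- and out-degree is preserved exactly. The observed overlap is
converted to a Z-score and a two-tailed normal p-value against the null
sample.

An edge overlaps the evidence when BOTH TFs of the pair satisfy the
evidence mode at the edge's promoter: a ChIP peak summit in the promoter in
any cell line, in the same cell line, summits within 50 bp of each other, a
core motif anywhere in the promoter, or core motifs within 10 nt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

__all__ = [
    "BipartiteNetwork",
    "RandomizationResult",
    "ProportionTestResult",
    "edge_switch_randomize",
    "overlap_count",
    "null_significance",
    "randomization_test",
    "two_proportion_test",
]


@dataclass
class BipartiteNetwork:
    """TF-pair -> promoter network with unique directed edges.

    ``pair_tfs`` maps each source (pair id) to its two member TFs.
    """

    edges: list[tuple[str, str]]
    pair_tfs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in bipartite network")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BipartiteNetwork":
        """Build from an edge list with columns pair_id, tf1, tf2, promoter."""
        edges = list(zip(df["pair_id"].astype(str), df["promoter"].astype(str)))
        pair_tfs = {
            str(r.pair_id): (str(r.tf1), str(r.tf2))
            for r in df.drop_duplicates("pair_id").itertuples()
        }
        return cls(edges=edges, pair_tfs=pair_tfs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, self.pair_tfs[p][0], self.pair_tfs[p][1], t) for p, t in self.edges
        ]
        return pd.DataFrame(rows, columns=["pair_id", "tf1", "tf2", "promoter"])

    @property
    def sources(self) -> list[str]:
        return sorted({s for s, _ in self.edges})

    @property
    def targets(self) -> list[str]:
        return sorted({t for _, t in self.edges})

    def degrees(self) -> tuple[dict[str, int], dict[str, int]]:
        out: dict[str, int] = {}
        inn: dict[str, int] = {}
        for s, t in self.edges:
            out[s] = out.get(s, 0) + 1
            inn[t] = inn.get(t, 0) + 1
        return out, inn


@njit(cache=False)
def _swap_loop(src, tgt, adj, n_switches, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    m = src.size
    done = 0
    attempts = 0
    while done < n_switches and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        s1, t1 = src[e1], tgt[e1]
        s2, t2 = src[e2], tgt[e2]
        if t1 == t2 or s1 == s2:
            continue
        if adj[s1, t2] or adj[s2, t1]:
            continue
        adj[s1, t1] = False
        adj[s2, t2] = False
        adj[s1, t2] = True
        adj[s2, t1] = True
        tgt[e1] = t2
        tgt[e2] = t1
        done += 1
    return done


def edge_switch_randomize(
    net: BipartiteNetwork,
    n_switches: int = 20_000,
    seed: int | np.random.SeedSequence | None = None,
    retry_factor: int = 100,
) -> BipartiteNetwork:
    """Randomize a network by double-edge swaps, preserving every degree.

    ``n_switches`` counts successful swaps; proposals that would duplicate
    an edge are rejected and retried, up to ``retry_factor * n_switches``
    attempts. If the attempt budget is exhausted (e.g. a single-edge
    network admits no swap) the partially-switched network is returned with
    a warning.
    """
    if len(net.edges) < 2:
        warnings.warn("network has < 2 edges; no swap possible")
        return BipartiteNetwork(edges=list(net.edges), pair_tfs=dict(net.pair_tfs))
    srcs = net.sources
    tgts = net.targets
    s_idx = {s: i for i, s in enumerate(srcs)}
    t_idx = {t: i for i, t in enumerate(tgts)}
    src = np.array([s_idx[s] for s, _ in net.edges], dtype=np.int64)
    tgt = np.array([t_idx[t] for _, t in net.edges], dtype=np.int64)
    adj = np.zeros((len(srcs), len(tgts)), dtype=np.bool_)
    adj[src, tgt] = True
    if isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed.generate_state(1)[0])
    else:
        seed_int = int(np.random.SeedSequence(seed).generate_state(1)[0])
    done = _swap_loop(src, tgt, adj, n_switches, retry_factor * n_switches, np.uint32(seed_int))
    if done < n_switches:
        warnings.warn(f"only {done}/{n_switches} swaps succeeded within the retry budget")
    edges = [(srcs[s], tgts[t]) for s, t in zip(src, tgt)]
    return BipartiteNetwork(edges=edges, pair_tfs=dict(net.pair_tfs))


_CHIP_MODES = ("chip_any_cell", "chip_same_cell", "chip_summits_50bp")
_MOTIF_MODES = ("motif_anywhere", "motif_within_10bp")


def _edge_predicate(
    pair_tfs: dict[str, tuple[str, str]],
    evidence: pd.DataFrame,
    mode: str,
    summit_distance: int,
    motif_gap: int,
):
    """Build the per-edge support predicate for an evidence set and mode."""
    if mode in _CHIP_MODES:
        required = {"tf", "promoter", "summit"} | (
            {"cell_line"} if mode == "chip_same_cell" else set()
        )
    elif mode in _MOTIF_MODES:
        required = {"tf", "promoter", "start", "end"}
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    missing = required - set(evidence.columns)
    if missing:
        raise ValueError(f"mode {mode!r} requires evidence columns {sorted(missing)}")

    by_tf_prom: dict[tuple[str, str], pd.DataFrame] = {
        (str(tf), str(prom)): grp
        for (tf, prom), grp in evidence.groupby(["tf", "promoter"], sort=False)
    }

    def supported(pair_id: str, prom: str) -> bool:
        tf1, tf2 = pair_tfs[pair_id]
        g1 = by_tf_prom.get((tf1, prom))
        g2 = by_tf_prom.get((tf2, prom))
        if g1 is None or g2 is None:
            return False
        if mode in ("chip_any_cell", "motif_anywhere"):
            return True
        if mode == "chip_same_cell":
            return bool(set(g1["cell_line"]) & set(g2["cell_line"]))
        if mode == "chip_summits_50bp":
            s1 = g1["summit"].to_numpy(dtype=float)
            s2 = g2["summit"].to_numpy(dtype=float)
            return bool((np.abs(s1[:, None] - s2[None, :]) <= summit_distance).any())
        # motif_within_10bp
        a1 = g1[["start", "end"]].to_numpy(dtype=float)
        a2 = g2[["start", "end"]].to_numpy(dtype=float)
        gap = np.maximum(
            0,
            np.maximum(a1[:, None, 0], a2[None, :, 0])
            - np.minimum(a1[:, None, 1], a2[None, :, 1]),
        )
        return bool((gap <= motif_gap).any())

    return supported


def overlap_count(
    net: BipartiteNetwork,
    evidence: pd.DataFrame,
    mode: str,
    summit_distance: int = 50,
    motif_gap: int = 10,
) -> int:
    """Count edges supported by evidence for both TFs at the promoter.

    Evidence columns: ``tf``, ``promoter`` always; ``cell_line`` and
    ``summit`` for the ChIP modes; ``start``/``end`` (core-motif intervals)
    for the motif modes.

    Modes
    -----
    chip_any_cell
        Both TFs have a peak summit within the promoter, any cell line.
    chip_same_cell
        Some single cell line has summits for both TFs in the promoter.
    chip_summits_50bp
        Both TFs have summits within ``summit_distance`` bp of each other.
    motif_anywhere
        Both TFs have a core motif in the promoter.
    motif_within_10bp
        The TFs have core motifs within ``motif_gap`` nt edge-to-edge.
    """
    supported = _edge_predicate(net.pair_tfs, evidence, mode, summit_distance, motif_gap)
    return sum(1 for pair_id, prom in net.edges if supported(pair_id, prom))


@dataclass(frozen=True)
class RandomizationResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    null_samples: np.ndarray = field(repr=False, default=None)


def null_significance(observed: float, null_samples: np.ndarray) -> RandomizationResult:
    """Z-score and two-tailed normal p of an observed overlap against a null sample."""
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size < 2:
        raise ValueError("need >= 2 null samples")
    mean = float(null_samples.mean())
    sd = float(null_samples.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate_null: null overlap distribution has zero spread")
    z = (float(observed) - mean) / sd
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return RandomizationResult(
        observed=int(observed), null_mean=mean, null_sd=sd, z=z, p=p, null_samples=null_samples
    )


def randomization_test(
    net: BipartiteNetwork,
    evidence: pd.DataFrame,
    mode: str,
    n_networks: int = 10_000,
    n_switches: int = 20_000,
    seed: int | None = None,
    **overlap_kwargs,
) -> RandomizationResult:
    """Full randomization analysis: observed overlap vs. a null of randomized networks.

    The evidence predicate depends only on (pair, promoter), so it is
    precomputed as a support table once; each null network then reduces to
    an edge-switch run plus a table lookup.
    """
    observed = overlap_count(net, evidence, mode, **overlap_kwargs)

    srcs, tgts = net.sources, net.targets
    s_idx = {s: i for i, s in enumerate(srcs)}
    t_idx = {t: i for i, t in enumerate(tgts)}
    src0 = np.array([s_idx[s] for s, _ in net.edges], dtype=np.int64)
    tgt0 = np.array([t_idx[t] for _, t in net.edges], dtype=np.int64)

    # support[pair, promoter]: would an edge there count under this mode?
    supported = _edge_predicate(
        net.pair_tfs,
        evidence,
        mode,
        overlap_kwargs.get("summit_distance", 50),
        overlap_kwargs.get("motif_gap", 10),
    )
    support = np.zeros((len(srcs), len(tgts)), dtype=np.bool_)
    for s in srcs:
        for t in tgts:
            support[s_idx[s], t_idx[t]] = supported(s, t)

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_networks).astype(np.uint32)
    null = np.empty(n_networks, dtype=np.int64)
    retry = 100 * n_switches
    for i in range(n_networks):
        src = src0.copy()
        tgt = tgt0.copy()
        adj = np.zeros((len(srcs), len(tgts)), dtype=np.bool_)
        adj[src, tgt] = True
        _swap_loop(src, tgt, adj, n_switches, retry, seeds[i])
        null[i] = int(support[src, tgt].sum())
    return null_significance(observed, null)


@dataclass(frozen=True)
class ProportionTestResult:
    p1: float
    n1: int
    p2: float
    n2: int
    se1: float
    se2: float
    z: float
    p: float


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, pooled: bool = True
) -> ProportionTestResult:
    """Two-tailed comparison of two proportions.

    Per-group standard errors are ``sqrt(p(1-p)/n)``; the z statistic uses
    the pooled-proportion variance by default (unpooled with
    ``pooled=False``).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    se1 = float(np.sqrt(p1 * (1 - p1) / n1))
    se2 = float(np.sqrt(p2 * (1 - p2) / n2))
    if pooled:
        pp = (x1 + x2) / (n1 + n2)
        denom = np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    else:
        denom = np.sqrt(se1**2 + se2**2)
    if denom == 0:
        z = 0.0
    else:
        z = float((p1 - p2) / denom)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ProportionTestResult(p1=p1, n1=n1, p2=p2, n2=n2, se1=se1, se2=se2, z=z, p=p)
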