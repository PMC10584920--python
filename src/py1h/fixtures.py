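"""Seeded synthetic-data generators with ground truth for every pipeline input.

Everything the analysis stack consumes can be generated here with known
truth: readout-plate images with planted colony amplitudes and radii,
whole screens with planted cooperative/antagonistic events, promoter
sequences with planted motif occurrences, cluster-level expression
matrices with planted specificity patterns, SAM alignment records with
planted well identities, and bipartite networks with planted evidence
enrichment. All generators are deterministic given their seed.

Plate model
-----------
Colonies are rendered as flat-top disks with a 1-pixel anti-aliased rim on
an equidistant 32 x 48 grid (one strain per 2 x 2 quadruplicate block, 384
strain positions). The true colony area is the count of pixels whose
center falls inside the disk, which the anti-aliasing leaves well defined.
The background is a low-order intensity gradient (default 5% of the
maximum colony amplitude) plus i.i.d. Gaussian pixel noise (default sd 2%
of the maximum amplitude). Larger pixel value means stronger reporter
signal; conversion from camera color to signal lives in
:mod:`py1h.plates`.

Screen semantics
----------------
Planted events follow the assay logic. In the 2-AD design each bait x
TF-pair series has a TF-pair strain and two single-TF strains whose
colony amplitudes encode the event: obligate cooperative (pair bright,
singles at the unstained baseline), enhanced cooperative (pair bright,
singles weak), TF1-/TF2-antagonized (that single bright, pair at
baseline), independent (everything bright), none (everything baseline).
The 1-AD design plants the activity pattern of a binding modality across
the two reciprocal AD orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import MODALITY_TABLE, Modality
from .motifs import BASES, PWM

__all__ = [
    "PlateTruth",
    "ScreenTruth",
    "plate_truth_from_strains",
    "gen_plate",
    "gen_screen",
    "gen_motif_set",
    "gen_expression",
    "gen_alignments",
    "gen_network",
    "EVENT_TYPES",
]

GRID_ROWS = 32
GRID_COLS = 48
N_BLOCKS = (GRID_ROWS // 2) * (GRID_COLS // 2)

#: Unstained colony amplitude (yeast grows but the reporter is off).
AMP_BASELINE = 0.12
#: Weak reporter activity (enhanced-cooperative singles). Calibrated to sit
#: ~3 robust-z above the unstained baseline under the default noise model
#: (per-colony empty RS spread ~0.4 signal*pixel after cell-local
#: background subtraction, dominated by the 3% colony-amplitude jitter).
AMP_WEAK = 0.131
#: Strong reporter activity.
AMP_STRONG = 0.85

#: Planted event vocabulary of the screen generator (2-AD design).
EVENT_TYPES = (
    "obligate-cooperative",
    "enhanced-cooperative",
    "TF1-antagonized",
    "TF2-antagonized",
    "independent",
    "none",
)

#: Expected interaction call per planted event type.
EXPECTED_CALL = {
    "obligate-cooperative": "cooperative",
    "enhanced-cooperative": "cooperative",
    "TF1-antagonized": "antagonistic_TF1",
    "TF2-antagonized": "antagonistic_TF2",
    "independent": "independent",
    "none": "none",
}


@dataclass
class PlateTruth:
    """Planted ground truth of one readout plate.

    ``layout`` has one row per grid position (1536 rows): ``row``, ``col``,
    ``strain``, ``strain_class`` and optionally ``pair_id``/``bait``.
    Amplitude, radius and presence are per grid position.
    """

    layout: pd.DataFrame
    amplitude: np.ndarray
    radius: np.ndarray
    present: np.ndarray
    bg_gradient: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        shape = (GRID_ROWS, GRID_COLS)
        for name in ("amplitude", "radius", "present"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if (self.amplitude < 0).any():
            raise ValueError("amplitudes must be >= 0")
        if (self.radius[self.present] <= 0).any():
            raise ValueError("present colonies need radius > 0")
        if len(self.layout) != GRID_ROWS * GRID_COLS:
            raise ValueError("layout must cover all 1536 grid positions")


def plate_truth_from_strains(
    strains: list[tuple],
    radius: float = 6.0,
    bg_gradient: float = 0.05,
    noise_sd: float = 0.02,
    amplitude_jitter: float = 0.03,
    seed: int = 0,
    extra_columns: dict | None = None,
    spread: bool = True,
) -> PlateTruth:
    """Lay out strains on quadruplicate blocks and build a PlateTruth.

    ``strains`` holds up to 384 tuples ``(strain_id, strain_class,
    amplitude)``; remaining blocks stay empty (absent colonies). With
    ``spread=True`` (default) occupied blocks are distributed evenly over
    the plate, as array pinning does; ``spread=False`` packs them
    row-major. Per-colony amplitudes get multiplicative Gaussian jitter of
    sd ``amplitude_jitter`` (biological colony-to-colony variation).
    ``extra_columns`` maps column name -> dict strain_id -> value, joined
    onto the layout (e.g. pair_id).
    """
    if len(strains) > N_BLOCKS:
        raise ValueError(f"at most {N_BLOCKS} strains fit on a plate")
    rng = np.random.default_rng(seed)
    amplitude = np.zeros((GRID_ROWS, GRID_COLS))
    rad = np.zeros((GRID_ROWS, GRID_COLS))
    present = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
    rows = []
    block_cols = GRID_COLS // 2
    if spread and strains:
        block_ids = np.round(np.linspace(0, N_BLOCKS - 1, len(strains))).astype(int)
    else:
        block_ids = np.arange(len(strains))
    strain_of_block = {int(b): strains[i] for i, b in enumerate(block_ids)}
    for b, (strain, cls, amp) in strain_of_block.items():
        br, bc = divmod(b, block_cols)
        for dr in (0, 1):
            for dc in (0, 1):
                r, c = 2 * br + dr, 2 * bc + dc
                jitter = 1.0 + amplitude_jitter * rng.standard_normal()
                amplitude[r, c] = max(0.0, amp * jitter)
                rad[r, c] = radius
                present[r, c] = True
    for r in range(GRID_ROWS):
        for c in range(GRID_COLS):
            b = (r // 2) * block_cols + (c // 2)
            if b in strain_of_block:
                strain, cls, _ = strain_of_block[b]
            else:
                strain, cls = "", "absent"
            rows.append((r, c, strain, cls))
    layout = pd.DataFrame(rows, columns=["row", "col", "strain", "strain_class"])
    if extra_columns:
        for col, mapping in extra_columns.items():
            layout[col] = layout["strain"].map(mapping).fillna("")
    return PlateTruth(
        layout=layout,
        amplitude=amplitude,
        radius=rad,
        present=present,
        bg_gradient=bg_gradient,
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_plate(
    truth: PlateTruth,
    spacing: int = 20,
    margin: int = 20,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a plate image and its per-position ground-truth table.

    Colonies are flat-top disks (amplitude plateau) whose rim pixel values
    fall off linearly over one pixel of coverage; the true area counts the
    pixels with >= half coverage. Identical seeds give byte-identical
    images. Raises ``ValueError("layout_overflow")`` when a colony cannot
    fit its grid cell.
    """
    max_r = float(truth.radius[truth.present].max()) if truth.present.any() else 0.0
    if 2 * max_r + 1 > spacing:
        raise ValueError("layout_overflow: colony radius exceeds grid cell")
    rng = np.random.default_rng(truth.seed)
    h = 2 * margin + GRID_ROWS * spacing
    w = 2 * margin + GRID_COLS * spacing
    amp_max = float(truth.amplitude.max())
    scale = amp_max if amp_max > 0 else 1.0
    yy = np.linspace(0.0, 1.0, h)[:, None]
    xx = np.linspace(0.0, 1.0, w)[None, :]
    image = truth.bg_gradient * scale * (0.5 * yy + 0.5 * xx) * np.ones((h, w))
    if truth.noise_sd > 0:
        image = image + truth.noise_sd * scale * rng.standard_normal((h, w))

    rows = []
    for r in range(GRID_ROWS):
        for c in range(GRID_COLS):
            cy = margin + (r + 0.5) * spacing
            cx = margin + (c + 0.5) * spacing
            area = 0
            if truth.present[r, c]:
                rad = float(truth.radius[r, c])
                amp = float(truth.amplitude[r, c])
                lo_y, hi_y = int(cy - rad - 2), int(cy + rad + 3)
                lo_x, hi_x = int(cx - rad - 2), int(cx + rad + 3)
                wy = np.arange(lo_y, hi_y)[:, None] - cy
                wx = np.arange(lo_x, hi_x)[None, :] - cx
                dist = np.hypot(wy, wx)
                coverage = np.clip(rad + 0.5 - dist, 0.0, 1.0)
                image[lo_y:hi_y, lo_x:hi_x] += amp * coverage
                area = int((dist <= rad).sum())
            rows.append((r, c, cy, cx, area, float(truth.amplitude[r, c]), bool(truth.present[r, c])))
    image = np.clip(image, 0.0, None)
    table = pd.DataFrame(
        rows,
        columns=["row", "col", "center_y", "center_x", "true_area", "amplitude", "present"],
    )
    table = truth.layout.merge(table, on=["row", "col"])
    return image, table


@dataclass
class ScreenTruth:
    """Planted events of a synthetic screen.

    ``events`` maps (bait, pair_id) to a planted event type (2-AD
    vocabulary above) or to a 1-AD binding modality name.
    """

    baits: list[str]
    pairs: list[str]
    events: dict[tuple[str, str], str]
    design: str = "2AD"

    def __post_init__(self) -> None:
        for key in ((b, p) for b in self.baits for p in self.pairs):
            if key not in self.events:
                raise ValueError(f"missing planted event for {key}")


def _amp_2ad(event: str) -> tuple[float, float, float]:
    """(pair, tf1-single, tf2-single) amplitudes of a planted 2-AD event."""
    table = {
        "obligate-cooperative": (AMP_STRONG, AMP_BASELINE, AMP_BASELINE),
        "enhanced-cooperative": (AMP_STRONG, AMP_WEAK, AMP_WEAK),
        "TF1-antagonized": (AMP_BASELINE, AMP_STRONG, AMP_BASELINE),
        "TF2-antagonized": (AMP_BASELINE, AMP_BASELINE, AMP_STRONG),
        "independent": (AMP_STRONG, AMP_STRONG, AMP_STRONG),
        "none": (AMP_BASELINE, AMP_BASELINE, AMP_BASELINE),
    }
    if event not in table:
        raise ValueError(f"unknown event type {event!r}")
    return table[event]


_PATTERN_OF_MODALITY = {}
for _pattern, _mod in MODALITY_TABLE.items():
    _PATTERN_OF_MODALITY.setdefault(_mod.value, _pattern)


def gen_screen(
    truth: ScreenTruth,
    seed: int = 0,
    n_empty: int = 24,
    **plate_kwargs,
) -> tuple[dict[str, PlateTruth], pd.DataFrame]:
    """Build one PlateTruth per bait plus the expected-call table.

    2-AD plates carry three strains per pair (classes ``pair``,
    ``tf1_single``, ``tf2_single``); 1-AD plates carry six (the two
    reciprocal AD orientations, classes suffixed ``_o1``/``_o2``, where
    ``tf1_single_oK`` is orientation K's AD-tagged single). ``n_empty``
    empty-empty control strains are interleaved evenly. Expected calls are
    emitted per (bait, pair).
    """
    plates: dict[str, PlateTruth] = {}
    expected_rows = []
    ss = np.random.SeedSequence(seed)
    plate_seeds = ss.generate_state(len(truth.baits))
    for bait, plate_seed in zip(truth.baits, plate_seeds):
        strains: list[tuple] = []
        pair_of: dict[str, str] = {}
        for pair in truth.pairs:
            event = truth.events[(bait, pair)]
            if truth.design == "2AD":
                amps = _amp_2ad(event)
                for cls, amp in zip(("pair", "tf1_single", "tf2_single"), amps):
                    name = f"{pair}|{cls}"
                    strains.append((name, cls, amp))
                    pair_of[name] = pair
                expected_rows.append((bait, pair, EXPECTED_CALL[event]))
            else:
                pattern = _PATTERN_OF_MODALITY.get(event)
                if pattern is None:
                    raise ValueError(f"unknown 1-AD modality {event!r}")
                tf1ad_alone, tf1ad_pair, tf2ad_alone, tf2ad_pair = (
                    AMP_STRONG if x else AMP_BASELINE for x in pattern
                )
                for cls, amp in (
                    ("pair_o1", tf1ad_pair),
                    ("tf1_single_o1", tf1ad_alone),
                    ("tf2_single_o1", AMP_BASELINE),  # non-AD single: never active
                    ("pair_o2", tf2ad_pair),
                    ("tf1_single_o2", tf2ad_alone),
                    ("tf2_single_o2", AMP_BASELINE),
                ):
                    name = f"{pair}|{cls}"
                    strains.append((name, cls, amp))
                    pair_of[name] = pair
                expected_rows.append((bait, pair, event))
        # interleave empty-empty controls evenly across the layout
        n_total = len(strains) + n_empty
        if n_total > N_BLOCKS:
            raise ValueError(f"screen needs {n_total} blocks; a plate has {N_BLOCKS}")
        step = max(1, n_total // n_empty) if n_empty else n_total + 1
        for i in range(n_empty):
            name = f"empty_{i:02d}"
            strains.insert(min(i * step, len(strains)), (name, "empty", AMP_BASELINE))
            pair_of[name] = ""
        plate = plate_truth_from_strains(
            strains,
            seed=int(plate_seed),
            extra_columns={"pair_id": pair_of, "bait": {s: bait for s, _, _ in strains}},
            **plate_kwargs,
        )
        plates[bait] = plate
    expected = pd.DataFrame(expected_rows, columns=["bait", "pair_id", "event"])
    return plates, expected


def gen_motif_set(
    n_pwms: int,
    promoter_lengths: dict[str, int],
    planted_sites: list[tuple],
    seed: int = 0,
    k_range: tuple[int, int] = (8, 12),
    cobind_gap: int = 10,
) -> tuple[dict[str, str], list[PWM], pd.DataFrame, pd.DataFrame]:
    """Generate promoters, information-rich PWMs and planted consensus sites.

    ``planted_sites`` holds tuples ``(tf_index, promoter, start, strand)``;
    the PWM's consensus (reverse complement on '-') replaces the promoter
    sequence at ``start``. Returns (promoters, pwms, site truth,
    co-binding truth); coordinates are 0-based half-open. Sites exceeding
    the promoter bounds raise.
    """
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    for i in range(n_pwms):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        mat = np.empty((k, 4))
        for pos in range(k):
            dom = int(rng.integers(4))
            p_dom = float(rng.uniform(0.85, 0.95))
            rest = rng.dirichlet(np.ones(3)) * (1 - p_dom)
            mat[pos] = np.insert(rest, dom, p_dom)
        pwms.append(PWM(name=f"TF{i:02d}", matrix=mat))

    promoters = {
        name: "".join(rng.choice(list(BASES), size=length))
        for name, length in promoter_lengths.items()
    }

    comp = str.maketrans("ACGT", "TGCA")
    truth_rows = []
    for tf_idx, prom, start, strand in planted_sites:
        pwm = pwms[tf_idx]
        if prom not in promoters:
            raise ValueError(f"unknown promoter {prom!r}")
        seq = promoters[prom]
        end = start + pwm.k
        if start < 0 or end > len(seq):
            raise ValueError(f"planted site {start}:{end} exceeds promoter {prom} bounds")
        site = pwm.consensus if strand == "+" else pwm.consensus.translate(comp)[::-1]
        promoters[prom] = seq[:start] + site + seq[end:]
        truth_rows.append((pwm.name, prom, start, end, strand))
    truth = pd.DataFrame(truth_rows, columns=["tf", "promoter", "start", "end", "strand"])

    cobind_rows = []
    for prom, grp in truth.groupby("promoter", sort=False):
        recs = grp.to_dict("records")
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                if a["tf"] == b["tf"]:
                    continue
                gap = max(0, max(a["start"], b["start"]) - min(a["end"], b["end"]))
                if gap <= cobind_gap:
                    cobind_rows.append((a["tf"], b["tf"], prom, gap))
    cobinding = pd.DataFrame(cobind_rows, columns=["tf_a", "tf_b", "promoter", "gap"])
    return promoters, pwms, truth, cobinding


def gen_expression(
    n_genes: int,
    n_clusters: int,
    specificity_patterns: list[str] | None = None,
    seed: int = 0,
    base_level: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster-level expression matrix with planted specificity patterns.

    Patterns per gene: ``uniform`` (identical totals in every cluster),
    ``exclusive`` (all expression in one random cluster), ``broad``
    (uniform over a random subset of clusters). Returns the raw cluster
    sums (no pseudocount; cpm-scale) and the pattern labels.
    """
    if n_genes < 1 or n_clusters < 2:
        raise ValueError("need n_genes >= 1 and n_clusters >= 2")
    rng = np.random.default_rng(seed)
    if specificity_patterns is None:
        specificity_patterns = [
            ["uniform", "exclusive", "broad"][i % 3] for i in range(n_genes)
        ]
    if len(specificity_patterns) != n_genes:
        raise ValueError("need one pattern per gene")
    mat = np.zeros((n_genes, n_clusters))
    for g, pattern in enumerate(specificity_patterns):
        if pattern == "uniform":
            mat[g] = base_level
        elif pattern == "exclusive":
            mat[g, rng.integers(n_clusters)] = base_level * n_clusters
        elif pattern == "broad":
            k = int(rng.integers(2, max(3, n_clusters // 3)))
            idx = rng.choice(n_clusters, size=k, replace=False)
            mat[g, idx] = base_level * n_clusters / k
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    clusters = [f"cluster{c:03d}" for c in range(n_clusters)]
    return (
        pd.DataFrame(mat, index=genes, columns=clusters),
        pd.Series(specificity_patterns, index=genes, name="pattern"),
    )


def gen_alignments(
    expected: dict[str, object],
    confirmed: dict[str, bool],
    n_reads: int = 100,
    read_length: int = 150,
    seed: int = 0,
    decoys: list[str] | None = None,
) -> tuple[str, pd.DataFrame]:
    """SAM text with planted per-well read identities, plus the truth table.

    ``expected`` maps well -> expected target (or tuple of targets);
    ``confirmed`` wells place ~95% of their filter-surviving reads on the
    expected target(s), unconfirmed wells concentrate reads on a decoy. A
    fraction of reads deliberately fails the score/mismatch/primary
    filters to exercise filtering.
    """
    rng = np.random.default_rng(seed)
    refs: set[str] = set(decoys or [])
    for t in expected.values():
        refs.update((t,) if isinstance(t, str) else tuple(t))
    if not decoys:
        decoys = [f"decoy{i}" for i in range(3)]
        refs.update(decoys)
    refs = sorted(refs)

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for ref in refs:
        lines.append(f"@SQ\tSN:{ref}\tLN:2000")
    truth_rows = []
    for well in sorted(expected):
        targets = expected[well]
        targets = (targets,) if isinstance(targets, str) else tuple(targets)
        is_conf = bool(confirmed.get(well, True))
        decoy = str(rng.choice(decoys))
        for i in range(n_reads):
            if is_conf:
                on = rng.random() < 0.95
            else:
                on = rng.random() < 0.25
            target = str(rng.choice(targets)) if on else decoy
            # ~10% of reads fail a filter (low score, many mismatches, or secondary)
            fail_mode = rng.integers(10)
            flag = 0
            if fail_mode == 0:
                score = int(0.9 * read_length) - int(rng.integers(1, 20))
                nm = int(rng.integers(0, 3))
            elif fail_mode == 1:
                score = read_length
                nm = int(0.05 * read_length) + int(rng.integers(0, 5))
            elif fail_mode == 2:
                flag = 256
                score = read_length
                nm = 0
            else:
                score = read_length - int(rng.integers(0, int(0.1 * read_length)))
                nm = int(rng.integers(0, max(1, int(0.05 * read_length))))
            lines.append(
                "\t".join(
                    [
                        f"{well}:r{i}",
                        str(flag),
                        target,
                        "1",
                        "60",
                        f"{read_length}M",
                        "*",
                        "0",
                        "0",
                        "A" * read_length,
                        "*",
                        f"AS:i:{score}",
                        f"NM:i:{nm}",
                    ]
                )
            )
        truth_rows.append((well, ";".join(targets), is_conf))
    truth = pd.DataFrame(truth_rows, columns=["well", "expected", "confirmed"])
    return "\n".join(lines) + "\n", truth


def gen_network(
    n_pairs: int,
    n_baits: int,
    enrichment: float,
    seed: int = 0,
    edges_per_pair: int = 3,
    base_rate: float = 0.15,
    promoter_length: int = 2000,
    cell_lines: tuple[str, ...] = ("HepG2", "K562", "GM12878"),
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Bipartite pY1H network plus ChIP-like evidence with planted enrichment.

    Every TF-pair connects to ``edges_per_pair`` random promoters. Each
    (TF, promoter) combination receives a peak with probability
    ``base_rate``, boosted by ``enrichment`` when the TF's pair has an edge
    to that promoter; ``enrichment=0`` makes evidence independent of the
    network (a null fixture). Returns (edge list, evidence records,
    enriched flag).
    """
    if n_pairs < 1 or n_baits < 1:
        raise ValueError("need n_pairs >= 1 and n_baits >= 1")
    rng = np.random.default_rng(seed)
    promoters = [f"prom{i:02d}" for i in range(n_baits)]
    edge_rows = []
    edge_set = set()
    for i in range(n_pairs):
        pair = f"pair{i:03d}"
        tf1, tf2 = f"TF{2 * i:03d}", f"TF{2 * i + 1:03d}"
        chosen = rng.choice(n_baits, size=min(edges_per_pair, n_baits), replace=False)
        for j in chosen:
            edge_rows.append((pair, tf1, tf2, promoters[j]))
            edge_set.add((tf1, promoters[j]))
            edge_set.add((tf2, promoters[j]))
    edges = pd.DataFrame(edge_rows, columns=["pair_id", "tf1", "tf2", "promoter"])

    ev_rows = []
    tfs = sorted(set(edges["tf1"]) | set(edges["tf2"]))
    for tf in tfs:
        for prom in promoters:
            p = base_rate + (enrichment * (1 - base_rate) if (tf, prom) in edge_set else 0.0)
            if rng.random() < p:
                cell = str(rng.choice(cell_lines))
                summit = int(rng.integers(0, promoter_length))
                ev_rows.append((tf, prom, cell, summit))
    evidence = pd.DataFrame(ev_rows, columns=["tf", "promoter", "cell_line", "summit"])
    return edges, evidence, enrichment > 0
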