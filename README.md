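# py1h

Analysis stack for **paired yeast one-hybrid (pY1H)** screens: colony-array
image quantification, cooperativity/antagonism event calling, and the
downstream statistics used to interpret TF-pair regulatory networks.

## The problem

Transcription factors (TFs) rarely act alone. A TF-pair can bind a promoter
cooperatively (only the pair activates the reporter), or one TF can
antagonize the other (a single-TF signal disappears in the pair strain).
pY1H assays read this out on 1536-colony agar arrays: a DNA-bait yeast
strain (promoter upstream of *HIS3* and *lacZ*) is mated against TF-pair
prey strains and their single-TF controls, spotted as 2×2 quadruplicates.
Colony size and blue (β-galactosidase) intensity are the reporter signal.

This package implements the computational side of such screens, for groups
running or reanalyzing colony-array reporter assays:

- **`py1h.plates`** — plate-image quantification: crop, 32×48 grid
  detection from projection peaks, per-cell segmentation, per-colony area
  `A` and background-removed mean intensity `I`.
- **`py1h.scoring`** — reporter signal per strain on a plate:
  `RS = med[(I − I_min)·A] − AVG[(I − I_min)·A]_empty-empty`,
  and the interaction indices
  `coop = RS_pair − RS_TF1 − RS_TF2`, `ant_i = RS_TFi − RS_pair`.
- **`py1h.calls`** — QC (mating growth, ≥3/4 uniform colonies) and
  rule-based event calling from activity levels quantized by robust z
  against the empty-empty controls; binding-modality classification for
  the 1-AD and 2-AD assay designs (mutual cooperativity, recruitment,
  sequestration, competition).
- **`py1h.motifs`** — PWM scanning with per-window log₂-odds scores,
  *exact* p-values by dynamic programming over the discretized score
  distribution, low-specificity PWM filtering, merging of overlapping hits
  into non-overlapping "core motifs", and TF-pair co-binding detection
  (cores within 10 nt).
- **`py1h.networks`** — degree-preserving edge-switch randomization of the
  bipartite TF-pair → promoter network, overlap counting against ChIP/motif
  evidence (any cell line / same cell line / summits within 50 bp), Z and
  two-tailed p against the randomized null, and the two-proportion test
  with `SE = √(p(1−p)/n)`.
- **`py1h.expression`** — tissue/cell-type expression specificity score
  (TCESS): `Σ_c f_c·log₂(C·f_c)` over cluster expression fractions, i.e.
  `log₂C − H(f)` in bits (0 = ubiquitous, `log₂C ≈ 7.54` for 187 clusters
  = fully specific), and Simpson co-expression `|A∩B|/min(|A|,|B|)` over
  expressed-cluster sets (>10% of the gene's max cpm).
- **`py1h.paralogs`** — global-alignment percent identity (BLOSUM62),
  homology-based expansion of known TF-pairs, and Jaccard similarity of
  paralog partner-relationship profiles.
- **`py1h.swimseq`** — sequencing-based strain confirmation: alignment
  filters (primary, score ≥ 90% of read length, < 5% mismatches) and
  well/series confirmation decisions.
- **`py1h.fixtures`** — seeded generators for every input above, with
  ground truth: rendered plates with planted colony amplitudes, screens
  with planted events, promoters with planted motif sites, expression
  matrices with planted specificity, SAM records with planted well
  identities, networks with planted evidence enrichment.

## Worked example

Simulate a one-bait 2-AD mini-screen with four planted events, render the
plate image, and run the full pipeline (quantify → score → call):

```python
from py1h import fixtures, pipeline

pairs = ["RELA-JUN", "REL-RELB", "FOS-JUNB", "MAX-MXI1"]
events = {
    ("IL6", "RELA-JUN"): "obligate-cooperative",
    ("IL6", "REL-RELB"): "TF1-antagonized",
    ("IL6", "FOS-JUNB"): "independent",
    ("IL6", "MAX-MXI1"): "none",
}
truth = fixtures.ScreenTruth(baits=["IL6"], pairs=pairs, events=events, design="2AD")
plates, expected = fixtures.gen_screen(truth, seed=7)
plate = plates["IL6"]
image, _ = fixtures.gen_plate(plate)          # 680 x 1000 px plate photo
scores, calls = pipeline.analyze_plate(image, plate.layout)
print(calls[["bait", "pair_id", "event", "modality",
             "pair_level", "tf1_level", "tf2_level"]].to_string(index=False))
```

prints

```
bait  pair_id            event             modality pair_level tf1_level tf2_level
 IL6 RELA-JUN      cooperative mutual_cooperativity     strong very_weak very_weak
 IL6 REL-RELB antagonistic_TF1        sequestration  very_weak    strong      weak
 IL6 FOS-JUNB      independent    indistinguishable     strong    strong    strong
 IL6 MAX-MXI1             none    indistinguishable  very_weak very_weak very_weak
```

Reading the output: RELA–JUN activates the reporter only as a pair while
both singles stay at the empty-empty baseline — cooperative binding, which
in the 2-AD design means mutual cooperativity. In REL–RELB the first TF
binds alone but the pair loses the signal — RELB antagonizes (sequesters)
REL. FOS–JUNB binds with or without its partner (independent), and
MAX–MXI1 shows no reporter activity at all. All four match the planted
truth.

The same steps are available from a shell:

```sh
py1h simulate screen --seed 7 --n-pairs 100 --out screen/
py1h plates --image screen/bait0.png --layout screen/bait0.layout.tsv --out meas.tsv
py1h score  --measurements meas.tsv --out scores.tsv
py1h call   --scores scores.tsv --design 2AD --out calls.tsv
```

plus `py1h motifs scan|merge|cobind`, `py1h randomize`,
`py1h expression tcess|coexpr`, `py1h paralogs identity|expand|jaccard`,
and `py1h swim` for the downstream statistics.

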