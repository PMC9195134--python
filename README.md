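# strepdelim

Threshold calibration and species delineation for the genus *Streptomyces*
from three pairwise genome-relatedness metrics:

* **MLSA distance** — Kimura two-parameter (K2P) evolutionary distance over
  the five concatenated housekeeping genes *atpD, gyrB, recA, rpoB, trpB*
  (substitutions/site), computed here from pre-aligned, in-frame gene
  alignments;
* **ANIm** — average nucleotide identity from MUMmer whole-genome
  alignments (%), consumed as an input number;
* **dDDH** — digital DNA–DNA hybridization from the Genome-to-Genome
  Distance Calculator, formula 2 (%), consumed as an input number.

The package ships a curated table of 80 type-strain pairs (all with
ANIm ≥ 90%), links the metrics pairwise through exponential regressions
`y = a·e^{b·x}` fitted by nonlinear least squares, and uses the fitted
curves to translate the classical 70% dDDH species boundary onto the other
two scales. For the K2P distance between concatenated sequences,

```
d = -1/2 · ln[(1 - 2P - Q) · √(1 - 2Q)]
```

with `P` and `Q` the transition (A↔G, C↔T) and transversion proportions
among compared sites (pairwise deletion of gaps and ambiguities).

On the curated table the 70% dDDH boundary corresponds to ≈ 96.6–96.7%
ANIm — not the often-quoted 95–96% — and to an MLSA distance of ≈ 0.008.
Because strain pairs with MLSA ≥ 0.008 can still be conspecific by genome
metrics, a single MLSA cut-off is not safe, and the package implements a
three-tier decision rule instead:

| evidence | verdict |
|---|---|
| MLSA < 0.008 | conspecific (heterotypic synonym) |
| MLSA ≥ 0.014 | distinct species |
| 0.008 ≤ MLSA < 0.014 | genome metrics required |
| dDDH ≥ 70% **or** ANIm ≥ 96.7% | conspecific |
| just below a cut-off (band) | borderline — polyphasic evidence required |
| clearly below both cut-offs | distinct species |

Intended users: microbial taxonomists delineating *Streptomyces* species
when only housekeeping-gene sequences (or only genome metrics) are in hand.

## Worked example

```
$ strepdelim fit --x anim --y ddh --invert-at 70
{
  "a": 0.002823612358638177,
  "b": 0.10478028657510889,
  "r2": 0.997900388536142,
  "n": 80,
  ...
  "invert_at": { "y": 70.0, "x": 96.56619396951783 }
}
```

dDDH is almost perfectly predicted by ANIm (R² = 0.99790 over the 80
pairs), and the fitted curve reaches 70% dDDH at 96.57% ANIm: a pair at
"only" 96% ANIm is already below the classical dDDH species boundary.

```
$ strepdelim classify --mlsa 0.010 --ddh 72.0 --anim 96.90
(unnamed pair): CONSPECIFIC_GENOME
    conspecific by genome metrics (either-metric sufficiency): dDDH 72.0 >= 70.0%; ANIm 96.9 >= 96.7%
```

Genome metrics override the indeterminate MLSA tier: despite an MLSA
distance of 0.010 the pair is conspecific.

The numbered scripts under `analysis/` run the whole study in order —
`01_table_overview.py` (filter enumerations: 7 / 4 / 9 pairs),
`02_fit_regressions.py` (the three fits and threshold translations),
`03_classify_pairs.py` (verdicts: 31 conspecific, 44 distinct, 5
borderline), `04_simulation_validation.py` (estimator validation on
synthetic ground truth) — and write their tables under `results/`.

`strepdelim mlsa-dist --genes atpD=...,gyrB=...,recA=...,rpoB=...,trpB=...`
computes the K2P distance matrix from five aligned FASTA files, and
`strepdelim simulate` generates synthetic sequence pairs or metric tables
with known ground truth.

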