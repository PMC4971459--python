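# e3screen

An in-silico screen for candidate ERAD ubiquitin ligases, built as a
tested, reusable pipeline with a fully synthetic, planted-ground-truth
test surface.

## The problem

Endoplasmic-reticulum-associated degradation (ERAD) retrotranslocates
unfolded ER proteins to the cytosol for ubiquitin–proteasome destruction.
The E3 ubiquitin ligases that drive ERAD share two structural features:
a canonical RING-finger domain and one or more transmembrane spans.
`e3screen` implements a genome-wide candidate screen on those two
criteria, plus the downstream computational analyses used to prioritise
candidates:

1. **RING-finger detection** — a variable-gap motif matcher for the
   canonical pattern

   ```
   C-X2-C-X9-39-C-X1-3-H-X2-3-C/H-X2-C-X9-39-C-X2-C
   ```

   Eight Zn²⁺-coordinating residues with bounded spacers; the fifth
   coordination slot decides the subtype (His → C3H2C3, two His total;
   Cys → C3HC4, one His). The matcher enumerates *every* distinct
   coordination-residue assignment, verified against a brute-force
   oracle in the test suite.

2. **Transmembrane filtering** — per-protein helix counts either parsed
   from TMHMM v2 long-format reports or predicted with a built-in
   Kyte–Doolittle sliding-window scheme (window 19, threshold 1.6,
   minimum length 15). Signal peptides count as spans.

3. **ER-stress element scanning** — degenerate-consensus search of
   TSS-relative 5′ upstream DNA (default 5 kb) for ERSE-I
   (`CCAAT-N9-CCACG/A`), ERSE-II (`ATTGG-N-CCACG`) and UPRE
   (`TGACGTGG/A`) on both strands; reverse-orientation hits are labelled
   `-r` (e.g. `UPRE-r`). Coordinates use TSS = +1, last upstream
   base = −1, no position 0.

4. **Expression analysis** — comparative-Ct qPCR quantification
   (fold = 2^−ΔΔCt), the tau tissue-specificity index, ER-stress
   responsiveness calls (one-way ANOVA per stressor with
   Bonferroni-adjusted comparisons against control, requiring induction
   under both thapsigargin and tunicamycin), and crystal-violet
   viability ratios.

Because no sequence accessions accompany the screen's published gene
lists, the package ships a **synthetic-data module** that plants RING
motifs, membrane spans, promoter elements and fold-change effects with
known ground truth; every generator verifies its own plants with the
same pipeline modules that are later screened.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
default planted fixture (one synthetic protein per gene row of the
screen's two tables plus 200 motif-free decoys; one 5-kb upstream region
per gene with elements planted in 8 of them):

```
$ python analysis/01_build_fixture.py
$ python analysis/02_screen_candidates.py
screened 237 proteins -> 37 candidates
  subtype split: 19 C3H2C3 / 18 C3HC4
  membrane spans: 1 to 12
  decoys passing: 0

$ python analysis/03_scan_promoters.py
scanned 37 upstream regions -> 8 genes with elements
  RNF130 (UPRE, -315)
  RNF149 (ERSE-I, -2586)
  SYVN1 (UPRE, -2303; ERSE-I, -506)
  ...
  RNF19A (UPRE-r, -428)

$ python analysis/04_expression_profiles.py
ER-stress responsiveness (both Tg and Tm required):
  BiP: RESPONSIVE [Tg peak 21.3x @ 6h (p_adj 4.2e-10); ...]
  RNFT1: RESPONSIVE [Tg peak 2.0x @ 6h (p_adj 3.8e-05); ...]
  RNF13: not responsive ...
tissue panel: RNF183 tau = 0.978 -> specific (highest: kidney, 48.5x ...)
```

The screen recovers exactly the 37 planted candidate genes (19 two-His,
18 one-His; membrane spans 1–12), none of the 200 decoys pass, the
promoter scan finds elements in exactly the 8 planted genes at the
planted positions and orientations, and the responsiveness caller flags
exactly the genes with induction planted under both stressors.

A `click` CLI exposes the same stages
(`e3screen motifs|tm|promoters|run|expression|synth`); run
`e3screen --help` for options. Library use:

```python
from e3screen import compile_pattern, find_ring_motifs, ProteinRecord

pattern = compile_pattern("C-X2-C-X9-39-C-X1-3-H-X2-3-C/H-X2-C-X9-39-C-X2-C")
matches = find_ring_motifs(ProteinRecord("MYGENE", "", sequence), pattern)
```

Real proteomes (FASTA, optionally with precomputed TMHMM output) and real
genomes (FASTA + TSS table) are supported through the same interfaces.

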