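# Methods

This note documents the models, conventions and parameter choices behind
`e3screen`, what the synthetic study does and does not demonstrate, and
the numerical edge cases the implementation pins down.

## RING-finger matching

The matcher compiles dash-notation motif specifications into an ordered
list of residue *slots* (sets of allowed one-letter codes) separated by
bounded *spacers*. The shipped pattern is the canonical RING consensus

```
C-X2-C-X9-39-C-X1-3-H-X2-3-C/H-X2-C-X9-39-C-X2-C
```

eight Zn²⁺-coordination slots `{C},{C},{C},{H},{C/H},{C},{C},{C}` with
spacer bounds (2,2), (9,39), (1,3), (2,3), (2,2), (9,39), (2,2). Matching
is a depth-first search over candidate coordination positions that
enumerates **every** distinct coordination 8-tuple satisfying all
constraints, in lexicographic order. Subtype is assigned per match from
coordination slot 5: His → C3H2C3 (two His), Cys → C3HC4 (one His). The
slot-5 alternative is encoded as a residue set rather than two separate
patterns, so one pass classifies both subtypes.

Conventions, chosen once and tested:

* **Overlap policy.** All distinct coordination assignments are
  enumerated; the screen criterion is "≥ 1 match per protein" and tables
  show the canonical match (lexicographically smallest position tuple:
  leftmost, then shortest spacers). Whether published gene counts
  collapsed multiple motifs per protein is unknowable from counts alone;
  enumerating everything loses no information.
* **Ambiguity codes.** `X`, `B`, `Z`, `U` are legal sequence characters
  that may fill spacers but never satisfy a C/H slot — conservative,
  equivalent to a literal regex over database strings. `*` terminates
  the scan at its position. Sequences are uppercased on ingest.
* A protein matching both subtypes through distinct assignments takes
  the canonical match's subtype and a `both-subtypes` flag in the notes
  column, keeping one deterministic row per gene.

Non-goals: the RINGv/C4HC3 (MARCH-family) and RING-C2 variants are
outside the shipped pattern by design, as is profile-based (PROSITE/
Pfam/HMM) matching.

## Transmembrane spans

Primary input is TMHMM v2 long-format text (`# <id> ... Number of
predicted TMHs: n` headers plus `TMhelix` body lines, 1-based
inclusive); the parser validates the declared count against the helix
lines and converts to 0-based half-open intervals. A writer provides the
exact inverse (round-trip identity is tested). When both parsed output
and raw FASTA are available, parsed output wins.

The built-in predictor is a classical Kyte–Doolittle sliding-window
scheme used for desk-scale fixtures: centred window mean over hydropathy
scores (window 19, threshold 1.6), maximal marked runs extended to
window extent, runs closer than 5 residues merged, intervals ≥ 15
residues kept. Signal peptides are *not* excluded — an N-terminal
hydrophobic stretch counts, matching the screen convention that counts
HRD1/SYVN1's signal peptide among its six spans. The fixture generator
closes the loop by construction (it redraws until the predictor recovers
the planted count), so **no agreement with the TMHMM HMM on real
proteins is claimed**; for real data, supply TMHMM output.

Numerical behaviour worth knowing: raising the threshold shrinks the
*marked-position set* monotonically, and every helix predicted at a
higher threshold is nested inside a helix from a lower threshold — but
the helix *count* is not globally monotone in the threshold, because a
long marked run can split into two keepable fragments. Count
monotonicity does hold in the separated-hydrophobic-block regime the
fixtures use; both facts are property-tested.

## Upstream element scanning

Regions are stored 5′→3′ on the gene's sense strand with the TSS
convention TSS = +1, final upstream base = −1, no position 0; index *i*
of a length-*L* region is position *i − L*. Extraction from a genome
takes, for + genes, the 1-based half-open window `[tss − window, tss)`
as-is and, for − genes, the reverse complement of `[tss, tss + window)`,
truncated at contig edges. The default window is 5000 nt — deep enough
for the deepest planted element at −4801 — and configurable.

The three elements ship as IUPAC degenerate strings — ERSE-I
`CCAATNNNNNNNNNCCACR` (19 nt, half-sites exactly 9 nt apart), ERSE-II
`ATTGGNCCACG` (11 nt), UPRE `TGACGTGR` (8 nt) — compiled to overlapping
regex searches. Both strands are scanned by default (reverse-orientation
hits are real regulatory signals and are labelled with a `-r` suffix);
sense-only is a flag. The reported coordinate is always the element's
5′-most base **on the sense strand**, whichever strand matched; whether
published position lists anchor at the element's 5′ or 3′ end is not
stated anywhere we can check, so this convention is declared rather than
inferred, and the planted fixtures adopt it consistently. An `N` in
input sequence matches only an element's `N` slot, never a specified
base, so gapped assemblies cannot fabricate hits. Exact degenerate
consensus only — no position-weight-matrix scoring, no near-consensus
variants.

## The screen

A protein becomes a candidate iff it has ≥ 1 RING match and ≥ 1
transmembrane span. Motif-positive proteins lacking transmembrane data
are a hard error listing every affected id (silent dropping would bias
counts). Candidates sort by subtype then gene id; the summary
(total, per-subtype counts, span range) is recomputed from the candidate
list. The screen is a pure filter: shuffling the proteome or injecting
motif-free decoys cannot change the candidate set (tested). An optional
isoform→gene map collapses isoforms keeping the max-span isoform. The
candidate table serialises upstream elements closest-to-TSS first
(`ERSE-I,-506;UPRE,-2303`) and round-trips through its reader.

## Expression analyses

**ΔΔCt.** Technical replicates are averaged *before* the per-sample
ΔCt (mean Ct_target − mean Ct_reference); ΔΔCt subtracts the
calibrator's ΔCt and fold = 2^−ΔΔCt, so the calibrator's fold is
exactly 1. Replicate-level folds (each target replicate against the
sample's mean reference Ct) supply means and SDs for display and
testing. Folds are invariant under adding a constant to *all* of a
sample's Ct values and scale by 2^−c when only the target shifts — both
directions are asserted.

**Tissue specificity.** tau = Σ(1 − x_i/x_max)/(n − 1) over per-tissue
mean folds (0 = uniform, 1 = single-tissue), requiring ≥ 5 tissues;
all-zero profiles are an error. Classes: specific (tau ≥ 0.95),
selective (tau ≥ 0.85), else ubiquitous. The thresholds are descriptive
defaults chosen to reproduce the qualitative single-tissue /
limited-tissue / ubiquitous split on the synthetic emulations; they are
configurable, and no inferential claim stands behind them (pooled-RNA
tissue panels carry no replicate structure to test against).

**Responsiveness.** Per gene and stressor (thapsigargin, tunicamycin), a
one-way ANOVA over replicate ΔCt values across timepoint groups
including the untreated control, followed by pairwise t-tests of each
timepoint against control with Bonferroni adjustment (raw p × number of
comparisons, capped at 1). Pairwise significance counts only when the
ANOVA is itself significant (protected testing). A gene is *responsive*
iff **every** stressor shows ≥ 1 timepoint with adjusted p < 0.05 and
mean fold > 1. This both-stressor conjunction makes the simulated null
false-call rate far below the nominal 0.05 (bounded at 1000 null
replications in the acceptance suite). Groups need ≥ 3 replicates;
zero-variance groups give exact-limit p values (0 or 1) with a warning
rather than NaNs. The factor structure (one-way per stressor, timepoints
as groups) is the simplest design consistent with per-timepoint
significance stars against a shared control.

**Viability.** OD590(assay)/OD590(vehicle), optionally over the mock
ratio; non-positive inputs are rejected.

## Synthetic data: what it emulates and what it does not

The default fixture transcribes the screen's gene tables — 37 genes with
their subtype, span count and protein length (19 C3H2C3 / 18 C3HC4,
spans 1–12) — and the 8-gene upstream-element list with orientations and
positions (including the reverse-orientation UPRE at −428 and the
two-element SYVN1 promoter at −506/−2303).

* **Proteins** are block layouts: an N-terminal 21-residue hydrophobic
  span (Leu/Ile/Val/Phe), the RING motif, further spans separated by
  ≥ 24 hydrophilic residues, padding distributed pseudo-randomly to hit
  the exact tabulated length. The hydrophilic background alphabet
  excludes Cys and His, so the planted coordination residues are the
  only slot candidates and exactly one assignment of the planted subtype
  exists; the generator nevertheless re-verifies every draw with the
  real matcher and predictor. Lengths below the feasible minimum raise
  an infeasibility error. Decoys draw uniformly from all 20 residues and
  are rejection-sampled motif-free, which makes screen specificity
  exactly testable (0 of 200 decoys pass).
* **Promoters** draw uniform-ACGT background rejection-verified free of
  all three elements on both strands, then write concrete element
  instances at the requested strand/position and re-verify that a scan
  returns exactly the planted hit set.
* **Ct tables** set target Ct = 28 − log2(true_fold) + N(0, sd) with a
  constant-up-to-noise reference at Ct 18; with sd = 0 the ΔΔCt estimate
  recovers true folds exactly, and at sd 0.2/n 4 the log2-fold estimator
  is unbiased to < 0.05 over 500 tables. Defaults emulate the stress
  panel: BiP ~20-fold and HRD1 ~4-fold positive controls, ~2-fold test
  genes peaking at 6 h or 24 h, one flat gene, sd 0.1, n = 4.

All generators are deterministic given their spec and seed (emitted
fixture files are byte-identical across runs). What passing the planted
study shows is that the pipeline's logic is correct and self-consistent:
the matcher finds exactly what is planted, filters compose correctly,
and the statistics are calibrated. What it cannot show is agreement with
results computed on live RefSeq/Ensembl sequences — database drift,
isoform choice and the external TMHMM version all move real per-gene
numbers, and real genomic background (composition bias, CpG islands,
repeats) is deliberately not emulated. Real inputs are supported through
the same interfaces for that use.

## Problem sizes and defaults

The study runs at the sizes the analyses describe: 37 planted genes plus
200 decoys (~240 proteins, 150–940 residues), 37 upstream regions of
5 kb, Ct tables with n = 4 replicates. Oracle-equivalence sweeps use 200
random proteins (≤ 500 residues) and 100 random regions (≤ 4 kb);
statistical calibration uses 1000 null replications and 500
fold-recovery tables. The full test suite runs in well under a minute;
`scripts/acceptance.py` in a few seconds.
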