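"""Synthetic fixtures with planted ground truth for every pipeline stage.

No sequence accessions accompany the screen's published gene lists, so the
test surface is built from generators that *plant* the features the
pipeline must recover:

* proteins carrying one RING motif of a chosen subtype plus a chosen
  number of hydrophobic membrane spans, among motif-free decoys;
* 5'-upstream regions with ER-stress elements written at chosen
  TSS-relative positions on either strand into element-free background;
* long-format Ct tables with chosen fold-change effects and Gaussian
  noise.

Each generator verifies its own plants using the same pipeline modules
that will later be screened (rejection sampling on failure), so planted
labels are recoverable by construction.  All generators are deterministic
given a spec and a seed.

The default :class:`FixtureSpec` transcribes the screen's gene tables —
37 genes (19 C3H2C3 / 18 C3HC4) with their per-gene transmembrane counts
and protein lengths — and the 8-gene upstream-element list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from e3screen.motif import (
    C3H2C3,
    C3HC4,
    ProteinRecord,
    RING_PATTERN,
    find_ring_motifs,
    write_fasta,
)
from e3screen.promoter import (
    DEFAULT_ELEMENTS,
    ElementDef,
    IUPAC_CLASSES,
    PromoterRegion,
    reverse_complement,
    scan_upstream,
)
from e3screen.tm import TMTopology, predict_tm_hydropathy, write_tmhmm_output

# hydrophilic background residues (no C/H, so planted coordination
# residues are the only slot candidates; no accidental TM calls)
_BG_RESIDUES = "DEKRNQSTGP"
# strongly hydrophobic residues for membrane spans
_TM_RESIDUES = "LIVF"
_TM_LEN = 21
_MIN_GAP = 24  # keeps extended hydropathy intervals from merging
_TAIL = 2
_MAX_TRIES = 10_000

_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


class InfeasibleSpecError(ValueError):
    """The requested protein length cannot hold the requested features."""


# ---------------------------------------------------------------------------
# Planted-motif proteins


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BG_RESIDUES), size=n)) if n else ""


def _motif_block(subtype: str, spacer_lengths: Sequence[int], rng: np.random.Generator) -> str:
    fifth = "H" if subtype == C3H2C3 else "C"
    residues = ["C", "C", "C", "H", fifth, "C", "C", "C"]
    parts = [residues[0]]
    for res, gap in zip(residues[1:], spacer_lengths):
        parts.append(_bg(rng, gap))
        parts.append(res)
    return "".join(parts)


def minimum_length(n_tm: int) -> int:
    """Smallest protein length that can hold one minimal RING motif and
    ``n_tm`` membrane spans with safe separation."""
    return n_tm * _TM_LEN + RING_PATTERN.min_span() + n_tm * _MIN_GAP + _TAIL


def make_motif_protein(
    gene_id: str,
    subtype: str,
    n_tm: int,
    length: int,
    rng: np.random.Generator,
) -> ProteinRecord:
    """Build a protein of exactly ``length`` residues containing one RING
    motif of the requested subtype and exactly ``n_tm`` membrane spans
    recoverable by :func:`~e3screen.tm.predict_tm_hydropathy`.

    The first span is N-terminal (a signal-peptide-like stretch), so
    single- and multi-span layouts both exercise the "signal peptides
    count" convention.  The build is verified with the pipeline's own
    matcher and predictor and redrawn on failure.
    """
    if subtype not in (C3H2C3, C3HC4):
        raise ValueError(f"unknown subtype {subtype!r}")
    if n_tm < 0:
        raise ValueError("n_tm must be >= 0")
    base = minimum_length(n_tm)
    if length < base:
        raise InfeasibleSpecError(
            f"{gene_id}: length {length} cannot hold {n_tm} TM span(s) plus "
            f"a RING motif (minimum {base})"
        )

    spacer_caps = [hi - lo for lo, hi in RING_PATTERN.spacers]
    n_gaps = n_tm  # gaps between the n_tm+1 blocks (TM first, motif second)

    for _ in range(50):
        # distribute the slack over motif spacers (capped), inter-block
        # gaps and the tail
        spacer_extra = [0] * len(spacer_caps)
        gap_extra = [0] * n_gaps
        tail_extra = 0
        slack = length - base
        open_spacers = [i for i, cap in enumerate(spacer_caps) if cap > 0]
        while slack > 0:
            bin_id = int(rng.integers(0, len(open_spacers) + n_gaps + 1))
            if bin_id < len(open_spacers):
                i = open_spacers[bin_id]
                if spacer_extra[i] < spacer_caps[i]:
                    spacer_extra[i] += 1
                    slack -= 1
            elif bin_id < len(open_spacers) + n_gaps:
                gap_extra[bin_id - len(open_spacers)] += 1
                slack -= 1
            else:
                tail_extra += 1
                slack -= 1

        spacers = [
            lo + extra for (lo, _), extra in zip(RING_PATTERN.spacers, spacer_extra)
        ]
        motif = _motif_block(subtype, spacers, rng)
        tm = lambda: "".join(rng.choice(list(_TM_RESIDUES), size=_TM_LEN))

        if n_tm == 0:
            seq = motif + _bg(rng, _TAIL + tail_extra)
        else:
            blocks = [tm(), motif] + [tm() for _ in range(n_tm - 1)]
            parts = [blocks[0]]
            for blk, extra in zip(blocks[1:], gap_extra):
                parts.append(_bg(rng, _MIN_GAP + extra))
                parts.append(blk)
            parts.append(_bg(rng, _TAIL + tail_extra))
            seq = "".join(parts)
        assert len(seq) == length

        record = ProteinRecord(
            id=gene_id, description=f"{gene_id} synthetic {subtype} n_tm={n_tm}",
            sequence=seq,
        )
        matches = find_ring_motifs(record)
        if not matches or any(m.subtype != subtype for m in matches):
            continue
        if predict_tm_hydropathy(record).count() != n_tm:
            continue
        return record
    raise RuntimeError(f"{gene_id}: could not realise spec after 50 redraws")


def make_decoy_protein(
    decoy_id: str, length: int, rng: np.random.Generator
) -> ProteinRecord:
    """A motif-free decoy with uniform residue composition (rejection-
    checked against the RING matcher)."""
    for _ in range(_MAX_TRIES):
        seq = "".join(rng.choice(list(_ALL_AA), size=length))
        record = ProteinRecord(id=decoy_id, description=f"{decoy_id} decoy", sequence=seq)
        if not find_ring_motifs(record):
            return record
    raise RuntimeError(f"{decoy_id}: could not draw a motif-free decoy")


# ---------------------------------------------------------------------------
# Planted-element promoters


def instantiate_iupac(iupac: str, rng: np.random.Generator) -> str:
    """A concrete realisation of a degenerate consensus (N/R etc. drawn
    uniformly from their base classes)."""
    out = []
    for c in iupac:
        bases = IUPAC_CLASSES[c].replace("N", "")
        out.append(bases if len(bases) == 1 else str(rng.choice(list(bases))))
    return "".join(out)


def make_promoter(
    gene_id: str,
    plants: Sequence[tuple[str, str, int]],
    window: int = 5000,
    rng: Optional[np.random.Generator] = None,
    elements: Sequence[ElementDef] = DEFAULT_ELEMENTS,
) -> PromoterRegion:
    """Build an upstream region of ``window`` nt whose complete element
    hit set equals ``plants``.

    Each plant is (element_name, strand, position) with the position the
    TSS-relative coordinate of the element's 5'-most base on the sense
    strand (negative; TSS = +1).  Background is drawn element-free on
    both strands and the whole construct is re-verified by
    :func:`~e3screen.promoter.scan_upstream`, redrawing until exact.
    """
    rng = np.random.default_rng() if rng is None else rng
    by_name = {e.name: e for e in elements}
    intervals = []
    for name, strand, pos in plants:
        if name not in by_name:
            raise ValueError(f"unknown element {name!r}")
        if strand not in "+-":
            raise ValueError(f"bad strand {strand!r}")
        elen = len(by_name[name])
        if pos + elen > 0 or pos < -window:
            raise ValueError(
                f"{gene_id}: plant {name} at {pos} outside window {window}"
            )
        intervals.append((pos + window, pos + window + elen))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"{gene_id}: overlapping plants")

    want = {(name, strand, pos) for name, strand, pos in plants}
    for _ in range(_MAX_TRIES):
        seq = list("".join(rng.choice(list("ACGT"), size=window)))
        for name, strand, pos in plants:
            concrete = instantiate_iupac(by_name[name].iupac, rng)
            if strand == "-":
                concrete = reverse_complement(concrete)
            i = pos + window
            seq[i : i + len(concrete)] = concrete
        region = PromoterRegion(gene_id=gene_id, sequence="".join(seq))
        got = {(h.element, h.strand, h.position) for h in scan_upstream(region, elements)}
        if got == want:
            return region
    raise RuntimeError(f"{gene_id}: could not realise promoter plants")


# ---------------------------------------------------------------------------
# Ct tables


@dataclass(frozen=True)
class CtEffect:
    """One planted expression effect: a gene at a chosen true fold in one
    sample (a condition/timepoint or a tissue)."""

    gene: str
    condition: str
    time_h: Optional[float]
    true_fold: float
    sd: float
    n: int

    @property
    def sample(self) -> str:
        if self.time_h is None:
            return self.condition
        return f"{self.condition}_{self.time_h:g}h"


_TARGET_BASELINE_CT = 28.0
_REFERENCE_BASELINE_CT = 18.0


def make_ct_table(
    effects: Sequence[CtEffect],
    reference_gene: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format Ct table realising the planted effects.

    Target Ct = baseline − log2(true_fold) + N(0, sd); the reference gene
    is constant across samples up to the same noise.  Returns the table
    and a ground-truth manifest.  With sd = 0 the delta-delta-Ct estimate
    recovers each true fold exactly.
    """
    rows = []
    seen_samples: dict[str, CtEffect] = {}
    for eff in effects:
        if eff.sd < 0 or eff.n < 1 or eff.true_fold <= 0:
            raise ValueError(f"bad effect row {eff}")
        if eff.sample not in seen_samples:
            seen_samples[eff.sample] = eff
            ref_cts = _REFERENCE_BASELINE_CT + rng.normal(0.0, eff.sd, size=eff.n)
            for r, ct in enumerate(ref_cts, start=1):
                rows.append(
                    (eff.sample, eff.condition, eff.time_h, reference_gene, r, float(ct))
                )
        cts = (
            _TARGET_BASELINE_CT
            - np.log2(eff.true_fold)
            + rng.normal(0.0, eff.sd, size=eff.n)
        )
        for r, ct in enumerate(cts, start=1):
            rows.append((eff.sample, eff.condition, eff.time_h, eff.gene, r, float(ct)))

    table = pd.DataFrame(
        rows, columns=["sample", "condition", "time_h", "gene", "replicate", "ct"]
    )
    truth = pd.DataFrame(
        [
            (e.gene, e.sample, e.condition, e.time_h, e.true_fold, e.sd, e.n)
            for e in effects
        ],
        columns=["gene", "sample", "condition", "time_h", "true_fold", "sd", "n"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# The default fixture: the screen's gene tables transcribed

#: (gene, subtype, transmembrane spans, protein length) — the 19 two-His
#: genes followed by the 18 one-His genes.
TABLE_ROWS: tuple[tuple[str, str, int, int], ...] = (
    ("RNF130", C3H2C3, 2, 419),
    ("RNF150", C3H2C3, 2, 438),
    ("RNF149", C3H2C3, 1, 400),
    ("RNF133", C3H2C3, 1, 376),
    ("RNF128", C3H2C3, 1, 428),
    ("RNF122", C3H2C3, 1, 155),
    ("RNF24", C3H2C3, 1, 148),
    ("RNF13", C3H2C3, 1, 381),
    ("RNF167", C3H2C3, 1, 350),
    ("ZNRF4", C3H2C3, 1, 429),
    ("RNF43", C3H2C3, 2, 783),
    ("ZNRF3", C3H2C3, 1, 936),
    ("SYVN1", C3H2C3, 6, 617),
    ("AMFR", C3H2C3, 5, 643),
    ("RNF175", C3H2C3, 5, 328),
    ("RNF121", C3H2C3, 6, 327),
    ("RNF145", C3H2C3, 12, 663),
    ("RNF139", C3H2C3, 12, 664),
    ("RNF103", C3H2C3, 4, 685),
    ("RNF19A", C3HC4, 2, 838),
    ("RNF19B", C3HC4, 2, 732),
    ("RNF5", C3HC4, 2, 180),
    ("RNF185", C3HC4, 2, 192),
    ("RNF170", C3HC4, 3, 258),
    ("RNF186", C3HC4, 2, 227),
    ("RNF152", C3HC4, 1, 203),
    ("RNF183", C3HC4, 1, 192),
    ("RNF182", C3HC4, 2, 247),
    ("TRIM59", C3HC4, 1, 403),
    ("TRIM13", C3HC4, 1, 407),
    ("BFAR", C3HC4, 3, 450),
    ("RNF180", C3HC4, 1, 592),
    ("RNFT1", C3HC4, 5, 435),
    ("RNF26", C3HC4, 4, 433),
    ("CGRRF1", C3HC4, 1, 332),
    ("MUL1", C3HC4, 2, 352),
    ("RNF217", C3HC4, 1, 542),
)

#: The 8 genes with upstream ER-stress elements: (element, strand,
#: TSS-relative position); the RNF19A UPRE is in reverse orientation.
PROMOTER_PLANTS: dict[str, tuple[tuple[str, str, int], ...]] = {
    "RNF130": (("UPRE", "+", -315),),
    "RNF149": (("ERSE-I", "+", -2586),),
    "RNF145": (("ERSE-II", "+", -1258),),
    "SYVN1": (("ERSE-I", "+", -506), ("UPRE", "+", -2303)),
    "RNF121": (("UPRE", "+", -2372),),
    "RNF19A": (("UPRE", "-", -428),),
    "RNF170": (("UPRE", "+", -627),),
    "RNF180": (("ERSE-II", "+", -4801),),
}


def _default_ct_effects() -> tuple[CtEffect, ...]:
    """ER-stress timecourse emulating the qPCR panel: BiP induced ~20-fold
    and HRD1 ~4-fold (positive controls), RNFT1 ~2-fold peaking at 6 h,
    RNF185 ~2-fold peaking at 24 h, and a non-responsive gene."""
    effects: list[CtEffect] = [CtEffect(g, "control", 0.0, 1.0, 0.1, 4)
                               for g in ("BiP", "HRD1", "RNFT1", "RNF185", "RNF13")]
    peak = {"BiP": 20.0, "HRD1": 4.0, "RNFT1": 2.0, "RNF185": 2.0, "RNF13": 1.0}
    late = {"BiP": 10.0, "HRD1": 2.5, "RNFT1": 1.2, "RNF185": 2.0, "RNF13": 1.0}
    for condition in ("Tg", "Tm"):
        for gene in peak:
            effects.append(CtEffect(gene, condition, 6.0, peak[gene], 0.1, 4))
            effects.append(CtEffect(gene, condition, 24.0, late[gene], 0.1, 4))
    return tuple(effects)


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to regenerate the full synthetic study."""

    proteome_seed: int = 7
    promoter_seed: int = 11
    ct_seed: int = 5
    proteins: tuple[tuple[str, str, int, int], ...] = TABLE_ROWS
    promoter_plants: Mapping[str, tuple[tuple[str, str, int], ...]] = field(
        default_factory=lambda: dict(PROMOTER_PLANTS)
    )
    n_decoys: int = 200
    promoter_window: int = 5000
    reference_gene: str = "GAPDH"
    ct_effects: tuple[CtEffect, ...] = field(default_factory=_default_ct_effects)


def make_proteome(spec: FixtureSpec = FixtureSpec()) -> list[ProteinRecord]:
    """Planted proteins for every gene row plus motif-free decoys."""
    rng = np.random.default_rng(spec.proteome_seed)
    records = [
        make_motif_protein(gene, subtype, n_tm, length, rng)
        for gene, subtype, n_tm, length in spec.proteins
    ]
    for i in range(spec.n_decoys):
        length = int(rng.integers(150, 700))
        records.append(make_decoy_protein(f"DECOY{i + 1:04d}", length, rng))
    return records


def make_tm_topologies(records: Sequence[ProteinRecord]) -> dict[str, TMTopology]:
    return {rec.id: predict_tm_hydropathy(rec) for rec in records}


def make_promoter_set(
    spec: FixtureSpec = FixtureSpec(),
) -> dict[str, PromoterRegion]:
    """One upstream region per gene row; only the listed genes carry
    planted elements, all others are verified element-free."""
    rng = np.random.default_rng(spec.promoter_seed)
    regions: dict[str, PromoterRegion] = {}
    for gene, _subtype, _n_tm, _length in spec.proteins:
        plants = spec.promoter_plants.get(gene, ())
        regions[gene] = make_promoter(
            gene, plants, window=spec.promoter_window, rng=rng
        )
    return regions


def emit_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete fixture to disk as plain-text files.

    Emits proteome FASTA, TMHMM-format predictions, a promoter "genome"
    FASTA (one contig per gene: upstream window plus 20 downstream bases,
    alternating gene strands to exercise strand-aware extraction) with a
    TSS table, the Ct table, and a ground-truth manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records = make_proteome(spec)
    paths["proteome"] = out / "proteome.fasta"
    write_fasta(records, paths["proteome"])

    topologies = make_tm_topologies(records)
    paths["tmhmm"] = out / "tmhmm.txt"
    paths["tmhmm"].write_text(
        write_tmhmm_output([topologies[r.id] for r in records])
    )

    regions = make_promoter_set(spec)
    genome_rng = np.random.default_rng(spec.promoter_seed + 1)
    contigs: dict[str, str] = {}
    tss_rows: list[tuple[str, int, str, str]] = []
    for i, (gene, region) in enumerate(regions.items()):
        downstream = "".join(genome_rng.choice(list("ACGT"), size=20))
        strand = "+" if i % 2 == 0 else "-"
        chrom = f"chr_{gene}"
        if strand == "+":
            contigs[chrom] = region.sequence + downstream
            tss_rows.append((chrom, len(region.sequence) + 1, strand, gene))
        else:
            # minus-strand extraction takes revcomp of [tss, tss+window)
            contigs[chrom] = downstream + reverse_complement(region.sequence)
            tss_rows.append((chrom, len(downstream) + 1, strand, gene))

    paths["genome"] = out / "promoters.fasta"
    with open(paths["genome"], "w") as fh:
        for chrom, seq in contigs.items():
            fh.write(f">{chrom}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    paths["tss"] = out / "tss.tsv"
    with open(paths["tss"], "w") as fh:
        for chrom, tss, strand, gene in tss_rows:
            fh.write(f"{chrom}\t{tss}\t{strand}\t{gene}\n")

    ct_rng = np.random.default_rng(spec.ct_seed)
    table, truth = make_ct_table(spec.ct_effects, spec.reference_gene, ct_rng)
    paths["ct"] = out / "ct.tsv"
    table.to_csv(paths["ct"], sep="\t", index=False)

    manifest = pd.DataFrame(
        [
            {
                "gene": gene,
                "subtype": subtype,
                "n_tm": n_tm,
                "protein_length": length,
                "upstream_motifs": ";".join(
                    f"{name}{'-r' if strand == '-' else ''},{pos}"
                    for name, strand, pos in spec.promoter_plants.get(gene, ())
                ),
            }
            for gene, subtype, n_tm, length in spec.proteins
        ]
    )
    paths["truth"] = out / "truth.tsv"
    manifest.to_csv(paths["truth"], sep="\t", index=False)
    paths["ct_truth"] = out / "ct_truth.tsv"
    truth.to_csv(paths["ct_truth"], sep="\t", index=False)
    return paths
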