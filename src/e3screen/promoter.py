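"""Scanning TSS-relative upstream DNA for ER-stress cis-elements.

ER-stress-inducible genes carry short degenerate promoter elements bound
by the unfolded-protein-response transcription factors: ERSE-I
(``CCAAT-N9-CCACG/A``, bound by ATF6), ERSE-II (``ATTGG-N-CCACG``) and
UPRE (``TGACGTGG/A``, bound by spliced XBP1).  This module extracts
upstream windows from a genome relative to a transcription start site
(TSS) and scans them for the three elements on both strands.

Coordinate convention: the TSS is +1, the last upstream base is −1, and
there is no position 0.  A region of length L stores its sequence 5'→3'
on the gene's sense strand, so index ``i`` (0-based) is promoter position
``i − L``.  A hit's reported position is the 5'-most base of the element
*on the sense strand* regardless of which strand matched; reverse-strand
hits get a ``-r`` label suffix (e.g. ``UPRE-r``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# IUPAC degenerate nucleotide codes -> concrete bases they stand for.
# An 'N' in *input* sequence matches only an element's 'N' slot, never a
# specified base (avoids fabricating hits in gapped assemblies): only the
# N class below includes the literal N.
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC-code aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ElementDef:
    """A named cis-element as a degenerate IUPAC consensus."""

    name: str
    iupac: str

    def __len__(self) -> int:
        return len(self.iupac)


#: The three ER-stress response elements searched by the screen.
DEFAULT_ELEMENTS: tuple[ElementDef, ...] = (
    ElementDef("ERSE-I", "CCAATNNNNNNNNNCCACR"),
    ElementDef("ERSE-II", "ATTGGNCCACG"),
    ElementDef("UPRE", "TGACGTGR"),
)


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream DNA for one gene, written 5'→3' on the sense strand.

    The base immediately after the final sequence character is the TSS
    (+1); index ``i`` is promoter position ``i − len(sequence)``.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"promoter {self.gene_id!r}: illegal base(s) {''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def position_of_index(self, i: int) -> int:
        return i - len(self.sequence)


@dataclass(frozen=True)
class PromoterHit:
    """One element occurrence in an upstream region.

    ``position`` is the TSS-relative coordinate (negative; TSS = +1, no
    position 0) of the element's 5'-most base on the sense strand.
    """

    gene_id: str
    element: str
    strand: str
    position: int
    matched: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.position + len(self.matched) > 0:
            raise ValueError("element extends past the TSS")

    @property
    def label(self) -> str:
        return self.element + ("-r" if self.strand == "-" else "")


def _iupac_regex(iupac: str) -> re.Pattern[str]:
    body = "".join(
        f"[{IUPAC_CLASSES[c]}]" if len(IUPAC_CLASSES[c]) > 1 else IUPAC_CLASSES[c]
        for c in iupac
    )
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({body}))")


def scan_upstream(
    region: PromoterRegion,
    elements: Sequence[ElementDef] = DEFAULT_ELEMENTS,
    both_strands: bool = True,
) -> list[PromoterHit]:
    """Find all element occurrences in an upstream region.

    Sense-strand occurrences always; with ``both_strands`` the reverse
    complement of each element is also scanned, reported at its sense-
    strand 5'-most coordinate with strand '−'.  Overlapping and nested
    hits are all reported; output is sorted by position, then element
    name, then strand.
    """
    seq = region.sequence
    L = len(seq)
    hits: list[PromoterHit] = []
    for element in elements:
        searches = [(element.iupac, "+")]
        if both_strands:
            searches.append((reverse_complement(element.iupac), "-"))
        for pattern_str, strand in searches:
            for m in _iupac_regex(pattern_str).finditer(seq):
                i = m.start()
                hits.append(
                    PromoterHit(
                        gene_id=region.gene_id,
                        element=element.name,
                        strand=strand,
                        position=i - L,
                        matched=seq[i : i + len(element)],
                    )
                )
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def genes_with_elements(
    hits_by_gene: Mapping[str, Sequence[PromoterHit]]
) -> list[str]:
    """Genes with at least one element hit, input order preserved."""
    return [g for g, hits in hits_by_gene.items() if len(hits) > 0]


# ---------------------------------------------------------------------------
# Genome extraction


def _contig_sequence(genome, chrom: str) -> str:
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(chrom)
    if isinstance(record, str):
        return record.upper()
    return str(record[:]).upper()  # pyfaidx FastaRecord


def extract_upstream(
    genome,
    tss_row: tuple[str, int, str, str],
    window: int = 5000,
) -> PromoterRegion:
    """Extract the upstream window for one TSS table row.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of contig name to
    sequence string); ``tss_row`` is (chrom, tss, strand, gene_id) with a
    1-based TSS.  Plus-strand genes take the 1-based half-open window
    ``[tss − window, tss)``; minus-strand genes take the reverse
    complement of ``[tss, tss + window)``, so the returned string always
    reads 5'→3' toward the TSS.  Windows are truncated at contig edges.
    """
    chrom, tss, strand, gene_id = tss_row
    tss = int(tss)
    if window < 1:
        raise ValueError("window must be >= 1")
    try:
        contig = _contig_sequence(genome, chrom)
    except KeyError:
        raise ValueError(f"unknown contig {chrom!r} in TSS row for {gene_id!r}")
    if not (1 <= tss <= len(contig)):
        raise ValueError(
            f"TSS {tss} outside contig {chrom!r} (length {len(contig)}) "
            f"for gene {gene_id!r}"
        )
    if strand == "+":
        start0 = max(0, tss - 1 - window)
        seq = contig[start0 : tss - 1]
    elif strand == "-":
        end0 = min(len(contig), tss - 1 + window)
        seq = reverse_complement(contig[tss - 1 : end0])
    else:
        raise ValueError(f"bad strand {strand!r} for gene {gene_id!r}")
    return PromoterRegion(gene_id=gene_id, sequence=seq)


def read_tss_table(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read a BED-like TSS table: chrom, tss (1-based), strand, gene_id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "tss", "strand", "gene_id"],
        comment="#", dtype={"chrom": str, "gene_id": str},
    )
    return [
        (str(r.chrom), int(r.tss), str(r.strand), str(r.gene_id))
        for r in df.itertuples()
    ]


HIT_TABLE_COLUMNS = ["gene_id", "label", "element", "strand", "position", "matched"]


def write_hit_table(hits: Iterable[PromoterHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.gene_id}\t{h.label}\t{h.element}\t{h.strand}\t"
                f"{h.position}\t{h.matched}\n"
            )


def hits_to_bed(
    hits: Iterable[PromoterHit],
    tss_rows: Sequence[tuple[str, int, str, str]],
    window: int,
) -> list[tuple[str, int, int, str, int, str]]:
    """Convert hits back to BED6 genomic intervals (0-based half-open).

    The BED strand column is the element's strand relative to the
    *genome*; a sense-strand hit in a minus-strand gene is therefore '−'.
    Regions truncated at contig edges are not supported here (the fixture
    genomes are built large enough).
    """
    by_gene = {row[3]: row for row in tss_rows}
    bed = []
    for h in hits:
        chrom, tss, gene_strand, _ = by_gene[h.gene_id]
        length = len(h.matched)
        if gene_strand == "+":
            start = tss - 1 + h.position
        else:
            start = tss - 1 - h.position - length
        genomic_strand = "+" if gene_strand == h.strand else "-"
        bed.append((chrom, start, start + length, h.label, 0, genomic_strand))
    return bed
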