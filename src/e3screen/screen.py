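"""The candidate screen: RING motif -> transmembrane filter -> upstream scan.

A protein enters the candidate table iff it (1) carries at least one
canonical RING-finger motif and (2) has at least one predicted
transmembrane helix.  Each candidate row records the gene, the subtype of
its canonical (leftmost) RING match, transmembrane-span count, protein
length and any ER-stress elements found upstream — mirroring the screen's
published-style summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from e3screen.motif import (
    MotifPattern,
    ProteinRecord,
    RING_PATTERN,
    RingMatch,
    best_match,
    find_ring_motifs,
)
from e3screen.promoter import PromoterHit
from e3screen.tm import TMTopology, passes_tm_filter


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs for one screen run."""

    pattern: MotifPattern = RING_PATTERN
    min_tm: int = 1
    #: optional isoform -> gene collapse map; the max-TM isoform is kept
    gene_map: Optional[Mapping[str, str]] = None


@dataclass(frozen=True)
class CandidateRecord:
    """One gene that passed both screen criteria."""

    gene_id: str
    subtype: str
    ring: RingMatch
    n_tm: int
    protein_length: int
    upstream_hits: tuple[PromoterHit, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n_tm < 1:
            raise ValueError(f"{self.gene_id}: candidate requires >= 1 TM helix")


@dataclass(frozen=True)
class ScreenSummary:
    n_total: int
    n_c3h2c3: int
    n_c3hc4: int
    tm_min: int
    tm_max: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_c3h2c3 + self.n_c3hc4:
            raise ValueError("subtype counts do not sum to total")


class MissingTMDataError(ValueError):
    """A motif-positive protein has no transmembrane information."""

    def __init__(self, ids: Sequence[str]):
        self.ids = tuple(ids)
        super().__init__(
            "no transmembrane data for motif-positive protein(s): "
            + ", ".join(self.ids)
        )


def run_screen(
    proteome: Sequence[ProteinRecord],
    tm_source: Mapping[str, TMTopology],
    promoter_hits: Optional[Mapping[str, Sequence[PromoterHit]]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list[CandidateRecord], ScreenSummary]:
    """Run the full screen over a proteome.

    ``tm_source`` maps protein id to topology (parsed TMHMM output or the
    built-in predictor); it must cover every motif-positive protein —
    missing entries raise :class:`MissingTMDataError` listing all ids
    rather than silently dropping them.  ``promoter_hits`` maps gene id to
    upstream element hits and may be ``None``.  Candidates are sorted by
    subtype then gene id; the summary is recomputed from the candidates.
    """
    missing: list[str] = []
    prelim: list[CandidateRecord] = []

    for protein in proteome:
        matches = find_ring_motifs(protein, config.pattern)
        if not matches:
            continue
        topo = tm_source.get(protein.id)
        if topo is None:
            missing.append(protein.id)
            continue
        if not passes_tm_filter(topo, config.min_tm):
            continue
        canonical = best_match(matches)
        assert canonical is not None and canonical.subtype is not None
        subtypes = {m.subtype for m in matches}
        notes = "both-subtypes" if len(subtypes) > 1 else ""
        gene_id = (
            config.gene_map.get(protein.id, protein.id)
            if config.gene_map
            else protein.id
        )
        hits = tuple(promoter_hits.get(gene_id, ())) if promoter_hits else ()
        prelim.append(
            CandidateRecord(
                gene_id=gene_id,
                subtype=canonical.subtype,
                ring=canonical,
                n_tm=topo.count(),
                protein_length=len(protein),
                upstream_hits=hits,
                notes=notes,
            )
        )

    if missing:
        raise MissingTMDataError(missing)

    if config.gene_map:
        # collapse isoforms: keep the max-TM isoform per gene (ties: keep
        # the first in input order)
        by_gene: dict[str, CandidateRecord] = {}
        for rec in prelim:
            held = by_gene.get(rec.gene_id)
            if held is None or rec.n_tm > held.n_tm:
                by_gene[rec.gene_id] = rec
        prelim = list(by_gene.values())

    candidates = sorted(prelim, key=lambda r: (r.subtype, r.gene_id))
    return candidates, summarize(candidates)


def summarize(candidates: Sequence[CandidateRecord]) -> ScreenSummary:
    n_h = sum(1 for c in candidates if c.subtype == "C3H2C3")
    n_c = sum(1 for c in candidates if c.subtype == "C3HC4")
    tms = [c.n_tm for c in candidates]
    return ScreenSummary(
        n_total=len(candidates),
        n_c3h2c3=n_h,
        n_c3hc4=n_c,
        tm_min=min(tms) if tms else 0,
        tm_max=max(tms) if tms else 0,
    )


# ---------------------------------------------------------------------------
# Candidate table serialization

CANDIDATE_TABLE_COLUMNS = [
    "gene_id",
    "subtype",
    "upstream_motifs",
    "n_tm",
    "protein_length",
    "notes",
]


@dataclass(frozen=True)
class CandidateRow:
    """A deserialized candidate-table row (the serialisable projection of
    :class:`CandidateRecord`)."""

    gene_id: str
    subtype: str
    upstream_motifs: tuple[tuple[str, int], ...]
    n_tm: int
    protein_length: int
    notes: str = ""


def _as_row(rec) -> CandidateRow:
    if isinstance(rec, CandidateRow):
        return rec
    # table convention: elements listed closest-to-TSS first
    hits = sorted(rec.upstream_hits, key=lambda h: -h.position)
    return CandidateRow(
        gene_id=rec.gene_id,
        subtype=rec.subtype,
        upstream_motifs=tuple((h.label, h.position) for h in hits),
        n_tm=rec.n_tm,
        protein_length=rec.protein_length,
        notes=rec.notes,
    )


def format_upstream_motifs(pairs: Sequence[tuple[str, int]]) -> str:
    """Serialise hits as semicolon-joined ``LABEL,POSITION`` pairs,
    e.g. ``ERSE-I,-506;UPRE,-2303``."""
    return ";".join(f"{label},{pos}" for label, pos in pairs)


def write_candidate_table(candidates: Sequence, path: str | Path) -> None:
    """Write candidates (records or rows) as a deterministic TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_TABLE_COLUMNS) + "\n")
        for rec in candidates:
            row = _as_row(rec)
            fh.write(
                "\t".join(
                    [
                        row.gene_id,
                        row.subtype,
                        format_upstream_motifs(row.upstream_motifs),
                        str(row.n_tm),
                        str(row.protein_length),
                        row.notes,
                    ]
                )
                + "\n"
            )


def read_candidate_table(path: str | Path) -> list[CandidateRow]:
    rows: list[CandidateRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_TABLE_COLUMNS:
            raise ValueError(f"unexpected candidate-table header: {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            gene_id, subtype, motifs, n_tm, plen, notes = fields
            pairs = tuple(
                (label, int(pos))
                for label, pos in (
                    item.split(",") for item in motifs.split(";") if item
                )
            )
            rows.append(
                CandidateRow(
                    gene_id=gene_id,
                    subtype=subtype,
                    upstream_motifs=pairs,
                    n_tm=int(n_tm),
                    protein_length=int(plen),
                    notes=notes,
                )
            )
    return rows
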