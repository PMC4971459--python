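"""Variable-gap protein motif matching and RING-finger subtype classification.

Canonical RING fingers coordinate two Zn2+ ions through eight residues
(cysteines plus one or two histidines).  The screen's search pattern is
written in the field's dash notation::

    C-X2-C-X9-39-C-X1-3-H-X2-3-C/H-X2-C-X9-39-C-X2-C

where a residue token is a single one-letter code (alternatives joined by
``/``) and a spacer token ``Xn`` or ``Xn1-n2`` allows a bounded run of
arbitrary residues between consecutive coordination positions.  The fifth
coordination slot decides the subtype: His gives C3H2C3 (two His total),
Cys gives C3HC4 (one His).

:func:`find_ring_motifs` enumerates *every* distinct coordination-residue
assignment satisfying the slot and spacer constraints; screening decisions
("has at least one RING") and canonical per-protein reporting
(:func:`best_match`) are layered on top, so no information is discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

#: The shipped RING-finger search pattern (dash notation).
RING_PATTERN_SPEC = "C-X2-C-X9-39-C-X1-3-H-X2-3-C/H-X2-C-X9-39-C-X2-C"

C3H2C3 = "C3H2C3"
C3HC4 = "C3HC4"

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Residues legal in input sequences: the 20 standard codes, ambiguity
#: codes X/B/Z, selenocysteine U, and the stop character '*'.
ALLOWED_RESIDUES = _STANDARD_AA | set("XUBZ*")
#: Codes that can fill a spacer but never satisfy a C/H coordination slot.
AMBIGUOUS_RESIDUES = set("XUBZ")


class MotifParseError(ValueError):
    """Raised for a malformed dash-notation motif specification."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identifier and free-text description."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(seq) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains illegal residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """Compiled motif: fixed residue slots separated by bounded spacers.

    ``slots[i]`` is the set of residues allowed at coordination position
    ``i``; ``spacers[i]`` bounds (inclusive) the number of arbitrary
    residues between slots ``i`` and ``i+1``.
    """

    slots: tuple[frozenset[str], ...]
    spacers: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.slots) - 1:
            raise ValueError("need exactly one spacer between consecutive slots")
        for lo, hi in self.spacers:
            if not (0 <= lo <= hi):
                raise ValueError(f"bad spacer bounds ({lo},{hi})")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    def min_span(self) -> int:
        """Residues covered by the shortest possible match."""
        return self.n_slots + sum(lo for lo, _ in self.spacers)

    def max_span(self) -> int:
        return self.n_slots + sum(hi for _, hi in self.spacers)


@dataclass(frozen=True)
class RingMatch:
    """One motif occurrence: the coordination residues and their spacing.

    ``span`` is 0-based half-open from the first to just past the last
    coordination residue.  ``subtype`` is set for the 8-slot RING pattern
    (decided by the residue in slot 5) and ``None`` for other patterns.
    """

    protein_id: str
    coord_positions: tuple[int, ...]
    coord_residues: tuple[str, ...]
    subtype: Optional[str]
    spacer_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        pos = self.coord_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("coordination positions must be strictly increasing")
        if len(self.coord_residues) != len(pos):
            raise ValueError("positions/residues length mismatch")
        expected = tuple(b - a - 1 for a, b in zip(pos, pos[1:]))
        if self.spacer_lengths and self.spacer_lengths != expected:
            raise ValueError("spacer_lengths inconsistent with positions")
        if not self.spacer_lengths:
            object.__setattr__(self, "spacer_lengths", expected)

    @property
    def span(self) -> tuple[int, int]:
        return (self.coord_positions[0], self.coord_positions[-1] + 1)


_SPACER_RE = re.compile(r"^X(\d+)$")


def compile_pattern(spec: str, name: str = "") -> MotifPattern:
    """Compile a dash-notation motif specification.

    Tokens are separated by ``-``; a residue token is one uppercase letter
    or letters joined by ``/``; a spacer token is ``Xn`` (fixed) or
    ``Xn1-n2`` (bounded range, parsed as two dash-separated pieces).
    The spec must start and end with residue tokens and strictly
    alternate residue / spacer.
    """
    raw = spec.strip().split("-")
    if not raw or not spec.strip():
        raise MotifParseError("empty motif specification")

    slots: list[frozenset[str]] = []
    spacers: list[tuple[int, int]] = []
    expect_residue = True
    i = 0
    while i < len(raw):
        tok = raw[i]
        m = _SPACER_RE.match(tok)
        if m:
            if expect_residue:
                raise MotifParseError(
                    f"spacer token {tok!r} where a residue token was expected"
                )
            lo = int(m.group(1))
            hi = lo
            # an Xn1-n2 range arrives as two dash-split pieces: 'Xn1', 'n2'
            if i + 1 < len(raw) and raw[i + 1].isdigit():
                hi = int(raw[i + 1])
                i += 1
            if lo > hi:
                raise MotifParseError(f"spacer {tok!r}-{hi}: min exceeds max")
            spacers.append((lo, hi))
            expect_residue = True
        else:
            if not expect_residue:
                raise MotifParseError(
                    f"residue token {tok!r} where a spacer token was expected "
                    "(two adjacent residue tokens?)"
                )
            parts = tok.split("/")
            if not all(len(p) == 1 and p.isalpha() and p.isupper() for p in parts):
                raise MotifParseError(f"malformed token {tok!r}")
            if any(p == "X" for p in parts):
                raise MotifParseError(
                    f"token {tok!r}: bare X is reserved for spacers"
                )
            slots.append(frozenset(parts))
            expect_residue = False
        i += 1
    if expect_residue:
        raise MotifParseError("specification must end with a residue token")
    if len(slots) < 2:
        raise MotifParseError("need at least two residue slots")
    return MotifPattern(tuple(slots), tuple(spacers), name=name)


#: Compiled shipped RING pattern, importable as a ready-made default.
RING_PATTERN = compile_pattern(RING_PATTERN_SPEC, name="RING")


def _subtype_for(pattern: MotifPattern, residues: tuple[str, ...]) -> Optional[str]:
    if pattern.n_slots != 8 or residues[3] != "H":
        return None
    if residues[4] == "H":
        return C3H2C3
    if residues[4] == "C":
        return C3HC4
    return None


def find_ring_motifs(
    protein: ProteinRecord, pattern: MotifPattern = RING_PATTERN
) -> list[RingMatch]:
    """Enumerate every distinct coordination assignment of ``pattern``.

    Returns all matches (distinct position tuples), sorted lexicographically
    by ``coord_positions``.  Scanning stops at the first ``'*'``; ambiguity
    codes never satisfy a residue slot but may fill spacers.  Deterministic.
    """
    seq = protein.sequence
    stop = seq.find("*")
    if stop != -1:
        seq = seq[:stop]
    n = len(seq)
    slots = pattern.slots
    spacers = pattern.spacers
    k = pattern.n_slots

    out: list[RingMatch] = []
    positions: list[int] = []

    def extend(slot_idx: int) -> None:
        if slot_idx == k:
            coords = tuple(positions)
            out.append(
                RingMatch(
                    protein_id=protein.id,
                    coord_positions=coords,
                    coord_residues=tuple(seq[p] for p in coords),
                    subtype=_subtype_for(pattern, tuple(seq[p] for p in coords)),
                )
            )
            return
        lo, hi = spacers[slot_idx - 1]
        prev = positions[-1]
        for p in range(prev + lo + 1, min(prev + hi + 1, n - 1) + 1):
            if seq[p] in slots[slot_idx]:
                positions.append(p)
                extend(slot_idx + 1)
                positions.pop()

    for p0 in range(n):
        if seq[p0] in slots[0]:
            positions.append(p0)
            extend(1)
            positions.pop()
    # DFS over ascending start positions and ascending spacer choices
    # already yields lexicographic order on coord_positions.
    return out


def classify_subtype(match: RingMatch) -> str:
    """Return the RING subtype decided by coordination slot 5.

    His at slot 5 (two His among the eight residues) gives C3H2C3; Cys
    (one His) gives C3HC4.
    """
    if len(match.coord_residues) != 8:
        raise ValueError("subtype is defined for 8-slot RING matches only")
    fifth = match.coord_residues[4]
    if fifth == "H":
        return C3H2C3
    if fifth == "C":
        return C3HC4
    raise ValueError(f"coordination slot 5 holds {fifth!r}, expected C or H")


def best_match(matches: Iterable[RingMatch]) -> Optional[RingMatch]:
    """Canonical match for table output: lexicographically smallest
    coordination tuple (leftmost start, then shortest spacers); ``None``
    on empty input."""
    best: Optional[RingMatch] = None
    for m in matches:
        if best is None or m.coord_positions < best.coord_positions:
            best = m
    return best


# ---------------------------------------------------------------------------
# FASTA and table IO


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (wrapped or unwrapped) multi-record protein FASTA."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, description=rec.description, sequence=str(rec.seq))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


MATCH_TABLE_COLUMNS = [
    "protein_id",
    "subtype",
    "coord_positions",
    "span_start",
    "span_end",
    "spacer_lengths",
]


def write_match_table(matches: Iterable[RingMatch], path: str | Path) -> None:
    """Write matches as TSV; positions and spans reported 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("\t".join(MATCH_TABLE_COLUMNS) + "\n")
        for m in matches:
            fh.write(
                "\t".join(
                    [
                        m.protein_id,
                        m.subtype or "NA",
                        ",".join(str(p + 1) for p in m.coord_positions),
                        str(m.span[0] + 1),
                        str(m.span[1]),  # half-open end == 1-based inclusive end
                        ",".join(str(s) for s in m.spacer_lengths),
                    ]
                )
                + "\n"
            )
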