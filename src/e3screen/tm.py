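"""Transmembrane-helix counts: TMHMM-format parsing and a hydropathy predictor.

The screen needs one number per protein — how many membrane-spanning
helices it has.  Two sources are supported:

* :func:`parse_tmhmm_output` reads the long-format text report produced by
  TMHMM v2 (`# <id> ... Number of predicted TMHs: n` headers and
  `<id>  TMHMM2.0  TMhelix  <start>  <end>` body lines, 1-based inclusive).
* :func:`predict_tm_hydropathy` is a built-in Kyte–Doolittle sliding-window
  predictor used for synthetic fixtures, where the generator guarantees by
  construction that the predicted count equals the planted count.  No
  agreement with the TMHMM hidden-Markov model on real proteins is claimed.

Signal peptides are deliberately *not* excluded: an N-terminal hydrophobic
stretch counts as a helix, matching how the screen treats proteins such as
HRD1/SYVN1 whose six membrane spans include the signal peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from e3screen.motif import ProteinRecord


@dataclass(frozen=True)
class TMTopology:
    """Predicted or parsed transmembrane helices for one protein.

    ``helices`` are 0-based half-open residue intervals, sorted and
    pairwise non-overlapping.  ``source`` records provenance and is
    excluded from equality so that write→parse round trips compare equal.
    """

    protein_id: str
    helices: tuple[tuple[int, int], ...]
    source: str = field(default="predicted", compare=False)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.helices:
            if start < prev_end:
                raise ValueError(
                    f"{self.protein_id}: helices overlap or are unsorted"
                )
            if end <= start:
                raise ValueError(f"{self.protein_id}: empty helix interval")
            prev_end = end

    def count(self) -> int:
        return len(self.helices)


class TMHMMParseError(ValueError):
    """Raised for inconsistent or malformed TMHMM-style report text."""


_HEADER_RE = re.compile(r"^#\s*(\S+).*Number of predicted TMHs:\s*(\d+)")


def parse_tmhmm_output(text: str) -> list[TMTopology]:
    """Parse TMHMM v2 long-format output into one topology per sequence id.

    The declared per-id TMH count must equal the number of TMhelix lines;
    a mismatch raises :class:`TMHMMParseError` naming the id.  Non-TMhelix
    body lines (inside/outside) and other comment lines are ignored.
    """
    declared: dict[str, int] = {}
    helices: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if m:
                pid, n = m.group(1), int(m.group(2))
                if pid not in declared:
                    order.append(pid)
                declared[pid] = n
                helices.setdefault(pid, [])
            continue
        fields = line.split()
        if len(fields) != 5:
            continue
        pid, _program, kind, start, end = fields
        if kind != "TMhelix":
            continue
        if pid not in declared:
            order.append(pid)
            helices.setdefault(pid, [])
        # file coordinates are 1-based inclusive
        helices.setdefault(pid, []).append((int(start) - 1, int(end)))

    out = []
    for pid in order:
        hx = sorted(helices.get(pid, []))
        if pid in declared and declared[pid] != len(hx):
            raise TMHMMParseError(
                f"{pid}: header declares {declared[pid]} TMH(s) "
                f"but {len(hx)} TMhelix line(s) found"
            )
        out.append(TMTopology(protein_id=pid, helices=tuple(hx), source="parsed"))
    return out


def write_tmhmm_output(topologies: Iterable[TMTopology]) -> str:
    """Serialise topologies in TMHMM v2 long format (1-based inclusive)."""
    lines = []
    for topo in topologies:
        lines.append(
            f"# {topo.protein_id} Number of predicted TMHs:  {topo.count()}"
        )
        for start, end in topo.helices:
            lines.append(
                f"{topo.protein_id}\tTMHMM2.0\tTMhelix\t{start + 1}\t{end}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


# '*' and ambiguity codes get strongly hydrophilic scores so they break
# hydrophobic runs rather than extending them.
_KD_DEFAULT = -4.5


def predict_tm_hydropathy(
    protein: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    merge_gap: int = 5,
) -> TMTopology:
    """Sliding-window Kyte–Doolittle transmembrane prediction.

    Residue positions whose centred ``window``-mean hydropathy is at least
    ``threshold`` are marked; each maximal run of marked positions is
    extended to the window extent, runs closer than ``merge_gap`` are
    merged, and surviving intervals of length >= ``min_len`` become
    helices.  Sequences shorter than the window yield zero helices.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    seq = protein.sequence
    n = len(seq)
    if n < window:
        return TMTopology(protein_id=protein.id, helices=(), source="predicted")

    half = window // 2
    scores = [KYTE_DOOLITTLE.get(aa, _KD_DEFAULT) for aa in seq]

    # centred window means via a running sum
    wsum = sum(scores[:window])
    marked: list[bool] = [False] * n
    c = half
    if wsum / window >= threshold:
        marked[c] = True
    for right in range(window, n):
        wsum += scores[right] - scores[right - window]
        c = right - half
        if wsum / window >= threshold:
            marked[c] = True

    # maximal marked runs, extended to the full window extent
    intervals: list[list[int]] = []
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j + 1 < n and marked[j + 1]:
                j += 1
            intervals.append([max(0, i - half), min(n, j + 1 + half)])
            i = j + 1
        else:
            i += 1

    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], iv[1])
        else:
            merged.append(iv)

    helices = tuple(
        (s, e) for s, e in merged if e - s >= min_len
    )
    return TMTopology(protein_id=protein.id, helices=helices, source="predicted")


def passes_tm_filter(topology: TMTopology, min_count: int = 1) -> bool:
    """Screen criterion: at least ``min_count`` membrane-spanning helices."""
    return topology.count() >= min_count
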