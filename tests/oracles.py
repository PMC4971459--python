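"""Independent brute-force oracles, deliberately sharing no code with the
package: a nested-loop RING enumerator with hard-coded spacer bounds, and
a per-position degenerate comparator for the promoter elements."""

from __future__ import annotations

# --- RING enumeration ------------------------------------------------------

# hard-coded C-X2-C-X9-39-C-X1-3-H-X2-3-C/H-X2-C-X9-39-C-X2-C


def brute_force_ring(sequence: str) -> set[tuple[int, ...]]:
    """All coordination 8-tuples satisfying the RING pattern, by explicit
    nested loops over C/H positions with per-gap bound checks."""
    seq = sequence.split("*")[0]
    c_pos = [i for i, a in enumerate(seq) if a == "C"]
    h_pos = [i for i, a in enumerate(seq) if a == "H"]
    ch_pos = sorted(c_pos + h_pos)
    out: set[tuple[int, ...]] = set()
    for p0 in c_pos:
        for p1 in c_pos:
            if p1 - p0 - 1 != 2:
                continue
            for p2 in c_pos:
                if not 9 <= p2 - p1 - 1 <= 39:
                    continue
                for p3 in h_pos:
                    if not 1 <= p3 - p2 - 1 <= 3:
                        continue
                    for p4 in ch_pos:
                        if not 2 <= p4 - p3 - 1 <= 3:
                            continue
                        for p5 in c_pos:
                            if p5 - p4 - 1 != 2:
                                continue
                            for p6 in c_pos:
                                if not 9 <= p6 - p5 - 1 <= 39:
                                    continue
                                for p7 in c_pos:
                                    if p7 - p6 - 1 != 2:
                                        continue
                                    out.add((p0, p1, p2, p3, p4, p5, p6, p7))
    return out


def brute_force_ring_subtype(sequence: str, coords: tuple[int, ...]) -> str:
    return "C3H2C3" if sequence[coords[4]] == "H" else "C3HC4"


# --- degenerate promoter scan ---------------------------------------------

_ALLOWED = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "N": "ACGTN",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "N": "N"}


def naive_revcomp(pattern: str) -> str:
    return "".join(_COMP[c] for c in reversed(pattern))


def naive_scan(
    sequence: str, elements: list[tuple[str, str]], both_strands: bool = True
) -> set[tuple[str, str, int]]:
    """Position-by-position degenerate comparison on both strands.

    ``elements`` are (name, iupac) pairs; returns (name, strand,
    TSS-relative position of the sense-strand 5'-most base).
    """
    L = len(sequence)
    hits: set[tuple[str, str, int]] = set()
    for name, iupac in elements:
        searches = [(iupac, "+")]
        if both_strands:
            searches.append((naive_revcomp(iupac), "-"))
        for pattern, strand in searches:
            m = len(pattern)
            for i in range(L - m + 1):
                if all(sequence[i + j] in _ALLOWED[pattern[j]] for j in range(m)):
                    hits.add((name, strand, i - L))
    return hits
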