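"""Upstream extraction and degenerate element scanning."""

import numpy as np
import pytest

from e3screen.promoter import (
    DEFAULT_ELEMENTS,
    PromoterHit,
    PromoterRegion,
    extract_upstream,
    genes_with_elements,
    hits_to_bed,
    reverse_complement,
    scan_upstream,
)
from e3screen.synthetic import make_promoter

from oracles import naive_scan

ELEMENT_PAIRS = [(e.name, e.iupac) for e in DEFAULT_ELEMENTS]


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestExtractUpstream:
    def test_plus_strand_window(self):
        genome = {"chr1": "AAAAAAAAAACCGGTCCGGT"}
        region = extract_upstream(genome, ("chr1", 11, "+", "g"), window=10)
        assert region.sequence == "AAAAAAAAAA"

    def test_minus_strand_revcomp(self):
        genome = {"chr1": "ACGTTTTTGG"}
        region = extract_upstream(genome, ("chr1", 5, "-", "g"), window=4)
        assert region.sequence == "AAAA"

    def test_truncation_keeps_position_mapping(self, rng):
        """A window larger than the contig start yields a shorter region
        whose index<->position bijection still holds (checked by brute
        force on a toy contig)."""
        contig = random_dna(rng, 50)
        genome = {"c": contig}
        region = extract_upstream(genome, ("c", 31, "+", "g"), window=100)
        assert len(region) == 30
        for i in range(len(region)):
            pos = region.position_of_index(i)
            assert region.sequence[i] == contig[30 + pos]  # pos negative
            assert pos == i - len(region)

    def test_unknown_contig_and_bad_tss_error(self):
        genome = {"chr1": "ACGT"}
        with pytest.raises(ValueError, match="geneX"):
            extract_upstream(genome, ("chr9", 2, "+", "geneX"), window=2)
        with pytest.raises(ValueError, match="geneY"):
            extract_upstream(genome, ("chr1", 99, "+", "geneY"), window=2)


class TestScanUpstream:
    def test_planted_upre_at_convention_anchor(self, rng):
        region = make_promoter("g", [("UPRE", "+", -315)], window=334, rng=rng)
        (hit,) = scan_upstream(region)
        assert (hit.element, hit.strand, hit.position, hit.label) == (
            "UPRE", "+", -315, "UPRE",
        )

    def test_reverse_orientation_gets_r_label(self, rng):
        region = make_promoter("g", [("UPRE", "-", -428)], window=500, rng=rng)
        (hit,) = scan_upstream(region)
        assert hit.label == "UPRE-r" and hit.position == -428
        assert hit.matched == reverse_complement("TGACGTGG") or hit.matched == (
            reverse_complement("TGACGTGA")
        )

    def test_sense_only_flag_drops_reverse_hits(self, rng):
        region = make_promoter("g", [("UPRE", "-", -100)], window=200, rng=rng)
        assert scan_upstream(region, both_strands=False) == []

    def test_input_n_matches_only_element_n_slots(self):
        # UPRE with one base replaced by N must not match...
        seq = "A" * 20 + "TGACGTGN" + "A" * 4
        assert all(
            h.element != "UPRE" for h in scan_upstream(PromoterRegion("g", seq))
        )
        # ...but N under an ERSE-II 'N' slot does
        seq = "A" * 20 + "ATTGGNCCACG" + "A" * 4
        hits = [h for h in scan_upstream(PromoterRegion("g", seq)) if h.strand == "+"]
        assert [h.element for h in hits] == ["ERSE-II"]

    def test_matched_substrings_have_element_length(self, rng):
        region = make_promoter(
            "g", [("ERSE-I", "+", -300), ("ERSE-II", "-", -100)], window=400, rng=rng
        )
        by_name = {e.name: len(e) for e in DEFAULT_ELEMENTS}
        for h in scan_upstream(region):
            assert len(h.matched) == by_name[h.element]

    def test_erse1_half_sites_nine_bases_apart(self, rng):
        region = make_promoter("g", [("ERSE-I", "+", -200)], window=300, rng=rng)
        (hit,) = scan_upstream(region)
        assert hit.matched[:5] == "CCAAT" and hit.matched[14:19].startswith("CCAC")
        assert len(hit.matched) == 19  # CCAAT + 9 + CCACR

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_on_random_regions(self, seed):
        """Scanner equals naive per-position degenerate comparison over
        both strands, on random regions with occasional planted elements."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 3000))
        seq = list(random_dna(rng, n))
        if seed % 3 == 0:  # plant an element instance to guarantee signal
            elem = DEFAULT_ELEMENTS[seed % len(DEFAULT_ELEMENTS)]
            inst = "".join(
                str(rng.choice(list("ACGT"))) if c == "N"
                else (str(rng.choice(list("AG"))) if c == "R" else c)
                for c in elem.iupac
            )
            i = int(rng.integers(0, n - len(inst)))
            seq[i : i + len(inst)] = inst
        region = PromoterRegion("g", "".join(seq))
        got = {(h.element, h.strand, h.position) for h in scan_upstream(region)}
        assert got == naive_scan(region.sequence, ELEMENT_PAIRS)

    @pytest.mark.parametrize("seed", range(30))
    def test_strand_symmetry(self, seed):
        """Scanning the reverse complement swaps strand labels and remaps
        positions (p -> -len(element) - p - L... expressed via indices)."""
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 500)
        if seed % 2 == 0:
            i = int(rng.integers(0, 490))
            seq = seq[:i] + "TGACGTGG" + seq[i + 8 :]
        L = len(seq)
        fwd = scan_upstream(PromoterRegion("g", seq))
        rev = scan_upstream(PromoterRegion("g", reverse_complement(seq)))
        by_len = {e.name: len(e) for e in DEFAULT_ELEMENTS}

        def key(hits):
            return sorted(
                (h.element, h.strand, h.position + L) for h in hits
            )

        mapped = sorted(
            (h.element, "+" if h.strand == "-" else "-",
             L - (h.position + L) - by_len[h.element])
            for h in rev
        )
        assert key(fwd) == mapped


class TestGenesWithElements:
    def test_empty_map(self):
        assert genes_with_elements({"a": [], "b": []}) == []

    def test_gene_with_two_hits_listed_once_in_order(self, rng):
        region = make_promoter(
            "HRD1", [("ERSE-I", "+", -506), ("UPRE", "+", -2303)], window=3000, rng=rng
        )
        hits = {"zzz": [], "HRD1": scan_upstream(region), "aaa": []}
        assert genes_with_elements(hits) == ["HRD1"]

    def test_planted_fixture_recovers_the_eight_genes(self, promoter_regions, fixture_spec):
        hits = {g: scan_upstream(r) for g, r in promoter_regions.items()}
        got = genes_with_elements(hits)
        assert set(got) == set(fixture_spec.promoter_plants)
        # input (gene-table) order is preserved
        order = [g for g, *_ in fixture_spec.proteins if g in set(got)]
        assert got == order


class TestBedConversion:
    def test_round_trip_against_genome_slices(self, rng):
        contig = random_dna(rng, 400)
        i = 100
        contig = contig[:i] + "TGACGTGG" + contig[i + 8 :]
        # plus-strand gene with TSS at base 301 (1-based)
        genome = {"c": contig}
        row = ("c", 301, "+", "g")
        hits = scan_upstream(extract_upstream(genome, row, window=300))
        bed = hits_to_bed(hits, [row], window=300)
        for (chrom, start, end, label, _score, strand), h in zip(bed, hits):
            segment = contig[start:end]
            if strand == "-":
                segment = reverse_complement(segment)
            # the genomic slice, oriented by the BED strand, is the element
            assert segment == (
                h.matched if h.strand == "+" else reverse_complement(h.matched)
            )
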