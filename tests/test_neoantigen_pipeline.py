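"""Mutant transcript construction, translation, tiling and selection."""

import numpy as np
import pytest

from njatlas.junction_catalog import build_annotation_index
from njatlas.neoantigen_pipeline import (
    DEFAULT_ALLELES,
    MutantTranscript,
    PeptideCandidate,
    build_mutant_transcript,
    filter_tumour_specific,
    map_to_nej,
    match_ms_peptides,
    select_presented,
    tile_peptides,
    translate_cds,
)
from njatlas.synthetic_data import (
    LOSS_TYPES,
    PlantSpec,
    SimulationConfig,
    generate_reference,
    generate_score_tables,
    planted_junction_key,
    worked_example_a3_loss,
)

# independent codon table for the translation oracle
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODON = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def _oracle_translate(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - 2, 3):
        aa = _CODON.get(cds[i : i + 3], "X")
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


class TestMutantTranscript:
    def test_inframe_a3_loss_of_six_deletes_two_residues(self):
        """An in-frame acceptor-site loss of 6 nt removes exactly two
        consecutive amino acids from the product."""
        tx, genome, junction = worked_example_a3_loss()
        mut = build_mutant_transcript(tx, junction, genome)
        ref, alt = mut.reference_protein, mut.mutant_protein
        assert not mut.frameshift
        assert len(ref) - len(alt) == 2
        # the mutant equals the reference with two consecutive residues cut
        assert any(
            ref[:i] + ref[i + 2 :] == alt for i in range(len(ref) - 1)
        )

    def test_two_nt_a3_loss_causes_frameshift_with_novel_tail(self):
        tx, genome, _ = worked_example_a3_loss()
        junction = ("chrW", 200, 302, "+")  # A3 loss of 2 nt
        mut = build_mutant_transcript(tx, junction, genome)
        assert mut.frameshift
        ref, alt = mut.reference_protein, mut.mutant_protein
        assert alt[:33] == ref[:33]  # exon-1 codons unchanged
        first, last = mut.junction_residue_span
        assert last == len(alt)  # frameshift tail runs to the C terminus
        assert "*" not in alt

    def test_stop_truncation(self):
        assert translate_cds("ATGGCCTAA") == ("MA", True)
        assert translate_cds("ATGGCC") == ("MA", False)

    def test_translation_matches_independent_oracle_on_random_plants(self):
        """Mutant proteins equal a codon-by-codon oracle translation of the
        mutant CDS across many random planted events, and the frameshift
        flag always agrees with nt_delta mod 3."""
        config = SimulationConfig(seed=17, n_genes=25, n_tumour_samples=1,
                                  n_normal_samples=1)
        reference = generate_reference(config)
        rng = np.random.default_rng(99)
        types = ["A3_loss", "A3_gain", "A5_loss", "A5_gain", "exon_skip",
                 "in_exon", "in_intron"]
        for i in range(150):
            tx = reference.transcripts[int(rng.integers(0, 25))]
            st = types[int(rng.integers(0, len(types)))]
            mag = int(rng.integers(2, 20))
            spec = PlantSpec(tx.gene_id, st, -mag if st in LOSS_TYPES else mag)
            key, realized = planted_junction_key(spec, tx)
            mut = build_mutant_transcript(tx, key, genome=reference.genome)
            assert mut.mutant_protein == _oracle_translate(mut.mutant_cds)
            assert mut.frameshift == (abs(realized) % 3 != 0)
            assert mut.mutant_protein.startswith("M")
            assert "*" not in mut.mutant_protein


def _mut(protein, span, junction=("c", 1, 2, "+")):
    return MutantTranscript(
        "tx", junction, "", "", protein, span, frameshift=False,
        premature_stop=False,
    )


class TestTiling:
    def test_window_counts_match_brute_force(self):
        """Tile counts equal brute-force substring enumeration for every k
        on proteins up to 50 residues."""
        rng = np.random.default_rng(5)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for trial in range(25):
            n = int(rng.integers(12, 51))
            protein = "".join(aas[rng.integers(0, 20, n)])
            lo = int(rng.integers(1, n + 1))
            hi = int(rng.integers(lo, n + 1))
            tiles = tile_peptides(_mut(protein, (lo, hi)))
            brute = []
            for k in (8, 9, 10, 11):
                for i in range(1, n - k + 2):
                    if i <= hi and i + k - 1 >= lo:
                        brute.append(protein[i - 1 : i - 1 + k])
            assert {t.sequence for t in tiles} == set(brute)
            assert len(tiles) == len(set(brute))  # dedup by sequence

    def test_single_affected_residue_mid_protein_gives_38_windows(self):
        rng = np.random.default_rng(0)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        protein = "".join(aas[rng.permutation(20)[:20]])  # 20 distinct
        protein = protein + "".join(aas[rng.integers(0, 20, 10)])
        tiles = tile_peptides(_mut(protein[:30], (15, 15)))
        assert len(tiles) == 8 + 9 + 10 + 11  # 38 before dedup (all distinct)

    def test_affected_residue_at_position_one_gives_one_tile_per_k(self):
        rng = np.random.default_rng(1)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        protein = "".join(aas[rng.integers(0, 20, 30)])
        tiles = tile_peptides(_mut(protein, (1, 1)))
        assert len(tiles) == 4
        assert sorted(len(t.sequence) for t in tiles) == [8, 9, 10, 11]

    def test_repetitive_protein_deduplicates(self):
        tiles = tile_peptides(_mut("AG" * 20, (10, 12)))
        seqs = [t.sequence for t in tiles]
        assert len(seqs) == len(set(seqs))

    def test_flanks_truncated_to_30(self):
        protein = "M" + "A" * 80 + "W" + "C" * 80
        tiles = tile_peptides(_mut(protein, (82, 82)))
        for t in tiles:
            assert len(t.flank_n) <= 30 and len(t.flank_c) <= 30
            start = t.position
            assert protein[start - 1 - len(t.flank_n): start - 1] == t.flank_n

    def test_empty_span_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning, match="no junction-affected"):
            assert tile_peptides(_mut("ACDEFGHIKLMN", None)) == []


class TestProteomeFilter:
    def test_reference_fragment_flagged_not_specific(self):
        proteome = {"P1": "MACDEFGHIKLMNPQR"}
        cands = [
            PeptideCandidate("CDEFGHIK", ("c", 1, 2, "+"), 1, "", ""),
            PeptideCandidate("WWWWYYYY", ("c", 1, 2, "+"), 1, "", ""),
        ]
        filter_tumour_specific(cands, proteome)
        assert cands[0].tumour_specific is False
        assert cands[1].tumour_specific is True

    def test_planted_decoy_flags_exactly_that_tile(self):
        tiles = tile_peptides(_mut("MACDEFGHIKLMNPQRSTVWYA", (10, 12)))
        decoy = tiles[3].sequence
        filter_tumour_specific(tiles, {"decoy": "XXX" + decoy + "ZZZ"})
        flags = {t.sequence: t.tumour_specific for t in tiles}
        assert flags[decoy] is False
        assert all(v for s, v in flags.items() if s != decoy)

    def test_concatenation_cannot_create_false_matches(self):
        proteome = {"P1": "AAAA", "P2": "CCCC"}
        cands = [PeptideCandidate("AACC", ("c", 1, 2, "+"), 1, "", "")]
        filter_tumour_specific(cands, proteome)
        assert cands[0].tumour_specific is True


def _candidates(n, junction=("c", 1, 2, "+")):
    rng = np.random.default_rng(42)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(aas[rng.integers(0, 20, 9)]))
    return [
        PeptideCandidate(s, junction, 1, "", "", tumour_specific=True)
        for s in sorted(seqs)
    ]


class TestSelection:
    def test_double_top_percentile_conjunction(self):
        cands = _candidates(300)
        planted = {c.sequence for c in cands[:3]}
        ta, tb = generate_score_tables(
            [c.sequence for c in cands], planted, seed=1
        )
        select_presented(cands, ta, tb, DEFAULT_ALLELES, q=0.01)
        assert {c.sequence for c in cands if c.selected} == planted

    def test_top_by_one_scorer_only_is_not_selected(self):
        cands = _candidates(300)
        planted = {c.sequence for c in cands[:3]}
        ta, tb = generate_score_tables(
            [c.sequence for c in cands], planted, seed=1
        )
        select_presented(cands, ta, tb, DEFAULT_ALLELES, q=0.01)
        # the best non-planted candidate of scorer A is near the bottom of B
        al = DEFAULT_ALLELES[0]
        best_a = max(
            (c for c in cands if c.sequence not in planted),
            key=lambda c: -c.percentile_rank[("A", al)],
        )
        assert not best_a.selected

    def test_enlarging_q_never_removes_selection(self):
        cands = _candidates(200)
        planted = {c.sequence for c in cands[:4]}
        ta, tb = generate_score_tables(
            [c.sequence for c in cands], planted, seed=3
        )
        select_presented(cands, ta, tb, DEFAULT_ALLELES, q=0.01)
        sel_small = {c.sequence for c in cands if c.selected}
        select_presented(cands, ta, tb, DEFAULT_ALLELES, q=0.10)
        sel_big = {c.sequence for c in cands if c.selected}
        assert sel_small <= sel_big

    def test_q_one_selects_all_tumour_specific(self):
        cands = _candidates(50)
        cands[0].tumour_specific = False
        ta, tb = generate_score_tables([c.sequence for c in cands], set(), seed=2)
        select_presented(cands, ta, tb, DEFAULT_ALLELES, q=1.0)
        assert all(c.selected == c.tumour_specific for c in cands)

    def test_missing_peptide_raises_with_keys(self):
        cands = _candidates(10)
        ta, tb = generate_score_tables(
            [c.sequence for c in cands[:-1]], set(), seed=2
        )
        with pytest.raises(KeyError, match="missing peptides"):
            select_presented(cands, ta, tb, DEFAULT_ALLELES, q=0.5)


class TestNEJMapping:
    def test_distinct_parent_junctions(self):
        j1, j2 = ("c", 1, 2, "+"), ("c", 5, 9, "+")
        cands = _candidates(3, j1) + _candidates(2, j2)
        for c in cands:
            c.selected = True
        nej = map_to_nej(cands)
        assert set(nej) == {j1, j2}

    def test_no_selection_empty(self):
        assert map_to_nej(_candidates(5)) == {}

    def test_counts_per_junction(self):
        cands = _candidates(10)
        for c in cands:
            c.selected = True
        assert map_to_nej(cands) == {("c", 1, 2, "+"): 10}


class TestMSMatching:
    def test_junction_spanning_peptide_confirms(self):
        mut = _mut("MAAAACDEFWKLMNPQR", (10, 10))  # W at position 10
        assert match_ms_peptides(["DEFWKLM"], [mut], {"P": "QQQQ"}) == {
            mut.junction
        }

    def test_upstream_only_match_does_not_confirm(self):
        mut = _mut("MAAAACDEFWKLMNPQR", (15, 15))
        assert match_ms_peptides(["MAAAACD"], [mut], {"P": "QQQQ"}) == set()

    def test_proteome_peptide_does_not_confirm(self):
        mut = _mut("MAAAACDEFWKLMNPQR", (10, 10))
        assert (
            match_ms_peptides(["DEFWKLM"], [mut], {"P": "XXDEFWKLMXX"}) == set()
        )
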