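"""Peptidome tests: mapping, ladders, trimming steps, cleavage
specificity, and precursor contribution — each against hand-computed or
generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from milknet.peptidome import (
    PLASMIN,
    PeptideLocation,
    cleavage_sites,
    cleavage_specificity,
    detect_ladders,
    map_peptide,
    parse_range,
    precursor_contribution,
    trimming_steps,
)
from milknet.synthetic import DigestSpec, random_protein_sequence, simulate_digest


def locs(coords, acc="P1"):
    return [PeptideLocation(acc, s, e, "") for s, e in coords]


class TestMapPeptide:
    def test_internal_placement_by_hand(self):
        hits = map_peptide("TAYI", {"prec": "MKTAYIAKQR"})
        assert (hits[0].start, hits[0].end) == (3, 6)
        assert not hits[0].multi_hit

    def test_whole_precursor(self):
        hits = map_peptide("MKTAYIAKQR", {"prec": "MKTAYIAKQR"})
        assert (hits[0].start, hits[0].end) == (1, 10)

    def test_no_match_raises_naming_peptide(self):
        with pytest.raises(ValueError, match="WWWW"):
            map_peptide("WWWW", {"prec": "MKTAYIAKQR"})

    def test_repeated_occurrence_is_flagged_ambiguous(self):
        hits = map_peptide("AHAH", {"prec": "AHAHAH"})
        assert len(hits) == 2 and all(h.multi_hit for h in hits)

    def test_secretory_form_ranges_parse(self):
        # PTHLH secretory forms, signal peptide included in numbering
        assert [parse_range(t) for t in ("37–72", "74–130", "143–175")] == [
            (37, 72), (74, 130), (143, 175),
        ]


class TestDetectLadders:
    def test_toy_ladder_span_count_and_mean_length(self, toy_ladder_coords):
        ladders = detect_ladders(locs(toy_ladder_coords), min_peptides=5)
        assert len(ladders) == 1
        lad = ladders[0]
        assert (lad.range_start, lad.range_end) == (10, 25)
        assert lad.n_peptides == 5
        assert lad.mean_length == 14.8  # (16+15+14+15+14)/5

    def test_below_threshold_is_no_ladder(self, toy_ladder_coords):
        assert detect_ladders(locs(toy_ladder_coords[:4]), min_peptides=5) == []

    def test_two_disjoint_ladders_on_one_precursor(self):
        coords = [(10, 20), (11, 20), (12, 20), (10, 19), (10, 18),
                  (50, 60), (51, 60), (52, 60), (50, 59), (50, 58)]
        ladders = detect_ladders(locs(coords), min_peptides=5)
        spans = {(l.range_start, l.range_end) for l in ladders}
        assert spans == {(10, 20), (50, 60)}

    def test_butyrophilin_like_ladder_statistics(self):
        """Synthetic stand-in for a dense milk-fat-globule-membrane protein
        ladder: 19 nested peptides spanning 504-526, mean length 14.9."""
        coords = [(s, s + 14) for s in range(504, 513)]  # nine 15-mers
        coords += [(s, s + 15) for s in range(504, 512)]  # eight 16-mers
        coords += [(510, 517), (507, 518)]  # 19 peptides, lengths sum to 283
        lad = detect_ladders(locs(coords), min_peptides=5)
        assert len(lad) == 1
        assert (lad[0].range_start, lad[0].range_end) == (504, 526)
        assert lad[0].n_peptides == 19
        assert lad[0].mean_length == 14.9

    def test_union_span_attained_by_members(self, toy_ladder_coords):
        ladders = detect_ladders(locs(toy_ladder_coords), min_peptides=2)
        lad = ladders[0]
        starts = {p.start for p in lad.members}
        ends = {p.end for p in lad.members}
        assert lad.range_start in starts and lad.range_end in ends


class TestTrimmingSteps:
    def test_single_n_terminal_step(self):
        steps = trimming_steps(locs([(10, 25), (11, 25)]))
        assert len(steps) == 1 and steps[0][2] == "N"

    def test_toy_ladder_has_two_n_and_two_c_steps(self, toy_ladder_coords):
        steps = trimming_steps(locs(toy_ladder_coords))
        kinds = sorted(s[2] for s in steps)
        assert kinds == ["C", "C", "N", "N"]

    def test_identical_coordinates_make_no_pair(self):
        steps = trimming_steps(locs([(5, 20), (5, 20)]))
        assert steps == []


class TestCleavageSpecificity:
    def test_hand_enumerated_sites_and_plasmin_fraction(self):
        seq = {"P": "AKRLMKGW"}
        peptides = [PeptideLocation("P", 4, 6, ""), PeptideLocation("P", 4, 7, "")]
        sites, fractions = cleavage_specificity(peptides, seq)
        assert set(zip(sites.bond_position, sites.p1)) == {(3, "R"), (6, "K"), (7, "G")}
        assert fractions["plasmin"] == pytest.approx(66.7)

    def test_full_length_peptide_has_no_cleavage_sites(self):
        seq = {"P": "AKRLMKGW"}
        sites = cleavage_sites([PeptideLocation("P", 1, 8, "")], seq)
        assert sites.empty

    def test_duplicate_peptides_do_not_double_count(self):
        seq = {"P": "AKRLMKGW"}
        peptides = [PeptideLocation("P", 4, 6, "")] * 3
        sites, fractions = cleavage_specificity(peptides, seq)
        assert len(sites) == 2
        assert fractions["plasmin"] == pytest.approx(100.0)

    def test_out_of_range_coordinates_raise(self):
        with pytest.raises(ValueError, match="outside"):
            cleavage_sites([PeptideLocation("P", 2, 50, "")], {"P": "AKRLMKGW"})

    def test_synthetic_kr_digest_is_pure_plasmin_and_sites_recover_exactly(self):
        seq = random_protein_sequence(200, seed=5)
        spec = DigestSpec({"PR": seq}, cleavage_prob=1.0, exo_steps=0, seed=5)
        rng = np.random.default_rng(5)
        abund = pd.DataFrame({"PR": np.exp2(rng.normal(24, 1, 10))},
                             index=[f"S{i}" for i in range(10)])
        table, truth = simulate_digest(spec, abund)
        peptides = [
            PeptideLocation("PR", int(table.meta.at[f, "start"]),
                            int(table.meta.at[f, "end"]), str(table.meta.at[f, "sequence"]))
            for f in table.feature_ids
        ]
        sites, fractions = cleavage_specificity(peptides, {"PR": seq})
        assert fractions["plasmin"] == pytest.approx(100.0)
        recovered = {("PR", int(b), p1) for b, p1 in zip(sites.bond_position, sites.p1)}
        assert recovered == truth.true_cleavage_sites

    def test_per_terminus_counting_mode(self):
        seq = {"P": "AKRLMKGW"}
        peptides = [PeptideLocation("P", 4, 6, ""), PeptideLocation("P", 4, 7, "")]
        sites, fractions = cleavage_specificity(peptides, seq, per_terminus=True)
        assert len(sites) == 4  # two termini per peptide, no deduplication
        assert fractions["plasmin"] == pytest.approx(75.0)


class TestPrecursorContribution:
    def _peptide_table(self, counts):
        from conftest import make_table

        n_samples = 6
        total = sum(counts.values())
        vals = np.full((n_samples, total), 100.0)
        table = make_table(vals, kind="peptide", feature_prefix="pep")
        prec = []
        for acc, k in counts.items():
            prec.extend([acc] * k)
        table.meta["precursor_accession"] = prec
        return table

    def test_single_precursor_contributes_everything(self):
        out = precursor_contribution(self._peptide_table({"CSN2": 4}))
        assert out.loc["CSN2", "count_percent"] == pytest.approx(100.0)

    def test_toy_counts_and_ranking(self):
        out = precursor_contribution(self._peptide_table({"CSN2": 3, "PIGR": 1, "BTN1A1": 1}))
        np.testing.assert_allclose(out["count_percent"], [60.0, 20.0, 20.0])
        assert out.index[0] == "CSN2"  # the beta-casein-like dominant precursor first
        assert out["count_percent"].sum() == pytest.approx(100.0, abs=0.1)
        assert out["abundance_percent"].sum() == pytest.approx(100.0, abs=0.1)


class TestLadderProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    intervals = st.lists(
        st.tuples(st.integers(1, 80), st.integers(0, 24)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=25,
    )

    @given(intervals)
    @settings(derandomize=True, max_examples=50)
    def test_ladders_partition_into_connected_overlap_components(self, coords):
        ladders = detect_ladders(locs(coords), min_peptides=1)
        # spans are exact unions and members pairwise reachable by overlaps
        covered = []
        for lad in ladders:
            assert lad.range_start == min(p.start for p in lad.members)
            assert lad.range_end == max(p.end for p in lad.members)
            covered.extend(lad.members)
        assert len(covered) == len(coords)
        # distinct ladders never overlap
        spans = sorted((l.range_start, l.range_end) for l in ladders)
        for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
            assert s2 > e1
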