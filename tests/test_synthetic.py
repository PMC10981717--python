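"""Generator tests: planted GGM structure, in-silico digestion, censoring,
and MaxQuant-dialect round trips."""

import numpy as np
import pandas as pd
import pytest

from milknet import ggm
from milknet.synthetic import (
    DigestSpec,
    PrecisionSpec,
    apply_mnar_censoring,
    build_precision_matrix,
    random_protein_sequence,
    simulate_abundances,
    simulate_digest,
    write_peptides_table,
    write_protein_groups,
)
from milknet.ingest import read_maxquant_table

from conftest import make_table


class TestSimulateAbundances:
    def test_independent_features_have_near_zero_partial_correlations(self):
        spec = PrecisionSpec(
            n_features=5, block_sizes=(), within_block_pcor=0.0, n_samples=5000, seed=0
        )
        table, truth = simulate_abundances(spec)
        pcm, _ = ggm.partial_correlations(table.log2_matrix())
        off = pcm.offdiagonal()
        assert np.abs(off).max() < 0.05
        assert truth.true_edges == set()

    def test_planted_pair_partial_correlation_matches_closed_form(self):
        # block of 2 at pcor 0.5 plus an unconnected feature:
        # rho_12 = 0.5 exactly, rho_13 = rho_23 = 0
        spec = PrecisionSpec(
            n_features=3, block_sizes=(2,), within_block_pcor=0.5, n_samples=5000, seed=1
        )
        table, truth = simulate_abundances(spec)
        pcm, _ = ggm.partial_correlations(table.log2_matrix())
        r = pcm.rho.to_numpy()
        assert r[0, 1] == pytest.approx(0.5, abs=0.05)
        assert abs(r[0, 2]) < 0.05 and abs(r[1, 2]) < 0.05
        f = table.feature_ids
        assert truth.true_edges == {(f[0], f[1])}
        assert truth.true_clusters == {f[0]: 1, f[1]: 1, f[2]: 0}

    def test_same_seed_is_bit_identical(self):
        spec = PrecisionSpec(
            n_features=10, block_sizes=(4,), within_block_pcor=0.3, n_samples=50, seed=7
        )
        t1, _ = simulate_abundances(spec)
        t2, _ = simulate_abundances(spec)
        assert t1.intensities.equals(t2.intensities)

    def test_non_positive_definite_block_is_rejected_naming_block(self):
        spec = PrecisionSpec(
            n_features=10, block_sizes=(4, 5), within_block_pcor=0.3, n_samples=50, seed=0
        )
        with pytest.raises(ValueError, match="block 1"):
            build_precision_matrix(spec)

    def test_intensities_are_on_lfq_log_scale(self):
        spec = PrecisionSpec(
            n_features=4, block_sizes=(), within_block_pcor=0.0, n_samples=200, seed=3
        )
        table, _ = simulate_abundances(spec)
        log2 = table.log2_matrix().to_numpy()
        assert log2.min() > 10 and log2.max() < 40


def brute_force_kr_fragments(seq, length_range=(8, 25)):
    """Independent oracle: fragments between every K/R bond, length-filtered."""
    bonds = [i for i in range(1, len(seq)) if seq[i - 1] in "KR"]
    bounds = [0, *bonds, len(seq)]
    frags = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if length_range[0] <= b - a <= length_range[1]:
            frags.append((a + 1, b))
    return frags


class TestSimulateDigest:
    SEQ = "AAACCDDEEKFFGGHHIIRLLMMNNPPQQKSSTTVVWWYY"  # K/R at 10, 19, 30

    def _abund(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"P1": np.exp2(rng.normal(25, 1, n))},
            index=[f"S{i}" for i in range(n)],
        )

    def test_full_cleavage_without_trimming_gives_inter_kr_fragments(self):
        spec = DigestSpec({"P1": self.SEQ}, cleavage_prob=1.0, exo_steps=0, seed=0)
        table, truth = simulate_digest(spec, self._abund())
        got = {
            (int(table.meta.at[f, "start"]), int(table.meta.at[f, "end"]))
            for f in table.feature_ids
        }
        assert got == set(brute_force_kr_fragments(self.SEQ))
        # planted sites are the internal bonds flanking emitted fragments
        assert all(self.SEQ[pos - 1] in "KR" for _, pos, _ in truth.true_cleavage_sites)

    def test_trimmed_variants_have_correct_coordinates_and_decreasing_abundance(self):
        spec = DigestSpec({"P1": self.SEQ}, cleavage_prob=1.0, exo_steps=2, seed=0)
        table, _ = simulate_digest(spec, self._abund(n=500))
        meta = table.meta
        base = "P1|20-30"  # fragment between the R at 19 and the K at 30
        for variant in ("P1|21-30", "P1|22-30"):
            assert variant in table.feature_ids
        means = [table.intensities[f].mean() for f in (base, "P1|21-30", "P1|22-30")]
        assert means[0] > means[1] > means[2]
        for f in table.feature_ids:
            s, e = int(meta.at[f, "start"]), int(meta.at[f, "end"])
            assert meta.at[f, "sequence"] == self.SEQ[s - 1 : e]

    def test_zero_cleavage_probability_emits_nothing(self):
        spec = DigestSpec({"P1": self.SEQ}, cleavage_prob=0.0, exo_steps=2, seed=0)
        table, truth = simulate_digest(spec, self._abund())
        # the intact chain exceeds the 25-residue cap, so nothing is emitted
        assert table.n_features == 0
        assert truth.true_cleavage_sites == set()

    def test_invalid_residue_and_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="invalid residues"):
            DigestSpec({"P1": "AAAKBBBBRCCCC"})  # B is not an amino acid
        with pytest.raises(ValueError, match="empty sequence"):
            DigestSpec({"P1": ""})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_peptide_is_exact_substring_at_recorded_coordinates(self, seed):
        seq = random_protein_sequence(180, seed=seed)
        spec = DigestSpec({"P1": seq}, cleavage_prob=0.6, exo_steps=2, seed=seed)
        table, _ = simulate_digest(spec, self._abund())
        for f in table.feature_ids:
            s, e = int(table.meta.at[f, "start"]), int(table.meta.at[f, "end"])
            pep = table.meta.at[f, "sequence"]
            assert seq[s - 1 : e] == pep
            assert 8 <= len(pep) <= 25

    def test_peptide_precursor_coupling_at_default_noise(self):
        seq = random_protein_sequence(150, seed=4)
        spec = DigestSpec({"P1": seq}, cleavage_prob=1.0, exo_steps=1, seed=4)
        abund = self._abund(n=300, seed=4)
        table, _ = simulate_digest(spec, abund)
        prec_log = np.log2(abund["P1"])
        for f in table.feature_ids:
            r = np.corrcoef(np.log2(table.intensities[f]), prec_log)[0, 1]
            assert r >= 0.5


class TestCensoring:
    def test_zero_quantile_leaves_table_unchanged(self, rng):
        table = make_table(np.exp2(rng.normal(20, 1, (50, 3))))
        assert apply_mnar_censoring(table, 0.0, seed=0) is table

    def test_censored_cells_sit_below_the_empirical_quantile(self, rng):
        table = make_table(np.exp2(rng.normal(20, 1, (1000, 4))))
        out = apply_mnar_censoring(table, 0.3, seed=0)
        for f in out.feature_ids:
            miss = out.mask[f]
            assert miss.sum() == pytest.approx(300, abs=15)
            thr = table.intensities[f].quantile(0.3)
            assert (table.intensities[f][miss] < thr).all()

    def test_constant_feature_is_never_partially_censored(self):
        table = make_table(np.full((100, 1), 5.0))
        out = apply_mnar_censoring(table, 0.3, seed=0)
        n_missing = int(out.mask.to_numpy().sum())
        assert n_missing in (0, 100)

    def test_soft_censoring_is_stochastic_but_seed_deterministic(self, rng):
        table = make_table(np.exp2(rng.normal(20, 1, (500, 2))))
        a = apply_mnar_censoring(table, 0.3, seed=1, soft=True)
        b = apply_mnar_censoring(table, 0.3, seed=1, soft=True)
        assert a.mask.equals(b.mask)
        assert a.mask.to_numpy().sum() > 0


class TestRoundTrip:
    def test_protein_groups_round_trip(self, tmp_path, rng):
        vals = np.exp2(rng.normal(22, 2, (4, 3)))
        vals[1, 2] = np.nan
        table = make_table(vals, feature_prefix="PROT")
        path = tmp_path / "proteinGroups.txt"
        write_protein_groups(table, path)
        back = read_maxquant_table(path, "proteinGroups")
        assert back.sample_ids == table.sample_ids
        assert back.feature_ids == table.feature_ids
        assert back.mask.equals(table.mask)
        np.testing.assert_allclose(
            back.intensities.fillna(0).to_numpy(), table.intensities.fillna(0).to_numpy()
        )

    def test_peptides_round_trip(self, tmp_path):
        seq = random_protein_sequence(120, seed=9)
        spec = DigestSpec({"PR1": seq}, cleavage_prob=1.0, exo_steps=1, seed=9)
        rng = np.random.default_rng(9)
        abund = pd.DataFrame({"PR1": np.exp2(rng.normal(24, 1, 5))},
                             index=[f"S{i}" for i in range(5)])
        table, _ = simulate_digest(spec, abund)
        path = tmp_path / "peptides.txt"
        write_peptides_table(table, path)
        back = read_maxquant_table(path, "peptides")
        assert back.feature_ids == table.feature_ids
        assert list(back.meta["sequence"]) == list(table.meta["sequence"])
        np.testing.assert_allclose(
            back.intensities.to_numpy(), table.intensities.to_numpy(), rtol=1e-12
        )
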