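import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sirnafit as sf
from sirnafit.profiles import ALPHABET


def dataset_from(seq_z_pairs):
    return sf.ScreenDataset(
        [sf.SiRNARecord(f"o{i}", s, z) for i, (s, z) in enumerate(seq_z_pairs)]
    )


class TestPositionalProfile:
    def test_hand_derived_toy_values(self, toy_dataset):
        p = sf.build_positional_profile(toy_dataset, include_position_1=True, ci="none")
        assert p.values.loc["A", 1] == 2.0
        assert p.values.loc["C", 2] == 1.0
        assert p.values.loc["A", 2] == 3.0
        assert p.values.loc["G", 3] == 1.0
        assert p.values.loc["A", 3] == 3.0

    def test_constant_phenotype(self):
        ds = dataset_from([("ACGT", 1.5), ("TGCA", 1.5), ("AACC", 1.5)])
        p = sf.build_positional_profile(ds, include_position_1=True, ci="none")
        defined = p.values.to_numpy()[~np.isnan(p.values.to_numpy())]
        assert np.allclose(defined, 1.5)

    def test_absent_nucleotide_is_undefined_not_zero(self):
        ds = dataset_from([("AA", 1.0), ("AC", 2.0)])
        p = sf.build_positional_profile(ds, include_position_1=True, ci="none")
        assert np.isnan(p.values.loc["G", 2])
        assert p.counts.loc["G", 2] == 0

    def test_position_1_excluded_by_default(self, toy_dataset):
        p = sf.build_positional_profile(toy_dataset, ci="none")
        assert 1 not in p.values.columns

    def test_min_count_flags_cells_undefined(self):
        ds = dataset_from([("AA", 1.0), ("AC", 2.0), ("AC", 3.0)])
        p = sf.build_positional_profile(ds, min_count=2, include_position_1=True, ci="none")
        assert np.isnan(p.values.loc["A", 2])  # only one A at position 2
        assert p.values.loc["C", 2] == 2.5

    def test_all_undefined_raises(self):
        ds = dataset_from([("AC", 1.0)])
        with pytest.raises(sf.ValidationError, match="too small"):
            sf.build_positional_profile(ds, min_count=5, ci="none")

    def test_empty_dataset_raises(self):
        with pytest.raises(sf.ValidationError):
            sf.build_positional_profile(sf.ScreenDataset([]), ci="none")

    def test_bootstrap_ci_defined_and_positive(self, random_dataset):
        p = sf.build_positional_profile(random_dataset, ci="bootstrap", n_boot=200)
        vals = p.ci_halfwidth.to_numpy()
        assert np.nanmin(vals) > 0

    @given(st.data())
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_conservation_invariant(self, data):
        """Count-weighted mean of profile values at each position equals the
        global mean phenotype of oligos covering that position (exactly)."""
        n = data.draw(st.integers(5, 30))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        nts = np.array(list(ALPHABET))
        pairs = [
            ("".join(nts[rng.integers(0, 4, rng.integers(6, 10))]), float(rng.standard_normal()))
            for _ in range(n)
        ]
        ds = dataset_from(pairs)
        p = sf.build_positional_profile(ds, include_position_1=True, ci="none")
        z = ds.phenotypes().to_numpy()
        lengths = np.array([len(s) for s in ds.sequences()])
        for pos in p.positions:
            counts = p.counts[pos].to_numpy(dtype=float)
            vals = p.values[pos].to_numpy()
            mask = counts > 0
            weighted = (counts[mask] * vals[mask]).sum() / counts[mask].sum()
            global_mean = z[lengths >= pos].mean()
            assert weighted == pytest.approx(global_mean, abs=1e-12)

    @pytest.mark.parametrize("n_small,n_big", [(500, 8000)])
    def test_label_permutation_converges_to_global_mean(self, n_small, n_big):
        """Shuffling phenotypes across oligos erases positional structure; the
        max deviation from the global mean shrinks roughly as n^(-1/2)."""
        devs = {}
        for n in (n_small, n_big):
            screen, _ = sf.generate_screen(
                sf.ScreenSimConfig(n_oligos=n, background="uniform", rng_seed=5)
            )
            rng = np.random.default_rng(1)
            z = rng.permutation(screen.phenotypes().to_numpy())
            shuffled = sf.ScreenDataset(
                [
                    sf.SiRNARecord(r.oligo_id, r.guide_seq, float(z[i]))
                    for i, r in enumerate(screen)
                ]
            )
            p = sf.build_positional_profile(shuffled, ci="none")
            devs[n] = np.nanmax(np.abs(p.values.to_numpy() - z.mean()))
        ratio = devs[n_small] / devs[n_big]
        expected = np.sqrt(n_big / n_small)
        assert ratio > expected / 3  # n^(-1/2) scaling up to statistical slack


class TestFrequencyProfile:
    def test_hand_counts(self):
        fp = sf.build_frequency_profile(["AA", "AC"])
        assert fp.freqs.loc["A", 2] == 0.5
        assert fp.freqs.loc["C", 2] == 0.5
        assert fp.freqs.loc["A", 1] == 1.0

    def test_single_oligo_indicator_columns(self):
        fp = sf.build_frequency_profile(["ACGT"])
        for pos, nt in enumerate("ACGT", start=1):
            col = fp.freqs[pos]
            assert col[nt] == 1.0 and col.sum() == 1.0

    def test_uniform_library_frequencies(self):
        cfg = sf.ScreenSimConfig(n_oligos=100_000, background="uniform", rng_seed=0)
        lib = sf.generate_library(cfg)
        fp = sf.build_frequency_profile(lib)
        assert np.abs(fp.freqs.to_numpy() - 0.25).max() < 0.01

    def test_columns_sum_to_one_invariant(self):
        with pytest.raises(sf.ValidationError):
            sf.FrequencyProfile(pd.DataFrame(0.3, index=list(ALPHABET), columns=[1, 2]))


class TestConditionalShift:
    def test_hand_arithmetic(self):
        ds = dataset_from([("AG", 1.0), ("CG", 1.0), ("AA", 3.0), ("CA", 3.0)])
        s = sf.conditional_shift(ds, 2, "G")
        assert s.mean_shift == -2.0
        assert s.n_subset == 2 and s.n_complement == 2

    def test_no_shift_when_distributions_identical(self):
        ds = dataset_from([("AG", 1.0), ("CG", 2.0), ("AA", 1.0), ("CA", 2.0)])
        s = sf.conditional_shift(ds, 2, "G")
        assert s.mean_shift == 0.0

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        nts = np.array(list(ALPHABET))
        n = 20_000
        seqs = ["".join(nts[rng.integers(0, 4, 19)]) for _ in range(n)]
        z = rng.normal(0, 1, n)
        hasG6 = np.array([s[5] == "G" for s in seqs])
        z[hasG6] -= 0.5
        ds = dataset_from(zip(seqs, z))
        s = sf.conditional_shift(ds, 6, "G")
        assert abs(s.mean_shift - (-0.5)) < 0.05
        assert s.p_value < 1e-10

    def test_empty_subset_raises_identifying_cell(self):
        ds = dataset_from([("AA", 1.0), ("AC", 2.0), ("AA", 0.0)])
        with pytest.raises(sf.ValidationError, match="G at position 2"):
            sf.conditional_shift(ds, 2, "G")


class TestSeedGroups:
    def seqs_with_seed(self, seed7, n, rng):
        nts = np.array(list(ALPHABET))
        out = []
        for _ in range(n):
            tail = "".join(nts[rng.integers(0, 4, 11)])
            out.append(nts[rng.integers(0, 4)] + seed7 + tail)
        return out

    def test_group_mean_hand_value(self):
        rng = np.random.default_rng(0)
        seqs = self.seqs_with_seed("CGTACGT", 3, rng)
        ds = dataset_from(zip(seqs, [-1.0, -2.0, -3.0]))
        groups = sf.seed_group_summary(ds, min_count=2)
        assert len(groups) == 1
        g = groups[0]
        assert g.seed == "CGTACGT" and g.n == 3
        assert list(g.mean_phenotype.values())[0] == -2.0

    def test_all_unique_seeds_empty_summary(self):
        rng = np.random.default_rng(1)
        seqs = [self.seqs_with_seed(s, 1, rng)[0] for s in ("AAAAAAA", "CCCCCCC", "GGGGGGG")]
        ds = dataset_from(zip(seqs, [1.0, 2.0, 3.0]))
        assert sf.seed_group_summary(ds, min_count=2) == []

    def test_planted_seed_effects_rank_first_and_last(self):
        rng = np.random.default_rng(2)
        nts = np.array(list(ALPHABET))
        pairs = []
        for seed7, eff in (("AAACCCG", -2.0), ("GGGTTTA", 2.0)):
            for s in self.seqs_with_seed(seed7, 30, rng):
                pairs.append((s, eff + rng.normal(0, 0.5)))
        for _ in range(500):
            pairs.append(("".join(nts[rng.integers(0, 4, 19)]), rng.normal(0, 0.5)))
        groups = sf.seed_group_summary(dataset_from(pairs), min_count=5)
        ranked = sorted(groups, key=lambda g: abs(list(g.mean_phenotype.values())[0]), reverse=True)
        assert {ranked[0].seed, ranked[1].seed} == {"AAACCCG", "GGGTTTA"}

    def test_two_screen_correlation_contributions_sum_to_r(self):
        rng = np.random.default_rng(3)
        seeds = ["".join(np.array(list(ALPHABET))[rng.integers(0, 4, 7)]) for _ in range(20)]
        effects = rng.normal(0, 1, 20)
        datasets = []
        for screen in ("s1", "s2"):
            recs = []
            for k, (sd, eff) in enumerate(zip(seeds, effects)):
                for j, seq in enumerate(self.seqs_with_seed(sd, 3, rng)):
                    recs.append(
                        sf.SiRNARecord(
                            f"{screen}_{k}_{j}", seq, float(eff + rng.normal(0, 0.3)),
                            screen=screen,
                        )
                    )
            datasets.append(sf.ScreenDataset(recs))
        groups = sf.seed_group_summary(datasets, min_count=2)
        contribs = [g.cross_screen_correlation_contribution for g in groups]
        m1 = np.array([g.mean_phenotype["s1"] for g in groups])
        m2 = np.array([g.mean_phenotype["s2"] for g in groups])
        r = np.corrcoef(m1, m2)[0, 1]
        assert np.nansum(contribs) == pytest.approx(r, abs=1e-10)
        assert r > 0.8  # shared seed effects reproduce across screens


class TestProfileDistances:
    def make_profiles(self, k=3, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(k):
            screen, _ = sf.generate_screen(
                sf.ScreenSimConfig(n_oligos=400, rng_seed=int(rng.integers(1e6)))
            )
            out.append(sf.build_positional_profile(screen, ci="none"))
        return out

    def test_identical_profiles_distance_zero(self):
        p = self.make_profiles(1)[0]
        d = sf.profile_distance_matrix([p, p])
        assert np.allclose(d, 0)

    def test_unit_perturbation_uncentered(self):
        p1, _, _ = self.make_profiles(3)
        import copy

        p2 = copy.deepcopy(p1)
        p2.values.iloc[0, 0] += 1.0
        d = sf.profile_distance_matrix([p1, p2], center=False)
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_a_equals_b(self):
        p1, _, p3 = self.make_profiles(3)
        import copy

        d = sf.profile_distance_matrix([p1, copy.deepcopy(p1), p3])
        assert d[0, 1] == 0
        assert d[0, 2] == pytest.approx(d[1, 2], abs=1e-12)
        assert d[0, 2] > 0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_incompatible_shapes_raise(self):
        ds = dataset_from([("ACGTACGTA", 1.0), ("TGCATGCAT", 2.0)])
        short = sf.build_positional_profile(ds, ci="none")
        long_ = self.make_profiles(1)[0]
        with pytest.raises(sf.ValidationError, match="incompatible"):
            sf.profile_distance_matrix([short, long_])


class TestPCoA:
    def test_collinear_points_recover_spacing(self):
        d = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        coords, eig = sf.pcoa(d, k=1)
        x = coords.iloc[:, 0].to_numpy()
        gaps = np.abs(np.diff(np.sort(x)))
        assert np.allclose(gaps, [1.0, 1.0], atol=1e-10)

    def test_identical_points_embed_at_origin(self):
        d = np.zeros((4, 4))
        coords, _ = sf.pcoa(d, k=2)
        assert np.allclose(coords.to_numpy(), 0)

    def test_round_trip_random_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = sf.pcoa(d, k=5)
        emb = coords.to_numpy()
        d2 = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        assert np.abs(d - d2).max() < 1e-8

    def test_matches_direct_eigendecomposition_oracle(self):
        """Cross-check against an independent double-centering implementation."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, eig = sf.pcoa(d, k=2)
        # oracle: B = -1/2 J D^2 J, eigendecompose
        n = d.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (d**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        oracle = vecs[:, order[:2]] * np.sqrt(vals[order[:2]])
        got = coords.to_numpy()
        for j in range(2):  # axes defined up to sign
            assert (
                np.allclose(got[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(got[:, j], -oracle[:, j], atol=1e-8)
            )
        assert np.allclose(np.sort(eig)[::-1][:2], vals[order[:2]], atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1], [2, 0]])
        with pytest.raises(sf.ValidationError, match="symmetric"):
            sf.pcoa(d)
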