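"""Pair extraction, rank statistics, mode truncation, and the runner."""

import numpy as np
import pytest

from commutime import (
    ConnectomeSpec,
    PairMask,
    build_operators,
    commute_time,
    generate_connectome,
    ks_compare,
    metric_comparison,
    pair_vector,
    run_experiment,
    spearman_correlation,
    top_mode,
)

from conftest import connectome_from_weights


class TestPairVector:
    def test_order_for_three_regions(self):
        m = np.array([[0, 12, 13], [12, 0, 23], [13, 23, 0]], dtype=float)
        np.testing.assert_array_equal(pair_vector(m), [12, 13, 23])

    def test_all_pairs_count_for_84_regions(self):
        m = np.zeros((84, 84))
        assert pair_vector(m).size == 84 * 83 // 2

    def test_intra_left_count(self):
        m = np.zeros((84, 84))
        hemi = ["left"] * 42 + ["right"] * 42
        assert pair_vector(m, PairMask.intra("left"), hemi).size == 42 * 41 // 2

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pair_vector(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_custom_mask_excludes_diagonal(self):
        with pytest.raises(ValueError):
            PairMask(mode="custom", custom_pairs=((1, 1),)).indices(4)


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.linspace(1, 10, 50)
        rho, _ = spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(20.0)
        rho, _ = spearman_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_input_flagged_nan(self):
        with pytest.warns(RuntimeWarning):
            rho, p = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2])

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=100)
        y = rng.lognormal(size=100)
        base, _ = spearman_correlation(x, y)
        assert spearman_correlation(np.log(x), y)[0] == pytest.approx(base)
        assert spearman_correlation(x, y**3)[0] == pytest.approx(base)


class TestKs:
    def test_identical_samples_zero(self):
        stat, _ = ks_compare([1, 2, 3], [1, 2, 3])
        assert stat == 0.0

    def test_disjoint_supports_one(self):
        stat, _ = ks_compare([1, 2, 3], [10, 11, 12])
        assert stat == 1.0

    def test_explicit_cdf_gap(self):
        stat, _ = ks_compare([1, 2, 3], [1, 2, 4])
        assert stat == pytest.approx(1.0 / 3.0)

    def test_undersized_input_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([1.0], [1, 2, 3])


class TestTopMode:
    def test_full_rank_reconstruction_is_identity(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10, 10))
        m = (m + m.T) / 2
        np.testing.assert_allclose(top_mode(m, 10), m, atol=1e-10)

    def test_rank_one_input_recovered_exactly(self):
        v = np.arange(1.0, 7.0)
        m = np.outer(v, v)
        np.testing.assert_allclose(top_mode(m, 1), m, atol=1e-10)

    def test_eckart_young_optimality(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(8, 8))
        m = (m + m.T) / 2
        best = np.linalg.norm(m - top_mode(m, 1), "fro")
        for _ in range(100):
            v = rng.normal(size=8)
            lam = rng.normal()
            rival = np.linalg.norm(m - lam * np.outer(v, v), "fro")
            assert best <= rival + 1e-12

    def test_error_non_increasing_in_k(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(12, 12))
        m = (m + m.T) / 2
        errs = [np.linalg.norm(m - top_mode(m, k), "fro") for k in range(1, 13)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        np.testing.assert_array_equal(top_mode(m, 3), top_mode(m.copy(), 3))

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            top_mode(np.eye(3), 4)


class TestMetricComparison:
    @pytest.fixture
    def conn(self):
        return generate_connectome(ConnectomeSpec(n_regions=20, seed=5))

    def test_fc_constructed_from_commute_gives_unity(self, conn):
        ct = commute_time(build_operators(conn)).values
        fc = np.exp(-ct / ct.max())  # monotone decreasing in commute time
        np.fill_diagonal(fc, 1.0)
        reports = metric_comparison(conn, fc)
        by = {r.metric_tag: r for r in reports}
        # commute time is sign-flipped for reporting, so the correlation is +1
        assert by["commute_time"].rho == pytest.approx(1.0)
        assert by["commute_time"].sign_flipped

    def test_report_bookkeeping(self, conn):
        rng = np.random.default_rng(6)
        fc = rng.normal(size=(20, 20))
        fc = np.clip((fc + fc.T) / 2, -1, 1)
        np.fill_diagonal(fc, 1.0)
        reports = metric_comparison(
            conn, fc, rank_settings=[("full", "full"), ("top_k", "top_k")]
        )
        assert len(reports) == 8
        assert all(r.n_pairs == 190 for r in reports)

    def test_relabeling_invariance(self, conn):
        rng = np.random.default_rng(7)
        fc = rng.normal(size=(20, 20))
        fc = (fc + fc.T) / 2
        np.fill_diagonal(fc, 1.0)
        base = {r.metric_tag: r.rho for r in metric_comparison(conn, fc)}
        # permute within hemispheres so hemisphere labels are unchanged
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
        c2 = connectome_from_weights(
            conn.weights[np.ix_(perm, perm)],
            lengths=conn.lengths[np.ix_(perm, perm)],
            hemisphere=[conn.hemisphere[i] for i in perm],
        )
        permuted = {
            r.metric_tag: r.rho
            for r in metric_comparison(c2, fc[np.ix_(perm, perm)])
        }
        for tag, rho in base.items():
            assert permuted[tag] == pytest.approx(rho, abs=1e-9)


class TestRunExperiment:
    CONFIG = {
        "connectome": {"spec": {"n_regions": 16, "seed": 2}},
        "fc": {"ising": {"coupling": 2.0, "n_steps": 200}},
        "replicates": 3,
        "seed": 9,
        "rank_settings": [["full", "full"], ["top_k", "top_k"]],
    }

    def test_bundle_contents_and_quartiles(self, tmp_path):
        result = run_experiment(self.CONFIG, tmp_path)
        assert (tmp_path / "correlation_reports.tsv").exists()
        assert (tmp_path / "summary_quartiles.tsv").exists()
        assert (tmp_path / "experiment_config.yaml").exists()
        assert len(result["reports"]) == 3 * 2 * 4  # replicates x settings x metrics
        assert {"q25", "median", "q75"} <= set(result["summary"].columns)

    def test_rerun_bit_identical(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_experiment(self.CONFIG, out1)
        run_experiment(self.CONFIG, out2)
        for f in sorted(out1.iterdir()):
            assert (out2 / f.name).read_bytes() == f.read_bytes(), f.name

    def test_supplied_fc_file(self, tmp_path):
        from commutime import write_matrix

        conn = generate_connectome(ConnectomeSpec(n_regions=16, seed=2))
        rng = np.random.default_rng(1)
        fc = rng.normal(size=(16, 16))
        fc = np.clip((fc + fc.T) / 2, -1, 1)
        np.fill_diagonal(fc, 1.0)
        fc_path = tmp_path / "fc.tsv"
        write_matrix(fc, fc_path, conn.region_labels)
        config = {
            "connectome": {"spec": {"n_regions": 16, "seed": 2}},
            "fc": {"path": str(fc_path)},
            "seed": 3,
        }
        result = run_experiment(config, tmp_path / "out")
        assert len(result["reports"]) == 4


class TestRankInvarianceProperty:
    """Spearman depends only on ranks: property-based check."""

    def test_arbitrary_monotone_transform(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(
            st.lists(
                st.floats(-1e6, 1e6, allow_nan=False),
                min_size=5,
                max_size=40,
                unique=True,
            ),
            st.integers(0, 2**31 - 1),
        )
        def check(xs, seed):
            rng = np.random.default_rng(seed)
            x = np.array(xs)
            y = rng.normal(size=x.size)
            if np.ptp(y) == 0:
                return
            base, _ = spearman_correlation(x, y)
            # x -> 8x is strictly monotone and exact in floating point,
            # so it preserves the rank vector without introducing ties
            transformed, _ = spearman_correlation(8.0 * x, y)
            assert transformed == pytest.approx(base, abs=1e-9)

        check()
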