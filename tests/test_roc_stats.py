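"""AUC machinery: brute-force oracles, closed forms, MRMC pooling,
multiplicity adjustment, bootstrap reduction test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import synthetic_manifest
from lcdbench.errors import InputError, UndefinedROCError
from lcdbench.reader_sim import make_profiles, simulate_ratings
from lcdbench.roc_stats import (
    bh_adjust,
    bootstrap_auc_reduction,
    compare_auc,
    empirical_auc,
    hanley_mcneil_se,
    mrmc_auc,
)


def brute_force_auc(pos, neg):
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert empirical_auc([5, 5], [1, 1]).auc == 1.0

    def test_ties_get_half_credit(self):
        res = empirical_auc([4, 5, 3], [1, 2, 4])
        assert res.auc == pytest.approx(7.5 / 9, abs=1e-12)

    def test_all_ties_is_chance(self):
        assert empirical_auc([2, 2, 2], [2, 2]).auc == 0.5

    def test_empty_class_rejected(self):
        with pytest.raises(UndefinedROCError):
            empirical_auc([], [1, 2])

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force(self, data):
        vals = st.integers(0, 5)
        pos = data.draw(st.lists(vals, min_size=1, max_size=20))
        neg = data.draw(st.lists(vals, min_size=1, max_size=20))
        assert empirical_auc(pos, neg).auc == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complementarity(self, data):
        vals = st.floats(0, 1, allow_nan=False)
        pos = data.draw(st.lists(vals, min_size=1, max_size=15))
        neg = data.draw(st.lists(vals, min_size=1, max_size=15))
        a = empirical_auc(pos, neg).auc
        b = empirical_auc(neg, pos).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestHanleyMcNeil:
    def test_chance_auc_small_n(self):
        assert hanley_mcneil_se(0.5, 10, 10) == pytest.approx(0.1322876, abs=1e-6)

    def test_perfect_auc_has_zero_se(self):
        assert hanley_mcneil_se(1.0, 25, 13) == 0.0

    def test_large_n_closed_form(self):
        # direct evaluation of the Q1/Q2 formula at A=0.886, 320/320
        assert hanley_mcneil_se(0.886, 320, 320) == pytest.approx(0.0134537, abs=1e-6)

    def test_se_shrinks_with_n(self):
        ses = [hanley_mcneil_se(0.8, n, n) for n in (10, 40, 160, 640)]
        assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_se_maximized_near_half(self):
        ses = {a: hanley_mcneil_se(a, 20, 20) for a in (0.5, 0.7, 0.9, 0.99)}
        assert ses[0.5] == max(ses.values())

    def test_bad_inputs(self):
        with pytest.raises(InputError):
            hanley_mcneil_se(1.2, 10, 10)
        with pytest.raises(InputError):
            hanley_mcneil_se(0.5, 0, 10)


class TestCompareAuc:
    def test_null_identity(self):
        a = empirical_auc([3, 4], [1, 2])
        res = compare_auc(a, a)
        assert res.z == 0.0
        assert res.p_raw == 1.0

    def test_arithmetic_example(self):
        from lcdbench.roc_stats import AUCResult

        a1 = AUCResult(0.9, 10, 10, 0.01, (0, 1))
        a2 = AUCResult(0.692, 10, 10, 0.01, (0, 1))
        res = compare_auc(a1, a2)
        assert res.z == pytest.approx(14.7078, abs=1e-3)
        assert res.p_raw < 1e-15

    def test_antisymmetry(self):
        from lcdbench.roc_stats import AUCResult

        a1 = AUCResult(0.8, 10, 10, 0.02, (0, 1))
        a2 = AUCResult(0.7, 10, 10, 0.03, (0, 1))
        r12 = compare_auc(a1, a2)
        r21 = compare_auc(a2, a1)
        assert r12.z == pytest.approx(-r21.z)
        assert r12.p_raw == pytest.approx(r21.p_raw)

    def test_zero_se_unequal_rejected(self):
        from lcdbench.roc_stats import AUCResult

        with pytest.raises(InputError):
            compare_auc(
                AUCResult(1.0, 5, 5, 0.0, (1, 1)), AUCResult(0.9, 5, 5, 0.0, (0, 1))
            )


class TestMrmc:
    def _table(self, manifest, dprimes, seed=0):
        frames = []
        for i, d in enumerate(dprimes):
            p = make_profiles(1, dprime=d, seed=seed + i)[0]
            t = simulate_ratings(
                [p], manifest, seed=seed + 100 + i
            )
            t["reader_id"] = f"reader-{i:02d}"
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def test_pooled_is_mean_of_per_reader_aucs(self):
        manifest = synthetic_manifest(200, seed=1)
        table = self._table(manifest, [0.5, 1.0, 2.0], seed=5)
        res = mrmc_auc(table, manifest, n_boot=50, seed=2)
        per_reader = []
        truth = manifest.set_index("case_id")["present"]
        for rid, grp in table.groupby("reader_id"):
            labels = truth.loc[grp["case_id"]].to_numpy()
            scores = grp["rating"].to_numpy()
            per_reader.append(
                brute_force_auc(scores[labels], scores[~labels])
            )
        assert res.auc == pytest.approx(np.mean(per_reader), abs=1e-12)

    def test_identical_readers_degenerate_pooling(self):
        manifest = synthetic_manifest(100, seed=3)
        single = self._table(manifest, [1.0], seed=9)
        triple = pd.concat(
            [single.assign(reader_id=f"r{i}") for i in range(3)], ignore_index=True
        )
        res1 = mrmc_auc(single, manifest, n_boot=200, seed=4)
        res3 = mrmc_auc(triple, manifest, n_boot=200, seed=4)
        assert res3.auc == pytest.approx(res1.auc, abs=1e-12)
        assert res3.se == pytest.approx(res1.se, abs=1e-12)

    def test_incomplete_crossing_rejected(self):
        manifest = synthetic_manifest(50, seed=6)
        table = self._table(manifest, [1.0, 1.0], seed=7)
        with pytest.raises(InputError):
            mrmc_auc(table.iloc[:-5], manifest, n_boot=10, seed=0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_oracle(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 25)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_permutation_invariance(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        perm = np.array([3, 1, 4, 0, 2])
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 40)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])


def _reduction_inputs(seed, d_a=(1.5, 1.0), d_b=(1.5, 1.0), n=80, readers=4):
    """Latent-model scores/ratings for two condition arms."""
    rng = np.random.default_rng(seed)
    out = []
    for arm, (da, db) in enumerate(zip(d_a, d_b)):
        labels = np.zeros(n, dtype=bool)
        labels[: n // 2] = True
        scores = rng.standard_normal(n) + da * labels
        cuts = np.array([-1.0, 0.0, 1.0, 2.0])
        latents = rng.standard_normal((readers, n)) + db * labels
        ratings = 1 + (latents[..., None] > cuts).sum(axis=-1)
        out.append((scores, labels, ratings))
    return out


class TestBootstrapReduction:
    def test_exact_null_gives_zero(self):
        (s1, l1, r1), _ = _reduction_inputs(1)
        res = bootstrap_auc_reduction(
            s1, l1, s1, l1, r1, r1, n_boot=50, seed=3
        )
        assert res.estimate == 0.0
        assert res.z == 0.0
        assert res.p_raw == 1.0

    def test_seeded_determinism(self):
        (s1, l1, r1), (s2, l2, r2) = _reduction_inputs(2)
        a = bootstrap_auc_reduction(s1, l1, s2, l2, r1, r2, n_boot=100, seed=9)
        b = bootstrap_auc_reduction(s1, l1, s2, l2, r1, r2, n_boot=100, seed=9)
        assert a.z == b.z and a.ci95 == b.ci95

    def test_z_grows_with_effect_size(self):
        zs = []
        for drop in (0.0, 0.8, 1.6):
            # modality A keeps d'=2 in both arms; B drops by `drop`
            (s1, l1, r1), (s2, l2, r2) = _reduction_inputs(
                7, d_a=(2.0, 2.0), d_b=(2.0, 2.0 - drop), n=120
            )
            res = bootstrap_auc_reduction(s1, l1, s2, l2, r1, r2, n_boot=200, seed=5)
            zs.append(abs(res.z))
        assert zs[0] < zs[1] < zs[2]

    def test_length_mismatch_rejected(self):
        (s1, l1, r1), (s2, l2, r2) = _reduction_inputs(4)
        with pytest.raises(InputError):
            bootstrap_auc_reduction(s1[:-1], l1, s2, l2, r1, r2, n_boot=10, seed=0)
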