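"""Gini consistency and percent-variance-explained decomposition."""
import numpy as np
import pandas as pd
import pytest

from prsvar.containers import DosageMatrix, ReplicateSet, default_variant_table
from prsvar.contribution import (
    contribution_quadrants,
    gini_pve_table,
    percent_variance_explained,
    snp_gini,
)


def _reps(dosages, typed=None):
    dosages = np.asarray(dosages, dtype=float)
    k, n, m = dosages.shape
    if typed is None:
        typed = np.zeros(m, dtype=bool)
    return ReplicateSet(
        process="test",
        samples=[f"s{i}" for i in range(n)],
        variants=default_variant_table(m),
        dosages=dosages,
        typed_mask=typed,
        seeds=[0] * k,
    )


def oracle_gini(values):
    """Pairwise-sum Gini over one individual's replicate dosages."""
    k = len(values)
    mean = sum(values) / k
    if mean == 0:
        return 0.0
    num = sum(abs(a - b) for a in values for b in values)
    return num / (2 * k * k * mean)


class TestSnpGini:
    def test_identical_replicates_give_exact_zero(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 2, (20, 10))
        g = snp_gini(_reps(np.stack([base] * 6)))
        np.testing.assert_array_equal(g, np.zeros(10))

    def test_single_carrier_pairwise_value(self):
        # replicates (2,0,0,0,0,0): sum |pairs| = 20, mean = 1/3 -> G = 20/24
        d = np.zeros((6, 1, 1))
        d[0, 0, 0] = 2.0
        assert snp_gini(_reps(d))[0] == pytest.approx(20 / 24)

    def test_zero_mean_individual_contributes_zero(self):
        d = np.zeros((4, 3, 1))
        d[:, 0, 0] = [1.0, 1.0, 0.0, 0.0]  # only first individual varies
        g = snp_gini(_reps(d))
        assert g[0] == pytest.approx(oracle_gini([1.0, 1.0, 0.0, 0.0]) / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 2, (6, 15, 8))
        got = snp_gini(_reps(d))
        want = np.array(
            [
                np.mean([oracle_gini(list(d[:, i, j])) for i in range(15)])
                for j in range(8)
            ]
        )
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 2, (6, 30, 12))
        g = snp_gini(_reps(d))
        assert ((g >= 0) & (g <= 1)).all()
        np.testing.assert_allclose(g, snp_gini(_reps(np.clip(0.5 * d, 0, 2))), atol=1e-10)

    def test_pooled_aggregation_differs_but_bounded(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0, 2, (5, 20, 4))
        g = snp_gini(_reps(d), aggregation="pooled")
        assert ((g >= 0) & (g <= 1)).all()

    def test_typed_snps_zero_on_emulator_output(self, small_sim, small_replicates):
        g = snp_gini(small_replicates)
        assert (g[small_sim["mask"]] == 0).all()

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            snp_gini(_reps(np.zeros((1, 2, 2))))


class TestPercentVarianceExplained:
    def _model(self, variants, weights):
        return pd.DataFrame(
            {
                "rsID": variants["id"],
                "chr_name": variants["chrom"],
                "chr_position": variants["pos"],
                "effect_allele": variants["alt"],
                "other_allele": variants["ref"],
                "effect_weight": weights,
            }
        )

    def test_single_variant_is_100(self):
        variants = default_variant_table(1)
        m = DosageMatrix(["a", "b", "c"], variants, np.array([[0.0], [1.0], [2.0]]))
        pve = percent_variance_explained(self._model(variants, [0.3]), m)
        assert pve[0] == pytest.approx(100.0)

    def test_symmetric_split(self):
        variants = default_variant_table(2)
        d = np.array([[0.0, 2.0], [2.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        pve = percent_variance_explained(self._model(variants, [0.5, 0.5]), m := DosageMatrix(["a", "b", "c", "d"], variants, d))
        np.testing.assert_allclose(pve, [50.0, 50.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_variance_normalize_oracle(self, seed):
        rng = np.random.default_rng(seed)
        variants = default_variant_table(20)
        d = rng.uniform(0, 2, (40, 20))
        w = rng.normal(size=20)
        m = DosageMatrix([f"s{i}" for i in range(40)], variants, d)
        got = percent_variance_explained(self._model(variants, w), m)
        v = [w[j] ** 2 * np.var(d[:, j]) for j in range(20)]
        want = 100.0 * np.array(v) / sum(v)
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert got.sum() == pytest.approx(100.0, abs=1e-6)

    def test_hwe_variance_closed_form(self):
        # under random mating, Var(dosage) ~ 2 p (1 - p)
        rng = np.random.default_rng(8)
        p = np.array([0.1, 0.3, 0.5])
        d = (rng.random((20000, 3)) < p).astype(int) + (rng.random((20000, 3)) < p)
        variants = default_variant_table(3)
        m = DosageMatrix([f"s{i}" for i in range(20000)], variants, d.astype(float))
        w = np.array([1.0, 1.0, 1.0])
        got = percent_variance_explained(self._model(variants, w), m)
        v = 2 * p * (1 - p)
        want = 100.0 * v / v.sum()
        np.testing.assert_allclose(got, want, rtol=0.05)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        variants = default_variant_table(5)
        d = rng.uniform(0, 2, (30, 5))
        w = rng.normal(size=5)
        m = DosageMatrix([f"s{i}" for i in range(30)], variants, d)
        a = percent_variance_explained(self._model(variants, w), m)
        b = percent_variance_explained(self._model(variants, 3.0 * w), m)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_degenerate_score_rejected(self):
        variants = default_variant_table(2)
        m = DosageMatrix(["a", "b"], variants, np.ones((2, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            percent_variance_explained(self._model(variants, [1.0, 1.0]), m)


class TestQuadrants:
    def test_partition_and_zero_gini(self, small_sim, small_replicates):
        table = gini_pve_table(
            small_replicates, small_sim["model"], small_sim["cohort"].truth
        )
        out = contribution_quadrants(table, gini_cut=0.1, pve_cut=1.0)
        assert len(out) == len(table)
        assert out["quadrant"].notna().all()
        zero_g = out[out["gini"] == 0]
        assert zero_g["quadrant"].str.endswith("low_gini").all()

    def test_planted_noisy_high_weight_snp(self):
        rng = np.random.default_rng(10)
        n, m = 300, 10
        variants = default_variant_table(m)
        truth_d = rng.integers(0, 3, (n, m)).astype(float)
        rep_d = np.stack([truth_d.copy() for _ in range(6)])
        rep_d[:, :, 0] = np.clip(
            truth_d[:, 0] + rng.normal(0, 0.5, (6, n)), 0, 2
        )  # planted: SNP 0 noisy across replicates
        typed = np.ones(m, dtype=bool)
        typed[0] = False
        reps = _reps(rep_d, typed)
        w = np.full(m, 0.05)
        w[0] = 1.0  # planted high weight
        model = TestPercentVarianceExplained()._model(variants, w)
        truth = DosageMatrix([f"s{i}" for i in range(n)], variants, truth_d)
        table = gini_pve_table(reps, model, truth)
        out = contribution_quadrants(table, gini_cut=0.01, pve_cut=50.0)
        assert out.iloc[0]["quadrant"] == "high_pve_high_gini"
        assert out.iloc[0]["gini"] > table[table["typed"]]["gini"].max()

    def test_invalid_cuts_rejected(self):
        table = pd.DataFrame({"gini": [0.1], "pve": [10.0]})
        with pytest.raises(ValueError):
            contribution_quadrants(table, gini_cut=1.5)
        with pytest.raises(ValueError):
            contribution_quadrants(table, pve_cut=0.0)

    def test_low_gini_majority_on_sampled_emulator(self, small_sim, small_replicates):
        g = snp_gini(small_replicates)[~small_sim["mask"]]
        assert np.percentile(g, 90) >= 2 * np.median(g)
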