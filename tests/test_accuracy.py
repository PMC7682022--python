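"""Imputation accuracy metrics: R2, F-score, IQS, MAF bins, paired tests."""
import numpy as np
import pytest

from prsvar.accuracy import (
    best_tag_ld,
    calls_from_dosage,
    dosage_r2,
    genotype_fscore,
    iqs,
    maf_binned_accuracy,
    paired_process_comparison,
    per_individual_r2_summary,
)
from prsvar.containers import DosageMatrix, ReplicateSet, default_variant_table


def _replicate_set(truth_dosages, rep_dosages, typed=None):
    truth_dosages = np.asarray(truth_dosages, dtype=float)
    n, m = truth_dosages.shape
    variants = default_variant_table(m)
    samples = [f"s{i}" for i in range(n)]
    truth = DosageMatrix(samples, variants, truth_dosages)
    if typed is None:
        typed = np.zeros(m, dtype=bool)
    reps = ReplicateSet(
        process="test",
        samples=samples,
        variants=variants,
        dosages=np.asarray(rep_dosages, dtype=float),
        typed_mask=typed,
        seeds=[0] * len(rep_dosages),
    )
    return truth, reps


def oracle_r2(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return 0.0 if va == 0 or vb == 0 else cov**2 / (va * vb)


def oracle_confusion(imp, tru):
    table = np.zeros((3, 3))
    for i, t in zip(imp, tru):
        table[i, t] += 1
    return table


def oracle_fscore(imp, tru):
    table = oracle_confusion(imp, tru)
    f1s = []
    for c in range(3):
        if table[:, c].sum() == 0:
            continue
        p = table[c, c] / table[c, :].sum() if table[c, :].sum() else 0.0
        r = table[c, c] / table[:, c].sum()
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return float(np.mean(f1s))


def oracle_iqs(imp, tru):
    table = oracle_confusion(imp, tru)
    n = table.sum()
    po = np.trace(table) / n
    pe = sum(table[i, :].sum() * table[:, i].sum() for i in range(3)) / n**2
    if pe >= 1 - 1e-12:
        return 1.0 if po >= 1 - 1e-12 else 0.0
    return (po - pe) / (1 - pe)


class TestDosageR2:
    def test_perfect_and_degenerate(self):
        x = np.array([0.0, 1.0, 2.0, 1.0])
        assert dosage_r2(x, x) == pytest.approx(1.0)
        assert dosage_r2(np.full(4, 1.0), x) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covariance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 2, 50), rng.uniform(0, 2, 50)
        assert dosage_r2(a, b) == pytest.approx(oracle_r2(a, b), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 2, 30), rng.uniform(0, 2, 30)
        assert dosage_r2(0.5 * a + 0.2, b) == pytest.approx(dosage_r2(a, b), abs=1e-10)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            dosage_r2(np.array([1.0]), np.array([1.0]))


class TestPerIndividualR2:
    def test_perfect_replicates(self):
        rng = np.random.default_rng(2)
        truth_d = rng.integers(0, 3, (10, 20)).astype(float)
        truth, reps = _replicate_set(truth_d, np.stack([truth_d] * 3))
        for agg in ("mean", "min"):
            got = per_individual_r2_summary(reps, truth, agg)
            np.testing.assert_allclose(got, 1.0)

    def test_aggregation_against_per_replicate_loop(self):
        rng = np.random.default_rng(3)
        truth_d = rng.integers(0, 3, (8, 30)).astype(float)
        rep_d = np.clip(truth_d + rng.normal(0, 0.4, (2, 8, 30)), 0, 2)
        truth, reps = _replicate_set(truth_d, rep_d)
        per_rep = np.array(
            [
                [oracle_r2(rep_d[k][i], truth_d[i]) for i in range(8)]
                for k in range(2)
            ]
        )
        np.testing.assert_allclose(
            per_individual_r2_summary(reps, truth, "mean"), per_rep.mean(axis=0),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            per_individual_r2_summary(reps, truth, "min"), per_rep.min(axis=0),
            atol=1e-10,
        )

    def test_min_left_shifted_under_run_noise(self, small_sim):
        from prsvar.emulator import EmulatorConfig, emulate_parametric

        truth = small_sim["cohort"].truth
        cfg = EmulatorConfig(mode="parametric", r2_target=0.8, sigma_run=0.3, k=6)
        reps = emulate_parametric(truth, small_sim["mask"], cfg, master_seed=4)
        med_mean = np.median(per_individual_r2_summary(reps, truth, "mean"))
        med_min = np.median(per_individual_r2_summary(reps, truth, "min"))
        assert med_min < med_mean


class TestGenotypeMetrics:
    def test_calls_from_dosage_rounding(self):
        d = np.array([0.0, 0.49, 0.5, 0.51, 1.5, 1.51, 2.0])
        np.testing.assert_array_equal(calls_from_dosage(d), [0, 0, 0, 1, 1, 2, 2])

    def test_fscore_perfect_and_disjoint(self):
        tru = np.array([0, 1, 2, 1, 0])
        assert genotype_fscore(tru, tru) == pytest.approx(1.0)
        assert genotype_fscore(np.full(5, 2), np.zeros(5, int)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_fscore_matches_confusion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        imp, tru = rng.integers(0, 3, 20), rng.integers(0, 3, 20)
        assert genotype_fscore(imp, tru) == pytest.approx(oracle_fscore(imp, tru))

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            genotype_fscore(np.array([3]), np.array([0]))

    def test_iqs_perfect(self):
        tru = np.array([0, 1, 2, 1])
        assert iqs(tru, tru) == pytest.approx(1.0)

    def test_iqs_independent_shuffles_near_zero(self):
        rng = np.random.default_rng(6)
        tru = rng.integers(0, 3, 300)
        vals = []
        for _ in range(200):
            vals.append(iqs(rng.permutation(tru), tru))
        assert abs(np.mean(vals)) < 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_iqs_matches_kappa_oracle(self, seed):
        rng = np.random.default_rng(seed)
        imp, tru = rng.integers(0, 3, 40), rng.integers(0, 3, 40)
        assert iqs(imp, tru) == pytest.approx(oracle_iqs(imp, tru), abs=1e-12)

    def test_iqs_bounded_by_agreement(self):
        rng = np.random.default_rng(7)
        imp, tru = rng.integers(0, 3, 100), rng.integers(0, 3, 100)
        agreement = np.mean(imp == tru)
        assert iqs(imp, tru) <= agreement + 1e-12


class TestMafBinned:
    def test_single_bin_reproduces_unbinned(self):
        rng = np.random.default_rng(8)
        truth_d = rng.integers(0, 3, (50, 10)).astype(float)
        rep_d = np.clip(truth_d + rng.normal(0, 0.3, (2, 50, 10)), 0, 2)
        truth, reps = _replicate_set(truth_d, rep_d)
        table = maf_binned_accuracy(reps, truth, bins=(0.0, 0.5))
        from prsvar.accuracy import per_variant_accuracy

        all_r2 = per_variant_accuracy(reps, truth)["r2"]
        assert table.iloc[0]["r2_min"] == pytest.approx(all_r2.min())
        assert table.iloc[0]["r2_median"] == pytest.approx(np.median(all_r2))
        assert table.iloc[0]["r2_max"] == pytest.approx(all_r2.max())

    def test_cut_point_assigned_to_lower_bin(self):
        # variant with MAF exactly 0.05 must land in the (0.01, 0.05] bin
        truth_d = np.zeros((10, 1))
        truth_d[:1, 0] = 1.0  # mean dosage 0.1 -> MAF 0.05
        rep_d = truth_d[None, :, :].repeat(2, axis=0)
        truth, reps = _replicate_set(truth_d, rep_d)
        table = maf_binned_accuracy(reps, truth)
        row = table[table["n"] > 0].iloc[0]
        assert row["maf_bin"] == "(0.01,0.05]"

    def test_rare_bin_has_widest_r2_range(self):
        # noise scaled up at rare variants: their accuracy spread dominates
        rng = np.random.default_rng(9)
        p = np.concatenate([np.full(20, 0.004), np.full(20, 0.3)])
        truth_d = (rng.random((400, 40)) < p).astype(float) + (
            rng.random((400, 40)) < p
        )
        sd = np.where(p < 0.01, rng.uniform(0, 0.6, 40), 0.05)
        rep_d = np.clip(truth_d + rng.normal(0, 1, (3, 400, 40)) * sd, 0, 2)
        truth, reps = _replicate_set(truth_d, rep_d)
        table = maf_binned_accuracy(reps, truth).set_index("maf_bin")
        spread = table["r2_max"] - table["r2_min"]
        assert spread["(0,0.005]"] >= spread["(0.1,0.5]"]


class TestPairedComparison:
    def test_equal_inputs_flagged_degenerate(self):
        x = np.arange(10, dtype=float)
        out = paired_process_comparison(x, x)
        assert out["degenerate"] and out["pvalue"] == 1.0

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0.5, 1.0, 50)
        out = paired_process_comparison(a, a - 0.1)
        assert out["pvalue"] < 1e-6

    def test_type_i_error_control(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            d = rng.normal(0, 1, 200)
            out = paired_process_comparison(d, np.zeros(200))
            rejections += out["pvalue"] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < 3 * se


class TestBestTagLd:
    def test_duplicated_snp_has_r2_one(self):
        rng = np.random.default_rng(12)
        col = rng.integers(0, 3, 100).astype(float)
        other = rng.integers(0, 3, 100).astype(float)
        d = np.column_stack([col, other, col])
        m = DosageMatrix([f"s{i}" for i in range(100)], default_variant_table(3), d)
        out = best_tag_ld(m, np.array([True, False, False]))
        idx = list(out["ids"]).index(m.variants["id"].iloc[2])
        assert out["best_r2"][idx] == pytest.approx(1.0)

    def test_independent_snps_low_r2_and_nested_fractions(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, (2000, 12)).astype(float)
        m = DosageMatrix([f"s{i}" for i in range(2000)], default_variant_table(12), d)
        typed = np.zeros(12, dtype=bool)
        typed[:4] = True
        out = best_tag_ld(m, typed)
        # max over 4 independent pairs: ~chi2(1)/n scale, Bonferroni allowance
        assert out["best_r2"].max() < 16.0 / 2000
        f = [out["fractions"][t] for t in (0.5, 0.8, 0.9)]
        assert f[0] >= f[1] >= f[2]

    def test_requires_typed_snp(self):
        m = DosageMatrix(["s0", "s1"], default_variant_table(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            best_tag_ld(m, np.array([False, False]))
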