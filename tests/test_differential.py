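"""Donor centering, fold changes, Student and moderated t, BH adjustment."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phospipe import differential
from phospipe.containers import DesignError, IntensityMatrix


def _design(samples, treatments, donors=None, timepoints=None):
    n = len(samples)
    return pd.DataFrame({
        "sample_id": samples, "genotype": "g",
        "donor": donors or ["d1"] * n,
        "replicate": range(1, n + 1), "treatment": treatments,
        "dose": [0.0 if t == "vehicle" else 100.0 for t in treatments],
        "timepoint": timepoints or [30.0] * n,
        "assay": "global", "cell_type": "CD4T",
    })


class TestCenterByDonor:
    def test_single_donor_identity(self):
        values = pd.DataFrame(np.arange(8, dtype=float).reshape(2, 4),
                              columns=list("abcd"))
        mat = IntensityMatrix(values, "log2")
        design = _design(list("abcd"), ["IFN-b"] * 4)
        out = differential.center_by_donor(mat, design)
        pd.testing.assert_frame_equal(out.values, values)

    def test_constant_donor_offset_removed(self):
        base = np.array([[1.0, 2.0], [5.0, 6.0]])
        values = pd.DataFrame(
            np.hstack([base, base + 3.0]), columns=list("abcd"))
        mat = IntensityMatrix(values, "log2")
        design = _design(list("abcd"), ["IFN-b", "vehicle"] * 2,
                         donors=["d1", "d1", "d2", "d2"])
        out = differential.center_by_donor(mat, design)
        # offset gone: both donors now have identical centered blocks
        np.testing.assert_allclose(out.values[["a", "b"]].to_numpy(),
                                   out.values[["c", "d"]].to_numpy())
        # within-donor differences untouched
        np.testing.assert_allclose(
            out.values["a"] - out.values["b"], base[:, 0] - base[:, 1])

    def test_within_donor_contrasts_preserved(self, simulate_screen):
        complete, _, _, design, _ = simulate_screen(seed=3, n_features=100,
                                                    donor_sigma=1.0)
        centered = differential.center_by_donor(complete, design)
        for donor, grp in design.groupby("donor"):
            t = grp.loc[grp["treatment"] != "vehicle", "sample_id"].tolist()
            v = grp.loc[grp["treatment"] == "vehicle", "sample_id"].tolist()
            before = (complete.values[t].mean(axis=1)
                      - complete.values[v].mean(axis=1))
            after = (centered.values[t].mean(axis=1)
                     - centered.values[v].mean(axis=1))
            np.testing.assert_allclose(before, after, atol=1e-10)

    def test_between_donor_variance_removed(self, simulate_screen):
        complete, _, _, design, _ = simulate_screen(seed=4, n_features=100,
                                                    donor_sigma=1.0)
        centered = differential.center_by_donor(complete, design)
        donor_means = []
        for donor, grp in design.groupby("donor"):
            donor_means.append(
                centered.values[grp["sample_id"].tolist()].mean(axis=1))
        spread = np.var(np.stack(donor_means), axis=0)
        np.testing.assert_allclose(spread, 0.0, atol=1e-10)


class TestFoldChange:
    def test_zero_when_means_equal(self):
        values = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], columns=list("abcd"))
        mat = IntensityMatrix(values, "log2")
        design = _design(list("abcd"), ["IFN-b", "IFN-b", "vehicle", "vehicle"])
        fc = differential.fold_change_vs_control(mat, design)
        assert fc["log2fc"].iloc[0] == 0.0

    def test_unit_difference(self):
        values = pd.DataFrame([[5.0] * 4 + [4.0] * 4],
                              columns=[f"s{i}" for i in range(8)])
        mat = IntensityMatrix(values, "log2")
        design = _design(list(values.columns),
                         ["IFN-b"] * 4 + ["vehicle"] * 4)
        fc = differential.fold_change_vs_control(mat, design)
        assert fc["log2fc"].iloc[0] == 1.0

    def test_unmatched_timepoint_raises(self):
        values = pd.DataFrame([[5.0, 4.0]], columns=["a", "b"])
        mat = IntensityMatrix(values, "log2")
        design = _design(["a", "b"], ["IFN-b", "vehicle"],
                         timepoints=[30.0, 240.0])
        with pytest.raises(DesignError, match="timepoint=30"):
            differential.fold_change_vs_control(mat, design)

    def test_antisymmetric_under_role_swap(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(rng.normal(0, 1, size=(20, 8)),
                              columns=[f"s{i}" for i in range(8)])
        mat = IntensityMatrix(values, "log2")
        fwd = _design(list(values.columns), ["IFN-b"] * 4 + ["vehicle"] * 4)
        rev = _design(list(values.columns), ["vehicle"] * 4 + ["IFN-b"] * 4)
        fc_fwd = differential.fold_change_vs_control(mat, fwd)
        fc_rev = differential.fold_change_vs_control(mat, rev)
        np.testing.assert_allclose(fc_fwd["log2fc"], -fc_rev["log2fc"])


class TestStudentT:
    def test_identical_groups(self):
        t, p = differential.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_permutation_invariant_null(self):
        t, _ = differential.student_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)

    def test_matches_pooled_formula_by_hand(self):
        a, b = np.array([0.0, 1.0]), np.array([2.0, 3.0])
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (0.5 + 0.5))
        t, p = differential.student_t(a, b)
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), 2))

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(size=7)
            t, p = differential.student_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        a = rng.normal(size=(10_000, 4))
        b = rng.normal(size=(10_000, 4))
        p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
        mine = np.array([differential.student_t(a[i], b[i])[1]
                         for i in range(0, 10_000, 10)])
        np.testing.assert_allclose(mine, p[::10])
        assert 0.04 <= (p < 0.05).mean() <= 0.06


class TestModeratedT:
    def _pooled(self, rng, n_feat=100):
        a = rng.normal(0, 0.5, size=(n_feat, 4))
        b = rng.normal(0.3, 0.5, size=(n_feat, 4))
        fc = b.mean(axis=1) - a.mean(axis=1)
        s2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
        return fc, s2

    def test_d0_zero_reproduces_student(self):
        rng = np.random.default_rng(21)
        fc, s2 = self._pooled(rng)
        prior = differential.VariancePrior(d0=0.0, s0_2=1.0)
        mod = differential.moderated_t(fc, s2, 6.0, np.sqrt(0.5), prior=prior)
        student_t = fc / (np.sqrt(s2) * np.sqrt(0.5))
        np.testing.assert_allclose(mod["t"], student_t, atol=1e-10)
        np.testing.assert_allclose(
            mod["p"], 2 * stats.t.sf(np.abs(student_t), 6), atol=1e-10)

    def test_d0_infinite_uses_prior_variance_exactly(self):
        rng = np.random.default_rng(22)
        fc, s2 = self._pooled(rng)
        prior = differential.VariancePrior(d0=np.inf, s0_2=0.04)
        mod = differential.moderated_t(fc, s2, 6.0, np.sqrt(0.5), prior=prior)
        np.testing.assert_allclose(mod["s2_post"], 0.04)
        np.testing.assert_allclose(
            mod["t"], fc / (0.2 * np.sqrt(0.5)), atol=1e-12)

    def test_prior_recovery_on_simulated_variances(self):
        d0_true, s02_true, d = 8.0, 0.05, 6.0
        rng = np.random.default_rng(23)
        d0s, s02s = [], []
        for _ in range(10):
            sigma2 = s02_true * d0_true / rng.chisquare(d0_true, size=500)
            s2 = sigma2 * rng.chisquare(d, size=500) / d
            prior = differential.fit_variance_prior(s2, d)
            d0s.append(prior.d0)
            s02s.append(prior.s0_2)
        assert abs(np.mean(d0s) - d0_true) / d0_true < 0.25
        assert abs(np.mean(s02s) - s02_true) / s02_true < 0.25

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for x in (0.01, 0.5, 3.0, 50.0):
            y = float(polygamma(1, x))
            assert differential.trigamma_inverse(y) == pytest.approx(x,
                                                                     rel=1e-6)

    def test_matches_limma_ebayes(self, tmp_path):
        """Dual-route check against the reference empirical-Bayes fit."""
        rng = np.random.default_rng(42)
        n, d0, s02 = 60, 8.0, 0.05
        sigma2 = s02 * d0 / rng.chisquare(d0, size=n)
        data = np.concatenate([
            rng.normal(0, np.sqrt(sigma2)[:, None], (n, 4)),
            rng.normal(0.5, np.sqrt(sigma2)[:, None], (n, 4))], axis=1)
        fixture = tmp_path / "matrix.tsv"
        pd.DataFrame(data).to_csv(fixture, sep="\t", index=False)
        rscript = tmp_path / "ebayes.R"
        rscript.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{fixture}"))\n'
            'design <- cbind(Intercept=1, Group=c(rep(0,4), rep(1,4)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"],\n'
            '                  d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path / "out.tsv"}", sep="\\t", '
            'row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(rscript)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        a, b = data[:, :4], data[:, 4:]
        fc = b.mean(axis=1) - a.mean(axis=1)
        s2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
        mod = differential.moderated_t(fc, s2, 6.0, np.sqrt(0.5))
        assert mod["d0"][0] == pytest.approx(ref["d0"][0], rel=1e-6)
        assert mod["s0_2"][0] == pytest.approx(ref["s02"][0], rel=1e-6)
        np.testing.assert_allclose(mod["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(mod["p"], ref["p"], rtol=1e-8)


from oracles import bh_brute_force  # noqa: E402  (test-side oracle)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(differential.bh_adjust([0.03]), [0.03])

    def test_small_example(self):
        np.testing.assert_allclose(
            differential.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(
            differential.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.5], [np.nan]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            differential.bh_adjust(bad)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1.0, size=n)
            np.testing.assert_allclose(differential.bh_adjust(p),
                                       bh_brute_force(p), atol=1e-12)


class TestDifferentialTable:
    def test_spiked_feature_detected(self, simulate_screen):
        complete, _, _, design, truth = simulate_screen(
            seed=30, n_features=200, n_induced=5, timepoints=(1440.0,),
            induced_effect=3.0, noise_sigma=0.3)
        centered = differential.center_by_donor(complete, design)
        table = differential.differential_table(centered, design,
                                                engine="moderated")
        scramble = table[table["genotype"] == "scramble1"]
        spiked = scramble[scramble["feature_id"].isin(truth.induced_set)]
        assert ((spiked["adj_p"] < 0.05) & (spiked["log2fc"] > 0.75)).all()

    def test_engines_agree_on_homogeneous_variance(self):
        # eight replicates: enough residual df that shrinkage barely
        # reorders the statistics
        from phospipe import io_formats, preprocess
        from phospipe import synthetic_data as sd
        truth = sd.default_truth(seed=31, n_induced=0, n_active_kinases=0)
        design = sd.generate_design(1, 1, 8, [30.0], include_vehicle=True,
                                    assay="global")
        report, _ = sd.simulate_dataset(design, truth, 300)
        complete = preprocess.normalize(
            io_formats.pivot_to_matrix(report, design, "protein"))
        centered = differential.center_by_donor(complete, design)
        student = differential.differential_table(centered, design, "student")
        moderated = differential.differential_table(centered, design,
                                                    "moderated")
        merged = student.merge(moderated,
                               on=["feature_id"] + differential.COMPARISON_KEYS,
                               suffixes=("_s", "_m"))
        rho = merged.groupby("genotype").apply(
            lambda g: g["t_statistic_s"].corr(g["t_statistic_m"],
                                              method="spearman"),
            include_groups=False)
        assert (rho >= 0.99).all()
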