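import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from nemafauna.stats import paired_t, paired_t_by_day, rda, two_way_anova


def anova_oracle(y, a, b):
    """Brute-force cell-means sums of squares for a balanced two-way design."""
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = df["y"].mean()
    ss_total = ((df["y"] - grand) ** 2).sum()
    mean_a = df.groupby("a")["y"].mean()
    mean_b = df.groupby("b")["y"].mean()
    mean_ab = df.groupby(["a", "b"])["y"].mean()
    n_a = df.groupby("a").size()
    n_b = df.groupby("b").size()
    n_ab = df.groupby(["a", "b"]).size()
    ss_a = (n_a * (mean_a - grand) ** 2).sum()
    ss_b = (n_b * (mean_b - grand) ** 2).sum()
    fitted = df.set_index(["a", "b"]).index.map(mean_ab)
    ss_model = (n_ab * (mean_ab - grand) ** 2).sum()
    ss_ab = ss_model - ss_a - ss_b
    ss_resid = ((df["y"] - np.asarray(fitted)) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_resid, ss_total


class TestTwoWayAnova:
    def test_matches_brute_force_on_random_balanced_design(self):
        rng = np.random.default_rng(3)
        a = np.repeat(["impacted", "control"], 24)
        b = np.tile(np.repeat([0, 15, 40, 110], 6), 2)
        y = rng.normal(10, 3, size=48) + 5 * (a == "impacted") * (b == 40)
        table = two_way_anova(y, a, b)
        ss_a, ss_b, ss_ab, ss_resid, ss_total = anova_oracle(y, a, b)
        got = table.table["sum_sq"]
        assert got["C(A)"] == pytest.approx(ss_a, rel=1e-10)
        assert got["C(B)"] == pytest.approx(ss_b, rel=1e-10)
        assert got["C(A):C(B)"] == pytest.approx(ss_ab, rel=1e-10)
        assert got["Residual"] == pytest.approx(ss_resid, rel=1e-10)

    def test_ss_conservation(self):
        rng = np.random.default_rng(11)
        a = np.repeat([0, 1], 18)
        b = np.tile(np.repeat([0, 1, 2], 6), 2)
        y = rng.gamma(2, 5, size=36)
        table = two_way_anova(y, a, b)
        total = ((y - y.mean()) ** 2).sum()
        assert table.total_ss == pytest.approx(total, rel=1e-9)

    def test_perfect_fit_limit(self):
        # response = cell index exactly: zero residual, p -> 0 flagged
        a = np.repeat([0, 1], 4)
        b = np.tile([0, 0, 1, 1], 2)
        y = (2 * a + b).astype(float)
        table = two_way_anova(y, a, b)
        assert "perfect_fit" in table.flags
        assert table.p_value("C(A)") == 0.0
        assert table.p_value("C(B)") == 0.0

    def test_constant_response_degenerate(self):
        a = np.repeat([0, 1], 4)
        b = np.tile([0, 0, 1, 1], 2)
        table = two_way_anova(np.ones(8), a, b)
        assert "degenerate" in table.flags
        assert (table.table.loc[["C(A)", "C(B)", "C(A):C(B)"], "F"] == 0).all()

    def test_empty_cell_errors(self):
        a = [0, 0, 1, 1]
        b = [0, 1, 0, 0]  # cell (1, 1) empty
        with pytest.raises(ValueError, match="empty cells"):
            two_way_anova([1.0, 2.0, 3.0, 4.0], a, b)

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError, match="levels"):
            two_way_anova([1.0, 2.0], [0, 0], [0, 1])

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(2024)
        a = np.repeat([0, 1], 12)
        b = np.tile(np.repeat([0, 1, 2], 4), 2)
        n_sims, hits = 250, 0
        for _ in range(n_sims):
            y = rng.normal(size=24)
            hits += two_way_anova(y, a, b).p_value("C(A)") < 0.05
        rate = hits / n_sims
        ci = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < ci


class TestPairedT:
    def test_hand_computed_three_pairs(self):
        res = paired_t([1, 2, 3], [2, 4, 3])
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.t == pytest.approx(-np.sqrt(3), rel=1e-9)
        assert res.df == 2

    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_single_pair_errors(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])

    def test_zero_variance_nonzero_shift_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p == 0.0 and res.t == np.inf

    def test_antisymmetric(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=8)
        fwd, rev = paired_t(x, y), paired_t(y, x)
        assert rev.t == pytest.approx(-fwd.t)
        assert rev.p == pytest.approx(fwd.p)

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(99)
        n_sims, hits = 2000, 0
        for _ in range(n_sims):
            x, y = rng.normal(size=(2, 6))
            hits += paired_t(x, y).p < 0.05
        rate = hits / n_sims
        ci = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < ci

    def test_by_day_pairs_sites(self):
        wide = pd.DataFrame(
            {
                "site": [1, 2, 3, 1, 2, 3],
                "treatment": ["impacted"] * 3 + ["control"] * 3,
                "study_day": [0] * 6,
                "richness": [1.0, 2.0, 3.0, 2.0, 4.0, 3.0],
            }
        )
        out = paired_t_by_day(wide, "richness")
        assert len(out) == 1
        assert out["mean_difference"].iloc[0] == pytest.approx(-1.0)
        assert out["df"].iloc[0] == 2


class TestRda:
    @staticmethod
    def _toy(seed=0, n=12, p=5, groups=("a", "b", "c")):
        rng = np.random.default_rng(seed)
        g = np.repeat(groups, n // len(groups))
        shift = {lvl: rng.normal(0, 3, size=p) for lvl in groups}
        Y = rng.normal(10, 1, size=(n, p)) + np.array([shift[x] for x in g])
        return pd.DataFrame(Y, columns=[f"t{j}" for j in range(p)]), g

    def test_single_group_unconstrained(self):
        Y, _ = self._toy()
        res = rda(Y, ["g"] * len(Y))
        assert res.constrained_proportion == pytest.approx(0.0, abs=1e-12)
        assert res.eigenvalues.size == 0

    def test_saturated_design_fully_constrained(self):
        Y, _ = self._toy()
        res = rda(Y, np.arange(len(Y)))
        assert res.constrained_proportion == pytest.approx(1.0)

    def test_eigenvalues_match_dense_eigendecomposition(self):
        Y, g = self._toy(seed=8, n=6, p=4, groups=("a", "b"))
        res = rda(Y, g)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        means = pd.DataFrame(Yc, index=g).groupby(level=0).transform("mean").to_numpy()
        cov_fit = means.T @ means / (len(Y) - 1)
        dense = np.sort(np.linalg.eigvalsh(cov_fit))[::-1]
        assert res.eigenvalues[0] == pytest.approx(dense[0], rel=1e-9)

    def test_variance_decomposition(self):
        Y, g = self._toy(seed=2)
        res = rda(Y, g)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        total = (Yc**2).sum()
        fitted = res.constrained_proportion * total
        resid = total - fitted
        assert fitted + resid == pytest.approx(total, rel=1e-9)
        # canonical eigenvalues sum to the constrained variance
        assert res.eigenvalues.sum() == pytest.approx(fitted / (len(Y) - 1), rel=1e-9)

    def test_scores_invariant_to_sample_order(self):
        Y, g = self._toy(seed=4)
        res = rda(Y, g)
        perm = np.random.default_rng(1).permutation(len(Y))
        res_p = rda(Y.iloc[perm], np.asarray(g)[perm])
        np.testing.assert_allclose(
            res.site_scores.loc[Y.index].to_numpy(),
            res_p.site_scores.loc[Y.index].to_numpy(),
            atol=1e-9,
        )

    def test_more_groups_than_samples_errors(self):
        Y, _ = self._toy(n=3, groups=("a", "b", "c"))
        with pytest.raises(ValueError, match="groups"):
            rda(Y.iloc[:2], ["a", "b", "c"][:3])

    def test_centroids_and_sd_shapes(self):
        Y, g = self._toy(seed=6)
        res = rda(Y, g)
        assert list(res.centroids.index) == ["a", "b", "c"]
        assert res.group_sd.shape == res.centroids.shape
        assert (res.group_sd.to_numpy() >= 0).all()

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_vegan(self, tmp_path):
        """Cross-check constrained eigenvalues against vegan's rda()."""
        Y, g = self._toy(seed=7)
        res = rda(Y, g)
        Y.to_csv(tmp_path / "Y.csv", index=False)
        pd.Series(g, name="g").to_csv(tmp_path / "g.csv", index=False)
        script = (
            'suppressMessages(library(vegan));'
            f'Y<-read.csv("{tmp_path}/Y.csv"); g<-read.csv("{tmp_path}/g.csv")$g;'
            'm<-rda(Y~g); cat(m$CCA$eig, sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vegan_eig = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(res.eigenvalues, vegan_eig, rtol=1e-6)
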