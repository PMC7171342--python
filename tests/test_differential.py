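import numpy as np
import pytest
from scipy import special

from amnioscan.differential import (
    BiomarkerRecord,
    PLSDA,
    biomarker_table,
    fit_plsda,
    fold_change,
    select_biomarkers,
    welch_t,
)
from amnioscan.simulate import CohortSpec, LogisticRise, generate_cohort
from amnioscan.extraction import build_matrix, tic_normalize

from conftest import make_matrix


def welch_oracle(a, b):
    """Welch statistic from the textbook formula, p via the regularised
    incomplete beta function — an independent route from the implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = special.betainc(df / 2, 0.5, df / (df + t * t))
    return t, df, p


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_case(self):
        t, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=2e-4)
        _, df, _ = welch_oracle([1, 2, 3], [4, 5, 6])
        assert df == pytest.approx(4.0)

    def test_antisymmetry(self):
        t1, p1 = welch_t([1.0, 2.5, 3.0], [4.0, 4.5, 7.0, 8.0])
        t2, p2 = welch_t([4.0, 4.5, 7.0, 8.0], [1.0, 2.5, 3.0])
        assert t1 == pytest.approx(-t2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_high_precision_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nb)
            t, p = welch_t(a, b)
            t_ref, _, p_ref = welch_oracle(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-8)

    def test_degenerate_groups(self):
        assert welch_t([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestFoldChange:
    @pytest.mark.parametrize("m, n, fc", [(10, 5, 2.0), (5, 10, 0.5), (7, 7, 1.0)])
    def test_arithmetic(self, m, n, fc):
        assert fold_change(m, n) == pytest.approx(fc)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(10.0, 0.0)


class TestPlsda:
    def _toy(self, seed=0, n=40, p=6, informative=True):
        rng = np.random.default_rng(seed)
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, p))
        if informative:
            X[:, 0] += np.where(y == "a", 1.5, -1.5)
        return X, y

    def test_scores_orthogonal(self):
        X, y = self._toy()
        res = PLSDA(X, y, n_components=3).fit()
        t = res.scores
        for i in range(3):
            for j in range(i + 1, 3):
                denom = np.linalg.norm(t[:, i]) * np.linalg.norm(t[:, j])
                assert abs(t[:, i] @ t[:, j]) <= 1e-8 * denom

    def test_first_weight_proportional_to_xy_covariance(self):
        """Single-component fit: the weight vector is the unit-normalised
        covariance of the (autoscaled) columns with centered y."""
        X, y = self._toy(seed=3, p=2)
        res = PLSDA(X, y, n_components=1).fit()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = (y == "b").astype(float)
        yc -= yc.mean()
        ref = Xs.T @ yc
        ref /= np.linalg.norm(ref)
        assert np.allclose(res.weights[0], ref, atol=1e-12) or np.allclose(
            res.weights[0], -ref, atol=1e-12
        )

    def test_matches_sklearn_first_component(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = self._toy(seed=8)
        res = PLSDA(X, y, n_components=2).fit()
        skl = PLSRegression(n_components=2, scale=True).fit(X, (y == "b").astype(float))
        w_mine, w_skl = res.weights[0], skl.x_weights_[:, 0]
        assert np.allclose(w_mine, w_skl, atol=1e-8) or np.allclose(
            w_mine, -w_skl, atol=1e-8
        )

    def test_permuted_labels_explain_little_y_variance(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(200, 5))
        y = np.repeat(["a", "b"], 100)
        rng.shuffle(y)
        res = PLSDA(X, y, n_components=2).fit()
        assert res.y_variance_explained.sum() < 0.1

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            PLSDA(X, ["a"] * 10, n_components=1)


class TestVip:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 1))
        y = (X[:, 0] > 0).astype(int)
        res = PLSDA(X, y, n_components=1).fit()
        assert res.vip().iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_single_component(self):
        """One component with unit-norm weights (0.8, 0.6):
        VIP = sqrt(p * w_j^2) = (sqrt(1.28), sqrt(0.72))."""
        res = PLSDA(np.zeros((4, 2)) + np.eye(4, 2), [0, 0, 1, 1], 1).fit()
        res.weights = np.array([[0.8, 0.6]])
        res.ssy = np.array([1.0])
        vips = res.vip().to_numpy()
        assert vips == pytest.approx([np.sqrt(1.28), np.sqrt(0.72)], abs=1e-12)

    def test_sum_of_squares_identity(self):
        """Sum_j VIP_j^2 == number of variables, for any fitted model."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n, p = int(rng.integers(8, 24)), int(rng.integers(2, 10))
            X = rng.normal(size=(n, p))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                y[0] = 1 - y[0]
            A = min(3, n - 1, p)
            res = PLSDA(X, y, n_components=A).fit()
            if not np.any(res.ssy > 0):
                continue
            vips = res.vip().to_numpy()
            assert (vips**2).sum() == pytest.approx(p, rel=1e-8)

    def test_error_when_nothing_explained(self):
        res = PLSDA(np.eye(4), [0, 0, 1, 1], 1).fit()
        res.ssy = np.zeros(1)
        with pytest.raises(ValueError, match="predictive"):
            res.vip()


class TestSelectBiomarkers:
    def _rec(self, name, fc, vip, p):
        return BiomarkerRecord(name, fc, vip, p)

    def test_rule_application(self):
        records = [
            self._rec("PC(20:4/0:0)", 6.7425, 1.54297, 4.729e-6),
            self._rec("fails_fc", 1.9, 1.5, 0.001),
            self._rec("edge_pass", 2.01, 1.11, 0.049),
            self._rec("fails_vip", 3.0, 1.1, 0.001),   # strict: 1.1 not > 1.1
            self._rec("fails_p", 3.0, 1.5, 0.05),      # strict: 0.05 not < 0.05
        ]
        selected = select_biomarkers(records)
        assert [r.species_name for r in selected] == ["PC(20:4/0:0)", "edge_pass"]
        assert all(r.selected for r in selected)

    def test_sorted_by_fold_change_then_name(self):
        records = [
            self._rec("b", 3.0, 2.0, 0.001),
            self._rec("a", 3.0, 2.0, 0.001),
            self._rec("c", 5.0, 2.0, 0.001),
        ]
        assert [r.species_name for r in select_biomarkers(records)] == ["c", "a", "b"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(6)
        records = [
            self._rec(f"sp{i}", float(rng.uniform(0.5, 8)), float(rng.uniform(0, 3)),
                      float(rng.uniform(0, 0.2)))
            for i in range(30)
        ]
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert select_biomarkers(records) == select_biomarkers(shuffled)


class TestPlantedRecovery:
    def test_selection_rule_recovers_planted_fold_changes(self, library):
        """10 species planted at true FC 4 among 151 (lecithin surge off,
        so the rest are null); n = 10 vs 10. The p<0.05 / VIP>1.1 / FC>2
        rule should recover >= 8/10 with <= 2 false positives."""
        planted = {n: 4.0 for n in library.names[70:75] + library.names[95:100]}
        spec = CohortSpec(
            seed=20,
            n_per_group=10,
            groups=("premature", "mature_gt38"),
            lecithin_rise=LogisticRise(max_multiplier=1.0),
            planted_biomarkers=planted,
        )
        peaklists, records = generate_cohort(spec, library)
        matrix = tic_normalize(build_matrix(peaklists, library))
        labels = [r.resolved_outcome() for r in records]
        table = biomarker_table(matrix, labels)
        selected = set(table.loc[table["selected"], "compound"])
        assert len(selected & set(planted)) >= 8
        assert len(selected - set(planted)) <= 2
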