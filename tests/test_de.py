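"""DE filter and robust residualization against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from follinet.de import (
    SignatureCriteria,
    compute_signature,
    huber_irls,
    residualize_batches,
    signature_overlap_counts,
    union_signatures,
    welch_t,
)
from follinet.simulate import SimulationConfig, Treatment, generate_expression


def welch_oracle(a, b):
    """Textbook Welch t with Welch-Satterthwaite degrees of freedom."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def naive_huber_irls(X, y, t=1.345, iters=200):
    """Scalar-path IRLS with Huber weights and median-centred MAD scale."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(iters):
        r = y - X @ beta
        s = np.median(np.abs(r - np.median(r))) / 0.6745
        s = max(s, 1e-12)
        w = np.array([1.0 if abs(ri) / s <= t else t / (abs(ri) / s) for ri in r])
        W = np.diag(w)
        beta_new = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        if np.max(np.abs(beta_new - beta)) < 1e-13 * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    return beta, y - X @ beta


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_textbook_formula(self):
        t, p = welch_t([10, 11, 12], [20, 21, 22])
        t0, p0 = welch_oracle([10, 11, 12], [20, 21, 22])
        assert abs(t - t0) < 1e-10 and abs(p - p0) < 1e-10

    def test_group_exchange_symmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=4)
        t1, p1 = welch_t(a, b)
        t2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_conventions(self):
        assert welch_t([5, 5], [5, 5]) == (0.0, 1.0)
        t, p = welch_t([6, 6], [5, 5])
        assert p == 0.0 and t == np.inf

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])

    def test_pooled_variant_matches_scipy(self, rng):
        from scipy.stats import ttest_ind

        a, b = rng.normal(size=4), rng.normal(size=6)
        t, p = welch_t(a, b, equal_var=True)
        t0, p0 = ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(t0)) and p == pytest.approx(float(p0))


def _brute_force_signature(expr, design, treatment, crit, control="control"):
    passing = set()
    trt_cols = design.loc[design["treatment"] == treatment, "sample_id"]
    ctl_cols = design.loc[design["treatment"] == control, "sample_id"]
    for g in expr.index:
        xt, xc = expr.loc[g, trt_cols], expr.loc[g, ctl_cols]
        fc = xt.mean() / xc.mean()
        diff = xt.mean() - xc.mean()
        _, p = welch_oracle(xt, xc) if xt.var(ddof=1) + xc.var(ddof=1) > 0 else (0, 1.0)
        if (
            (fc >= crit.fc_up or fc <= crit.fc_down)
            and p <= crit.p_max
            and abs(diff) >= crit.min_abs_diff
        ):
            passing.add(g)
    return passing


class TestComputeSignature:
    def _frame(self, rows, n_trt=3, n_ctl=3):
        genes = [f"g{i}" for i in range(len(rows))]
        cols = [f"t{i}" for i in range(n_trt)] + [f"c{i}" for i in range(n_ctl)]
        expr = pd.DataFrame(rows, index=genes, columns=cols)
        design = pd.DataFrame(
            {"sample_id": cols, "treatment": ["TRT"] * n_trt + ["control"] * n_ctl}
        )
        return expr, design

    def test_fold_change_and_diff_boundaries_inclusive(self):
        # means 120 vs 100: FC exactly 1.2 and diff 20 -> included
        # means 12 vs 10: FC 1.2 but diff 2 -> excluded
        expr, design = self._frame(
            [[119, 120, 121, 99, 100, 101], [11.9, 12, 12.1, 9.9, 10, 10.1]]
        )
        sig = compute_signature(expr, design, "TRT")
        assert "g0" in sig.genes and "g1" not in sig.genes
        rec = sig.records.set_index("gene_id")
        assert rec.loc["g0", "fold_change"] == pytest.approx(1.2)
        assert rec.loc["g0", "mean_diff"] == pytest.approx(20.0)
        assert rec.loc["g0", "direction"] == "up"

    def test_down_regulation_boundary(self):
        expr, design = self._frame([[82, 83, 84, 99, 100, 101]])
        sig = compute_signature(expr, design, "TRT")
        rec = sig.records.set_index("gene_id")
        assert rec.loc["g0", "fold_change"] == pytest.approx(0.83)
        assert rec.loc["g0", "direction"] == "down"
        assert "g0" in sig.genes

    def test_unknown_treatment_raises(self):
        expr, design = self._frame([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(KeyError):
            compute_signature(expr, design, "NOPE")

    def test_matches_brute_force_on_random_matrices(self, rng):
        crit = SignatureCriteria()
        for _ in range(5):
            x = rng.lognormal(mean=4.5, sigma=0.4, size=(50, 8))
            genes = [f"g{i}" for i in range(50)]
            cols = [f"s{i}" for i in range(8)]
            expr = pd.DataFrame(x, index=genes, columns=cols)
            design = pd.DataFrame(
                {"sample_id": cols, "treatment": ["TRT"] * 4 + ["control"] * 4}
            )
            sig = compute_signature(expr, design, "TRT", crit)
            assert sig.genes == _brute_force_signature(expr, design, "TRT", crit)

    def test_scale_coherence(self, rng):
        """Scaling all intensities by c scales diffs by c, leaves FC and p alone."""
        x = rng.lognormal(4.5, 0.3, size=(20, 8))
        genes = [f"g{i}" for i in range(20)]
        cols = [f"s{i}" for i in range(8)]
        design = pd.DataFrame(
            {"sample_id": cols, "treatment": ["TRT"] * 4 + ["control"] * 4}
        )
        a = compute_signature(pd.DataFrame(x, index=genes, columns=cols), design, "TRT")
        b = compute_signature(
            pd.DataFrame(3.0 * x, index=genes, columns=cols), design, "TRT"
        )
        assert np.allclose(a.records["fold_change"], b.records["fold_change"])
        assert np.allclose(a.records["p_value"], b.records["p_value"])
        assert np.allclose(3.0 * a.records["mean_diff"], b.records["mean_diff"])

    @given(
        fc_up=st.floats(1.05, 2.0),
        p_max=st.floats(0.001, 0.2),
        diff=st.floats(0.0, 50.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_tightening_criteria_never_grows_signature(self, fc_up, p_max, diff):
        rng = np.random.default_rng(99)
        x = rng.lognormal(4.5, 0.4, size=(30, 8))
        genes = [f"g{i}" for i in range(30)]
        cols = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame(x, index=genes, columns=cols)
        design = pd.DataFrame(
            {"sample_id": cols, "treatment": ["TRT"] * 4 + ["control"] * 4}
        )
        loose = compute_signature(expr, design, "TRT", SignatureCriteria())
        tight = compute_signature(
            expr, design, "TRT",
            SignatureCriteria(
                fc_up=max(1.2, fc_up),
                fc_down=min(0.83, 1 / max(1.2, fc_up)),
                p_max=min(0.05, p_max),
                min_abs_diff=max(10.0, diff),
            ),
        )
        assert tight.genes <= loose.genes


class TestUnionsAndOverlaps:
    def _sig(self, name, genes):
        from follinet.de import SignatureList

        return SignatureList(treatment=name, records=pd.DataFrame(), genes=set(genes))

    def test_union_basic(self):
        out = union_signatures([self._sig("a", {"g1", "g2"}), self._sig("b", {"g2", "g3"})])
        assert out == {"g1", "g2", "g3"}

    def test_union_disjoint_sizes_add(self):
        out = union_signatures([self._sig("a", {"g1"}), self._sig("b", {"g2", "g3"})])
        assert len(out) == 3

    def test_overlap_table_against_brute_force(self, rng):
        gene_pool = [f"g{i}" for i in range(40)]
        sigs = [
            self._sig(n, rng.choice(gene_pool, size=rng.integers(5, 20), replace=False))
            for n in "abc"
        ]
        table = signature_overlap_counts(sigs)
        for i, si in enumerate(sigs):
            for j, sj in enumerate(sigs):
                assert table.iloc[i, j] == len(si.genes & sj.genes)
        assert (table.to_numpy() == table.to_numpy().T).all()
        assert all(table.iloc[i, i] == len(sigs[i].genes) for i in range(3))


class TestResidualization:
    def _design(self, batches):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(batches))],
                "treatment": ["control"] * len(batches),
                "batch": batches,
            }
        )

    def test_single_batch_residuals_are_centered_values(self, rng):
        x = rng.normal(100, 5, size=(3, 8))
        expr = pd.DataFrame(x, index=list("abc"), columns=[f"s{i}" for i in range(8)])
        design = self._design(["b1"] * 8)
        res = residualize_batches(expr, design)
        for g in expr.index:
            beta, r = naive_huber_irls(np.ones((8, 1)), expr.loc[g].to_numpy())
            assert np.allclose(res.loc[g].to_numpy(), r, atol=1e-8)

    def test_batch_shift_invariance(self, rng):
        x = rng.normal(100, 10, size=(5, 12))
        cols = [f"s{i}" for i in range(12)]
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(5)], columns=cols)
        batches = ["b1"] * 6 + ["b2"] * 6
        design = self._design(batches)
        res1 = residualize_batches(expr, design)
        shifted = expr.copy()
        shifted.loc[:, cols[6:]] += 57.0  # constant added to one whole batch
        res2 = residualize_batches(shifted, design)
        assert np.allclose(res1.to_numpy(), res2.to_numpy(), atol=1e-8)

    def test_matches_naive_irls_oracle_with_outlier(self, rng):
        y = np.array([10.0, 10.5, 9.8, 10.2, 9.9, 10.1, 10.3, 25.0])  # one outlier
        batches = ["b1"] * 4 + ["b2"] * 4
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        beta_vec, resid_vec = huber_irls(X, y.reshape(-1, 1))
        beta_naive, resid_naive = naive_huber_irls(X, y)
        assert np.allclose(beta_vec[:, 0], beta_naive, atol=1e-8)
        assert np.allclose(resid_vec[:, 0], resid_naive, atol=1e-8)

    def test_statsmodels_rlm_cross_check(self):
        """Independent Huber M-estimation route agrees on the coefficients."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ np.array([2.0, -1.0]) + rng.normal(scale=0.5, size=20)
        y[3] += 8.0
        beta_vec, _ = huber_irls(X, y.reshape(-1, 1))
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        assert np.allclose(beta_vec[:, 0], rlm.params, atol=1e-3)

    def test_collinear_batch_design_rejected(self, rng):
        x = rng.normal(100, 5, size=(2, 6))
        expr = pd.DataFrame(x, index=list("ab"), columns=[f"s{i}" for i in range(6)])
        design = self._design(["b1"] * 3 + ["b2"] * 3)
        design["batch2"] = design["batch"]  # perfectly confounded covariate
        with pytest.raises(ValueError, match="collinear"):
            residualize_batches(expr, design, ["batch", "batch2"])
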