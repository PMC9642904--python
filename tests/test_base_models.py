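import os
import stat
import sys

import numpy as np
import pytest

from prismvote.base_models import (
    ExternalBase,
    LinearBase,
    LogisticRidgeBase,
    RidgeBase,
    make_base,
)


def _ridge_normal_equations(G, y, C, alpha):
    """Dense oracle: solve the full penalized normal equations directly."""
    Z = np.hstack([C, G])
    pen = np.zeros(Z.shape[1])
    pen[C.shape[1]:] = alpha
    A = Z.T @ Z + np.diag(pen)
    theta = np.linalg.solve(A, Z.T @ y)
    return theta[: C.shape[1]], theta[C.shape[1]:]


class TestRidge:
    def test_noiseless_univariate_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 1))
        y = 2.0 * x[:, 0]
        est = RidgeBase(alpha=0.0).fit(x, y)
        assert est.coef_[0] == pytest.approx(2.0, abs=1e-8)

    def test_infinite_penalty_limit(self):
        rng = np.random.default_rng(1)
        G = rng.normal(size=(50, 10))
        cov = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        est = RidgeBase(alpha=1e12).fit(G, y, covariates=cov)
        np.testing.assert_allclose(est.coef_, 0.0, atol=1e-8)
        covariate_only = np.column_stack([np.ones(50), cov]) @ \
            np.linalg.lstsq(np.column_stack([np.ones(50), cov]), y, rcond=None)[0]
        np.testing.assert_allclose(est.predict(G, covariates=cov),
                                   covariate_only, atol=1e-6)

    @pytest.mark.parametrize("n,p", [(20, 30), (30, 20)])
    def test_matches_normal_equations_oracle(self, n, p):
        rng = np.random.default_rng(2)
        G = rng.normal(size=(n, p))
        cov = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        alpha = 2.5
        est = RidgeBase(alpha=alpha).fit(G, y, covariates=cov)
        C = np.column_stack([np.ones(n), cov])
        gamma_ref, beta_ref = _ridge_normal_equations(G, y, C, alpha)
        np.testing.assert_allclose(est.coef_, beta_ref, atol=1e-8)
        np.testing.assert_allclose(est.covar_coef_, gamma_ref, atol=1e-8)
        # in-sample predictions reproduce the oracle's fitted values
        np.testing.assert_allclose(est.predict(G, covariates=cov),
                                   G @ beta_ref + C @ gamma_ref, atol=1e-8)

    def test_zero_penalty_equals_ols_when_overdetermined(self):
        rng = np.random.default_rng(3)
        G = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        est = RidgeBase(alpha=0.0).fit(G, y)
        Z = np.column_stack([np.ones(60), G])
        theta = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(est.coef_, theta[1:], atol=1e-8)

    def test_variant_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.3, (40, 25)).astype(float)
        y = rng.normal(size=40)
        Gt = rng.binomial(2, 0.3, (10, 25)).astype(float)
        perm = rng.permutation(25)
        base = RidgeBase(alpha=1.0).fit(G, y).predict(Gt)
        permuted = RidgeBase(alpha=1.0).fit(G[:, perm], y).predict(Gt[:, perm])
        np.testing.assert_allclose(base, permuted, atol=1e-8)

    def test_reml_recovers_signal_regime(self):
        # dense polygenic signal: REML penalty must not drown the genotypes
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.3, (300, 400)).astype(float)
        beta = rng.normal(0, 0.05, 400)
        g = G @ beta
        y = g + rng.normal(0, g.std() * 0.5, 300)
        est = RidgeBase(alpha="reml").fit(G[:200], y[:200])
        pred = est.predict(G[200:])
        assert np.corrcoef(pred, y[200:])[0, 1] > 0.3

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            RidgeBase(alpha=-1.0).fit(np.ones((4, 2)), np.arange(4.0))

    def test_variant_mismatch_error_names_counts(self):
        rng = np.random.default_rng(6)
        est = RidgeBase(alpha=1.0).fit(rng.normal(size=(10, 5)), rng.normal(size=10))
        with pytest.raises(ValueError, match="variant count mismatch"):
            est.predict(rng.normal(size=(3, 4)))


class TestLinearAndLogistic:
    def test_linear_rejects_binary_outcome(self):
        with pytest.raises(ValueError, match="logistic"):
            LinearBase().fit(np.ones((6, 2)), np.array([0, 1, 0, 1, 0, 1.0]))

    def test_logistic_probabilities_bounded(self):
        rng = np.random.default_rng(7)
        G = rng.normal(size=(80, 10)) * 50  # extreme inputs
        y = (rng.uniform(size=80) > 0.5).astype(float)
        est = LogisticRidgeBase(alpha=1.0).fit(G, y)
        p = est.predict(G)
        assert ((p > 0) & (p < 1)).all()

    def test_logistic_learns_separation(self):
        rng = np.random.default_rng(8)
        G = rng.normal(size=(200, 3))
        eta = 2.0 * G[:, 0]
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-eta))).astype(float)
        est = LogisticRidgeBase(alpha=1.0).fit(G, y)
        from prismvote.evaluate import auc
        assert auc(y, est.predict(G)) > 0.75

    def test_logistic_requires_binary(self):
        with pytest.raises(ValueError, match="binary"):
            LogisticRidgeBase().fit(np.ones((5, 2)), np.arange(5.0))

    def test_all_zero_coefficients_predict_intercept(self):
        rng = np.random.default_rng(9)
        G = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        est = RidgeBase(alpha=1e14).fit(G, y)
        np.testing.assert_allclose(est.predict(G), np.full(30, y.mean()),
                                   atol=1e-5)


class TestExternalAdapter:
    def _script(self, tmp_path, body):
        path = tmp_path / "adapter.py"
        path.write_text(body)
        return f"{sys.executable} {path}"

    def test_constant_stub_runs_end_to_end(self, tmp_path):
        body = (
            "import sys\n"
            "test_prefix, out = sys.argv[1], sys.argv[2]\n"
            "iids = [l.split()[1] for l in open(test_prefix + '.fam')]\n"
            "open(out, 'w').write(''.join(f'{i} 0.5\\n' for i in iids))\n"
        )
        cmd = self._script(tmp_path, body) + " {test_prefix} {out}"
        est = ExternalBase(cmd, workdir=str(tmp_path))
        rng = np.random.default_rng(10)
        G = rng.binomial(2, 0.2, (12, 5)).astype(float)
        est.fit(G[:8], rng.normal(size=8))
        pred = est.predict(G[8:])
        np.testing.assert_allclose(pred, 0.5)

    def test_sample_order_preserved(self, tmp_path):
        body = (
            "import sys\n"
            "test_prefix, out = sys.argv[1], sys.argv[2]\n"
            "iids = [l.split()[1] for l in open(test_prefix + '.fam')]\n"
            "# reply out of order on purpose; values encode the input rank\n"
            "lines = [f'{iid} {k}.0\\n' for k, iid in enumerate(iids)]\n"
            "open(out, 'w').write(''.join(reversed(lines)))\n"
        )
        cmd = self._script(tmp_path, body) + " {test_prefix} {out}"
        est = ExternalBase(cmd, workdir=str(tmp_path))
        G = np.zeros((8, 3))
        est.fit(G[:4], np.arange(4.0) + 1)
        pred = est.predict(G[4:], samples=["a", "b", "c", "d"])
        np.testing.assert_allclose(pred, [0.0, 1.0, 2.0, 3.0])

    def test_self_adapter_matches_internal_ridge(self, tmp_path):
        body = (
            "import sys\n"
            "import numpy as np\n"
            "from prismvote.io import read_plink, read_phenotype\n"
            "from prismvote.base_models import RidgeBase\n"
            "train_prefix, pheno, test_prefix, out = sys.argv[1:5]\n"
            "tr = read_plink(train_prefix)\n"
            "te = read_plink(test_prefix)\n"
            "y = read_phenotype(pheno).align_to(tr).y\n"
            "est = RidgeBase(alpha=3.0).fit(tr.G.astype(float), y)\n"
            "pred = est.predict(te.G.astype(float))\n"
            "open(out, 'w').write(''.join(\n"
            "    f'{s} {float(v)!r}\\n' for s, v in zip(te.samples, pred)))\n"
        )
        cmd = self._script(tmp_path, body) + \
            " {train_prefix} {train_pheno} {test_prefix} {out}"
        rng = np.random.default_rng(11)
        G = rng.binomial(2, 0.2, (30, 12)).astype(float)  # low MAF: no recode
        y = rng.normal(size=30)
        internal = RidgeBase(alpha=3.0).fit(G[:20], y[:20]).predict(G[20:])
        est = ExternalBase(cmd, workdir=str(tmp_path))
        est.fit(G[:20], y[:20])
        external = est.predict(G[20:])
        np.testing.assert_allclose(external, internal, atol=1e-10)

    def test_nonzero_exit_surfaces_output(self, tmp_path):
        body = "import sys; sys.stderr.write('boom'); sys.exit(3)\n"
        cmd = self._script(tmp_path, body)
        est = ExternalBase(cmd, workdir=str(tmp_path))
        est.fit(np.zeros((4, 2)), np.arange(4.0))
        with pytest.raises(RuntimeError, match="boom"):
            est.predict(np.zeros((2, 2)))

    def test_unparseable_predictions_raise(self, tmp_path):
        body = (
            "import sys\n"
            "open(sys.argv[1], 'w').write('not numbers here\\n')\n"
        )
        cmd = self._script(tmp_path, body) + " {out}"
        est = ExternalBase(cmd, workdir=str(tmp_path))
        est.fit(np.zeros((4, 2)), np.arange(4.0))
        with pytest.raises(RuntimeError, match="parse"):
            est.predict(np.zeros((2, 2)))


def test_make_base_dispatch():
    assert isinstance(make_base("linear"), LinearBase)
    assert isinstance(make_base("ridge"), RidgeBase)
    assert isinstance(make_base("logistic"), LogisticRidgeBase)
    with pytest.raises(ValueError):
        make_base("bayesr")
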