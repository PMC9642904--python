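"""Per-stratum base prediction models.

Whole-genome linear-mixed-model predictors are represented here by their
ridge/GBLUP equivalent: a penalized linear model over all variants with the
covariates (intercept plus top principal components) left unpenalized.
``LinearBase`` is the unpenalized limit, ``LogisticRidgeBase`` the binary
analogue, and ``ExternalBase`` wraps an arbitrary command-line predictor
behind the same fit/predict contract so tools like BayesR or DPR can be
plugged in without touching the pipeline.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class BaseModelFit:
    """Frozen coefficients of a fitted base model."""

    kind: str
    coef: np.ndarray  # per-variant coefficients
    covar_coef: np.ndarray  # intercept + covariate coefficients
    alpha: float  # regularization strength actually used
    n_train: int
    stratum: int | None = None


def _design_covariates(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _check_Xy(G, y):
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.ndim != 2:
        raise ValueError("G must be an N x P matrix")
    if y.shape != (G.shape[0],):
        raise ValueError("y length does not match G rows")
    if G.shape[0] < 2 or G.shape[1] < 1:
        raise ValueError("need N >= 2 and P >= 1")
    return G, y


class RidgeBase(BaseEstimator, RegressorMixin):
    """Ridge regression over variants with unpenalized covariates.

    Solves ``min_{gamma, beta} ||y - C gamma - G beta||^2 + alpha ||beta||^2``
    where ``C`` holds the intercept and any covariates.  By the
    Frisch-Waugh-Lovell argument the genotype coefficients equal the ridge
    solution on covariate-residualized data, which is what is computed: one
    symmetric eigendecomposition of the smaller Gram matrix (P x P when
    P <= N, the N x N dual otherwise) yields the solution for every
    candidate penalty, so ``alpha="gcv"`` selects the strength by
    generalized cross-validation at negligible extra cost.

    Parameters
    ----------
    alpha : float, "reml" or "gcv"
        Penalty on variant coefficients.  ``"reml"`` (default) estimates
        the residual-to-effect variance ratio ``sigma_e^2 / sigma_beta^2``
        by restricted maximum likelihood on the spectral decomposition --
        the ridge solution at that penalty is the GBLUP/LMM predictor.
        ``"gcv"`` minimizes ``GCV(a) = n * RSS(a) / (n - edf(a))^2`` over a
        log-spaced grid; with many more variants than subjects GCV can be
        nearly flat and over-shrink, so REML is the default.
    """

    kind = "ridge"

    def __init__(self, alpha: float | str = "reml"):
        self.alpha = alpha

    def fit(self, G, y, covariates=None):
        G, y = _check_Xy(G, y)
        if isinstance(self.alpha, (int, float)) and self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        n, p = G.shape
        C = _design_covariates(covariates, n)
        # residualize out the unpenalized block
        Q, _ = np.linalg.qr(C)
        Gc = G - Q @ (Q.T @ G)
        yc = y - Q @ (Q.T @ y)
        p_c = C.shape[1]

        if p <= n:
            gram = Gc.T @ Gc
            s2, V = np.linalg.eigh(gram)
            s2 = np.maximum(s2, 0.0)
            z = V.T @ (Gc.T @ yc)
            primal = True
        else:
            gram = Gc @ Gc.T
            s2, U = np.linalg.eigh(gram)
            s2 = np.maximum(s2, 0.0)
            z = U.T @ yc
            primal = False

        yc_ss = float(yc @ yc)

        def coefs(a):
            if a == 0:
                tol = s2.max() * max(n, p) * np.finfo(float).eps if s2.size else 0.0
                inv = np.where(s2 > tol, 1.0 / np.maximum(s2, tol), 0.0)
            else:
                inv = 1.0 / (s2 + a)
            if primal:
                return V @ (inv * z)
            return Gc.T @ (U @ (inv * z))

        def gcv_score(a):
            inv = 1.0 / (s2 + a)
            fit_y = float(np.sum(z**2 * inv))  # yc' yhat
            norm_y = float(np.sum(z**2 * s2 * inv**2))  # ||yhat||^2
            rss = max(yc_ss - 2.0 * fit_y + norm_y, 0.0)
            edf = float(np.sum(s2 * inv)) + p_c
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2

        tol = s2.max() * max(n, p) * np.finfo(float).eps if s2.size else 0.0
        pos = s2 > tol
        m_pos = int(pos.sum())
        z2_pos = z[pos] ** 2
        s2_pos = s2[pos]
        ss0 = max(yc_ss - float(z2_pos.sum()), 0.0)
        n_resid = n - p_c

        def reml_criterion(lam):
            # profile restricted -2 loglik (up to a constant) at ratio
            # lam = sigma_e^2 / sigma_beta^2
            v = s2_pos / lam + 1.0
            sigma_e2 = (float(np.sum(z2_pos / v)) + ss0) / n_resid
            return float(np.sum(np.log(v))) + n_resid * np.log(max(sigma_e2, 1e-300))

        if self.alpha == "reml":
            if m_pos == 0 or n_resid <= 0:
                a = 1.0
            else:
                anchor = float(s2_pos.mean())
                grid = anchor * np.logspace(-6, 6, 61)
                vals = [reml_criterion(g) for g in grid]
                i = int(np.argmin(vals))
                lo = grid[max(i - 1, 0)]
                hi = grid[min(i + 1, len(grid) - 1)]
                from scipy.optimize import minimize_scalar
                res = minimize_scalar(lambda t: reml_criterion(np.exp(t)),
                                      bounds=(np.log(lo), np.log(hi)),
                                      method="bounded",
                                      options={"xatol": 1e-6})
                a = float(np.exp(res.x))
        elif self.alpha == "gcv":
            anchor = s2.mean() if s2.size and s2.mean() > 0 else 1.0
            grid = anchor * np.logspace(-4, 3, 22)
            scores = [gcv_score(a) for a in grid]
            a = float(grid[int(np.argmin(scores))])
        elif isinstance(self.alpha, (int, float)):
            a = float(self.alpha)
        else:
            raise ValueError(
                f"alpha must be a number, 'reml' or 'gcv', got {self.alpha!r}")

        beta = coefs(a)
        gamma, *_ = np.linalg.lstsq(C, y - G @ beta, rcond=None)
        self.coef_ = beta
        self.covar_coef_ = gamma
        self.alpha_ = a
        self.n_features_in_ = p
        self._n_covar = C.shape[1] - 1
        return self

    def predict(self, G, covariates=None):
        G = np.asarray(G, dtype=float)
        if G.shape[1] != self.n_features_in_:
            raise ValueError(
                f"variant count mismatch: model has {self.n_features_in_}, "
                f"input has {G.shape[1]}"
            )
        C = _design_covariates(covariates, G.shape[0])
        if C.shape[1] != self.covar_coef_.shape[0]:
            raise ValueError("covariate count differs from training")
        return G @ self.coef_ + C @ self.covar_coef_

    def to_fit(self, stratum=None) -> BaseModelFit:
        return BaseModelFit(kind=self.kind, coef=self.coef_,
                            covar_coef=self.covar_coef_, alpha=self.alpha_,
                            n_train=0, stratum=stratum)


class LinearBase(RidgeBase):
    """Ordinary least squares (minimum-norm when rank deficient)."""

    kind = "linear"

    def __init__(self):
        super().__init__(alpha=0.0)

    def fit(self, G, y, covariates=None):
        y_arr = np.asarray(y, dtype=float)
        if np.isin(y_arr, [0.0, 1.0]).all():
            raise ValueError(
                "outcome looks binary (only 0/1 values); use the logistic "
                "base model for binary traits"
            )
        return super().fit(G, y, covariates=covariates)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError("LinearBase has no parameters")
        return self


class LogisticRidgeBase(BaseEstimator):
    """L2-penalized logistic regression with unpenalized covariates.

    Minimizes the binomial negative log-likelihood plus
    ``alpha/2 * ||beta||^2`` on the variant coefficients by L-BFGS.
    ``alpha="cv"`` picks the penalty from a small grid by 3-fold deviance
    cross-validation (seeded, deterministic).
    """

    kind = "logistic"

    def __init__(self, alpha: float | str = 1.0, max_iter: int = 500,
                 random_state: int = 0):
        self.alpha = alpha
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _solve(G, y, C, a, max_iter):
        n, p = G.shape
        p_c = C.shape[1]
        X = np.hstack([C, G])

        def obj(theta):
            eta = X @ theta
            # stable log(1 + exp(eta)) - y*eta
            nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
            beta = theta[p_c:]
            grad_pen = np.concatenate([np.zeros(p_c), a * beta])
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = X.T @ (mu - y) + grad_pen
            return nll + 0.5 * a * beta @ beta, grad

        theta0 = np.zeros(p_c + p)
        res = optimize.minimize(obj, theta0, jac=True, method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": 1e-12,
                                         "gtol": 1e-8})
        return res.x[:p_c], res.x[p_c:]

    def fit(self, G, y, covariates=None):
        G, y = _check_Xy(G, y)
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("logistic base requires a binary 0/1 outcome")
        C = _design_covariates(covariates, G.shape[0])

        if self.alpha == "cv":
            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(len(y))
            folds = np.array_split(idx, 3)
            grid = np.logspace(-1, 3, 6)
            devs = []
            for a in grid:
                dev = 0.0
                for f in range(3):
                    te = folds[f]
                    tr = np.concatenate([folds[g] for g in range(3) if g != f])
                    gma, beta = self._solve(G[tr], y[tr], C[tr], a, self.max_iter)
                    eta = C[te] @ gma + G[te] @ beta
                    dev += float(np.sum(np.logaddexp(0.0, eta) - y[te] * eta))
                devs.append(dev)
            a = float(grid[int(np.argmin(devs))])
        elif isinstance(self.alpha, (int, float)) and self.alpha >= 0:
            a = float(self.alpha)
        else:
            raise ValueError("alpha must be a non-negative number or 'cv'")

        self.covar_coef_, self.coef_ = self._solve(G, y, C, a, self.max_iter)
        self.alpha_ = a
        self.n_features_in_ = G.shape[1]
        return self

    def predict(self, G, covariates=None):
        """Predicted probability of the positive class, in (0, 1)."""
        G = np.asarray(G, dtype=float)
        if G.shape[1] != self.n_features_in_:
            raise ValueError(
                f"variant count mismatch: model has {self.n_features_in_}, "
                f"input has {G.shape[1]}"
            )
        C = _design_covariates(covariates, G.shape[0])
        eta = C @ self.covar_coef_ + G @ self.coef_
        return 1.0 / (1.0 + np.exp(-eta))

    predict_proba_1 = predict


class ExternalBase(BaseEstimator):
    """Adapter running an external command-line predictor.

    The command template receives the placeholders ``{train_prefix}``,
    ``{train_pheno}``, ``{test_prefix}`` and ``{out}``.  Training genotypes
    are written as a PLINK triplet plus a phenotype file; the command must
    write per-subject predictions for the test samples as two-column text
    (IID, value).  Process failures surface with the captured output.
    """

    kind = "external"

    def __init__(self, command_template: str, workdir: str | None = None):
        self.command_template = command_template
        self.workdir = workdir

    def fit(self, G, y, covariates=None, samples=None, variants=None):
        G, y = _check_Xy(G, y)
        self._train = (G, y, samples)
        self._variants = variants
        return self

    def predict(self, G, covariates=None, samples=None):
        from .io import GenotypeMatrix, PhenotypeTable, VariantRecord, \
            write_phenotype, write_plink

        G = np.asarray(G, dtype=float)
        Gtr, ytr, train_samples = self._train
        if G.shape[1] != Gtr.shape[1]:
            raise ValueError("variant count mismatch between train and test")
        train_samples = train_samples or [f"tr{i}" for i in range(len(ytr))]
        test_samples = samples or [f"te{i}" for i in range(G.shape[0])]
        variants = self._variants or [
            VariantRecord("1", j + 1, f"snp{j}", "A", "C")
            for j in range(G.shape[1])
        ]
        tmp = tempfile.mkdtemp(dir=self.workdir)
        train_prefix = os.path.join(tmp, "train")
        test_prefix = os.path.join(tmp, "test")
        out_path = os.path.join(tmp, "pred.txt")
        write_plink(GenotypeMatrix(train_samples, variants,
                                   np.rint(Gtr).astype(np.int8)), train_prefix)
        write_plink(GenotypeMatrix(test_samples, variants,
                                   np.rint(G).astype(np.int8)), test_prefix)
        write_phenotype(PhenotypeTable(train_samples, ytr), train_prefix + ".pheno")
        cmd = self.command_template.format(
            train_prefix=train_prefix, train_pheno=train_prefix + ".pheno",
            test_prefix=test_prefix, out=out_path,
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external base model failed (exit {proc.returncode}):\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        preds = {}
        try:
            with open(out_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    iid, val = line.split()[:2]
                    preds[iid] = float(val)
            return np.array([preds[s] for s in test_samples])
        except (ValueError, KeyError, FileNotFoundError) as exc:
            raise RuntimeError(
                f"could not parse external predictions at {out_path}: {exc}"
            ) from exc


def make_base(kind: str, alpha=None, random_state: int = 0):
    """Instantiate a base model by name: linear | ridge | logistic."""
    if kind == "linear":
        return LinearBase()
    if kind == "ridge":
        return RidgeBase(alpha="reml" if alpha is None else alpha)
    if kind == "logistic":
        return LogisticRidgeBase(alpha=1.0 if alpha is None else alpha,
                                 random_state=random_state)
    raise ValueError(f"unknown base model kind: {kind!r}")


def fit_base(G, y, covariates=None, kind: str = "ridge", alpha=None):
    """Functional wrapper: fit a base model and return (estimator, BaseModelFit)."""
    est = make_base(kind, alpha=alpha)
    est.fit(G, y, covariates=covariates)
    fit = BaseModelFit(kind=est.kind, coef=est.coef_, covar_coef=est.covar_coef_,
                       alpha=est.alpha_, n_train=np.asarray(G).shape[0])
    return est, fit


def predict_base(est, G, covariates=None):
    """Functional wrapper over an estimator's ``predict``."""
    return est.predict(G, covariates=covariates)
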