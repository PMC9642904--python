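"""The Prism Vote procedure: stratify, fit, weight, aggregate.

A subject's predicted trait is the propensity-weighted sum of stratum-wise
predictions,

    E(Y | x_i) = sum_k E(Y | i in k, x_i) * Pr(i in k | x_i),

with strata formed as quantile bins of the eigenvalue-weighted principal
component score and propensities from Bayes' theorem over chi-squared
distance likelihoods.  The five steps are: (1) joint PCA on training and
test subjects, (2) quantile strata on the training scores, (3) one base
model per stratum (controlling for the top PCs), (4) posterior propensity
of each test subject to each stratum, (5) the weighted aggregation above.

``PrismVote`` packages the procedure as an estimator; ``run_pv``,
``reference_fit_predict`` and ``select_k_q`` are the functional surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold, StratifiedKFold

from . import ancestry as anc
from .base_models import BaseModelFit, make_base
from .io import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass
class PVModel:
    """Fitted state of one Prism Vote run."""

    ancestry: anc.AncestryModel
    strata: anc.StratumModel
    base_fits: list[BaseModelFit]
    labels: np.ndarray  # training stratum assignment
    config: dict = field(default_factory=dict)


@dataclass
class PVPrediction:
    """Final predictions with their stratum-wise decomposition."""

    final: np.ndarray  # (n_test,)
    stratum_predictions: np.ndarray  # (n_test, K)
    propensities: np.ndarray  # (n_test, K)


def pv_aggregate(stratum_preds, propensities) -> np.ndarray:
    """Propensity-weighted sum of stratum-wise predictions.

    Accepts length-K vectors or (N, K) matrices; propensity rows must sum
    to 1 (the aggregate is then a convex combination, so binary-trait
    probabilities stay in [0, 1]).
    """
    preds = np.atleast_2d(np.asarray(stratum_preds, dtype=float))
    prop = np.atleast_2d(np.asarray(propensities, dtype=float))
    if preds.shape != prop.shape:
        raise ValueError(f"shape mismatch: {preds.shape} vs {prop.shape}")
    if not np.allclose(prop.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("propensity rows must sum to 1")
    out = (preds * prop).sum(axis=1)
    return float(out[0]) if np.asarray(stratum_preds).ndim == 1 else out


def _as_counts(G):
    """Coerce input to (float matrix with NaN missing, variant ids or None)."""
    if isinstance(G, GenotypeMatrix):
        M = G.G.astype(float)
        M[G.G == MISSING] = np.nan
        return M, [v.id for v in G.variants]
    M = np.asarray(G, dtype=float)
    return M, None


def _impute_columns(M: np.ndarray) -> np.ndarray:
    if not np.isnan(M).any():
        return M
    means = np.nanmean(M, axis=0)
    idx = np.where(np.isnan(M))
    M = M.copy()
    M[idx] = means[idx[1]]
    return M


def _as_y(y):
    if isinstance(y, PhenotypeTable):
        return np.asarray(y.y, dtype=float), y.trait_type
    return np.asarray(y, dtype=float), None


def _infer_trait(y: np.ndarray, trait_type: str) -> str:
    if trait_type in ("continuous", "binary"):
        return trait_type
    return "binary" if np.isin(y, [0.0, 1.0]).all() else "continuous"


def _resolve_base(base: str, trait: str) -> str:
    if base == "auto":
        return "logistic" if trait == "binary" else "ridge"
    if trait == "binary" and base in ("linear", "ridge"):
        raise ValueError(f"base {base!r} does not support binary traits; "
                         "use 'logistic'")
    return base


class PrismVote(BaseEstimator):
    """Prism Vote predictor for multi-population genotype data.

    Parameters
    ----------
    K : int
        Number of ancestry strata (K=1 reduces exactly to the reference
        method: one base model controlling for the top PCs).
    q : int
        Number of principal components for the weighted ancestry score;
        the same components are used as base-model covariates.
    base : {"auto", "linear", "ridge", "logistic"}
        Per-stratum base model; "auto" picks ridge for continuous and
        logistic-ridge for binary traits.
    alpha : float, "gcv"/"cv" or None
        Base-model penalty; None uses each model's internal selection.
    trait_type : {"auto", "continuous", "binary"}
    pca_mode : {"joint", "project"}
        "joint" refits the PCA on training plus test subjects at predict
        time (the reference behaviour); "project" fits on training only
        and projects test subjects, for streaming deployment.
    random_state : int
        Seed for any randomized component (penalty cross-validation).

    Notes
    -----
    In joint mode the principal components depend on the test set, so the
    stratum base models are fitted inside :meth:`predict`; ``fit`` only
    validates and stores the training data.
    """

    def __init__(self, K: int = 2, q: int = 10, base: str = "auto",
                 alpha=None, trait_type: str = "auto",
                 pca_mode: str = "joint", random_state: int = 0):
        self.K = K
        self.q = q
        self.base = base
        self.alpha = alpha
        self.trait_type = trait_type
        self.pca_mode = pca_mode
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, G, y):
        M, var_ids = _as_counts(G)
        yv, ty = _as_y(y)
        if M.shape[0] != yv.shape[0]:
            raise ValueError("genotype and phenotype sample counts differ")
        if np.isnan(yv).any():
            raise ValueError("phenotype contains missing values; drop them first")
        if 2 * self.K > M.shape[0]:
            raise ValueError(f"K={self.K} needs at least {2 * self.K} training subjects")
        if self.pca_mode not in ("joint", "project"):
            raise ValueError("pca_mode must be 'joint' or 'project'")
        self._train_counts = M
        self._train_var_ids = var_ids
        self._y = yv
        self.trait_type_ = _infer_trait(yv, ty or self.trait_type)
        self.base_kind_ = _resolve_base(self.base, self.trait_type_)
        if self.pca_mode == "project":
            self._fit_project_mode()
        return self

    def _fit_bases(self, counts_train, pcs_train, labels):
        fits, ests = [], []
        for k in range(int(np.max(labels)) + 1):
            rows = labels == k
            est = make_base(self.base_kind_, alpha=self.alpha,
                            random_state=self.random_state)
            est.fit(counts_train[rows], self._y[rows], covariates=pcs_train[rows])
            ests.append(est)
            fits.append(BaseModelFit(kind=est.kind, coef=est.coef_,
                                     covar_coef=est.covar_coef_,
                                     alpha=est.alpha_,
                                     n_train=int(rows.sum()), stratum=k))
        return ests, fits

    def _fit_project_mode(self):
        X = anc.normalize(_impute_columns(self._train_counts))
        model = anc.fit_pca(X, q=self.q)
        strata, labels = anc.assign_strata(model.scores, self.K)
        pcs = model.eigenvectors
        ests, fits = self._fit_bases(self._train_counts, pcs, labels)
        self._ests = ests
        self.model_ = PVModel(ancestry=model, strata=strata, base_fits=fits,
                              labels=labels, config=self.get_params())

    # -- prediction -------------------------------------------------------

    def predict_detailed(self, G) -> PVPrediction:
        """Run steps (1)-(5) for a test set and return the decomposition."""
        M_test, var_ids = _as_counts(G)
        if self._train_var_ids is not None and var_ids is not None:
            for j, (a, b) in enumerate(zip(self._train_var_ids, var_ids)):
                if a != b:
                    raise ValueError(
                        f"variant mismatch at column {j}: train {a!r} vs test {b!r}"
                    )
        if M_test.shape[1] != self._train_counts.shape[1]:
            raise ValueError("train and test variant counts differ")
        n_tr = self._train_counts.shape[0]

        if self.pca_mode == "joint":
            stacked = _impute_columns(np.vstack([self._train_counts, M_test]))
            X = anc.normalize(stacked)
            model = anc.fit_pca(X, q=self.q)
            w_train = model.scores[:n_tr]
            w_test = model.scores[n_tr:]
            pcs_train = model.eigenvectors[:n_tr]
            pcs_test = model.eigenvectors[n_tr:]
            strata, labels = anc.assign_strata(w_train, self.K)
            ests, fits = self._fit_bases(self._train_counts, pcs_train, labels)
            self._ests = ests
            self.model_ = PVModel(ancestry=model, strata=strata,
                                  base_fits=fits, labels=labels,
                                  config=self.get_params())
        else:
            model = self.model_.ancestry
            strata = self.model_.strata
            loadings = anc.project(model, _impute_columns(M_test))
            w_test = anc.weighted_score(loadings, model.weights)
            pcs_test = loadings
            ests = self._ests

        preds = np.column_stack([
            est.predict(M_test, covariates=pcs_test) for est in ests
        ])
        prop = anc.propensity_matrix(w_test, self.model_.strata
                                     if self.pca_mode == "project" else strata)
        final = (preds * prop).sum(axis=1)
        self.prediction_ = PVPrediction(final=final, stratum_predictions=preds,
                                        propensities=prop)
        return self.prediction_

    def predict(self, G) -> np.ndarray:
        return self.predict_detailed(G).final

    def predict_proba(self, G) -> np.ndarray:
        """(n, 2) class probabilities for binary traits."""
        if self.trait_type_ != "binary":
            raise ValueError("predict_proba is only defined for binary traits")
        p = self.predict(G)
        return np.column_stack([1.0 - p, p])


def run_pv(train_G, train_y, test_G, K: int = 2, q: int = 10,
           base: str = "auto", alpha=None, trait_type: str = "auto",
           pca_mode: str = "joint", random_state: int = 0):
    """Execute the five-step procedure and return (PVModel, PVPrediction)."""
    est = PrismVote(K=K, q=q, base=base, alpha=alpha, trait_type=trait_type,
                    pca_mode=pca_mode, random_state=random_state)
    est.fit(train_G, train_y)
    pred = est.predict_detailed(test_G)
    return est.model_, pred


def reference_fit_predict(train_G, train_y, test_G, q: int = 10,
                          base: str = "auto", alpha=None,
                          trait_type: str = "auto",
                          random_state: int = 0) -> np.ndarray:
    """The reference method: one base model on all data, controlling top PCs.

    Implemented independently of the stratified path (joint PCA, single
    fit, no propensity machinery); Prism Vote with K=1 must agree with it
    exactly.
    """
    M_tr, _ = _as_counts(train_G)
    M_te, _ = _as_counts(test_G)
    yv, ty = _as_y(train_y)
    trait = _infer_trait(yv, ty or trait_type)
    kind = _resolve_base(base, trait)
    n_tr = M_tr.shape[0]
    stacked = _impute_columns(np.vstack([M_tr, M_te]))
    model = anc.fit_pca(anc.normalize(stacked), q=q)
    pcs = model.eigenvectors
    est = make_base(kind, alpha=alpha, random_state=random_state)
    est.fit(M_tr, yv, covariates=pcs[:n_tr])
    return est.predict(M_te, covariates=pcs[n_tr:])


def select_k_q(G, y, K_grid=(1, 2, 3, 4), q_grid=(5, 10, 20), folds: int = 5,
               base: str = "auto", alpha=None, trait_type: str = "auto",
               random_state: int = 0, return_table: bool = False):
    """Choose (K, q) by grid search over internal cross-validation accuracy.

    The search uses only the supplied (training) data: it is re-split into
    ``folds`` internal folds, every grid cell is scored by mean held-out
    accuracy (Pearson r for continuous, AUC for binary), and the best cell
    wins with ties broken toward smaller K, then smaller q.  Cells that are
    infeasible on some fold (e.g. an under-filled stratum) are skipped with
    a warning; if every cell fails an error is raised.
    """
    from .evaluate import auc, pearson_r

    if not K_grid or not q_grid:
        raise ValueError("K and q grids must be non-empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    M, _ = _as_counts(G)
    yv, ty = _as_y(y)
    trait = _infer_trait(yv, ty or trait_type)
    metric = auc if trait == "binary" else pearson_r

    if trait == "binary":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=random_state)
        split_arg = yv
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=random_state)
        split_arg = None

    q_max = int(max(q_grid))
    cells = sorted((int(K), int(q)) for K in K_grid for q in q_grid)
    scores: dict[tuple[int, int], list[float]] = {c: [] for c in cells}
    dead: set[tuple[int, int]] = set()

    for tr, te in splitter.split(M, split_arg):
        stacked = _impute_columns(np.vstack([M[tr], M[te]]))
        X = anc.normalize(stacked)
        full = anc.fit_pca(X, q=min(q_max, min(stacked.shape) - 1)
                           if q_max >= min(stacked.shape) else q_max)
        for K, q in cells:
            if (K, q) in dead:
                continue
            try:
                sub = _slice_pca(full, q)
                n_tr = len(tr)
                strata, labels = anc.assign_strata(sub.scores[:n_tr], K)
                preds = []
                for k in range(K):
                    rows = labels == k
                    est = make_base(_resolve_base(base, trait), alpha=alpha,
                                    random_state=random_state)
                    est.fit(M[tr][rows], yv[tr][rows],
                            covariates=sub.eigenvectors[:n_tr][rows])
                    preds.append(est.predict(M[te],
                                             covariates=sub.eigenvectors[n_tr:]))
                prop = anc.propensity_matrix(sub.scores[n_tr:], strata)
                final = (np.column_stack(preds) * prop).sum(axis=1)
                scores[(K, q)].append(metric(yv[te], final))
            except ValueError as exc:
                warnings.warn(f"(K={K}, q={q}) infeasible: {exc}", RuntimeWarning)
                dead.add((K, q))

    means = {c: float(np.mean(v)) for c, v in scores.items()
             if c not in dead and v}
    if not means:
        raise ValueError("every (K, q) grid cell was infeasible")
    best = None
    for c in cells:  # sorted by (K, q): ties keep the smaller cell
        if c in means and (best is None or means[c] > means[best]):
            best = c
    if return_table:
        return best, means
    return best


def _slice_pca(model: anc.AncestryModel, q: int) -> anc.AncestryModel:
    """Restrict a fitted decomposition to its top q components."""
    if q > model.q:
        raise ValueError(f"q={q} exceeds the {model.q} fitted components")
    lam = model.eigenvalues[:q]
    U = model.eigenvectors[:, :q]
    a = lam / lam.sum()
    return anc.AncestryModel(eigenvectors=U, eigenvalues=lam, q=q,
                             weights=a, scores=U @ a)
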