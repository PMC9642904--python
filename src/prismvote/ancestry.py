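"""PCA-based population stratification and stratum-membership estimation.

The pipeline: normalize minor-allele counts, eigendecompose the N x N
genetic covariance, collapse the top ``q`` principal components into a
single eigenvalue-weighted ancestry score ``w``, cut the training subjects
into ``K`` equal-size quantile strata of ``w``, and convert a subject's
distance to each stratum center into a posterior membership probability
(the "propensity") via a 1-df chi-squared likelihood and Bayes' theorem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GenotypeMatrix, impute_mean


@dataclass
class NormalizedMatrix:
    """Genotypes centered and scaled to unit binomial variance.

    x_ij = (g_ij - mean_j) / sqrt(2 p_j (1 - p_j)) with the shrunk
    allele-frequency estimate p_j = (1 + sum_i g_ij) / (2 + 2N), which is
    never exactly 0 or 1 so the scale is always positive.
    """

    X: np.ndarray
    col_means: np.ndarray
    p: np.ndarray


@dataclass
class AncestryModel:
    """Top-q eigenpairs of the genetic covariance plus the weighted score.

    ``eigenvectors`` is N x q (columns are subject loadings v^r),
    ``eigenvalues`` the matching non-increasing values, ``weights`` the
    eigenvalues normalized to sum to one over the retained components, and
    ``scores`` the per-subject weighted score w_i = sum_r a_r v_i^r.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    q: int
    weights: np.ndarray
    scores: np.ndarray
    # projection components (right basis scaled for out-of-sample subjects)
    _proj: np.ndarray | None = field(default=None, repr=False)
    _norm: NormalizedMatrix | None = field(default=None, repr=False)


@dataclass
class StratumModel:
    """K quantile strata of the ancestry score with Gaussian-style summaries."""

    K: int
    boundaries: np.ndarray  # K-1 interior cut points of w
    centers: np.ndarray  # c_k, strictly increasing
    variances: np.ndarray  # within-stratum sample variance of w
    priors: np.ndarray  # pi_k = N_k / N
    sizes: np.ndarray


def normalize(G, return_matrix: bool = True) -> NormalizedMatrix:
    """Normalize a genotype matrix for PCA.

    Accepts a :class:`GenotypeMatrix` (missing calls are mean-imputed
    first) or a float array with no missing entries.
    """
    if isinstance(G, GenotypeMatrix):
        G = impute_mean(G)
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need an N x P matrix with N >= 2")
    n = G.shape[0]
    col_means = G.mean(axis=0)
    p = (1.0 + G.sum(axis=0)) / (2.0 + 2.0 * n)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    X = (G - col_means[None, :]) / scale[None, :]
    return NormalizedMatrix(X=X, col_means=col_means, p=p)


def fit_pca(X, q: int = 10) -> AncestryModel:
    """Eigendecompose the N x N covariance Psi = X X' / P and weight the top q.

    The decomposition goes through whichever Gram matrix is smaller
    (N x N or P x P), so the result is exact either way.  Eigenvector signs
    are fixed by making the largest-magnitude loading positive, which makes
    the weighted score reproducible across runs and platforms.
    """
    if isinstance(X, NormalizedMatrix):
        norm = X
        X = norm.X
    else:
        norm = None
        X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= q <= min(n, p):
        raise ValueError(f"q must be in [1, min(N, P)] = [1, {min(n, p)}], got {q}")

    if n <= p:
        psi = (X @ X.T) / p
        evals, evecs = np.linalg.eigh(psi)
        order = np.argsort(evals)[::-1][:q]
        lam = evals[order]
        U = evecs[:, order]
    else:
        gram = X.T @ X  # P x P
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1][:q]
        mu = evals[order]
        V = evecs[:, order]
        lam = mu / p
        with np.errstate(divide="ignore", invalid="ignore"):
            U = X @ (V / np.sqrt(np.maximum(mu, 0.0))[None, :])

    if lam[q - 1] <= 1e-12 * max(lam[0], 1.0):
        raise ValueError(f"q={q} exceeds the numerical rank of the data")

    # sign convention: largest-|loading| entry positive
    for r in range(q):
        i = int(np.argmax(np.abs(U[:, r])))
        if U[i, r] < 0:
            U[:, r] = -U[:, r]

    a = lam / lam.sum()
    w = U @ a
    proj = None
    if norm is not None:
        # right basis for projecting new normalized subjects: V / sqrt(mu)
        # recovered as X' U / (lam * p) scaled; store X' U diag(1/(lam*p))
        proj = X.T @ (U / (lam * p)[None, :])
    return AncestryModel(eigenvectors=U, eigenvalues=lam, q=q, weights=a,
                         scores=w, _proj=proj, _norm=norm)


def project(model: AncestryModel, G_new) -> np.ndarray:
    """Project new subjects onto a fitted model's component space.

    Returns an M x q loading matrix on the training eigenvector scale; new
    genotypes are normalized with the training means and frequencies.
    Only available when the model was fitted from a NormalizedMatrix.
    """
    if model._proj is None or model._norm is None:
        raise ValueError("model was not fitted with projection support")
    if isinstance(G_new, GenotypeMatrix):
        G_new = impute_mean(G_new)
    G_new = np.asarray(G_new, dtype=float)
    scale = np.sqrt(2.0 * model._norm.p * (1.0 - model._norm.p))
    Xn = (G_new - model._norm.col_means[None, :]) / scale[None, :]
    return Xn @ model._proj


def weighted_score(loadings: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """w = sum_r a_r v^r for arbitrary (projected) subject loadings."""
    return np.asarray(loadings) @ np.asarray(weights)


def assign_strata(w: np.ndarray, K: int) -> tuple[StratumModel, np.ndarray]:
    """Cut subjects into K equal-size quantile bins of the ancestry score.

    Ties are broken by stable input order, so bin sizes differ by at most
    one.  Returns the stratum summaries and a length-N label vector.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, N], got K={K}, N={n}")
    order = np.argsort(w, kind="stable")
    chunks = np.array_split(order, K)
    if min(len(c) for c in chunks) < 2:
        raise ValueError(
            f"K={K} leaves a stratum with fewer than 2 subjects "
            f"(variance undefined); use a smaller K"
        )
    labels = np.empty(n, dtype=int)
    centers = np.empty(K)
    variances = np.empty(K)
    sizes = np.empty(K, dtype=int)
    for k, idx in enumerate(chunks):
        labels[idx] = k
        centers[k] = w[idx].mean()
        variances[k] = w[idx].var(ddof=1)
        sizes[k] = len(idx)
    if K > 1 and not np.all(np.diff(centers) > 0):
        raise ValueError("stratum centers are not strictly increasing; "
                         "the score has too many ties for this K")
    if np.any(variances <= 0):
        raise ValueError("a stratum has zero score variance; use a smaller K")
    boundaries = np.array([w[chunks[k + 1]].min() for k in range(K - 1)])
    priors = sizes / n
    model = StratumModel(K=K, boundaries=boundaries, centers=centers,
                         variances=variances, priors=priors, sizes=sizes)
    return model, labels


def membership_likelihood(w, center: float, variance: float) -> np.ndarray:
    """Pr(x | stratum) = Pr[chi2_1 > (w - c_k)^2 / sigma_k^2].

    The squared standardized distance of a subject's score to the stratum
    center is referred to the 1-df chi-squared survival function, so the
    likelihood is 1 at the center and decays with distance.
    """
    if variance <= 0:
        raise ValueError("stratum variance must be positive")
    d2 = (np.asarray(w, dtype=float) - center) ** 2 / variance
    return stats.chi2.sf(d2, df=1)


def posterior_propensity(likelihoods, priors) -> np.ndarray:
    """Bayes posterior over strata: normalize likelihood x prior per subject.

    Accepts a length-K vector or an N x K matrix of likelihoods.  Rows whose
    likelihoods all underflow to zero fall back to the priors (with a
    warning) rather than producing 0/0.
    """
    lik = np.atleast_2d(np.asarray(likelihoods, dtype=float))
    priors = np.asarray(priors, dtype=float)
    if lik.shape[1] != priors.shape[0]:
        raise ValueError("likelihood and prior lengths differ")
    if np.any(lik < 0):
        raise ValueError("likelihoods must be non-negative")
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    num = lik * priors[None, :]
    total = num.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} subject(s) had zero likelihood in every "
            "stratum; falling back to the prior proportions", RuntimeWarning
        )
        num[zero] = priors[None, :]
        total[zero] = 1.0
    post = num / total[:, None]
    return post[0] if np.asarray(likelihoods).ndim == 1 else post


def propensity_matrix(w, strata: StratumModel) -> np.ndarray:
    """N x K posterior membership probabilities for scores ``w`` (Eqs. 2-3)."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    lik = np.column_stack([
        membership_likelihood(w, strata.centers[k], strata.variances[k])
        for k in range(strata.K)
    ])
    return np.atleast_2d(posterior_propensity(lik, strata.priors))


class PCAncestry(BaseEstimator):
    """Estimator wrapper around the normalize -> PCA -> strata pipeline.

    Parameters
    ----------
    q : int
        Number of principal components retained for the weighted score.
    K : int
        Number of quantile strata.

    After ``fit`` the instance exposes ``model_`` (eigenpairs and scores),
    ``strata_`` (stratum summaries), and ``labels_``; ``predict_proba``
    returns posterior stratum propensities for the fitted subjects or,
    via projection, for new genotype matrices.
    """

    def __init__(self, q: int = 10, K: int = 2):
        self.q = q
        self.K = K

    def fit(self, G, y=None):
        norm = normalize(G)
        self.model_ = fit_pca(norm, q=self.q)
        self.strata_, self.labels_ = assign_strata(self.model_.scores, self.K)
        return self

    def predict_proba(self, G=None) -> np.ndarray:
        if G is None:
            w = self.model_.scores
        else:
            w = weighted_score(project(self.model_, G), self.model_.weights)
        return propensity_matrix(w, self.strata_)

    def predict(self, G=None) -> np.ndarray:
        return np.argmax(self.predict_proba(G), axis=1)


# ---------------------------------------------------------------------------
# PLINK --pca dialect import/export
# ---------------------------------------------------------------------------

def write_eigenvec(model: AncestryModel, samples: list[str], prefix: str) -> None:
    """Write .eigenvec / .eigenval files in the PLINK --pca output dialect."""
    with open(f"{prefix}.eigenvec", "w") as fh:
        for i, s in enumerate(samples):
            pcs = " ".join(repr(float(v)) for v in model.eigenvectors[i])
            fh.write(f"{s} {s} {pcs}\n")
    with open(f"{prefix}.eigenval", "w") as fh:
        for lam in model.eigenvalues:
            fh.write(f"{float(lam)!r}\n")


def read_eigenvec(prefix: str, q: int | None = None) -> tuple[list[str], AncestryModel]:
    """Read PLINK-style .eigenvec/.eigenval into an :class:`AncestryModel`.

    Lets externally computed principal components (e.g. from PLINK itself)
    be injected into the stratification pipeline.
    """
    rows = []
    samples = []
    with open(f"{prefix}.eigenvec") as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            rows.append([float(x) for x in parts[2:]])
    U = np.array(rows)
    lam = np.loadtxt(f"{prefix}.eigenval", ndmin=1)
    q = q or min(U.shape[1], lam.shape[0])
    U, lam = U[:, :q], lam[:q]
    a = lam / lam.sum()
    model = AncestryModel(eigenvectors=U, eigenvalues=lam, q=q, weights=a,
                          scores=U @ a)
    return samples, model
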