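"""Five-group cross-validation harness and accuracy metrics.

All method arms share one fold partition (a paired comparison), folds are
derived from sample identifiers so the split is invariant to input order,
and accuracy is the Pearson correlation between observed and predicted
outcome for continuous traits or the AUC for binary traits.  Results are
reported as per-fold values plus mean and across-fold SD, mirroring how
5GCV accuracies are normally summarized.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, PhenotypeTable
from .prism import PrismVote, _as_counts, _as_y, _infer_trait, reference_fit_predict


def pearson_r(observed, predicted) -> float:
    """Product-moment correlation between observed and predicted outcomes."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two 1-d vectors of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


def auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Ties between case and control scores contribute 1/2.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("labels must be 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVReport:
    """Per-fold, per-arm accuracies from one shared fold partition."""

    fold_metrics: pd.DataFrame  # rows = arms, columns = fold0..foldk
    means: pd.Series
    sds: pd.Series
    fold_assignments: np.ndarray  # fold index per subject
    fingerprint: str
    seed: int
    trait_type: str
    config: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "fold_metrics": {a: list(map(float, row))
                             for a, row in self.fold_metrics.iterrows()},
            "means": {a: float(v) for a, v in self.means.items()},
            "sds": {a: float(v) for a, v in self.sds.items()},
            "fingerprint": self.fingerprint,
            "seed": self.seed,
            "trait_type": self.trait_type,
            "config": self.config,
            "errors": self.errors,
        }, indent=2)


def _fold_assignments(sample_ids, y, folds, seed, stratify) -> np.ndarray:
    """Seeded fold labels, stable under permutation of input order.

    Subjects are processed in sorted-identifier order so that the same
    cohort presented in a different row order receives identical fold
    membership per subject.
    """
    ids = np.asarray(sample_ids, dtype=str)
    if len(set(ids)) != len(ids):
        raise ValueError("sample identifiers must be unique")
    order = np.argsort(ids, kind="stable")
    rng = np.random.default_rng(seed)
    assign = np.empty(len(ids), dtype=int)
    if stratify:
        for cls in (0.0, 1.0):
            members = order[y[order] == cls]
            perm = rng.permutation(len(members))
            assign[members[perm]] = np.arange(len(members)) % folds
    else:
        perm = rng.permutation(len(ids))
        assign[order[perm]] = np.arange(len(ids)) % folds
    return assign


def run_5gcv(G, y, arms: dict | None = None, folds: int = 5, seed: int = 0,
             trait_type: str = "auto", sample_ids=None) -> CVReport:
    """Paired cross-validated comparison of method arms.

    ``arms`` maps an arm name to a parameter dict for :class:`PrismVote`
    (e.g. ``{"pv": {"K": 2, "q": 10}, "reference": {"K": 1, "q": 10}}``,
    which is also the default).  An arm named exactly ``"reference"`` with
    no ``K`` entry runs the independent single-model reference path.  All
    arms see the same fold partition; binary traits are case-stratified so
    no test fold is single-class.  A failing arm is recorded under
    ``errors`` and the remaining arms proceed.
    """
    M, _ = _as_counts(G)
    yv, ty = _as_y(y)
    trait = _infer_trait(yv, ty if ty else trait_type)
    if sample_ids is None:
        if isinstance(G, GenotypeMatrix):
            sample_ids = G.samples
        else:
            sample_ids = [f"S{i}" for i in range(M.shape[0])]
    if arms is None:
        arms = {"pv": {"K": 2, "q": 10}, "reference": {"K": 1, "q": 10}}

    metric = auc if trait == "binary" else pearson_r
    assign = _fold_assignments(sample_ids, yv, folds, seed,
                               stratify=(trait == "binary"))
    fingerprint = hashlib.sha1(
        ("|".join(f"{s}:{f}" for s, f in sorted(zip(map(str, sample_ids),
                                                    assign)))).encode()
    ).hexdigest()[:16]

    results = {name: [] for name in arms}
    errors: dict[str, str] = {}
    for f in range(folds):
        te = np.where(assign == f)[0]
        tr = np.where(assign != f)[0]
        for name, params in arms.items():
            if name in errors:
                continue
            try:
                params = dict(params)
                if name == "reference" and "K" not in params:
                    pred = reference_fit_predict(
                        M[tr], yv[tr], M[te], trait_type=trait, **params)
                else:
                    est = PrismVote(trait_type=trait, **params)
                    est.fit(M[tr], yv[tr])
                    pred = est.predict(M[te])
                results[name].append(metric(yv[te], pred))
            except Exception as exc:  # noqa: BLE001 - arm isolation
                warnings.warn(f"arm {name!r} failed on fold {f}: {exc}",
                              RuntimeWarning)
                errors[name] = str(exc)

    ok = {n: v for n, v in results.items() if n not in errors and len(v) == folds}
    fold_metrics = pd.DataFrame.from_dict(ok, orient="index",
                                          columns=[f"fold{i}" for i in range(folds)])
    return CVReport(
        fold_metrics=fold_metrics,
        means=fold_metrics.mean(axis=1),
        sds=fold_metrics.std(axis=1, ddof=1),
        fold_assignments=assign,
        fingerprint=fingerprint,
        seed=seed,
        trait_type=trait,
        config={name: dict(p) for name, p in arms.items()},
        errors=errors,
    )


def compare_arms(report: CVReport, arm: str = "pv",
                 reference: str = "reference") -> dict:
    """Fold-wise relative improvement of ``arm`` over ``reference``.

    Computes 100 * (a_f - r_f) / r_f per fold, then the mean and SD across
    folds.  Folds where the reference accuracy is not positive are excluded
    with a warning (the ratio is meaningless there).
    """
    for name in (arm, reference):
        if name not in report.fold_metrics.index:
            raise KeyError(f"arm {name!r} not present in the report")
    a = report.fold_metrics.loc[arm].to_numpy()
    r = report.fold_metrics.loc[reference].to_numpy()
    ok = r > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} fold(s) had non-positive reference accuracy "
            "and were excluded from the relative improvement", RuntimeWarning)
    if not ok.any():
        raise ValueError("no fold with positive reference accuracy")
    rel = 100.0 * (a[ok] - r[ok]) / r[ok]
    return {
        "per_fold_percent": rel,
        "mean_percent": float(rel.mean()),
        "sd_percent": float(rel.std(ddof=1)) if rel.size > 1 else 0.0,
        "n_folds_used": int(ok.sum()),
    }


def plot_accuracy_sweep(x, arm_means: dict, xlabel: str, ylabel: str,
                        path: str) -> None:
    """Line plot of mean accuracy against a swept parameter, one line per arm."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, means in arm_means.items():
        ax.plot(x, means, marker="o", label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
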