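"""Synthetic multi-population genotype/phenotype generation.

Three generative designs are covered:

* a mixed cohort of two source populations plus admixed subjects, with
  three-tier polygenic effects partially shared between populations
  (``simulate_mixed_cohort`` with ``effect_model="tiered"``);
* the same cohort with causal effects drawn jointly from a bivariate
  normal whose cross-population correlation is the effect-similarity
  ratio eta (``effect_model="correlated"``);
* sample-size sweeps, obtained by calling the generator at increasing N.

Allele-frequency divergence between the two source populations follows the
Balding-Nichols model at a chosen Fst, standing in for real reference MAF
spectra when none are supplied.  Admixed subjects draw genotypes from
Bin(2, Q_E p_E + Q_A p_A) and carry the Q-weighted combination of the two
populations' effect vectors.  Phenotypes are built on normalized genotypes
with the residual variance calibrated to a target heritability, or
dichotomized by a liability threshold for binary traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ancestry import normalize
from .io import GenotypeMatrix, PhenotypeTable, VariantRecord


@dataclass
class SimScenario:
    """Parameters of one synthetic cohort.

    Defaults mirror the reference mixed-population design: two source
    populations (2,657 and 1,932 subjects) plus 2,000 admixed subjects,
    9,242 common variants, 3,000 causal variants per population with 75%
    shared, effect tiers of 10 large N(0, 1e-2), 300 moderate N(0, 1e-3)
    and the remaining causal variants N(0, 1e-4), and heritability 0.5.
    """

    P: int = 9242
    n_pop1: int = 2657
    n_pop2: int = 1932
    n_admixed: int = 2000
    fst: float = 0.15
    n_causal: int = 3000
    shared_fraction: float = 0.75
    effect_model: str = "tiered"  # "tiered" | "correlated"
    tiers: tuple = ((10, 1e-2), (300, 1e-3))
    tail_variance: float = 1e-4
    sigma1: float = 1.0  # total effect scale, correlated model
    sigma2: float = 1.0
    eta: float = 0.5
    h2: float = 0.5
    trait_type: str = "continuous"
    prevalence: float = 0.5
    q_distribution: str = "uniform"  # admixed ancestry fractions
    use_normalized: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must be in [0, 1]")
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.n_causal > self.P:
            raise ValueError("n_causal cannot exceed P")


@dataclass
class SimOutput:
    """A generated cohort with its full generative truth attached."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    beta_pop1: np.ndarray
    beta_pop2: np.ndarray
    causal_pop1: np.ndarray
    causal_pop2: np.ndarray
    Q: np.ndarray  # (N, 2) ancestry fractions (pop1, pop2)
    population: np.ndarray  # string labels per subject
    maf_pop1: np.ndarray
    maf_pop2: np.ndarray
    realized_h2: float
    genetic_value: np.ndarray = field(repr=False, default=None)


def draw_maf_spectra(P: int, fst: float, rng, maf_range=(0.05, 0.5)):
    """Paired population allele frequencies under the Balding-Nichols model.

    Ancestral MAFs are uniform on ``maf_range``; each population's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral value,
    which gives between-population divergence Fst = F.  Population
    frequencies are clipped away from 0 and 1 but may drift above 0.5.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    p0 = rng.uniform(*maf_range, size=P)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    eps = 1e-4
    return np.clip(p1, eps, 1 - eps), np.clip(p2, eps, 1 - eps)


def load_maf_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (p_pop1, p_pop2) frequency table (tab/space/comma)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two frequency columns")
    arr = df.iloc[:, :2].to_numpy(dtype=float)
    if np.any((arr <= 0) | (arr >= 1)) or np.isnan(arr).any():
        raise ValueError(f"{path}: frequencies must be in (0, 1)")
    return arr[:, 0], arr[:, 1]


def simulate_genotypes(p1: np.ndarray, p2: np.ndarray, Q: np.ndarray, rng) -> np.ndarray:
    """Independent Bin(2, Q1 p1 + Q2 p2) draws per subject and locus."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    mix = Q[:, [0]] * p1[None, :] + Q[:, [1]] * p2[None, :]
    if np.any((mix <= 0) | (mix >= 1)):
        raise ValueError("mixture frequencies must be in (0, 1)")
    return rng.binomial(2, mix).astype(np.int8)


def sample_effects_tiered(P: int, n_causal: int, shared_fraction: float, rng,
                          tiers=((10, 1e-2), (300, 1e-3)),
                          tail_variance: float = 1e-4):
    """Three-tier causal effects for two populations with partial overlap.

    Each population gets ``n_causal`` causal positions; a fraction
    ``shared_fraction`` of them is common to both.  Within each
    population's causal set, tier sizes and variances follow ``tiers``
    (large and moderate effects) with every remaining causal variant drawn
    at ``tail_variance``.  Non-causal positions have effect 0.
    """
    n_tier = sum(t[0] for t in tiers)
    if n_tier > n_causal:
        raise ValueError("tier sizes exceed the causal count")
    n_shared = int(round(shared_fraction * n_causal))
    n_unique = n_causal - n_shared
    if n_shared + 2 * n_unique > P:
        raise ValueError("P too small for the requested causal sets")
    pool = rng.permutation(P)
    shared = pool[:n_shared]
    uniq1 = pool[n_shared:n_shared + n_unique]
    uniq2 = pool[n_shared + n_unique:n_shared + 2 * n_unique]
    causal1 = np.sort(np.concatenate([shared, uniq1]))
    causal2 = np.sort(np.concatenate([shared, uniq2]))

    def draw(causal):
        beta = np.zeros(P)
        order = rng.permutation(causal)
        start = 0
        for size, var in tiers:
            beta[order[start:start + size]] = rng.normal(0, np.sqrt(var), size)
            start += size
        rest = order[start:]
        beta[rest] = rng.normal(0, np.sqrt(tail_variance), rest.size)
        return beta

    return draw(causal1), draw(causal2), causal1, causal2


def sample_effects_correlated(m: int, sigma1: float, sigma2: float,
                              eta: float, rng):
    """Joint causal effects for two populations with similarity eta.

    Per-SNP effects are bivariate normal with variances sigma_k^2 / m and
    covariance rho / m where rho = eta * sigma1 * sigma2, so the
    cross-population effect correlation equals eta and each population's
    total additive variance is sigma_k^2.
    """
    if not 0 <= eta <= 1:
        raise ValueError("eta must be in [0, 1] (covariance must be PSD)")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("effect scales must be positive")
    rho = eta * sigma1 * sigma2
    cov = np.array([[sigma1**2, rho], [rho, sigma2**2]]) / m
    if eta == 1.0 and sigma1 == sigma2:
        b = rng.normal(0, sigma1 / np.sqrt(m), m)
        return b, b.copy()
    draws = rng.multivariate_normal(np.zeros(2), cov, size=m)
    return draws[:, 0], draws[:, 1]


def admix_effects(beta1: np.ndarray, beta2: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Per-subject effect vectors: the Q-weighted convex combination."""
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.shape != beta2.shape:
        raise ValueError("effect vector lengths differ")
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    return Q[:, [0]] * beta1[None, :] + Q[:, [1]] * beta2[None, :]


def simulate_phenotype(G, beta1, beta2, Q, h2: float, rng,
                       trait_type: str = "continuous",
                       prevalence: float = 0.5,
                       use_normalized: bool = True):
    """Phenotypes from per-subject admixed effects at target heritability.

    The genetic value is g_i = sum_j x_ij (Q_i1 beta1_j + Q_i2 beta2_j) on
    normalized (or raw-count) genotypes; residuals are normal with variance
    Var(g) (1 - h2) / h2, calibrated on the realized sample variance of g
    so the target h2 holds per replicate.  Binary traits threshold the
    liability at the normal quantile matching ``prevalence``.

    Returns (y, genetic_value, realized_h2).
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    if isinstance(G, GenotypeMatrix):
        counts = G.G.astype(float)
    else:
        counts = np.asarray(G, dtype=float)
    X = normalize(counts).X if use_normalized else counts
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    g = Q[:, 0] * (X @ np.asarray(beta1, float)) + Q[:, 1] * (X @ np.asarray(beta2, float))
    var_g = float(np.var(g, ddof=1))
    if var_g <= 0:
        raise ValueError("genetic value has zero variance (all effects zero?)")
    sigma_e = np.sqrt(var_g * (1 - h2) / h2)
    liability = g + rng.normal(0, sigma_e, size=g.shape[0])
    realized = var_g / float(np.var(liability, ddof=1))
    if trait_type == "continuous":
        return liability, g, realized
    if trait_type == "binary":
        thr = stats.norm.ppf(1 - prevalence, loc=float(np.mean(liability)),
                             scale=np.sqrt(var_g / h2))
        return (liability > thr).astype(float), g, realized
    raise ValueError("trait_type must be 'continuous' or 'binary'")


def _variant_records(P: int) -> list[VariantRecord]:
    return [VariantRecord("1", j + 1, f"snp{j + 1}", "A", "C") for j in range(P)]


def simulate_mixed_cohort(scenario: SimScenario | None = None, **kwargs) -> SimOutput:
    """Generate a full mixed-population cohort from a :class:`SimScenario`.

    Keyword arguments override scenario fields, so
    ``simulate_mixed_cohort(P=800, n_admixed=0, seed=3)`` works directly.
    """
    if scenario is None:
        scenario = SimScenario(**kwargs)
    elif kwargs:
        from dataclasses import replace
        scenario = replace(scenario, **kwargs)
    s = scenario
    rng = np.random.default_rng(s.seed)

    p1, p2 = draw_maf_spectra(s.P, s.fst, rng)

    Q_parts, pops = [], []
    if s.n_pop1:
        Q_parts.append(np.column_stack([np.ones(s.n_pop1), np.zeros(s.n_pop1)]))
        pops += ["pop1"] * s.n_pop1
    if s.n_pop2:
        Q_parts.append(np.column_stack([np.zeros(s.n_pop2), np.ones(s.n_pop2)]))
        pops += ["pop2"] * s.n_pop2
    if s.n_admixed:
        if s.q_distribution == "uniform":
            qe = rng.uniform(0, 1, s.n_admixed)
        elif s.q_distribution == "beta":
            qe = rng.beta(2, 2, s.n_admixed)
        else:
            raise ValueError(f"unknown q_distribution {s.q_distribution!r}")
        Q_parts.append(np.column_stack([qe, 1 - qe]))
        pops += ["admixed"] * s.n_admixed
    if not Q_parts:
        raise ValueError("cohort is empty")
    Q = np.vstack(Q_parts)
    population = np.array(pops)

    counts = simulate_genotypes(p1, p2, Q, rng)

    if s.effect_model == "tiered":
        b1, b2, c1, c2 = sample_effects_tiered(
            s.P, s.n_causal, s.shared_fraction, rng,
            tiers=s.tiers, tail_variance=s.tail_variance,
        )
    elif s.effect_model == "correlated":
        pool = np.sort(rng.permutation(s.P)[: s.n_causal])
        bm1, bm2 = sample_effects_correlated(s.n_causal, s.sigma1, s.sigma2,
                                             s.eta, rng)
        b1 = np.zeros(s.P)
        b2 = np.zeros(s.P)
        b1[pool] = bm1
        b2[pool] = bm2
        c1 = c2 = pool
    else:
        raise ValueError(f"unknown effect_model {s.effect_model!r}")

    y, g, realized = simulate_phenotype(
        counts, b1, b2, Q, s.h2, rng, trait_type=s.trait_type,
        prevalence=s.prevalence, use_normalized=s.use_normalized,
    )

    samples = [f"S{i + 1}" for i in range(counts.shape[0])]
    gm = GenotypeMatrix(samples=samples, variants=_variant_records(s.P), G=counts)
    pt = PhenotypeTable(samples=samples, y=y, trait_type=s.trait_type)
    return SimOutput(genotypes=gm, phenotypes=pt, beta_pop1=b1, beta_pop2=b2,
                     causal_pop1=c1, causal_pop2=c2, Q=Q,
                     population=population, maf_pop1=p1, maf_pop2=p2,
                     realized_h2=realized, genetic_value=g)


def write_truth_tables(out: SimOutput, prefix: str) -> None:
    """Write beta / Q / causal-set truth tables as tab-delimited text."""
    np.savetxt(f"{prefix}.beta.tsv",
               np.column_stack([out.beta_pop1, out.beta_pop2]),
               delimiter="\t", header="beta_pop1\tbeta_pop2", comments="")
    np.savetxt(f"{prefix}.Q.tsv", out.Q, delimiter="\t",
               header="Q_pop1\tQ_pop2", comments="")
    with open(f"{prefix}.causal.tsv", "w") as fh:
        fh.write("population\tindex\n")
        for idx in out.causal_pop1:
            fh.write(f"pop1\t{idx}\n")
        for idx in out.causal_pop2:
            fh.write(f"pop2\t{idx}\n")
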