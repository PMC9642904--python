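"""Genotype and phenotype I/O plus variant-level quality control.

Genotypes are held as an N x P matrix of minor-allele counts (0/1/2, with
``MISSING = -1`` as the sentinel for no-calls).  The minor allele is always
the allele with the lower in-sample frequency; files whose counted allele is
in fact the major allele are recoded on read so that downstream code can
assume the minor-allele-count convention throughout.

Supported formats: PLINK 1 binary triplets (.bed/.bim/.fam, SNP-major) and
VCF v4.x with diploid GT fields.  Phenotypes are read from PLINK-style
.pheno tables (FID IID value, whitespace- or comma-delimited).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> minor-allele counts of the A1 allele:
#   00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2 (0 copies)
_PLINK_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_PLINK_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}

# byte -> 4 genotypes lookup, built once
_BYTE_LUT = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _PLINK_CODE_TO_COUNT[(_b >> (2 * _k)) & 3]


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant with its minor/major allele designation."""

    chromosome: str
    position: int
    id: str
    allele_minor: str
    allele_major: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1")
        if not self.allele_minor or not self.allele_major:
            raise ValueError(f"variant {self.id}: alleles must be non-empty")


@dataclass
class GenotypeMatrix:
    """N x P matrix of minor-allele counts with sample and variant metadata."""

    samples: list[str]
    variants: list[VariantRecord]
    G: np.ndarray  # int8, entries in {0, 1, 2, MISSING}

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.G, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return (self.G == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency among non-missing calls."""
        obs = self.G != MISSING
        counts = np.where(obs, self.G, 0).sum(axis=0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = counts / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[v for v, keep in zip(self.variants, mask) if keep],
            G=self.G[:, mask].copy(),
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            G=self.G[idx, :].copy(),
        )


@dataclass
class PhenotypeTable:
    """Outcome vector aligned to genotype samples.

    ``trait_type`` is "continuous" or "binary"; binary traits contain only
    0/1 plus NaN for missing.
    """

    samples: list[str]
    y: np.ndarray  # float, NaN = missing
    trait_type: str = "continuous"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.samples),):
            raise ValueError("phenotype length does not match sample count")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError("trait_type must be 'continuous' or 'binary'")
        if self.trait_type == "binary":
            obs = self.y[~np.isnan(self.y)]
            if not np.isin(obs, [0.0, 1.0]).all():
                raise ValueError("binary trait values must be 0/1 (or missing)")

    def align_to(self, gm: GenotypeMatrix) -> "PhenotypeTable":
        """Reorder/intersect to match the genotype sample order exactly."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in gm.samples if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}")
        idx = [lookup[s] for s in gm.samples]
        return PhenotypeTable(list(gm.samples), self.y[idx], self.trait_type)


@dataclass
class QCReport:
    """Per-criterion removal accounting from :func:`qc_filter`."""

    n_input: int
    n_retained: int
    removed_missing: int
    removed_hwe: int
    removed_maf: int
    keep_mask: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def _recode_to_minor(G: np.ndarray, a1: list[str], a2: list[str]):
    """Flip columns so the counted allele is the in-sample minor allele.

    Ties at frequency exactly 0.5 are broken lexicographically: the smaller
    allele string is designated minor.
    """
    variants_minor, variants_major = [], []
    obs = G != MISSING
    counts = np.where(obs, G, 0).sum(axis=0)
    n_obs = obs.sum(axis=0)
    for j in range(G.shape[1]):
        if n_obs[j] == 0:
            freq = 0.0
        else:
            freq = counts[j] / (2.0 * n_obs[j])
        flip = freq > 0.5 or (freq == 0.5 and a1[j] > a2[j])
        if flip:
            col = G[:, j]
            G[:, j] = np.where(col == MISSING, MISSING, 2 - col)
            variants_minor.append(a2[j])
            variants_major.append(a1[j])
        else:
            variants_minor.append(a1[j])
            variants_major.append(a2[j])
    return G, variants_minor, variants_major


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet into a :class:`GenotypeMatrix`.

    The .bed file must be SNP-major v1.1 (magic ``6c 1b 01``).  Columns are
    recoded so that counts refer to the in-sample minor allele regardless of
    which allele the file counted.
    """
    prefix = os.fspath(prefix)
    paths = {ext: f"{prefix}.{ext}" for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing PLINK member: {p}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype=str)
    bim = pd.read_csv(paths["bim"], sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    n, p = len(fam), len(bim)

    with open(paths["bed"], "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{paths['bed']}: bad magic bytes (not SNP-major PLINK 1 .bed)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * p:
        raise ValueError(
            f"{paths['bed']}: expected {bytes_per_snp * p} data bytes for "
            f"{n} samples x {p} variants, found {body.size}"
        )
    decoded = _BYTE_LUT[body.reshape(p, bytes_per_snp)]  # (p, bytes, 4)
    G = decoded.reshape(p, bytes_per_snp * 4)[:, :n].T.copy()  # (n, p)

    G, minor, major = _recode_to_minor(G, bim["a1"].tolist(), bim["a2"].tolist())
    variants = [
        VariantRecord(str(c), int(pos), str(vid), mi, ma)
        for c, pos, vid, mi, ma in zip(bim["chrom"], bim["pos"], bim["id"], minor, major)
    ]
    return GenotypeMatrix(samples=fam["iid"].tolist(), variants=variants, G=G)


def write_plink(gm: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a SNP-major PLINK triplet with A1 = minor allele."""
    prefix = os.fspath(prefix)
    with open(f"{prefix}.fam", "w") as fh:
        for s in gm.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chromosome}\t{v.id}\t0\t{v.position}\t{v.allele_minor}\t{v.allele_major}\n")

    n = gm.n_samples
    bytes_per_snp = (n + 3) // 4
    code = np.empty((gm.n_variants, bytes_per_snp * 4), dtype=np.uint8)
    code[:] = _COUNT_TO_PLINK_CODE[0]  # pad positions encode "0 copies"
    Gt = gm.G.T
    for count, c in _COUNT_TO_PLINK_CODE.items():
        code[:, :n][Gt == count] = c
    packed = (
        code[:, 0::4]
        | (code[:, 1::4] << 2)
        | (code[:, 2::4] << 4)
        | (code[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read diploid GT fields from a VCF into a :class:`GenotypeMatrix`.

    ALT dosages are converted to minor-allele counts (recoding columns where
    the ALT allele is the major one).  Half-calls and missing genotypes map
    to the missing sentinel.  Only biallelic sites are accepted.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    cols, ref, alt, meta = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: variant {var.ID or var.POS} is not biallelic")
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: non-diploid GT for sample {samples[i]} at {var.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                continue  # missing or half-call
            col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        cols.append(col)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        meta.append((str(var.CHROM), int(var.POS), var.ID or f"{var.CHROM}:{var.POS}"))
    G = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    G, minor, major = _recode_to_minor(G, alt, ref)
    variants = [
        VariantRecord(c, pos, vid, mi, ma)
        for (c, pos, vid), mi, ma in zip(meta, minor, major)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, G=G)


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 with GT fields (ALT = minor allele)."""
    with open(os.fspath(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in enumerate(gm.variants):
            gts = "\t".join(gt_map[int(g)] for g in gm.G[:, j])
            fh.write(f"{v.chromosome}\t{v.position}\t{v.id}\t{v.allele_major}\t"
                     f"{v.allele_minor}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotype(path: str | os.PathLike, trait_type: str = "continuous") -> PhenotypeTable:
    """Read a PLINK-style phenotype table (FID IID value, header optional).

    Accepts whitespace- or comma-delimited files.  PLINK missing codes
    (-9, NA) become NaN.
    """
    with open(os.fspath(path)) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    tokens = first.replace(",", " ").split()
    has_header = any(t.upper() in ("FID", "IID") for t in tokens[:2])
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     names=None if has_header else ["FID", "IID", "VALUE"],
                     dtype={0: str, 1: str})
    df.columns = ["FID", "IID", "VALUE"] + list(df.columns[3:])
    y = pd.to_numeric(df["VALUE"], errors="coerce").to_numpy(dtype=float)
    y = np.where(y == -9, np.nan, y)
    return PhenotypeTable(df["IID"].astype(str).tolist(), y, trait_type)


def write_phenotype(pt: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write("FID IID VALUE\n")
        for s, v in zip(pt.samples, pt.y):
            fh.write(f"{s} {s} {'NA' if np.isnan(v) else repr(float(v))}\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_pvalues(gm: GenotypeMatrix, method: str = "chisq") -> np.ndarray:
    """Per-variant Hardy–Weinberg p-values on observed genotype counts.

    method="chisq" is the 1-df goodness-of-fit approximation; "exact" is the
    full enumeration of heterozygote counts conditional on allele counts.
    Monomorphic variants get p = 1.
    """
    if method not in ("chisq", "exact"):
        raise ValueError("method must be 'chisq' or 'exact'")
    G = gm.G
    n2 = (G == 2).sum(axis=0)
    n1 = (G == 1).sum(axis=0)
    n0 = (G == 0).sum(axis=0)
    if method == "chisq":
        n = n0 + n1 + n2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (2 * n2 + n1) / (2 * n)
            e0 = n * (1 - p) ** 2
            e1 = n * 2 * p * (1 - p)
            e2 = n * p**2
            chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
        pvals = stats.chi2.sf(chi2, df=1)
        mono = (p <= 0) | (p >= 1) | (n == 0)
        pvals[mono] = 1.0
        return pvals
    return np.array([_hwe_exact(a, b, c) for a, b, c in zip(n1, n2, n0)])


def _hwe_exact(n_het: int, n_hom_min: int, n_hom_maj: int) -> float:
    """Exact HWE test (sum of probabilities <= observed, over het counts)."""
    n = n_het + n_hom_min + n_hom_maj
    n_rare = 2 * n_hom_min + n_het
    if n == 0 or n_rare == 0 or n_rare == 2 * n:
        return 1.0
    n_rare = min(n_rare, 2 * n - n_rare)
    # recurrence over heterozygote counts of the rare allele
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        # P(h) / P(h-2) = 4 * hom_r(h-2) * hom_c(h-2) / (h * (h-1))
        hom_r = (n_rare - hets[i - 1]) // 2
        hom_c = n - hets[i - 1] - hom_r
        logp[i] = logp[i - 1] + np.log(4.0 * hom_r * hom_c) - np.log(h * (h - 1.0))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = min(n_het, n_rare)
    p_obs = prob[np.searchsorted(hets, obs)]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    gm: GenotypeMatrix,
    max_missing: float = 0.05,
    hwe_alpha: float = 5e-8,
    min_maf: float = 0.01,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants failing any of: missingness, HWE, or MAF thresholds.

    A variant is removed when its missing-call fraction exceeds
    ``max_missing`` (call rate below 1 - max_missing), its HWE p-value is
    below ``hwe_alpha``, or its minor-allele frequency is below ``min_maf``.
    All criteria are evaluated on the input matrix, then the union of
    failures is dropped, so the filter is idempotent.
    """
    for name, v in (("max_missing", max_missing), ("hwe_alpha", hwe_alpha),
                    ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    miss = gm.missing_rate()
    maf = np.nan_to_num(gm.maf(), nan=0.0)
    hwe = hwe_pvalues(gm, method=hwe_method)

    fail_miss = miss > max_missing
    fail_hwe = hwe < hwe_alpha
    fail_maf = maf < min_maf
    keep = ~(fail_miss | fail_hwe | fail_maf)
    if not keep.any():
        raise ValueError("QC removed every variant; relax the thresholds")

    report = QCReport(
        n_input=gm.n_variants,
        n_retained=int(keep.sum()),
        removed_missing=int(fail_miss.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_maf=int(fail_maf.sum()),
        keep_mask=keep,
    )
    return gm.subset_variants(keep), report


def impute_mean(gm: GenotypeMatrix) -> np.ndarray:
    """Return a float matrix with missing calls replaced by the variant mean.

    Mean imputation keeps the column mean unchanged, which makes it neutral
    for the PCA normalization downstream.
    """
    G = gm.G.astype(float)
    obs = gm.G != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("variant with no observed genotypes cannot be imputed")
    means = np.where(obs, G, 0.0).sum(axis=0) / n_obs
    return np.where(obs, G, means[None, :])
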