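"""Genotype QC, Hardy-Weinberg testing, LD pruning, PCA and kinship.

This is the instrument-preparation stage of the Mendelian randomization
analysis: candidate SNP dosages are quality-controlled (missingness, MAF,
Hardy-Weinberg equilibrium, sample heterozygosity), pruned to an
approximately independent subset, summarised by principal components, and a
relatedness (kinship) matrix is built either from a two-generation pedigree
or from the genotypes themselves.

Dosages count copies of the SNP's *effect allele* and live in {0, 1, 2},
with ``NaN`` for missing calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "qc_filter",
    "hwe_test",
    "hwe_exact_test",
    "ld_prune",
    "pca",
    "kinship_from_pedigree",
    "kinship_from_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_kinship_tsv",
    "write_kinship_tsv",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with allele metadata.

    ``dosages`` is float (n_samples, n_snps) with entries in {0, 1, 2, NaN},
    counting the effect allele.
    """

    sample_ids: list
    snp_ids: list
    effect_alleles: list
    other_alleles: list
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("dosage shape does not match id lists")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        """Subset by boolean masks or index arrays (samples and/or SNPs)."""
        s_idx = np.arange(self.n_samples) if samples is None else np.arange(self.n_samples)[samples]
        m_idx = np.arange(self.n_snps) if snps is None else np.arange(self.n_snps)[snps]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in s_idx],
            snp_ids=[self.snp_ids[j] for j in m_idx],
            effect_alleles=[self.effect_alleles[j] for j in m_idx],
            other_alleles=[self.other_alleles[j] for j in m_idx],
            dosages=self.dosages[np.ix_(s_idx, m_idx)],
        )


@dataclass
class QCReport:
    """Audit trail of a QC pass: what was removed, by which filter, and why."""

    thresholds: dict
    n_snps_before: int = 0
    n_samples_before: int = 0
    n_snps_after: int = 0
    n_samples_after: int = 0
    removed_snps: list = field(default_factory=list)      # (snp_id, reason)
    removed_samples: list = field(default_factory=list)   # (sample_id, reason)

    def to_json(self) -> str:
        return json.dumps({
            "thresholds": self.thresholds,
            "n_snps_before": self.n_snps_before,
            "n_samples_before": self.n_samples_before,
            "n_snps_after": self.n_snps_after,
            "n_samples_after": self.n_samples_after,
            "removed_snps": [{"id": i, "reason": r} for i, r in self.removed_snps],
            "removed_samples": [{"id": i, "reason": r} for i, r in self.removed_samples],
        }, indent=2)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg equilibrium chi-square goodness-of-fit p-value.

    One degree of freedom: three genotype classes minus one constraint minus
    the estimated allele frequency. Monomorphic counts return p = 1 (no test
    possible). Symmetric in (n_AA, n_aa) by construction.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test (sum of probabilities of heterozygote
    counts no more likely than the observed one, conditional on allele
    counts). Optional alternative to the chi-square test for small counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # rarer allele count assumed; symmetrize
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    # log-probability of each feasible heterozygote count given allele counts
    hets = np.arange(n_a % 2, n_a + 1, 2)
    homr = (n_a - hets) // 2
    homc = n - hets - homr
    from scipy.special import gammaln
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(2 * n - n_a + 1))
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_Aa][0]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def _snp_hwe_pvalues(G: GenotypeMatrix, method: str = "chi2") -> np.ndarray:
    test = hwe_test if method == "chi2" else hwe_exact_test
    pvals = np.empty(G.n_snps)
    for j in range(G.n_snps):
        col = G.dosages[:, j]
        col = col[~np.isnan(col)]
        pvals[j] = test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
    return pvals


def qc_filter(
    G: GenotypeMatrix,
    snp_missing_max: float = 0.02,
    sample_missing_max: float = 0.02,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    het_sd: float = 3.0,
    hwe_method: str = "chi2",
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequential genotype QC with an itemized audit report.

    Filters are applied in order: (1) SNP missingness > ``snp_missing_max``;
    (2) sample missingness > ``sample_missing_max``; (3) MAF <
    ``maf_min``; (4) HWE p < ``hwe_p_min``; (5) sample heterozygosity
    outside mean +/- ``het_sd`` SD. Each filter recomputes its statistic on
    the matrix surviving the previous filters, so the pass is idempotent.
    If all heterozygosity rates are identical (SD 0) no sample is flagged.
    """
    if G.n_snps == 0 or G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        thresholds={
            "snp_missing_max": snp_missing_max,
            "sample_missing_max": sample_missing_max,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "het_sd": het_sd,
        },
        n_snps_before=G.n_snps,
        n_samples_before=G.n_samples,
    )

    def _drop_snps(g: GenotypeMatrix, mask_bad: np.ndarray, reason_fmt) -> GenotypeMatrix:
        for j in np.flatnonzero(mask_bad):
            report.removed_snps.append((g.snp_ids[j], reason_fmt(j)))
        if mask_bad.all():
            raise ValueError(f"all SNPs removed by filter: {reason_fmt(0).split(' ')[0]}")
        return g.subset(snps=~mask_bad)

    # 1. SNP missingness
    miss = G.snp_missingness()
    G = _drop_snps(G, miss > snp_missing_max,
                   lambda j, m=miss: f"snp_missingness {m[j]:.4f} > {snp_missing_max}")
    # 2. sample missingness
    smiss = G.sample_missingness()
    bad_s = smiss > sample_missing_max
    for i in np.flatnonzero(bad_s):
        report.removed_samples.append(
            (G.sample_ids[i], f"sample_missingness {smiss[i]:.4f} > {sample_missing_max}"))
    if bad_s.all():
        raise ValueError("all samples removed by filter: sample_missingness")
    G = G.subset(samples=~bad_s)
    # 3. MAF
    maf = G.maf()
    G = _drop_snps(G, maf < maf_min, lambda j, m=maf: f"maf {m[j]:.4f} < {maf_min}")
    # 4. HWE
    hwe_p = _snp_hwe_pvalues(G, method=hwe_method)
    G = _drop_snps(G, hwe_p < hwe_p_min,
                   lambda j, p=hwe_p: f"hwe_p {p[j]:.3e} < {hwe_p_min}")
    # 5. sample heterozygosity outliers
    het = np.nanmean(G.dosages == 1.0, axis=1)
    sd = het.std(ddof=0)
    if sd > 0:
        lo, hi = het.mean() - het_sd * sd, het.mean() + het_sd * sd
        bad_h = (het < lo) | (het > hi)
        for i in np.flatnonzero(bad_h):
            report.removed_samples.append(
                (G.sample_ids[i], f"heterozygosity {het[i]:.4f} outside mean±{het_sd}SD "
                                  f"[{lo:.4f}, {hi:.4f}]"))
        if bad_h.all():
            raise ValueError("all samples removed by filter: heterozygosity")
        G = G.subset(samples=~bad_h)

    report.n_snps_after = G.n_snps
    report.n_samples_after = G.n_samples
    return G, report


def ld_prune(G: GenotypeMatrix, r2_max: float) -> list:
    """Greedy LD pruning in input order.

    A SNP is kept iff its squared Pearson correlation (pairwise-complete
    observations) with every previously kept SNP is below ``r2_max``.
    Zero-variance SNPs are treated as uncorrelated with everything and kept.
    Returns the list of kept SNP indices.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    X = G.dosages
    kept: list[int] = []
    for j in range(G.n_snps):
        ok = True
        for k in kept:
            both = ~np.isnan(X[:, j]) & ~np.isnan(X[:, k])
            if both.sum() < 2:
                continue
            a, b = X[both, j], X[both, k]
            if a.std() == 0 or b.std() == 0:
                continue  # zero variance: r^2 defined as 0
            r = np.corrcoef(a, b)[0, 1]
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


def pca(G: GenotypeMatrix, n_components: int = 10, snp_subset=None) -> np.ndarray:
    """Principal component scores of the samples.

    Missing dosages are mean-imputed per SNP, columns standardized to mean 0
    and unit sample variance, and the top components of the sample
    covariance are returned as per-sample scores (n_samples, n_components).
    """
    X = G.dosages if snp_subset is None else G.dosages[:, snp_subset]
    X = X.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    rank = min(X.shape)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_components] * S[:n_components]


def kinship_from_pedigree(pedigree: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Expected relatedness from a pedigree, scaled so self = 1.

    ``pedigree`` has columns ``id``, ``father``, ``mother`` (parent ids, or
    "0"/NaN for founders). Relatedness is twice the recursive kinship
    coefficient: full siblings and parent-offspring 0.5, half siblings 0.25,
    unrelated founders 0. Returns (matrix, sample id order).
    """
    ids = list(pedigree["id"])
    parent = {}
    for _, row in pedigree.iterrows():
        f, m = row.get("father"), row.get("mother")
        f = None if pd.isna(f) or str(f) == "0" else f
        m = None if pd.isna(m) or str(m) == "0" else m
        parent[row["id"]] = (f, m)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(a, b):  # kinship coefficient
        if a is None or b is None:
            return 0.0
        if a == b:
            fa, mo = parent.get(a, (None, None))
            return 0.5 * (1.0 + phi(fa, mo))
        # recurse on the individual with the greater depth to guarantee
        # termination on acyclic pedigrees
        if depth(a) < depth(b):
            a, b = b, a
        fa, mo = parent.get(a, (None, None))
        return 0.5 * (phi(fa, b) + phi(mo, b))

    @lru_cache(maxsize=None)
    def depth(a):
        if a is None:
            return -1
        fa, mo = parent.get(a, (None, None))
        if fa == a or mo == a:
            raise ValueError(f"individual {a} listed as own ancestor")
        return 1 + max(depth(fa), depth(mo))

    for iid in ids:
        depth(iid)  # raises on self-ancestry

    n = len(ids)
    K = np.zeros((n, n))
    pos = {iid: i for i, iid in enumerate(ids)}
    if "family" in pedigree.columns:
        # relatedness cannot cross family boundaries in this pedigree model;
        # computing within-family blocks only keeps this O(sum f_k^2)
        groups = pedigree.groupby("family")["id"].apply(list)
        for fam_ids in groups:
            for a_i, a in enumerate(fam_ids):
                for b in fam_ids[a_i:]:
                    i, j = pos[a], pos[b]
                    K[i, j] = K[j, i] = 2.0 * phi(a, b)
    else:
        for i in range(n):
            for j in range(i, n):
                K[i, j] = K[j, i] = 2.0 * phi(ids[i], ids[j])
    return K, ids


def kinship_from_genotypes(G: GenotypeMatrix, min_snps: int = 20) -> np.ndarray:
    """Genomic relationship matrix from standardized dosages.

    K = (1/m) * sum_j (g_ij - 2 p_j)(g_kj - 2 p_j) / (2 p_j (1 - p_j)),
    averaging over SNPs with each sample pair's non-missing markers. Under
    Hardy-Weinberg equilibrium, diagonal entries are ~1 in expectation and
    full siblings average 0.5.
    """
    if G.n_snps < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs, have {G.n_snps}")
    p = G.allele_freq()
    usable = (p > 0) & (p < 1)
    X = G.dosages[:, usable]
    p = p[usable]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    obs = ~np.isnan(Z)
    Z0 = np.where(obs, Z, 0.0)
    counts = obs.astype(float) @ obs.astype(float).T
    K = (Z0 @ Z0.T) / np.maximum(counts, 1.0)
    return K


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """Dosage TSV: rows = samples, columns = SNPs, values 0/1/2/NA. Allele
    metadata rides in two comment header lines."""
    with open(path, "w") as fh:
        fh.write("#effect_allele\t" + "\t".join(G.effect_alleles) + "\n")
        fh.write("#other_allele\t" + "\t".join(G.other_alleles) + "\n")
        fh.write("sample_id\t" + "\t".join(map(str, G.snp_ids)) + "\n")
        for i, sid in enumerate(G.sample_ids):
            row = ["NA" if np.isnan(v) else str(int(v)) for v in G.dosages[i]]
            fh.write(str(sid) + "\t" + "\t".join(row) + "\n")


def read_dosage_tsv(path) -> GenotypeMatrix:
    effect, other = None, None
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#effect_allele"):
            effect = line.split("\t")[1:]
            body_start += 1
        elif line.startswith("#other_allele"):
            other = line.split("\t")[1:]
            body_start += 1
        else:
            break
    header = lines[body_start].split("\t")
    snp_ids = header[1:]
    sample_ids, rows = [], []
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        sample_ids.append(parts[0])
        rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
    m = len(snp_ids)
    if effect is None:
        effect = ["A"] * m
    if other is None:
        other = ["G"] * m
    return GenotypeMatrix(sample_ids, snp_ids, effect, other, np.array(rows, dtype=float))


def write_vcf(G: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Minimal biallelic VCF with GT fields; REF = other allele, ALT =
    effect allele, so the ALT dosage equals the stored effect-allele dosage."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.sample_ids)) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, sid in enumerate(G.snp_ids):
            gts = ["./." if np.isnan(v) else gt_map[v] for v in G.dosages[:, j]]
            fh.write(f"{chrom}\t{j + 1}\t{sid}\t{G.other_alleles[j]}\t"
                     f"{G.effect_alleles[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a GenotypeMatrix (ALT-allele dosage from GT).

    Uses cyvcf2 when available, else a plain-text fallback parser for
    uncompressed VCFs. Multi-allelic records are rejected.
    """
    try:
        from cyvcf2 import VCF  # noqa: PLC0415
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, eff, oth, cols = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        oth.append(var.REF)
        eff.append(var.ALT[0])
        gts = var.genotypes  # [allele1, allele2, phased]
        col = []
        for g in gts:
            a, b = g[0], g[1]
            col.append(np.nan if a < 0 or b < 0 else float(a + b))
        cols.append(col)
    return GenotypeMatrix(sample_ids, snp_ids, eff, oth,
                          np.array(cols, dtype=float).T)


def _read_vcf_text(path) -> GenotypeMatrix:
    sample_ids, snp_ids, eff, oth, cols = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[:5]
            if "," in alt:
                raise ValueError(f"non-biallelic record at {chrom}:{pos}")
            snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
            oth.append(ref)
            eff.append(alt)
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            col = []
            for entry in parts[9:]:
                gt = entry.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    col.append(np.nan)
                else:
                    col.append(float(sum(int(a) for a in gt.split("/"))))
            cols.append(col)
    return GenotypeMatrix(sample_ids, snp_ids, eff, oth,
                          np.array(cols, dtype=float).T)


def write_kinship_tsv(K: np.ndarray, sample_ids, path) -> None:
    pd.DataFrame(K, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", index_label="sample_id")


def read_kinship_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)
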