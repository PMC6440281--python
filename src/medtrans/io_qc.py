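"""Genotype/expression/covariate containers, file IO, QC filters and normalization.

Genotypes are SNP-by-sample dosage matrices (0/1/2 counts of one allele,
``NaN`` for missing). Expression is probe-by-sample with genomic intervals.
Quality control follows the standard microarray-era pipeline: sample call
rate, SNP missingness, minor allele frequency, an exact Hardy-Weinberg test,
and removal of SNPs in complete linkage disequilibrium or at duplicated
positions. Expression normalization covers across-sample quantile
normalization and the rank-based inverse-normal transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "CovariateTable",
    "SnpQcReport",
    "load_genotypes",
    "write_genotypes",
    "load_expression",
    "write_expression",
    "load_covariates",
    "write_covariates",
    "compute_maf",
    "recode_to_minor",
    "hwe_exact_test",
    "qc_filter",
    "dedup_complete_ld",
    "quantile_normalize",
    "inverse_normal_transform",
]

#: tokens accepted as missing dosage on read; the first is used on write
MISSING_TOKENS = ("NA", ".", "-9", "")


@dataclass
class GenotypeMatrix:
    """SNP-by-sample dosage matrix with genomic coordinates.

    ``dosages[i, j]`` is the allele count (0, 1 or 2) of SNP ``i`` in sample
    ``j``, with ``NaN`` for missing calls. Coordinates are 1-based.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]!r} at SNP {self.snp_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, snp_mask=None, sample_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        cm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        return GenotypeMatrix(
            self.snp_ids[sm], self.chrom[sm], self.pos[sm],
            self.dosages[np.ix_(sm, cm)], self.sample_ids[cm],
        )


@dataclass
class ExpressionMatrix:
    """Probe-by-sample expression matrix with 1-based inclusive probe intervals."""

    probe_ids: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if (self.start > self.end).any():
            bad = self.probe_ids[self.start > self.end][0]
            raise ValueError(f"probe {bad!r} has start > end")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape does not match ids")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class CovariateTable:
    """Sample-by-covariate table (e.g. sex, genotype PCs, PEER factors)."""

    covariate_names: np.ndarray
    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.covariate_names = np.asarray(self.covariate_names, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids), len(self.covariate_names)
        ):
            raise ValueError("covariate matrix shape does not match ids")

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)


@dataclass
class SnpQcReport:
    """Per-SNP and per-sample QC statistics and pass/fail flags."""

    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# file IO


def _parse_dosage_token(tok: str):
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return np.nan
    if tok in ("0", "1", "2"):
        return float(tok)
    return None


def load_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from a tab-delimited file or a minimal VCF.

    The TSV layout is ``snp_id chrom pos <sample...>`` with dosage tokens
    0/1/2 and missing tokens NA/./-9/empty. VCF import uses the genotype
    subfield only and accepts biallelic records (phased or unphased); the
    dosage is the ALT allele count. Dosages keep the file's allele coding;
    use :func:`recode_to_minor` to reorient to minor-allele counts.
    """
    if format == "vcf":
        return _load_vcf(path)
    if format != "tsv":
        raise ValueError(f"unknown genotype format {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["snp_id", "chrom", "pos"]:
            raise ValueError(f"{path}: expected header starting 'snp_id\\tchrom\\tpos'")
        sample_ids = header[3:]
        snp_ids, chrom, pos, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + len(sample_ids):
                raise ValueError(f"{path}:{lineno}: expected {3 + len(sample_ids)} fields, got {len(fields)}")
            snp_ids.append(fields[0])
            chrom.append(fields[1])
            pos.append(int(fields[2]))
            row = np.empty(len(sample_ids))
            for j, tok in enumerate(fields[3:]):
                val = _parse_dosage_token(tok)
                if val is None:
                    raise ValueError(
                        f"{path}:{lineno}: invalid dosage {tok!r} for SNP {fields[0]!r}"
                    )
                row[j] = val
            rows.append(row)
    if len(set(snp_ids)) != len(snp_ids):
        dup = pd.Series(snp_ids).value_counts().idxmax()
        raise ValueError(f"{path}: duplicate SNP id {dup!r}")
    dosages = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    return GenotypeMatrix(snp_ids, chrom, pos, dosages, sample_ids)


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, chrom, pos, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic sites only
        counts = np.full(len(sample_ids), np.nan)
        for j, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if alleles:
                counts[j] = float(sum(alleles))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        rows.append(counts)
    dosages = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    return GenotypeMatrix(snp_ids, chrom, pos, dosages, sample_ids)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as TSV; missing dosages become ``NA``."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\t" + "\t".join(map(str, g.sample_ids)) + "\n")
        for i in range(g.n_snps):
            toks = [
                "NA" if np.isnan(d) else str(int(d)) for d in g.dosages[i]
            ]
            fh.write(f"{g.snp_ids[i]}\t{g.chrom[i]}\t{g.pos[i]}\t" + "\t".join(toks) + "\n")


def load_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "start", "end"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: expected header starting {required}")
    values = df.iloc[:, 4:].to_numpy(float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing expression value for probe {df['probe_id'].iloc[i]!r}, "
            f"sample {df.columns[4 + j]!r}"
        )
    return ExpressionMatrix(
        df["probe_id"].to_numpy(), df["chrom"].to_numpy(),
        df["start"].to_numpy(), df["end"].to_numpy(),
        values, list(df.columns[4:]),
    )


def write_expression(e: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(e.values, columns=e.sample_ids)
    df.insert(0, "end", e.end)
    df.insert(0, "start", e.start)
    df.insert(0, "chrom", e.chrom)
    df.insert(0, "probe_id", e.probe_ids)
    df.to_csv(path, sep="\t", index=False)


def load_covariates(path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: expected first column 'sample_id'")
    return CovariateTable(
        list(df.columns[1:]), df.iloc[:, 1:].to_numpy(float), df["sample_id"].to_numpy()
    )


def write_covariates(c: CovariateTable, path) -> None:
    df = pd.DataFrame(c.values, columns=c.covariate_names)
    df.insert(0, "sample_id", c.sample_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-SNP statistics


def compute_maf(dosages) -> float:
    """Minor allele frequency of one SNP's dosage vector (missing excluded)."""
    d = np.asarray(dosages, float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def recode_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip SNPs so dosages count the minor allele (``x -> 2 - x`` where needed)."""
    dosages = g.dosages.copy()
    for i in range(g.n_snps):
        row = dosages[i]
        obs = row[~np.isnan(row)]
        if obs.size and obs.sum() / (2.0 * obs.size) > 0.5:
            dosages[i] = 2.0 - row
    return GenotypeMatrix(g.snp_ids, g.chrom, g.pos, dosages, g.sample_ids)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all outcomes no more
    likely than the observed one. The threshold used in genotype QC
    (p < 1e-5) sits far in the tail, where the chi-square approximation is
    unreliable; the exact test is standard there.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # P(het = h | n, n_rare) via log-factorials; h ranges over n_rare parity
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    lg = math.lgamma
    logp = np.array([
        lg(n + 1) - lg(h + 1) - lg((n_rare - h) // 2 + 1)
        - lg(n - (n_rare + h) // 2 + 1)
        + h * math.log(2) + lg(n_rare + 1) + lg(2 * n - n_rare + 1) - lg(2 * n + 1)
        for h in hs
    ])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(row: np.ndarray) -> tuple[int, int, int]:
    obs = row[~np.isnan(row)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


# ---------------------------------------------------------------------------
# QC filtering


def qc_filter(
    g: GenotypeMatrix,
    sample_call_rate_min: float = 0.97,
    snp_missing_max: float = 0.08,
    maf_min: float = 0.10,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, SnpQcReport]:
    """Apply the genotype QC cascade: samples, then SNP missingness, MAF, HWE.

    Samples with call rate below ``sample_call_rate_min`` are dropped first;
    SNP statistics are then computed on the retained samples. A SNP is kept
    when its missing rate is below ``snp_missing_max``, its MAF is strictly
    greater than ``maf_min``, and its exact HWE p-value is at least
    ``hwe_p_min``. Failure reasons are recorded in the order the filters
    apply, so a SNP failing missingness is not also tested for MAF/HWE flags
    downstream of its removal (statistics are still reported for all SNPs).
    """
    import warnings

    sample_cr = 1.0 - np.isnan(g.dosages).mean(axis=0) if g.n_snps else np.ones(g.n_samples)
    sample_keep = sample_cr >= sample_call_rate_min
    sample_table = pd.DataFrame({
        "sample_id": g.sample_ids, "call_rate": sample_cr, "pass": sample_keep,
    })
    g2 = g.subset(sample_mask=sample_keep)

    n_s = g2.n_samples
    miss = np.isnan(g2.dosages).mean(axis=1) if n_s else np.ones(g2.n_snps)
    call_rate = 1.0 - miss
    mafs = np.full(g2.n_snps, np.nan)
    hwe_p = np.full(g2.n_snps, np.nan)
    for i in range(g2.n_snps):
        row = g2.dosages[i]
        if np.isnan(row).all():
            continue
        mafs[i] = compute_maf(row)
        hwe_p[i] = hwe_exact_test(*_genotype_counts(row))
    pass_missing = miss < snp_missing_max
    pass_maf = mafs > maf_min
    pass_hwe = hwe_p >= hwe_p_min
    keep = pass_missing & pass_maf & pass_hwe
    reason = np.where(
        ~pass_missing, "missingness",
        np.where(~pass_maf, "maf", np.where(~pass_hwe, "hwe", "")),
    )
    snp_table = pd.DataFrame({
        "snp_id": g2.snp_ids, "call_rate": call_rate, "maf": mafs, "hwe_p": hwe_p,
        "pass_missing": pass_missing, "pass_maf": pass_maf, "pass_hwe": pass_hwe,
        "pass": keep, "fail_reason": reason,
    })
    out = g2.subset(snp_mask=keep)
    if out.n_snps == 0 or out.n_samples == 0:
        warnings.warn("QC filtering removed all SNPs or all samples", stacklevel=2)
    report = SnpQcReport(snp_table, sample_table, thresholds={
        "sample_call_rate_min": sample_call_rate_min,
        "snp_missing_max": snp_missing_max,
        "maf_min": maf_min, "hwe_p_min": hwe_p_min,
    })
    return out, report


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def dedup_complete_ld(g: GenotypeMatrix, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Keep one representative per group of SNPs in complete LD or at one position.

    SNPs with pairwise r-squared of 1 on shared non-missing samples (allele
    coding flips included, since r = -1 also gives r-squared 1) or with
    identical (chrom, pos) form groups; one SNP per group is retained. The
    default representative is deterministic (lowest position, ties broken by
    id); pass ``rng`` for a seeded random choice instead.
    """
    n = g.n_snps
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    pos_key: dict[tuple, int] = {}
    for i in range(n):
        key = (g.chrom[i], g.pos[i])
        if key in pos_key:
            union(pos_key[key], i)
        else:
            pos_key[key] = i
    for i in range(n):
        for j in range(i + 1, n):
            if _pairwise_r2(g.dosages[i], g.dosages[j]) >= 1.0 - 1e-12:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep = np.zeros(n, bool)
    for members in groups.values():
        if rng is not None and len(members) > 1:
            keep[rng.choice(members)] = True
        else:
            best = min(members, key=lambda i: (g.pos[i], str(g.snp_ids[i])))
            keep[best] = True
    return g.subset(snp_mask=keep)


# ---------------------------------------------------------------------------
# expression normalization


def quantile_normalize(e: ExpressionMatrix) -> ExpressionMatrix:
    """Across-sample quantile normalization of an expression matrix.

    Every sample's empirical distribution is forced onto the common reference
    distribution (the mean over samples of the per-rank sorted values). Ties
    within a sample receive the mean of the reference values at their tied
    ranks, the standard microarray convention.
    """
    if e.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    v = e.values
    order = np.argsort(v, axis=0, kind="stable")
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = np.empty(v.shape[0])
        col[order[:, j]] = reference
        # ties share the mean reference value over their rank range
        vals, inverse, counts = np.unique(v[:, j], return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=col)
            col = (sums / counts)[inverse]
        out[:, j] = col
    return ExpressionMatrix(e.probe_ids, e.chrom, e.start, e.end, out, e.sample_ids)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks to standard-normal quantiles via (rank - 3/8) / (n + 1/4);
    ties are mid-ranked before mapping.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("inverse-normal transform requires at least 3 values")
    ranks = rankdata(v, method="average")
    return norm.ppf((ranks - 0.375) / (v.size + 0.25))
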