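"""Seeded synthetic-data generators with planted cis/trans/mediation structure.

These generators produce genotype, expression, covariate and annotation
inputs at pipeline scale so the full workflow (QC, eQTL scan, trio
selection, mediation testing, enrichment) runs end to end without any
external download. SNPs are biallelic draws under Hardy-Weinberg
equilibrium on two synthetic chromosomes; mediated trios plant the
two-stage forward model (mediators cis to their SNP, trans gene on the
other chromosome, exchangeable mediator-error correlation); direct trans
effects and pure-noise probes provide negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .enrichment import SnpAnnotation
from .io_qc import CovariateTable, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "PlantedTrio",
    "PlantedDirectTrans",
    "FixtureSpec",
    "generate_genotype_matrix",
    "generate_expression",
    "generate_covariates",
    "generate_annotation_panel",
    "write_fixture_bundle",
]

CHROMS = ("chr1", "chr2")
SNP_SPACING = 3_000_000  # > 2x the cis window so neighbouring SNPs stay trans


@dataclass
class PlantedTrio:
    """A mediated trans-eQTL to plant: SNP -> cis mediators -> trans gene."""

    snp_index: int
    alphaX: tuple = (0.8, 0.8)
    betaM: tuple = (0.3, 0.3)
    betaX: float = 0.0
    rho: float = 0.2

    @property
    def p(self) -> int:
        return len(self.alphaX)


@dataclass
class PlantedDirectTrans:
    """A direct (unmediated) trans effect: SNP -> trans gene, no cis path."""

    snp_index: int
    effect: float = 0.8


@dataclass
class FixtureSpec:
    """Layout and effect sizes for one synthetic dataset."""

    n_samples: int = 300
    n_snps: int = 20
    maf_range: tuple = (0.1, 0.5)
    missing_rate: float = 0.01
    planted_trios: list = field(default_factory=list)
    planted_direct_trans: list = field(default_factory=list)
    n_null_probes: int = 10
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not 0.05 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        for t in self.planted_trios:
            if not 0 <= t.snp_index < self.n_snps:
                raise ValueError(f"planted trio SNP index {t.snp_index} out of range")
            if not -1 < t.rho < 1:
                raise ValueError("trio rho must be in (-1, 1)")
            if len(t.betaM) != t.p:
                raise ValueError("alphaX and betaM must have equal length")
        for t in self.planted_direct_trans:
            if not 0 <= t.snp_index < self.n_snps:
                raise ValueError(f"planted direct SNP index {t.snp_index} out of range")


def _snp_coords(spec: FixtureSpec):
    """Alternate SNPs between the two chromosomes, spaced beyond the cis window."""
    chrom, pos = [], []
    per_chrom = [0, 0]
    for i in range(spec.n_snps):
        c = i % 2
        chrom.append(CHROMS[c])
        pos.append((per_chrom[c] + 1) * SNP_SPACING)
        per_chrom[c] += 1
    return np.array(chrom, object), np.array(pos, np.int64)


def generate_genotype_matrix(spec: FixtureSpec, rng: np.random.Generator):
    """Biallelic dosages under HWE with per-SNP MAF drawn from ``maf_range``.

    Returns ``(GenotypeMatrix, true_dosages)``: the matrix has missing
    entries masked in at ``missing_rate``; ``true_dosages`` is the complete
    matrix used downstream to plant expression effects.
    """
    spec.validate()
    chrom, pos = _snp_coords(spec)
    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    true = rng.binomial(2, mafs[:, None], size=(spec.n_snps, spec.n_samples)).astype(float)
    dosages = true.copy()
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan
    g = GenotypeMatrix(
        snp_ids=[f"snp{i:04d}" for i in range(spec.n_snps)],
        chrom=chrom, pos=pos, dosages=dosages,
        sample_ids=[f"s{j:04d}" for j in range(spec.n_samples)],
    )
    return g, true


def generate_expression(
    spec: FixtureSpec, g: GenotypeMatrix, rng: np.random.Generator,
    true_dosages: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Expression with planted mediation structure plus pure-noise probes.

    For each planted trio, mediator probes sit within the cis window of
    their SNP and the trans probe sits on the other chromosome; values
    follow the two-stage forward model with exchangeable mediator-error
    correlation. Direct-trans probes get a genotype effect with no cis
    path. Null probes are independent standard normal noise.
    """
    spec.validate()
    dos = g.dosages if true_dosages is None else true_dosages
    other = {CHROMS[0]: CHROMS[1], CHROMS[1]: CHROMS[0]}
    probe_ids, chrom, start, end, values = [], [], [], [], []
    far = spec.n_snps * SNP_SPACING + 50_000_000  # away from every SNP

    def add(pid, c, s, vals):
        probe_ids.append(pid)
        chrom.append(c)
        start.append(s)
        end.append(s + 999)
        values.append(vals)

    for k, trio in enumerate(spec.planted_trios):
        x = dos[trio.snp_index]
        cov = np.full((trio.p, trio.p), trio.rho, float)
        np.fill_diagonal(cov, 1.0)
        eps_M = rng.multivariate_normal(np.zeros(trio.p), cov, size=spec.n_samples,
                                        method="cholesky")
        Y = trio.betaX * x + rng.normal(size=spec.n_samples)
        for j in range(trio.p):
            m = trio.alphaX[j] * x + eps_M[:, j]
            Y = Y + trio.betaM[j] * m
            add(f"med{k}_{j}", g.chrom[trio.snp_index],
                g.pos[trio.snp_index] + 10_000 + 2_000 * j, m)
        add(f"trans{k}", other[g.chrom[trio.snp_index]], far + 1_000_000 * k, Y)

    for k, direct in enumerate(spec.planted_direct_trans):
        x = dos[direct.snp_index]
        add(f"direct{k}", other[g.chrom[direct.snp_index]],
            far + 30_000_000 + 1_000_000 * k,
            direct.effect * x + rng.normal(size=spec.n_samples))

    for k in range(spec.n_null_probes):
        c = CHROMS[k % 2]
        add(f"null{k}", c, far + 60_000_000 + 1_000_000 * k,
            rng.normal(size=spec.n_samples))

    return ExpressionMatrix(probe_ids, chrom, start, end,
                            np.vstack(values), g.sample_ids)


def generate_covariates(spec: FixtureSpec, rng: np.random.Generator) -> CovariateTable:
    """A synthetic sex indicator plus one continuous covariate (both null)."""
    sex = rng.integers(0, 2, size=spec.n_samples).astype(float)
    pc1 = rng.normal(size=spec.n_samples)
    return CovariateTable(
        ["sex", "pc1"], np.column_stack([sex, pc1]),
        [f"s{j:04d}" for j in range(spec.n_samples)],
    )


def generate_annotation_panel(
    n_snps: int,
    trait_fraction: float,
    cis_count_distribution,
    rng: np.random.Generator,
    maf_range: tuple = (0.05, 0.5),
) -> list[SnpAnnotation]:
    """Background SNP panel with stated trait-association and cis-count rates.

    ``cis_count_distribution`` gives the probability of 0, 1, 2, ... cis
    associations per SNP.
    """
    if not 0 <= trait_fraction <= 1:
        raise ValueError("trait_fraction must be in [0, 1]")
    probs = np.asarray(cis_count_distribution, float)
    if probs.sum() <= 0:
        raise ValueError("cis_count_distribution must have positive mass")
    probs = probs / probs.sum()
    mafs = rng.uniform(*maf_range, size=n_snps)
    counts = rng.choice(len(probs), size=n_snps, p=probs)
    trait = rng.random(n_snps) < trait_fraction
    return [
        SnpAnnotation(f"panel{i:06d}", float(mafs[i]), int(counts[i]), bool(trait[i]))
        for i in range(n_snps)
    ]


def write_fixture_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Write genotype/expression/covariate/annotation TSVs plus a manifest.

    The manifest records the spec and seed, so the bundle can be
    regenerated byte-identically. Returns the file manifest as a dict.
    """
    from .io_qc import write_covariates, write_expression, write_genotypes

    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    g, true = generate_genotype_matrix(spec, rng)
    e = generate_expression(spec, g, rng, true)
    c = generate_covariates(spec, rng)
    panel = generate_annotation_panel(1000, 0.05, (0.7, 0.2, 0.08, 0.02), rng)

    write_genotypes(g, out / "genotypes.tsv")
    write_expression(e, out / "expression.tsv")
    write_covariates(c, out / "covariates.tsv")
    with open(out / "annotation.tsv", "w") as fh:
        fh.write("snp_id\tmaf\tn_cis_genes\ttrait_associated\n")
        for s in panel:
            fh.write(f"{s.snp_id}\t{s.maf:.6f}\t{s.n_cis_genes}\t{int(s.trait_associated)}\n")

    manifest = {
        "seed": spec.seed,
        "n_samples": spec.n_samples,
        "n_snps": spec.n_snps,
        "maf_range": list(spec.maf_range),
        "missing_rate": spec.missing_rate,
        "n_null_probes": spec.n_null_probes,
        "planted_trios": [
            {"snp_index": t.snp_index, "alphaX": list(t.alphaX),
             "betaM": list(t.betaM), "betaX": t.betaX, "rho": t.rho}
            for t in spec.planted_trios
        ],
        "planted_direct_trans": [
            {"snp_index": t.snp_index, "effect": t.effect}
            for t in spec.planted_direct_trans
        ],
        "files": ["genotypes.tsv", "expression.tsv", "covariates.tsv", "annotation.tsv"],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
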