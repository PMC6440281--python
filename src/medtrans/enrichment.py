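"""Enrichment tests: MAF-matched permutation and Fisher's exact test.

Two procedures. First, to ask whether trans-eQTLs are associated with
multiple cis-genes more often than comparable SNPs, query SNPs are compared
with MAF-matched draws from a background panel: each resample picks, within
MAF bins, the same number of panel SNPs as the query, and the empirical
p-value is the add-one-corrected fraction of resamples whose statistic
reaches the observed one. Second, enrichment of trait-associated SNPs among
mediated trans-eQTLs is assessed with Fisher's exact test on a 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "SnpAnnotation",
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "maf_matched_resample",
    "permutation_enrichment_test",
]


@dataclass
class SnpAnnotation:
    """Per-SNP annotation used by the enrichment procedures."""

    snp_id: str
    maf: float
    n_cis_genes: int = 0
    trait_associated: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"SNP {self.snp_id!r}: MAF must be in (0, 0.5]")
        if self.n_cis_genes < 0:
            raise ValueError(f"SNP {self.snp_id!r}: n_cis_genes must be >= 0")


@dataclass
class ContingencyTable2x2:
    """Counts a = query & positive, b = query & negative, c/d = background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each row must have at least one observation")


def fisher_exact_2x2(t: ContingencyTable2x2, alternative: str = "two_sided"):
    """Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``. The two-sided p sums the probabilities of
    all tables (at fixed margins) no more likely than the observed one;
    the odds ratio is a*d / (b*c), infinite when b*c = 0. A degenerate
    margin (an all-zero row or column) gives p = 1 and an undefined (NaN)
    odds ratio.
    """
    alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        return float("nan"), 1.0
    _, p = _scipy_fisher([[a, b], [c, d]], alternative=alt)
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(odds), float(p)


def _maf_bin(maf: float, bin_width: float) -> int:
    return min(int(maf / bin_width), int(np.ceil(0.5 / bin_width)) - 1)


def maf_matched_resample(
    query_mafs,
    panel,
    bin_width: float = 0.05,
    rng: np.random.Generator | None = None,
    replace: bool = False,
) -> list:
    """Sample |query| panel SNPs matching the query's MAF-bin composition.

    Within each MAF bin of width ``bin_width`` the same number of panel
    SNPs as query SNPs is drawn (without replacement by default). An empty
    or too-small panel bin raises an error naming the bin.
    """
    rng = np.random.default_rng() if rng is None else rng
    panel = list(panel)
    panel_bins: dict[int, list[int]] = {}
    for i, snp in enumerate(panel):
        panel_bins.setdefault(_maf_bin(snp.maf, bin_width), []).append(i)
    need: dict[int, int] = {}
    for maf in query_mafs:
        b = _maf_bin(float(maf), bin_width)
        need[b] = need.get(b, 0) + 1
    chosen: list = []
    for b, count in sorted(need.items()):
        pool = panel_bins.get(b, [])
        if (not pool) or (not replace and len(pool) < count):
            lo, hi = b * bin_width, (b + 1) * bin_width
            raise ValueError(
                f"panel has {len(pool)} SNPs in MAF bin [{lo:.3f}, {hi:.3f}), need {count}"
            )
        picks = rng.choice(pool, size=count, replace=replace)
        chosen.extend(panel[i] for i in picks)
    return chosen


def _statistic(snps, statistic: str) -> float:
    counts = np.array([s.n_cis_genes for s in snps])
    if statistic == "prop_ge2_cis":
        return float((counts >= 2).mean())
    if statistic == "prop_ge1_cis":
        return float((counts >= 1).mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_enrichment_test(
    query,
    panel,
    statistic: str = "prop_ge2_cis",
    B: int = 1000,
    seed: int | None = None,
    bin_width: float = 0.05,
    replace: bool = False,
):
    """MAF-matched permutation test of a cis-association proportion.

    The observed statistic (default: proportion of query SNPs associated
    with two or more cis-genes) is compared against ``B`` MAF-matched
    resamples from the panel; the empirical p-value is
    (1 + #{resample statistic >= observed}) / (B + 1).
    """
    query = list(query)
    if not query:
        raise ValueError("query must be nonempty")
    rng = np.random.default_rng(seed)
    observed = _statistic(query, statistic)
    query_mafs = [s.maf for s in query]
    hits = 0
    for _ in range(B):
        sample = maf_matched_resample(query_mafs, panel, bin_width, rng, replace)
        if _statistic(sample, statistic) >= observed:
            hits += 1
    return observed, (1 + hits) / (B + 1)
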