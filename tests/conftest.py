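import math
from fractions import Fraction

import numpy as np
import pytest

from medtrans.io_qc import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes():
    """3 SNPs x 4 samples with one missing call."""
    dosages = np.array([
        [0, 1, 2, 1],
        [2, 2, np.nan, 1],
        [0, 0, 1, 0],
    ], float)
    return GenotypeMatrix(
        ["rs1", "rs2", "rs3"], ["chr1", "chr1", "chr2"], [100, 5_000_000, 100],
        dosages, ["a", "b", "c", "d"],
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles (exact rational arithmetic where possible)


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-fraction enumeration of the conditional heterozygote distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)

    def weight(h):
        n_hom_rare = (n_rare - h) // 2
        return Fraction(
            math.comb(n, n_hom_rare) * math.comb(n - n_hom_rare, h) * 2**h
        )

    hs = range(n_rare % 2, n_rare + 1, 2)
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-fraction hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def weight(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: weight(x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    p_obs = weights[a]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


def bh_stepup_rejections(p_values, alpha: float) -> set:
    """Classic BH step-up: indices rejected at level alpha."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = p.size
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    return set(order[:k].tolist())
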