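"""Multi-mediator mediation model for trans-eQTLs, with bootstrap tests.

The model for one trio (SNP ``X``, cis-mediators ``M_1..M_p``, trans-gene
``Y``, covariates ``C``) is a pair of linear stages::

    Y_i   = beta_0 + X_i beta_X + M_i' beta_M + C_i' beta_C + eps_Y,
    M_ij  = alpha_0j + X_i alpha_Xj + C_i' alpha_Cj + eps_Mj,

with eps_Y ~ N(0, sigma^2) independent of the mediator errors
eps_M ~ N_p(0, Sigma); Sigma's off-diagonals are free, so cis-genes may be
correlated. The estimands are the product-of-coefficients indirect effects:

* TME (total mediation effect): Delta = alpha_X' beta_M,
* CME (component-wise): delta_j = alpha_Xj * beta_Mj,
* SME (single-mediator): delta_j re-estimated from the model that omits the
  other mediators — deliberately misspecified when p > 1.

Significance is assessed by nonparametric case-resampling bootstrap with
two-sided percentile p-values; the CME test combines per-component p-values
by Bonferroni.

The public surface follows the Model/Results convention: build a
:class:`MultiMediatorModel` from data, call :meth:`~MultiMediatorModel.fit`,
and use the returned :class:`MediationResults` for estimands, bootstrap
tests and a summary table. Functional wrappers (:func:`fit_joint`,
:func:`tme`, :func:`cme`, :func:`bootstrap_test_tme`, ...) expose the same
operations for pipeline code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_qc import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    inverse_normal_transform,
)

__all__ = [
    "MediationData",
    "MediationFit",
    "MediationTestResult",
    "MultiMediatorModel",
    "MediationResults",
    "fit_joint",
    "tme",
    "cme",
    "bootstrap_test_tme",
    "bootstrap_test_cme",
    "bootstrap_test_sme",
    "sme_any",
    "analyze_trio",
]

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100


@dataclass
class MediationData:
    """Complete-case data for one trio: Y (n,), X (n,), M (n, p), C (n, q)."""

    Y: np.ndarray
    X: np.ndarray
    M: np.ndarray
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, float).ravel()
        self.X = np.asarray(self.X, float).ravel()
        self.M = np.atleast_2d(np.asarray(self.M, float))
        if self.M.shape[0] != self.Y.size:
            self.M = self.M.T
        if self.C is not None:
            self.C = np.atleast_2d(np.asarray(self.C, float))
            if self.C.shape[0] != self.Y.size:
                self.C = self.C.T
            if self.C.shape[1] == 0:
                self.C = None
        n, p, q = self.n, self.p, self.q
        if self.X.size != n or (self.C is not None and self.C.shape[0] != n):
            raise ValueError("Y, X, M, C must share the sample dimension")
        arrays = [self.Y, self.X, self.M] + ([self.C] if self.C is not None else [])
        if any(np.isnan(a).any() for a in arrays):
            raise ValueError("mediation data must be complete-case (no missing values)")
        if p < 1:
            raise ValueError("at least one mediator required")
        if n <= p + q + 2:
            raise ValueError(f"need n > p + q + 2 = {p + q + 2}, got n = {n}")

    @property
    def n(self) -> int:
        return self.Y.size

    @property
    def p(self) -> int:
        return self.M.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.C is None else self.C.shape[1]


@dataclass
class MediationFit:
    """Least-squares estimates of both stages of the mediation model."""

    beta0: float
    betaX: float
    betaM: np.ndarray
    betaC: np.ndarray
    alpha0: np.ndarray
    alphaX: np.ndarray
    alphaC: np.ndarray
    sigma2: float
    Sigma: np.ndarray


@dataclass
class MediationTestResult:
    """Bootstrap test outcome for TME, CME or SME."""

    test: str
    estimate: float | np.ndarray
    p_value: float
    B: int
    seed: int | None
    component_p: np.ndarray | None = None
    component_estimates: np.ndarray | None = None
    n_redrawn: int = 0
    extra: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


# ---------------------------------------------------------------------------
# fitting


def _design_outcome(data: MediationData) -> np.ndarray:
    cols = [np.ones(data.n), data.X, data.M]
    if data.C is not None:
        cols.append(data.C)
    return np.column_stack(cols)


def _design_mediator(data: MediationData) -> np.ndarray:
    cols = [np.ones(data.n), data.X]
    if data.C is not None:
        cols.append(data.C)
    return np.column_stack(cols)


def _check_rank(D: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the offending columns for the error message
        keep: list[int] = []
        for j in range(D.shape[1]):
            if np.linalg.matrix_rank(D[:, keep + [j]]) > len(keep):
                keep.append(j)
        bad = [names[j] for j in range(D.shape[1]) if j not in keep]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_joint(data: MediationData) -> MediationFit:
    """Fit both stages of the mediation model by least squares.

    The outcome stage regresses Y on [1, X, M, C]; the mediator stage
    regresses each M_j on [1, X, C]. ``Sigma`` is the mediator residual
    covariance with divisor n - q - 2.
    """
    n, p, q = data.n, data.p, data.q
    D1 = _design_outcome(data)
    names1 = ["intercept", "X"] + [f"M{j + 1}" for j in range(p)] + [f"C{j + 1}" for j in range(q)]
    _check_rank(D1, names1)
    b1 = np.linalg.lstsq(D1, data.Y, rcond=None)[0]
    resid_Y = data.Y - D1 @ b1
    dof_Y = n - D1.shape[1]
    sigma2 = float(resid_Y @ resid_Y / dof_Y) if dof_Y > 0 else np.nan

    D2 = _design_mediator(data)
    names2 = ["intercept", "X"] + [f"C{j + 1}" for j in range(q)]
    _check_rank(D2, names2)
    b2 = np.linalg.lstsq(D2, data.M, rcond=None)[0]  # (2 + q, p)
    resid_M = data.M - D2 @ b2
    Sigma = resid_M.T @ resid_M / (n - q - 2)
    Sigma = (Sigma + Sigma.T) / 2.0

    return MediationFit(
        beta0=float(b1[0]),
        betaX=float(b1[1]),
        betaM=b1[2:2 + p].copy(),
        betaC=b1[2 + p:].copy(),
        alpha0=b2[0].copy(),
        alphaX=b2[1].copy(),
        alphaC=b2[2:].copy(),
        sigma2=sigma2,
        Sigma=Sigma,
    )


def tme(fit: MediationFit) -> float:
    """Total mediation effect Delta = alpha_X' beta_M."""
    return float(fit.alphaX @ fit.betaM)


def cme(fit: MediationFit) -> np.ndarray:
    """Component-wise mediation effects delta_j = alpha_Xj * beta_Mj."""
    return fit.alphaX * fit.betaM


# ---------------------------------------------------------------------------
# vectorized case-resampling bootstrap


def _resample_indices(n: int, B: int, x: np.ndarray, rng: np.random.Generator):
    """Draw B case-resampling index rows, redrawing rows with constant X."""
    idx = rng.integers(0, n, size=(B, n))
    n_redrawn = 0
    for _ in range(MAX_REDRAWS):
        const = np.ptp(x[idx], axis=1) == 0
        if not const.any():
            break
        n_redrawn += int(const.sum())
        idx[const] = rng.integers(0, n, size=(int(const.sum()), n))
    else:
        raise RuntimeError("could not draw bootstrap resamples with non-constant X")
    return idx, n_redrawn


def _batched_ls(Db: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Solve least squares for each resample: Db (B, n, k), yb (B, n[, m])."""
    Dt = np.swapaxes(Db, 1, 2)
    A = Dt @ Db
    if yb.ndim == 2:
        return np.linalg.solve(A, Dt @ yb[..., None])[..., 0]
    return np.linalg.solve(A, Dt @ yb)


def _bootstrap_products(
    data: MediationData, idx: np.ndarray, mediators: np.ndarray | None = None
) -> np.ndarray:
    """Per-resample delta_j* = alpha_Xj* beta_Mj* for the requested mediator set.

    ``mediators=None`` uses the joint model with all p mediators; a single
    index fits the single-mediator (SME) model. Returns an array (B, m).
    """
    cols = np.arange(data.p) if mediators is None else np.atleast_1d(mediators)
    M = data.M[:, cols]
    base_out = [np.ones(data.n), data.X]
    base_med = [np.ones(data.n), data.X]
    if data.C is not None:
        base_out.append(data.C)
        base_med.append(data.C)
    D1 = np.column_stack([base_out[0], base_out[1], M] + base_out[2:])
    D2 = np.column_stack(base_med)
    D1b = D1[idx]
    b1 = _batched_ls(D1b, data.Y[idx])  # (B, 2 + m + q)
    betaM = b1[:, 2:2 + len(cols)]
    b2 = _batched_ls(D2[idx], M[idx])  # (B, 2 + q, m)
    alphaX = b2[:, 1, :]
    return alphaX * betaM


def _percentile_p(stat_star: np.ndarray) -> float:
    """Two-sided percentile bootstrap p with add-one correction."""
    B = stat_star.shape[0]
    lo = (1 + int((stat_star <= 0).sum())) / (B + 1)
    hi = (1 + int((stat_star >= 0).sum())) / (B + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def bootstrap_test_tme(
    data: MediationData, B: int = 1000, seed: int | None = None,
    idx: np.ndarray | None = None,
) -> MediationTestResult:
    """Test H0: Delta = 0 by case-resampling percentile bootstrap.

    Whole rows (Y, X, M, C) are resampled with replacement; Delta* is
    recomputed on each resample from the joint fit. Resamples with constant
    X are redrawn. Pass ``idx`` to reuse a precomputed resample-index matrix.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    fit = fit_joint(data)
    n_redrawn = 0
    if idx is None:
        rng = np.random.default_rng(seed)
        idx, n_redrawn = _resample_indices(data.n, B, data.X, rng)
    delta_star = _bootstrap_products(data, idx)
    return MediationTestResult(
        test="TME", estimate=tme(fit), p_value=_percentile_p(delta_star.sum(axis=1)),
        B=idx.shape[0], seed=seed, n_redrawn=n_redrawn,
    )


def bootstrap_test_cme(
    data: MediationData, B: int = 1000, seed: int | None = None,
    idx: np.ndarray | None = None,
) -> MediationTestResult:
    """Test H0: delta = 0 componentwise; Bonferroni-combined overall p.

    The same case resampling as the TME test yields per-component two-sided
    percentile p-values p_j from delta_j*; the overall p-value is
    min(1, p * min_j p_j), which controls the composite null and reduces to
    the TME test when p = 1.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    fit = fit_joint(data)
    n_redrawn = 0
    if idx is None:
        rng = np.random.default_rng(seed)
        idx, n_redrawn = _resample_indices(data.n, B, data.X, rng)
    delta_star = _bootstrap_products(data, idx)
    comp_p = np.array([_percentile_p(delta_star[:, j]) for j in range(data.p)])
    return MediationTestResult(
        test="CME", estimate=cme(fit), p_value=float(min(1.0, data.p * comp_p.min())),
        B=idx.shape[0], seed=seed, component_p=comp_p, n_redrawn=n_redrawn,
    )


def bootstrap_test_sme(
    data: MediationData, mediator_index: int = 0, B: int = 1000,
    seed: int | None = None, idx: np.ndarray | None = None,
) -> MediationTestResult:
    """Single-mediation-effect bootstrap test for one mediator.

    Fits the single-mediator model (Y on [1, X, M_j, C]; M_j on [1, X, C]),
    deliberately omitting the other mediators, and bootstraps the
    product-of-coefficients statistic alpha_Xj * beta_Mj.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0 <= mediator_index < data.p:
        raise ValueError(f"mediator_index must be in [0, {data.p})")
    sub = MediationData(data.Y, data.X, data.M[:, [mediator_index]], data.C)
    fit = fit_joint(sub)
    n_redrawn = 0
    if idx is None:
        rng = np.random.default_rng(seed)
        idx, n_redrawn = _resample_indices(data.n, B, data.X, rng)
    delta_star = _bootstrap_products(data, idx, mediators=mediator_index)
    return MediationTestResult(
        test="SME", estimate=float(cme(fit)[0]), p_value=_percentile_p(delta_star[:, 0]),
        B=idx.shape[0], seed=seed, n_redrawn=n_redrawn,
        extra={"mediator_index": mediator_index},
    )


def sme_any(
    data: MediationData, B: int = 1000, seed: int | None = None,
    correction: str = "none", idx: np.ndarray | None = None,
) -> MediationTestResult:
    """Run the SME test on every mediator; reject if any is significant.

    With ``correction="none"`` the reported p-value is min_j p_j and the
    caller compares it with alpha directly (rejection of either component
    test rejects overall); ``correction="bonferroni"`` multiplies by p.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    n_redrawn = 0
    if idx is None:
        rng = np.random.default_rng(seed)
        idx, n_redrawn = _resample_indices(data.n, B, data.X, rng)
    results = [
        bootstrap_test_sme(data, j, B=idx.shape[0], seed=seed, idx=idx)
        for j in range(data.p)
    ]
    comp_p = np.array([r.p_value for r in results])
    estimates = np.array([r.estimate for r in results])
    p = comp_p.min() * (data.p if correction == "bonferroni" else 1)
    return MediationTestResult(
        test="SME-any", estimate=estimates, p_value=float(min(1.0, p)),
        B=idx.shape[0], seed=seed, component_p=comp_p,
        component_estimates=estimates, n_redrawn=n_redrawn,
        extra={"correction": correction},
    )


# ---------------------------------------------------------------------------
# Model / Results objects


class MultiMediatorModel:
    """Joint multi-mediator mediation model for one trio.

    Parameters
    ----------
    Y, X, M, C
        Trans-gene expression (n,), SNP dosage (n,), mediator expression
        (n, p) and optional covariates (n, q); complete cases only.
    """

    def __init__(self, Y, X, M, C=None):
        self.data = MediationData(Y, X, M, C)

    @classmethod
    def from_data(cls, data: MediationData) -> "MultiMediatorModel":
        obj = cls.__new__(cls)
        obj.data = data
        return obj

    @classmethod
    def from_dataframe(cls, df, outcome: str, exposure: str, mediators, covariates=()):
        """Build from a tidy DataFrame with one row per sample."""
        med = list(mediators)
        cov = list(covariates)
        return cls(
            df[outcome].to_numpy(float),
            df[exposure].to_numpy(float),
            df[med].to_numpy(float),
            df[cov].to_numpy(float) if cov else None,
        )

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def n_mediators(self) -> int:
        return self.data.p

    def fit(self) -> "MediationResults":
        return MediationResults(self, fit_joint(self.data))


class MediationResults:
    """Fitted mediation model: estimates, estimands, bootstrap tests, summary."""

    def __init__(self, model: MultiMediatorModel, fit: MediationFit):
        self.model = model
        self.params = fit

    @property
    def tme(self) -> float:
        return tme(self.params)

    @property
    def cme(self) -> np.ndarray:
        return cme(self.params)

    def bootstrap_tme(self, B: int = 1000, seed: int | None = None) -> MediationTestResult:
        return bootstrap_test_tme(self.model.data, B=B, seed=seed)

    def bootstrap_cme(self, B: int = 1000, seed: int | None = None) -> MediationTestResult:
        return bootstrap_test_cme(self.model.data, B=B, seed=seed)

    def bootstrap_sme(self, mediator_index: int = 0, B: int = 1000,
                      seed: int | None = None) -> MediationTestResult:
        return bootstrap_test_sme(self.model.data, mediator_index, B=B, seed=seed)

    def sme_any(self, B: int = 1000, seed: int | None = None,
                correction: str = "none") -> MediationTestResult:
        return sme_any(self.model.data, B=B, seed=seed, correction=correction)

    def summary(self) -> str:
        f = self.params
        d = self.model.data
        lines = [
            "Multi-mediator mediation model",
            f"  n = {d.n}, mediators p = {d.p}, covariates q = {d.q}",
            "",
            "  Outcome stage (Y ~ 1 + X + M + C)",
            f"    beta_0 = {f.beta0:10.4f}",
            f"    beta_X = {f.betaX:10.4f}",
        ]
        for j, b in enumerate(f.betaM):
            lines.append(f"    beta_M{j + 1} = {b:9.4f}")
        lines.append(f"    sigma^2 = {f.sigma2:9.4f}")
        lines.append("")
        lines.append("  Mediator stage (M_j ~ 1 + X + C)")
        for j in range(d.p):
            lines.append(
                f"    M{j + 1}: alpha_0 = {f.alpha0[j]:8.4f}, alpha_X = {f.alphaX[j]:8.4f}"
            )
        lines.append("")
        lines.append("  Mediation effects")
        for j, dj in enumerate(self.cme):
            lines.append(f"    delta_{j + 1} (CME) = {dj:10.4f}")
        lines.append(f"    Delta   (TME) = {self.tme:10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# trio-level driver


def analyze_trio(
    trio,
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    C: CovariateTable | None = None,
    B: int = 1000,
    seed: int | None = None,
    transform: str = "int",
) -> dict | None:
    """Assemble one trio's complete-case data and run the TME/CME/SME tests.

    Expression vectors are inverse-normal transformed when
    ``transform="int"``. Returns one result record, or ``None`` when the
    SNP is monomorphic after complete-case filtering (logged and skipped).
    """
    if transform not in ("int", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if trio.trans_probe_id in trio.mediator_probe_ids:
        raise ValueError(
            f"trio {trio.snp_id}: trans probe {trio.trans_probe_id!r} is also a mediator"
        )
    gi = {s: i for i, s in enumerate(g.sample_ids)}
    ei = {s: i for i, s in enumerate(e.sample_ids)}
    shared = [s for s in g.sample_ids if s in ei]
    if C is not None:
        cset = set(C.sample_ids)
        shared = [s for s in shared if s in cset]
    snp_row = int(np.flatnonzero(g.snp_ids == trio.snp_id)[0])
    probe_row = {pid: int(np.flatnonzero(e.probe_ids == pid)[0])
                 for pid in [trio.trans_probe_id, *trio.mediator_probe_ids]}
    x = g.dosages[snp_row, [gi[s] for s in shared]]
    ok = ~np.isnan(x)
    samples = [s for s, keep in zip(shared, ok) if keep]
    x = x[ok]
    if np.ptp(x) == 0:
        logger.info("skipping trio %s: monomorphic SNP after complete-case", trio.snp_id)
        return None
    e_idx = [ei[s] for s in samples]
    Y = e.values[probe_row[trio.trans_probe_id]][e_idx]
    M = np.column_stack([e.values[probe_row[pid]][e_idx] for pid in trio.mediator_probe_ids])
    if transform == "int":
        Y = inverse_normal_transform(Y)
        M = np.column_stack([inverse_normal_transform(M[:, j]) for j in range(M.shape[1])])
    c_vals = None
    if C is not None:
        ci = {s: i for i, s in enumerate(C.sample_ids)}
        c_vals = C.values[[ci[s] for s in samples]]
    data = MediationData(Y, x, M, c_vals)
    rng = np.random.default_rng(seed)
    idx, n_redrawn = _resample_indices(data.n, B, data.X, rng)
    res_tme = bootstrap_test_tme(data, B=B, seed=seed, idx=idx)
    res_cme = bootstrap_test_cme(data, B=B, seed=seed, idx=idx)
    res_sme = sme_any(data, B=B, seed=seed, idx=idx)
    return {
        "snp_id": trio.snp_id,
        "mediators": ";".join(map(str, trio.mediator_probe_ids)),
        "trans_probe_id": trio.trans_probe_id,
        "n": data.n,
        "tme": res_tme.estimate,
        "cme": ";".join(f"{d:.6g}" for d in res_cme.estimate),
        "p_tme": res_tme.p_value,
        "p_cme": res_cme.p_value,
        "cme_component_p": ";".join(f"{p:.6g}" for p in res_cme.component_p),
        "p_sme_min": res_sme.p_value,
        "sme_component_p": ";".join(f"{p:.6g}" for p in res_sme.component_p),
        "B": B,
        "seed": seed,
        "n_redrawn": n_redrawn,
    }
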