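"""Marginal eQTL scanning, cis/trans classification, BH-FDR and trio selection.

Each SNP-probe pair is tested with an additive linear model (expression on
dosage plus covariates, two-sided t-test on the dosage coefficient). Pairs
on the same chromosome within 1 Mb of the probe interval are cis; all
others, including every inter-chromosomal pair, are trans. Benjamini-
Hochberg q-values are assigned separately within the cis and trans classes.
Candidate trios for mediation testing pair each strong trans signal
(p < 1e-6) with that SNP's significant cis genes (q <= 0.05, at most 5,
smallest cis p first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_qc import CovariateTable, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "AssociationRecord",
    "Trio",
    "classify_pair",
    "association_test",
    "scan",
    "bh_fdr",
    "build_trios",
    "records_to_dataframe",
    "trios_to_dataframe",
]

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000


@dataclass
class AssociationRecord:
    """One SNP-probe association test result."""

    snp_id: str
    probe_id: str
    relation: str  # "cis" or "trans"
    effect: float
    stderr: float
    t_stat: float
    p: float
    q: float = np.nan
    n: int = 0
    perfect_fit: bool = False


@dataclass
class Trio:
    """A (SNP, cis-mediator set, trans-gene) candidate for mediation testing."""

    snp_id: str
    mediator_probe_ids: list
    trans_probe_id: str
    trans_p: float
    mediator_q: list = field(default_factory=list)


def classify_pair(
    snp_chrom, snp_pos: int, probe_chrom, probe_start: int, probe_end: int,
    window: int = CIS_WINDOW,
) -> str:
    """Classify a SNP-probe pair as cis or trans.

    Cis means same chromosome with the SNP within ``window`` bp of the probe
    interval (distance 0 if the SNP falls inside it); everything else,
    including all inter-chromosomal pairs, is trans.
    """
    if str(snp_chrom) != str(probe_chrom):
        return "trans"
    lo, hi = (probe_start, probe_end) if probe_start <= probe_end else (probe_end, probe_start)
    if lo <= snp_pos <= hi:
        dist = 0
    else:
        dist = min(abs(snp_pos - lo), abs(snp_pos - hi))
    return "cis" if dist <= window else "trans"


def association_test(y, x, C: CovariateTable | np.ndarray | None = None):
    """OLS of expression on dosage and covariates; t-test on the dosage slope.

    Samples with missing dosage are dropped (complete-case). Returns
    ``(effect, stderr, t, p)`` with a residual degrees of freedom of
    n - k - 2 for k covariates. A perfect fit reports p at the machine
    floor rather than zero.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if isinstance(C, CovariateTable):
        C = C.values
    Cm = None if C is None else np.atleast_2d(np.asarray(C, float))
    if Cm is not None and Cm.shape[0] != y.size:
        Cm = Cm.T
    ok = ~np.isnan(x) & ~np.isnan(y)
    y, x = y[ok], x[ok]
    k = 0 if Cm is None else Cm.shape[1]
    if y.size < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {y.size}")
    if np.ptp(x) == 0:
        raise ValueError("dosage is constant after dropping missing samples")
    cols = [np.ones_like(x), x]
    if Cm is not None:
        cols.extend(Cm[ok].T)
    D = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = y - D @ beta
    dof = y.size - D.shape[1]
    rss = float(resid @ resid)
    XtX_inv = np.linalg.inv(D.T @ D)
    tss = float(((y - y.mean()) ** 2).sum())
    perfect = rss <= 1e-12 * max(tss, 1.0)
    sigma2 = rss / dof if dof > 0 else np.nan
    se = float(np.sqrt(max(sigma2, np.finfo(float).tiny) * XtX_inv[1, 1]))
    t = beta[1] / se if se > 0 else np.sign(beta[1]) * np.inf
    p = float(2.0 * stats.t.sf(abs(t), dof)) if dof > 0 else np.nan
    if perfect:
        p = np.finfo(float).eps
    return float(beta[1]), se, float(t), max(p, np.finfo(float).tiny), perfect


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up adjusted p-values)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _align_samples(g: GenotypeMatrix, e: ExpressionMatrix, C: CovariateTable | None):
    shared = [s for s in g.sample_ids if s in set(e.sample_ids)]
    if C is not None:
        cset = set(C.sample_ids)
        shared = [s for s in shared if s in cset]
    if not shared:
        raise ValueError("no overlapping samples between genotype and expression data")
    gi = {s: i for i, s in enumerate(g.sample_ids)}
    ei = {s: i for i, s in enumerate(e.sample_ids)}
    g_idx = np.array([gi[s] for s in shared])
    e_idx = np.array([ei[s] for s in shared])
    c_vals = None
    if C is not None:
        ci = {s: i for i, s in enumerate(C.sample_ids)}
        c_vals = C.values[np.array([ci[s] for s in shared])]
    return shared, g_idx, e_idx, c_vals


def scan(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    C: CovariateTable | None = None,
    mode: str = "both",
    window: int = CIS_WINDOW,
) -> list[AssociationRecord]:
    """Test all SNP-probe pairs of the requested relation; assign q per class.

    Samples are intersected in genotype order. SNPs that are monomorphic
    after complete-case dropping are skipped with a log entry.
    """
    if mode not in ("cis", "trans", "both"):
        raise ValueError(f"unknown scan mode {mode!r}")
    _, g_idx, e_idx, c_vals = _align_samples(g, e, C)
    records: list[AssociationRecord] = []
    for i in range(g.n_snps):
        x = g.dosages[i, g_idx]
        for j in range(e.n_probes):
            relation = classify_pair(
                g.chrom[i], g.pos[i], e.chrom[j], e.start[j], e.end[j], window
            )
            if mode != "both" and relation != mode:
                continue
            y = e.values[j, e_idx]
            try:
                effect, se, t, p, perfect = association_test(y, x, c_vals)
            except ValueError as err:
                logger.info("skipping %s x %s: %s", g.snp_ids[i], e.probe_ids[j], err)
                continue
            records.append(AssociationRecord(
                snp_id=g.snp_ids[i], probe_id=e.probe_ids[j], relation=relation,
                effect=effect, stderr=se, t_stat=t, p=p,
                n=int((~np.isnan(x)).sum()), perfect_fit=perfect,
            ))
    for relation in ("cis", "trans"):
        idx = [k for k, r in enumerate(records) if r.relation == relation]
        if idx:
            q = bh_fdr([records[k].p for k in idx])
            for k, qv in zip(idx, q):
                records[k].q = float(qv)
    records.sort(key=lambda r: (str(r.snp_id), str(r.probe_id)))
    return records


def build_trios(
    trans_records,
    cis_records,
    trans_p_max: float = 1e-6,
    cis_fdr_max: float = 0.05,
    max_mediators: int = 5,
) -> list[Trio]:
    """Select candidate trios from a scan's trans and cis records.

    One trio per (SNP, trans-probe) pair with trans p strictly below
    ``trans_p_max`` whose SNP has at least one cis gene at q <= ``cis_fdr_max``;
    mediators are ordered by ascending cis p and truncated to
    ``max_mediators``.
    """
    cis_by_snp: dict[str, list] = {}
    for r in cis_records:
        if r.relation != "cis":
            continue
        if not np.isnan(r.q) and r.q <= cis_fdr_max:
            cis_by_snp.setdefault(r.snp_id, []).append(r)
    for snp in cis_by_snp:
        cis_by_snp[snp].sort(key=lambda r: (r.p, str(r.probe_id)))
    trios = []
    for r in trans_records:
        if r.relation != "trans" or not r.p < trans_p_max:
            continue
        mediators = cis_by_snp.get(r.snp_id, [])
        mediators = [m for m in mediators if m.probe_id != r.probe_id][:max_mediators]
        if not mediators:
            continue
        trios.append(Trio(
            snp_id=r.snp_id,
            mediator_probe_ids=[m.probe_id for m in mediators],
            trans_probe_id=r.probe_id,
            trans_p=r.p,
            mediator_q=[m.q for m in mediators],
        ))
    trios.sort(key=lambda t: (str(t.snp_id), str(t.trans_probe_id)))
    return trios


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def trios_to_dataframe(trios) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "snp_id": t.snp_id,
            "mediators": ";".join(map(str, t.mediator_probe_ids)),
            "trans_probe_id": t.trans_probe_id,
            "trans_p": t.trans_p,
            "mediator_q": ";".join(f"{q:.6g}" for q in t.mediator_q),
        }
        for t in trios
    ])
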