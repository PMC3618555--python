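"""Per-SNP logistic scans under three inheritance models with FDR q-values.

Each SNP is fitted under the dominant, recessive, and additive codings; the
best model is the one with the minimal Wald p-value (ties broken in that
order).  Storey q-values are computed over the per-SNP minimal p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .geno_data import GenotypeMatrix, ModelCode, Phenotype, encode_snp

logger = logging.getLogger(__name__)

_MODEL_ORDER = (ModelCode.DOMINANT, ModelCode.RECESSIVE, ModelCode.ADDITIVE)


@dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    or_: float
    ci95: tuple[float, float]
    separated: bool = False


@dataclass
class AssocResult:
    snp_id: str
    model: ModelCode
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    q: float = np.nan


def fit_logistic(x: np.ndarray, y: np.ndarray,
                 covariates: np.ndarray | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on one coded SNP.

    Returns the Wald statistic for the SNP term.  Perfect separation is
    flagged (infinite-beta sentinel) rather than raised, so scans can skip
    such SNPs without aborting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("constant predictor: logistic fit undefined")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes, coded 0/1")
    X = x[:, None] if covariates is None else np.column_stack([x, covariates])
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(np.inf, np.inf, np.nan, np.inf, (0.0, np.inf),
                           separated=True)
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 1e3 or abs(beta) > 15:
        # quasi-separation: Wald inference meaningless
        return LogisticFit(beta, se, np.nan, float(np.exp(beta)),
                           (0.0, np.inf), separated=True)
    p = float(res.pvalues[1])
    # clip the exponent: a wide-but-finite Wald interval may overflow exp
    lo = np.exp(np.clip(beta - 1.96 * se, -700, 700))
    hi = np.exp(np.clip(beta + 1.96 * se, -700, 700))
    return LogisticFit(beta, se, p, float(np.exp(beta)), (float(lo), float(hi)))


def best_model_scan(gm: GenotypeMatrix, phen: Phenotype,
                    covariates: np.ndarray | None = None) -> list[AssocResult]:
    """Fit each SNP under all three inheritance models, keep the minimal-p fit.

    Monomorphic SNPs and separated fits are skipped with a logged reason.
    q-values (Storey) are attached over the returned min-p values.
    """
    y = phen.y
    results: list[AssocResult] = []
    for j, snp in enumerate(gm.snps):
        d = gm.dosage[:, j]
        if np.ptp(d) == 0:
            logger.info("SNP %s is monomorphic: skipped", snp.snp_id)
            continue
        best: tuple[ModelCode, LogisticFit] | None = None
        for model in _MODEL_ORDER:
            coded = encode_snp(d, model)
            if np.ptp(coded) == 0:
                continue
            fit = fit_logistic(coded, y, covariates)
            if fit.separated or not np.isfinite(fit.p):
                logger.info("SNP %s under %s: separated fit excluded from "
                            "min-p selection", snp.snp_id, model.value)
                continue
            if best is None or fit.p < best[1].p:
                best = (model, fit)
        if best is None:
            logger.info("SNP %s: no valid model fit; skipped", snp.snp_id)
            continue
        model, fit = best
        results.append(AssocResult(snp_id=snp.snp_id, model=model,
                                   beta=fit.beta, se=fit.se, or_=fit.or_,
                                   ci95=fit.ci95, p=fit.p))
    if results:
        qs = qvalues(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def qvalues(p: np.ndarray, pi0: float | None = None,
            lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 (the null proportion) is estimated on a lambda grid 0.05..0.95 with a
    cubic smoother evaluated at the largest lambda, then clipped to (0, 1].
    Passing ``pi0=1`` reproduces Benjamini-Hochberg step-up values exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        if m < 100:
            pi0 = 1.0  # smoother unstable on short lists; conservative default
        else:
            pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas[-1]))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    # step-up: enforce monotone non-decreasing q along sorted p
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def expected_false_positives(n_selected: int, max_q: float) -> float:
    """Expected count of false positives among a q-value-selected set:
    n_selected * max_q."""
    return n_selected * max_q


def scan_table(results: list[AssocResult], gm: GenotypeMatrix):
    """Render scan results as a DataFrame with the familiar report columns."""
    import pandas as pd

    rows = []
    for r in results:
        snp = gm.record(r.snp_id)
        rows.append({
            "snp": r.snp_id, "chromosome": snp.chromosome,
            "gene": snp.gene_symbol or "",
            "major/minor": f"{snp.major_allele}/{snp.minor_allele}",
            "model": r.model.value, "p": r.p, "OR": r.or_,
            "ci_low": r.ci95[0], "ci_high": r.ci95[1], "q": r.q,
        })
    return pd.DataFrame(rows)
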