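"""Hardy-Weinberg filtering and LD-based pruning of a genotype panel.

Both filters mirror common pre-interaction-search practice: SNPs grossly out
of Hardy-Weinberg equilibrium (chi-square p < 1e-4 by default) are excluded,
then one SNP of every strongly correlated pair (composite genotypic r^2 over
a threshold, default 0.8) is dropped by a greedy pass in panel order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geno_data import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    hwe_p: dict[str, float]
    excluded_hwe: list[str]
    ld_pairs: list[tuple[str, str, float]]
    excluded_ld: list[str]
    retained_snps: list[str]


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Observed (n_AA, n_Aa, n_aa) counts, ignoring missing calls."""
    d = np.asarray(dosages)
    d = d[d != MISSING]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_test(counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit p-value against HWE expectations.

    Expected genotype counts derive from the sample allele frequency.  A
    monomorphic SNP fits HWE trivially and returns p = 1.
    """
    n_aa, n_ab, n_bb = counts
    if min(counts) < 0:
        raise ValueError(f"negative genotype count in {counts}")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype observation required")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(counts: tuple[int, int, int]) -> float:
    """Exact HWE test (conditional on allele counts, summing probabilities
    <= that of the observed heterozygote count).  Used as an independent
    cross-check of the chi-square ordering on small panels."""
    n_aa, n_ab, n_bb = counts
    if min(counts) < 0:
        raise ValueError(f"negative genotype count in {counts}")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype observation required")
    n_minor = 2 * n_bb + n_ab
    n_major = 2 * n_aa + n_ab
    rare = min(n_minor, n_major)
    if rare == 0:
        return 1.0
    # probabilities over all heterozygote counts with the same parity as rare
    het_values = np.arange(rare % 2, rare + 1, 2)
    logp = np.empty(het_values.size)
    from scipy.special import gammaln

    def log_prob(nab: int) -> float:
        # counts expressed in terms of the rarer allele for stability
        n_r = rare
        n_c = 2 * n - rare
        n_rr = (n_r - nab) // 2
        n_cc = n - nab - n_rr
        return (nab * np.log(2) + gammaln(n + 1)
                - gammaln(n_rr + 1) - gammaln(nab + 1) - gammaln(n_cc + 1)
                + gammaln(n_r + 1) + gammaln(n_c + 1) - gammaln(2 * n + 1))

    for i, h in enumerate(het_values):
        logp[i] = log_prob(int(h))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_idx = int(np.where(het_values == n_ab)[0][0])
    return float(min(1.0, probs[probs <= probs[obs_idx] + 1e-12].sum()))


def hwe_filter(gm: GenotypeMatrix, p_threshold: float = 1e-4,
               subjects: list[int] | None = None,
               exact: bool = False) -> tuple[list[str], dict[str, float]]:
    """Return (retained snp_ids, per-SNP HWE p).  ``subjects`` optionally
    restricts the test to a reference subset (e.g. external controls)."""
    test = hwe_exact_test if exact else hwe_test
    dosage = gm.dosage if subjects is None else gm.dosage[subjects, :]
    pvals: dict[str, float] = {}
    retained: list[str] = []
    for j, snp in enumerate(gm.snps):
        pv = test(genotype_counts(dosage[:, j]))
        pvals[snp.snp_id] = pv
        if pv >= p_threshold:
            retained.append(snp.snp_id)
    return retained, pvals


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Composite genotypic r^2: squared Pearson correlation of dosages."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero-variance dosage vector: r^2 defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, threshold: float = 0.8,
             record_pairs: bool = False
             ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy LD pruning in panel order.

    A SNP is dropped when its r^2 with any already-retained SNP exceeds the
    threshold; consequently no retained pair exceeds it.  Returns retained
    snp_ids and (if requested) the offending pairs.
    """
    X = gm.dosage.astype(np.float64)
    if (X == MISSING).any():
        raise ValueError("ld_prune requires a complete (imputed) matrix")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    retained_idx: list[int] = []
    pairs: list[tuple[str, str, float]] = []
    for j in range(gm.n_snps):
        if sd[j] == 0.0:
            retained_idx.append(j)  # monomorphic: r^2 with anything is 0
            continue
        drop = False
        if retained_idx:
            kept = [k for k in retained_idx if sd[k] > 0]
            if kept:
                r = (Xc[:, kept].T @ Xc[:, j]) / (n * sd[kept] * sd[j])
                r2 = r * r
                hit = np.flatnonzero(r2 > threshold)
                if hit.size:
                    drop = True
                    if record_pairs:
                        k = kept[int(hit[0])]
                        pairs.append((gm.snps[k].snp_id, gm.snps[j].snp_id,
                                      float(r2[hit[0]])))
        if not drop:
            retained_idx.append(j)
    return [gm.snps[j].snp_id for j in retained_idx], pairs


def apply_qc(gm: GenotypeMatrix, hwe_p: float = 1e-4, ld_threshold: float = 0.8,
             hwe_subjects: list[int] | None = None,
             exact_hwe: bool = False) -> tuple[GenotypeMatrix, QcReport]:
    """HWE filter then LD prune; returns the filtered matrix and a report."""
    hwe_keep, pvals = hwe_filter(gm, hwe_p, subjects=hwe_subjects, exact=exact_hwe)
    excluded_hwe = [s for s in gm.snp_ids if s not in set(hwe_keep)]
    gm_hwe = gm.subset_snps(hwe_keep)
    retained, pairs = ld_prune(gm_hwe, ld_threshold, record_pairs=True)
    excluded_ld = [s for s in gm_hwe.snp_ids if s not in set(retained)]
    logger.info("QC: %d input SNPs, %d failed HWE (p<%g), %d pruned at r2>%g, "
                "%d retained", gm.n_snps, len(excluded_hwe), hwe_p,
                len(excluded_ld), ld_threshold, len(retained))
    report = QcReport(hwe_p=pvals, excluded_hwe=excluded_hwe, ld_pairs=pairs,
                      excluded_ld=excluded_ld, retained_snps=retained)
    return gm.subset_snps(retained), report
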