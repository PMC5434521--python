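"""Statistical variant-filtering rules for marker panels.

Each rule is computed independently on the unfiltered input (so filters
are order-independent): minor-allele frequency (any SNP whose minor allele
occurs only once is always discarded), call rate, Hardy-Weinberg
equilibrium (chi-square goodness of fit, 1 df), Mendelian inconsistency
counts over parent-offspring links, a binomial transmission-distortion
test on offspring of heterozygous parents, and an array-vs-dense
concordance check for markers typed on both panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MISSING, GenotypeMatrix, Pedigree
from .mendel import count_mendel_inconsistencies, _transmitted_alleles

__all__ = ["FilterThresholds", "apply_filters", "concordance_filter"]


@dataclass
class FilterThresholds:
    maf_min: float = 0.01
    hwe_p_min: float = 0.05
    call_rate_min: float = 0.95
    mendel_max: int = 10
    transmission_p_min: float = 0.05


def _hwe_chi2_p(n_aa: np.ndarray, n_ab: np.ndarray, n_bb: np.ndarray) -> np.ndarray:
    """Chi-square goodness-of-fit p against Hardy-Weinberg proportions (1 df)."""
    n = n_aa + n_ab + n_bb
    p = np.full(len(n), np.nan)
    ok = n > 0
    q = (2 * n_bb[ok] + n_ab[ok]) / (2 * n[ok])
    exp_aa = n[ok] * (1 - q) ** 2
    exp_ab = n[ok] * 2 * q * (1 - q)
    exp_bb = n[ok] * q**2
    chi2 = np.zeros(ok.sum())
    for o, e in [(n_aa[ok], exp_aa), (n_ab[ok], exp_ab), (n_bb[ok], exp_bb)]:
        nz = e > 0
        chi2[nz] += (o[nz] - e[nz]) ** 2 / e[nz]
    p[ok] = stats.chi2.sf(chi2, df=1)
    # monomorphic markers fit trivially
    mono = ok.copy()
    mono[ok] = (q == 0) | (q == 1)
    p[mono] = 1.0
    return p


def _transmission_p(gt: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Binomial test of transmitted-allele counts from heterozygous parents."""
    v = gt.values
    n, m = v.shape
    alt = np.zeros(m, dtype=np.int64)
    tot = np.zeros(m, dtype=np.int64)
    for p_i in range(n):
        off = ped.offspring_of(p_i)
        if len(off) == 0:
            continue
        trans = _transmitted_alleles(v, ped, p_i, off)
        parent_het = v[p_i] == 1
        known = (trans != MISSING) & parent_het[None, :]
        alt += (known & (trans == 1)).sum(axis=0)
        tot += known.sum(axis=0)
    pvals = np.ones(m)
    for j in np.flatnonzero(tot > 0):
        pvals[j] = stats.binomtest(int(alt[j]), int(tot[j]), 0.5).pvalue
    return pvals


def apply_filters(
    gt: GenotypeMatrix,
    ped: Pedigree = None,
    thresholds: FilterThresholds = None,
):
    """Apply all variant filters; returns ``(report, retained_marker_indices)``.

    The report holds per-marker statistics and pass/fail flags per rule;
    the overall pass requires every evaluated rule to pass.  Rules needing
    a pedigree are marked not-evaluated (pass) when none is given, as are
    external-data filters (cross-dataset presence, assembly regions) that
    this package does not implement.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    v = gt.values
    n, m = v.shape
    called = v != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / n
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, np.where(called, v, 0).sum(axis=0) / (2 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(freq, 1 - freq)
    nma = np.rint(maf * 2 * n_called).astype(int)

    n_aa = ((v == 0) & called).sum(axis=0)
    n_ab = (v == 1).sum(axis=0)
    n_bb = (v == 2).sum(axis=0)
    hwe_p = _hwe_chi2_p(n_aa, n_ab, n_bb)

    pass_maf = (maf > thresholds.maf_min) & (nma > 1)
    pass_call = call_rate >= thresholds.call_rate_min
    pass_hwe = hwe_p > thresholds.hwe_p_min

    if ped is not None:
        mendel = count_mendel_inconsistencies(gt, ped)
        pass_mendel = mendel <= thresholds.mendel_max
        trans_p = _transmission_p(gt, ped)
        pass_trans = trans_p > thresholds.transmission_p_min
    else:
        mendel = np.zeros(m, dtype=np.int64)
        pass_mendel = np.ones(m, dtype=bool)
        trans_p = np.full(m, np.nan)
        pass_trans = np.ones(m, dtype=bool)

    overall = pass_maf & pass_call & pass_hwe & pass_mendel & pass_trans
    report = pd.DataFrame(
        {
            "call_rate": call_rate,
            "maf": maf,
            "nma": nma,
            "hwe_p": hwe_p,
            "mendel_inconsistencies": mendel,
            "transmission_p": trans_p,
            "pass_maf": pass_maf,
            "pass_call_rate": pass_call,
            "pass_hwe": pass_hwe,
            "pass_mendel": pass_mendel,
            "pass_transmission": pass_trans,
            "external_filters": "not-evaluated",
            "pass_overall": overall,
        }
    )
    return report, np.flatnonzero(overall)


def concordance_filter(
    array_gt: GenotypeMatrix,
    dense_gt: GenotypeMatrix,
    shared_markers: np.ndarray,
    threshold: float = 0.04,
):
    """Flag shared markers whose array-vs-dense mismatch rate exceeds ``threshold``.

    ``shared_markers`` maps each array marker to its dense-panel column.
    Mismatch rates are computed over individuals with calls on both panels.
    Returns ``(mismatch_rates, flagged_array_marker_indices)``.
    """
    shared = np.asarray(shared_markers, dtype=np.int64)
    a = array_gt.values
    d = dense_gt.values[:, shared]
    both = (a != MISSING) & (d != MISSING)
    with np.errstate(invalid="ignore"):
        rate = np.where(both.sum(axis=0) > 0, ((a != d) & both).sum(axis=0) / np.maximum(both.sum(axis=0), 1), np.nan)
    flagged = np.flatnonzero(rate > threshold)
    return rate, flagged
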