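"""Per-SNP differentiation scan between farmed and natural-origin pools.

Two statistic tracks are computed per SNP, mirroring the two-program
consensus design the pipeline reproduces:

* an FST track: the classical heterozygosity estimator
  ``FST = (hT - hS) / hT`` averaged over all farmed x wild population pairs,
  with a two-sided Fisher exact test on group-summed read counts;
* an XtX track: squared allele-frequency deviations standardised by the
  populations' scaled covariance matrix Omega, so that shared demography is
  whitened out before measuring differentiation.  Omega is estimated by the
  deterministic method of moments (empirical covariance of standardised
  frequencies across loci, lightly ridge-regularised) and the statistic is
  calibrated against a chi-square with J degrees of freedom, J the number of
  populations.

Each track's p-values are Benjamini-Hochberg adjusted genome-wide and the
consensus classifier labels a SNP "highly suggestive" when both adjusted
values fall below 1e-5, and "suggestive" when one falls below 1e-5 and the
other below 1e-3.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = ["allele_freq_matrix", "pairwise_fst", "mean_cross_group_fst",
           "fisher_group_test", "estimate_omega", "xtx_stat", "xtx_from_z",
           "bh_adjust", "classify_consensus", "population_pca", "scan",
           "Q_HIGHLY_SUGGESTIVE", "Q_SUGGESTIVE"]

log = logging.getLogger(__name__)

Q_HIGHLY_SUGGESTIVE = 1e-5
Q_SUGGESTIVE = 1e-3

_SITE = ["lg", "pos"]


def _groups(design: Mapping[str, str]) -> tuple[list[str], list[str]]:
    farmed = sorted(p for p, g in design.items() if g == "farmed")
    wild = sorted(p for p, g in design.items() if g == "wild")
    if not farmed or not wild:
        raise ValueError("design needs populations in both groups")
    return farmed, wild


def allele_freq_matrix(snps: pd.DataFrame) -> pd.DataFrame:
    """Populations x sites matrix of alternate-allele frequencies."""
    if snps.empty:
        raise ValueError("empty SNP table")
    if (snps["depth"] <= 0).any():
        raise ValueError("zero-depth entries in SNP table")
    mat = snps.pivot_table(index="population", columns=_SITE,
                           values="alt_freq", aggfunc="first")
    if mat.isna().any().any():
        raise ValueError("SNP table is not rectangular over populations")
    return mat.sort_index()


def pairwise_fst(p_a, p_b):
    """Classical per-SNP FST between two populations from frequencies.

    ``FST = (hT - hS)/hT`` with total heterozygosity ``hT = 2 pbar (1-pbar)``
    at the mean frequency and ``hS`` the mean of the two within-population
    heterozygosities; 0 where the site is monomorphic across both (hT = 0).
    Accepts scalars or arrays.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    p_bar = (p_a + p_b) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    return fst if fst.ndim else float(fst)


def mean_cross_group_fst(freqs: pd.DataFrame,
                         design: Mapping[str, str]) -> pd.Series:
    """Average pairwise FST over all farmed x wild pairs, per SNP."""
    farmed, wild = _groups(design)
    acc = np.zeros(freqs.shape[1])
    pairs = list(itertools.product(farmed, wild))
    for a, b in pairs:
        acc += pairwise_fst(freqs.loc[a].to_numpy(), freqs.loc[b].to_numpy())
    return pd.Series(acc / len(pairs), index=freqs.columns, name="mean_fst")


def fisher_group_test(snps: pd.DataFrame,
                      design: Mapping[str, str]) -> pd.Series:
    """Two-sided Fisher exact test on group-summed ref/alt read counts.

    The 2x2 table per SNP is (ref, alt) x (farmed, wild) with read counts
    summed within each group; the two-sided p-value follows the
    point-probability rule (all tables with probability <= the observed one).
    Empty margins give p = 1.
    """
    farmed, wild = _groups(design)
    group = snps["population"].map(
        {**{p: "farmed" for p in farmed}, **{p: "wild" for p in wild}})
    if group.isna().any():
        unknown = sorted(snps.loc[group.isna(), "population"].unique())
        raise ValueError(f"populations missing from design: {unknown}")
    sums = (snps.assign(group=group)
            .groupby(_SITE + ["group"], observed=True)[["ref_count",
                                                        "alt_count"]]
            .sum().unstack("group"))
    rf = sums[("ref_count", "farmed")].to_numpy(dtype=np.int64)
    af = sums[("alt_count", "farmed")].to_numpy(dtype=np.int64)
    rw = sums[("ref_count", "wild")].to_numpy(dtype=np.int64)
    aw = sums[("alt_count", "wild")].to_numpy(dtype=np.int64)
    empty_margin = ((rf + rw == 0) | (af + aw == 0)
                    | (rf + af == 0) | (rw + aw == 0))
    if empty_margin.any():
        log.warning("%d SNPs with an empty margin: p set to 1",
                    int(empty_margin.sum()))
    pvals = np.ones(len(sums))
    for i in range(len(sums)):
        if not empty_margin[i]:
            pvals[i] = stats.fisher_exact(
                [[rf[i], af[i]], [rw[i], aw[i]]])[1]
    return pd.Series(pvals, index=sums.index, name="fisher_p")


def _standardize(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-scores (p_j - pi)/sqrt(pi(1-pi)) and the polymorphic-site mask."""
    pi = freqs.mean(axis=0)
    poly = (pi > 0.0) & (pi < 1.0)
    z = np.zeros_like(freqs)
    z[:, poly] = (freqs[:, poly] - pi[poly]) / np.sqrt(
        pi[poly] * (1.0 - pi[poly]))
    return z, poly


def estimate_omega(freqs: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Moment estimate of the scaled covariance of population frequencies.

    Frequencies are standardised per site by the across-population mean
    ``pi``; Omega is the empirical covariance ``Z Z^T / L`` over polymorphic
    sites, plus a ridge ``1e-6 * trace`` for numerical invertibility.  Sites
    monomorphic across every population carry no information and are
    skipped.
    """
    arr = np.asarray(freqs, dtype=float)
    z, poly = _standardize(arr)
    n_used = int(poly.sum())
    if n_used == 0:
        return np.zeros((arr.shape[0], arr.shape[0]))
    zp = z[:, poly]
    omega = zp @ zp.T / n_used
    omega += 1e-6 * np.trace(omega) * np.eye(omega.shape[0])
    return omega


def xtx_from_z(z: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Quadratic form ``z_l' Omega^-1 z_l`` per site (columns of ``z``)."""
    try:
        solved = np.linalg.solve(omega, z)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "Omega is singular; re-estimate with regularisation "
            "(estimate_omega adds a small ridge)") from err
    return (z * solved).sum(axis=0)


def xtx_stat(freqs: pd.DataFrame | np.ndarray,
             omega: np.ndarray) -> pd.DataFrame:
    """Per-SNP XtX statistic and its chi-square(J) upper-tail p-value.

    Standardising by the across-population mean ``pi`` makes each site's
    z-scores sum to zero, which removes one degree of freedom from the raw
    quadratic form (its null mean is J-1, not J).  The statistic is
    therefore rescaled by ``J/(J-1)`` — the same first-moment correction as
    Bessel's in a sample variance — so that it is calibrated against the
    chi-square with J degrees of freedom used for the p-value.
    """
    arr = np.asarray(freqs, dtype=float)
    j = arr.shape[0]
    z, _ = _standardize(arr)
    xtx = xtx_from_z(z, omega) * (j / (j - 1) if j > 1 else 1.0)
    pvals = stats.chi2.sf(xtx, df=j)
    columns = freqs.columns if isinstance(freqs, pd.DataFrame) else None
    return pd.DataFrame({"xtx": xtx, "xtx_p": pvals},
                        index=columns)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any():
        raise ValueError("NaN p-values cannot be adjusted")
    return multipletests(arr, method="fdr_bh")[1]


def classify_consensus(fisher_q, xtx_q,
                       q_high: float = Q_HIGHLY_SUGGESTIVE,
                       q_sugg: float = Q_SUGGESTIVE) -> np.ndarray:
    """Consensus outlier class from the two adjusted-p tracks.

    "highly_suggestive" requires both adjusted values below ``q_high``;
    "suggestive" requires one below ``q_high`` and the other below
    ``q_sugg``; anything else is "none".
    """
    fq = np.asarray(fisher_q, dtype=float)
    xq = np.asarray(xtx_q, dtype=float)
    highly = (fq < q_high) & (xq < q_high)
    sugg = (((fq < q_high) & (xq < q_sugg))
            | ((xq < q_high) & (fq < q_sugg))) & ~highly
    out = np.where(highly, "highly_suggestive",
                   np.where(sugg, "suggestive", "none"))
    return out if out.ndim else np.asarray(str(out))


def population_pca(freqs: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of populations on the (column-centred) frequency matrix.

    Returns per-population principal-component coordinates and the
    explained-variance fractions.  A matrix with zero total variance yields
    all-zero fractions with a warning.
    """
    arr = np.asarray(freqs, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("PCA needs at least two populations")
    centred = arr - arr.mean(axis=0, keepdims=True)
    if not np.any(centred):
        log.warning("zero total variance: PCA fractions set to 0")
        n_comp = min(arr.shape)
        coords = pd.DataFrame(np.zeros((arr.shape[0], n_comp)),
                              index=freqs.index,
                              columns=[f"PC{i+1}" for i in range(n_comp)])
        return coords, np.zeros(n_comp)
    n_comp = min(arr.shape[0] - 1, arr.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(arr)
    coords = pd.DataFrame(coords, index=freqs.index,
                          columns=[f"PC{i+1}" for i in range(n_comp)])
    return coords, pca.explained_variance_ratio_


def scan(snps: pd.DataFrame, design: Mapping[str, str],
         q_high: float = Q_HIGHLY_SUGGESTIVE,
         q_sugg: float = Q_SUGGESTIVE) -> pd.DataFrame:
    """Full per-SNP scan: FST + Fisher and XtX tracks, BH, consensus class."""
    freqs = allele_freq_matrix(snps)
    mean_fst = mean_cross_group_fst(freqs, design)
    fisher_p = fisher_group_test(snps, design)
    omega = estimate_omega(freqs)
    xtx = xtx_stat(freqs, omega)

    alleles = (snps[_SITE + ["ref", "alt"]].drop_duplicates()
               .set_index(_SITE))
    result = pd.DataFrame(index=freqs.columns)
    result["ref"] = alleles["ref"]
    result["alt"] = alleles["alt"]
    result["mean_fst"] = mean_fst
    result["fisher_p"] = fisher_p
    result["fisher_q"] = bh_adjust(result["fisher_p"].to_numpy())
    result["xtx"] = xtx["xtx"].to_numpy()
    result["xtx_p"] = xtx["xtx_p"].to_numpy()
    result["xtx_q"] = bh_adjust(result["xtx_p"].to_numpy())
    result["snp_class"] = classify_consensus(
        result["fisher_q"], result["xtx_q"], q_high=q_high, q_sugg=q_sugg)
    return result.reset_index()
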