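"""From per-position pooled read counts to a biallelic SNP table.

Three steps, in the order the pipeline runs them: technical replicates are
merged by summing base counts; positions are kept only when every population
reaches the minimum read depth (default 25, justified by the
pool-representation simulation in :mod:`poolscan.depth_sim`); and biallelic
SNPs are called after discarding alleles whose dataset-wide frequency is
below the minor-allele threshold (default 1%, a screen against sequencing
error and mismapping).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import BASES

__all__ = ["merge_replicates", "filter_depth", "call_biallelic"]

log = logging.getLogger(__name__)

_SITE = ["lg", "pos"]
_BASE_COLS = list(BASES)


def merge_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum base counts over technical replicates of each population.

    Input rows are (site, population, replicate) with A/C/G/T counts; the
    reference base must agree across all rows of a site.  A single replicate
    (or an already-merged table) passes through unchanged.
    """
    ref_per_site = counts.groupby(_SITE)["ref"].nunique()
    conflicts = ref_per_site[ref_per_site > 1]
    if len(conflicts):
        site = conflicts.index[0]
        raise ValueError(f"conflicting reference base at site {site}")
    merged = (counts.groupby(_SITE + ["ref", "population"], as_index=False,
                             sort=True)[_BASE_COLS]
              .sum())
    return merged


def filter_depth(counts: pd.DataFrame, min_depth: int = 25) -> pd.DataFrame:
    """Keep sites whose total read depth is >= min_depth in every population.

    Applied to replicate-merged counts.  A site missing from any population
    is treated as depth 0 there and dropped, since the downstream group
    contrasts need every pool typed.
    """
    depth = counts[_BASE_COLS].sum(axis=1)
    per_site = depth.groupby([counts["lg"], counts["pos"]])
    n_pops = counts["population"].nunique()
    site_min = per_site.min()
    site_n = per_site.size()
    keep = site_min[(site_min >= min_depth) & (site_n == n_pops)].index
    mask = pd.MultiIndex.from_frame(counts[_SITE]).isin(keep)
    return counts[mask].reset_index(drop=True)


def call_biallelic(counts: pd.DataFrame, maf: float = 0.01,
                   per_population: bool = False) -> pd.DataFrame:
    """Call biallelic SNPs from depth-filtered, replicate-merged counts.

    Allele frequencies are computed from counts pooled across all
    populations; alleles with frequency strictly below ``maf`` are removed
    (a 1% allele survives the default threshold), and a site is emitted only
    when exactly two alleles remain.  With ``per_population=True`` an allele
    is instead retained when it reaches ``maf`` within at least one
    population, a per-pool screen for error alleles.

    The reference allele is the site's reference base when it survives
    filtering, otherwise the highest-count allele (ties broken A<C<G<T);
    the other surviving allele is the alternate.  Returns the long-format
    SNP table with per-population ref/alt counts, depth (ref+alt) and the
    alternate-allele frequency.
    """
    if counts.empty:
        return pd.DataFrame(columns=["lg", "pos", "ref", "alt", "population",
                                     "ref_count", "alt_count", "depth",
                                     "alt_freq"])
    site_totals = counts.groupby(_SITE + ["ref"], as_index=False,
                                 sort=True)[_BASE_COLS].sum()
    tot = site_totals[_BASE_COLS].to_numpy(dtype=float)
    grand = tot.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(grand > 0, tot / grand, 0.0)
    if per_population:
        pop_tot = counts[_BASE_COLS].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pop_freq = pop_tot / pop_tot.sum(axis=1, keepdims=True)
        reaches = pd.DataFrame(pop_freq >= maf, columns=_BASE_COLS).groupby(
            [counts["lg"], counts["pos"]]).any()
        reaches = reaches.reindex(
            pd.MultiIndex.from_frame(site_totals[_SITE])).to_numpy()
        keep = reaches & (tot > 0)
    else:
        keep = (freq >= maf) & (tot > 0)

    n_alleles = keep.sum(axis=1)
    biallelic = n_alleles == 2
    n_dropped = int((n_alleles == 0).sum())
    if n_dropped:
        log.info("%d sites had no allele above the %.3f frequency threshold",
                 n_dropped, maf)

    sites = site_totals.loc[biallelic, _SITE + ["ref"]].copy()
    keep_b = keep[biallelic]
    tot_b = tot[biallelic]
    ref_base_idx = np.array([_BASE_COLS.index(r) for r in sites["ref"]],
                            dtype=int) if len(sites) else np.empty(0, int)
    # the two surviving alleles, in base order A<C<G<T (stable argsort)
    allele_idx = np.argsort(~keep_b, axis=1, kind="stable")[:, :2] \
        if len(sites) else np.empty((0, 2), int)
    ref_idx = np.empty(len(sites), dtype=int)
    alt_idx = np.empty(len(sites), dtype=int)
    for row in range(len(sites)):
        a, b = allele_idx[row]
        if ref_base_idx[row] == b:
            a, b = b, a
        elif ref_base_idx[row] != a and tot_b[row, b] > tot_b[row, a]:
            # ref base itself was filtered out: highest count becomes ref,
            # ties already resolved by base order
            a, b = b, a
        ref_idx[row], alt_idx[row] = a, b

    base_arr = np.array(_BASE_COLS)
    sites["ref_allele"] = base_arr[ref_idx]
    sites["alt_allele"] = base_arr[alt_idx]

    out = counts.merge(sites, on=_SITE + ["ref"], how="inner")
    pop_counts = out[_BASE_COLS].to_numpy()
    ref_col = np.array([_BASE_COLS.index(x) for x in out["ref_allele"]],
                       dtype=int)
    alt_col = np.array([_BASE_COLS.index(x) for x in out["alt_allele"]],
                       dtype=int)
    rows = np.arange(len(out))
    ref_count = pop_counts[rows, ref_col]
    alt_count = pop_counts[rows, alt_col]
    depth = ref_count + alt_count
    snps = pd.DataFrame({
        "lg": out["lg"], "pos": out["pos"],
        "ref": out["ref_allele"], "alt": out["alt_allele"],
        "population": out["population"],
        "ref_count": ref_count, "alt_count": alt_count, "depth": depth,
        "alt_freq": np.where(depth > 0, alt_count / np.maximum(depth, 1),
                             np.nan),
    })
    # a pool whose reads were all on removed alleles cannot be typed
    bad_sites = snps.loc[snps["depth"] == 0, _SITE].drop_duplicates()
    if len(bad_sites):
        log.info("%d sites dropped: a population had zero ref+alt depth",
                 len(bad_sites))
        mask = ~pd.MultiIndex.from_frame(snps[_SITE]).isin(
            pd.MultiIndex.from_frame(bad_sites))
        snps = snps[mask]
    return snps.sort_values(_SITE + ["population"], ignore_index=True)
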