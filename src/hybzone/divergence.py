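"""Per-SNP differentiation and diversity: Weir–Cockerham F_ST, pi, d_xy.

The F_ST estimator is the Weir & Cockerham (1984) method-of-moments
estimator built from three variance components per site: a (among
populations), b (among individuals within populations) and c (within
individuals), with theta = a / (a + b + c).  Populations with no called
genotype at a site are excluded from that site; sites where the denominator
is zero (or where fewer than two populations have calls, or average sample
size is at most one individual) are reported undefined rather than zero.

pi and d_xy are missing-data-aware per-site estimators on haploid allele
bookkeeping: each called diploid contributes two alleles, and pi is the
fraction of differing pairs among all within-group allele pairs (an
unbiased n/(n-1)-corrected heterozygosity), while
d_xy = p_A (1 - p_B) + p_B (1 - p_A) averages over one-allele-from-each-group
pairs.  Values are per variant site; genome-scale d_xy would additionally
need invariant sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_anchor import GenotypeMatrix

__all__ = ["wc_fst", "species_fst", "pi_dxy", "summarize_divergence"]


def _per_pop_site_stats(dosage: np.ndarray, labels: np.ndarray):
    """Per (population, site): sample size, ALT frequency, het proportion."""
    pops = pd.unique(labels)
    n = np.zeros((len(pops), dosage.shape[1]))
    p = np.full_like(n, np.nan)
    het = np.full_like(n, np.nan)
    for k, pop in enumerate(pops):
        sub = dosage[labels == pop]
        called = ~np.isnan(sub)
        n[k] = called.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p[k] = np.nanmean(sub, axis=0) / 2.0
            het[k] = np.nansum(sub == 1.0, axis=0) / np.maximum(n[k], 1)
    return pops, n, p, het


def _wc_components(n: np.ndarray, p: np.ndarray, het: np.ndarray):
    """Weir–Cockerham (1984) a, b, c per site from per-pop (n, p, het) arrays.

    Rows are populations; entries with n == 0 are excluded site-wise.
    Returns (a, b, c, r_used) with nan where the estimator is undefined.
    """
    present = n > 0
    r = present.sum(axis=0).astype(float)
    n_masked = np.where(present, n, 0.0)
    p_masked = np.where(present, p, 0.0)
    het_masked = np.where(present, het, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_sum = n_masked.sum(axis=0)
        nbar = n_sum / r
        nc = (n_sum - (n_masked**2).sum(axis=0) / n_sum) / (r - 1.0)
        pbar = (n_masked * p_masked).sum(axis=0) / n_sum
        s2 = (n_masked * (p_masked - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_masked * het_masked).sum(axis=0) / n_sum

        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    bad = (r < 2) | (nbar <= 1.0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c, r


def wc_fst(
    matrix: GenotypeMatrix, pop_labels, mode: str = "multipop"
) -> pd.DataFrame:
    """Per-SNP Weir–Cockerham F_ST among populations.

    ``multipop`` computes the r-population estimator directly;
    ``mean_pairwise`` averages the 2-population estimator over all
    population pairs (pairs undefined at a site are skipped).  With exactly
    two populations the two modes coincide.

    Returns a DataFrame aligned with ``matrix.loci``: columns scaffold,
    pos, theta, a, b, c, n_pops (nan theta where undefined).
    """
    labels = np.asarray(pop_labels)
    if labels.shape[0] != matrix.n_individuals:
        raise ValueError("pop_labels length must match individuals")
    pops, n, p, het = _per_pop_site_stats(matrix.dosage, labels)
    if len(pops) < 2:
        raise ValueError("need at least two populations")

    if mode == "multipop":
        a, b, c, r = _wc_components(n, p, het)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = a + b + c
            theta = np.where(denom != 0.0, a / denom, np.nan)
    elif mode == "mean_pairwise":
        thetas = []
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                idx = np.array([i, j])
                ap, bp, cp, _ = _wc_components(n[idx], p[idx], het[idx])
                with np.errstate(divide="ignore", invalid="ignore"):
                    denom = ap + bp + cp
                    thetas.append(np.where(denom != 0.0, ap / denom, np.nan))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            theta = np.nanmean(np.vstack(thetas), axis=0)
        a = b = c = np.full_like(theta, np.nan)
        r = (n > 0).sum(axis=0).astype(float)
    else:
        raise ValueError("mode must be 'multipop' or 'mean_pairwise'")

    out = matrix.loci[["scaffold", "pos"]].copy()
    out["theta"] = theta
    out["a"] = a
    out["b"] = b
    out["c"] = c
    out["n_pops"] = r
    return out


def species_fst(matrix: GenotypeMatrix, panel_labels) -> pd.DataFrame:
    """Two-population F_ST between the pure parental panels.

    ``panel_labels`` are per-individual strings; individuals labelled
    ``pureA``/``pureB`` form the two populations, everyone else is ignored.
    """
    labels = np.asarray(panel_labels)
    use = np.isin(labels, ("pureA", "pureB"))
    if (labels == "pureA").sum() == 0 or (labels == "pureB").sum() == 0:
        raise ValueError("both pure panels must be non-empty")
    sub = matrix.take_samples(use)
    return wc_fst(sub, labels[use], mode="multipop")


def pi_dxy(matrix: GenotypeMatrix, groups: dict) -> pd.DataFrame:
    """Per-site nucleotide diversity within groups and divergence between them.

    ``groups`` maps two group names to boolean masks or index arrays over
    individuals (disjoint).  Output columns: pi_<name> for each group and
    dxy.  A group's pi is undefined (nan) at sites with fewer than two
    called alleles; dxy is undefined when either group has no called allele.
    """
    names = list(groups)
    if len(names) != 2:
        raise ValueError("pi_dxy expects exactly two groups")
    masks = {}
    for name, sel in groups.items():
        sel = np.asarray(sel)
        masks[name] = sel if sel.dtype == bool else np.isin(np.arange(matrix.n_individuals), sel)
    if (masks[names[0]] & masks[names[1]]).any():
        raise ValueError("groups must be disjoint")

    out = matrix.loci[["scaffold", "pos"]].copy()
    freqs = {}
    for name in names:
        sub = matrix.dosage[masks[name]]
        called = ~np.isnan(sub)
        n_alleles = 2.0 * called.sum(axis=0)
        alt = np.nansum(sub, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / n_alleles
            pi = alt * (n_alleles - alt) / (n_alleles * (n_alleles - 1.0) / 2.0)
        pi[n_alleles < 2] = np.nan
        p[n_alleles < 1] = np.nan
        freqs[name] = p
        out[f"pi_{name}"] = pi
    pA, pB = freqs[names[0]], freqs[names[1]]
    out["dxy"] = pA * (1.0 - pB) + pB * (1.0 - pA)
    return out


def summarize_divergence(
    fst: pd.DataFrame, matrix: GenotypeMatrix | None = None, panel_masks: dict | None = None
) -> dict:
    """Mean/median/SD of theta over defined sites, plus polymorphism fractions.

    ``panel_masks`` (name -> boolean individual mask) adds, per panel, the
    fraction of sites at which both alleles are observed within the panel.
    """
    theta = fst["theta"].to_numpy(dtype=float)
    defined = np.isfinite(theta)
    if defined.sum() == 0:
        raise ValueError("no defined F_ST values to summarize")
    vals = theta[defined]
    summary = {
        "n_sites": int(defined.sum()),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=0)),
    }
    # multi-locus (ratio-of-sums) estimator: unlike the per-site mean it is
    # not Jensen-biased when differentiation varies across loci, so it is
    # the quantity that recovers a generative divergence parameter
    if {"a", "b", "c"} <= set(fst.columns):
        a = fst["a"].to_numpy(dtype=float)
        abc = a + fst["b"].to_numpy(dtype=float) + fst["c"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(abc)
        if ok.any() and np.nansum(abc[ok]) > 0:
            summary["weighted_mean"] = float(np.sum(a[ok]) / np.sum(abc[ok]))
    if matrix is not None and panel_masks:
        for name, mask in panel_masks.items():
            sub = matrix.dosage[np.asarray(mask)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                alt = np.nansum(sub, axis=0)
                n_alleles = 2.0 * (~np.isnan(sub)).sum(axis=0)
            poly = (alt > 0) & (alt < n_alleles)
            summary[f"polymorphic_fraction_{name}"] = float(poly.mean())
    return summary
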