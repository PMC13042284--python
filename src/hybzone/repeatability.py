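"""Cross-transect comparison: shared-SNP scans, blockiness, candidate overlap.

Two hybrid zones derived from the same parental species are not
evolutionarily independent, so agreement of their genome scans is measured,
not assumed: scans are intersected on (scaffold, position), statistics
correlated (with the caveat that linked SNPs violate the independence
assumption of the correlation tests), and the "blockiness" of each scan is
quantified by Moran's I on ordinal SNP positions and compared between
transects with a paired t-test over scaffolds or linkage groups.  Candidate
genes are SNP-to-gene assignments with flanks, and the k-way candidate
overlap is tested against the independence expectation by permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "intersect_scans",
    "scan_correlations",
    "morans_i",
    "compare_blockiness",
    "read_bed",
    "read_gff3_genes",
    "genes_for_snps",
    "overlap_enrichment",
]

_KEY = ["scaffold", "pos"]


def intersect_scans(a: pd.DataFrame, b: pd.DataFrame, suffixes=("_a", "_b")) -> pd.DataFrame:
    """Inner join of two per-locus scan tables on (scaffold, pos).

    Duplicate keys in either input raise.  Undefined statistics survive the
    join as nan and are dropped per-statistic by the consumers.
    """
    for name, df in (("first", a), ("second", b)):
        if df.duplicated(subset=_KEY).any():
            raise ValueError(f"duplicate (scaffold, pos) keys in {name} scan")
    return a.merge(b, on=_KEY, how="inner", suffixes=suffixes)


def scan_correlations(shared: pd.DataFrame, statistic: str, suffixes=("_a", "_b")) -> dict:
    """Pearson r and Kendall tau of one statistic across the shared SNPs.

    P-values are reported but flagged: linked SNPs are not independent, so
    their significance is overestimated.
    """
    x = shared[f"{statistic}{suffixes[0]}"].to_numpy(dtype=float)
    y = shared[f"{statistic}{suffixes[1]}"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return {"n": int(ok.sum()), "pearson_r": np.nan, "kendall_tau": np.nan,
                "pearson_p": np.nan, "kendall_p": np.nan, "degenerate": True,
                "p_values_overestimated": True}
    pr = stats.pearsonr(x, y)
    kt = stats.kendalltau(x, y)
    return {
        "n": int(ok.sum()),
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "kendall_tau": float(kt.statistic),
        "kendall_p": float(kt.pvalue),
        "degenerate": False,
        # linked SNPs violate independence; treat p-values as descriptive
        "p_values_overestimated": True,
    }


def morans_i(values, positions, weighting: str = "inverse_distance") -> float:
    """Moran's I of a statistic along ordinal SNP positions.

    I = (n / sum w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with w_ij = 1 / |pos_i - pos_j| (``inverse_distance``) or w_ij = 1 for
    adjacent ordinal indices (``binary``), w_ii = 0.  Under random
    arrangement E[I] = -1/(n-1); blocky signals push I toward +1.  Returns
    nan when the values have zero variance.
    """
    x = np.asarray(values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if x.shape[0] != pos.shape[0]:
        raise ValueError("values and positions must align")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 values")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0.0:
        return float("nan")
    d = np.abs(pos[:, None] - pos[None, :])
    if weighting == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif weighting == "binary":
        w = (d == 1.0).astype(float)
    else:
        raise ValueError("weighting must be 'inverse_distance' or 'binary'")
    num = z @ w @ z
    return float(n / w.sum() * num / denom)


def compare_blockiness(
    scan_a: pd.DataFrame,
    scan_b: pd.DataFrame,
    statistic: str,
    unit: str = "scaffold",
    position: str = "ordinal",
    min_loci_per_unit: int = 10,
    alternative: str = "two-sided",
    weighting: str = "inverse_distance",
) -> dict:
    """Paired comparison of per-unit Moran's I between two scans.

    Both scans must carry columns ``unit`` (scaffold or LG), ``position``
    (ordinal index within the unit) and ``statistic``, restricted to the
    shared SNPs.  Units present in both scans with at least
    ``min_loci_per_unit`` defined loci in each enter a paired t-test on
    (I_a - I_b).  Returns the per-unit table and the test summary.
    """
    rows = []
    for u in sorted(set(scan_a[unit]) & set(scan_b[unit])):
        ia = ib = np.nan
        sub_a = scan_a[(scan_a[unit] == u) & np.isfinite(scan_a[statistic])]
        sub_b = scan_b[(scan_b[unit] == u) & np.isfinite(scan_b[statistic])]
        if len(sub_a) >= min_loci_per_unit and len(sub_b) >= min_loci_per_unit:
            ia = morans_i(sub_a[statistic], sub_a[position], weighting=weighting)
            ib = morans_i(sub_b[statistic], sub_b[position], weighting=weighting)
        if np.isfinite(ia) and np.isfinite(ib):
            rows.append({"unit": u, "moran_a": ia, "moran_b": ib, "diff": ia - ib})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 paired units for the t-test")
    diffs = table["diff"].to_numpy()
    if np.allclose(diffs, 0.0):
        t_stat, p = np.nan, 1.0
    else:
        res = stats.ttest_rel(table["moran_a"], table["moran_b"], alternative=alternative)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "table": table,
        "n_units": len(table),
        "t": t_stat,
        "p": p,
        "mean_diff": float(diffs.mean()),
        "median_diff": float(np.median(diffs)),
    }


# ---------------------------------------------------------------------------
# Gene intervals and candidate overlap
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED gene intervals (0-based half-open): scaffold, start, end, gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["scaffold", "start", "end", "gene_id"]
    _validate_intervals(df)
    return df


def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from GFF3 (1-based closed, converted to 0-based half-open)."""
    cols = ["scaffold", "source", "type", "start", "end", "score", "strand", "phase", "attrs"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df = df[df["type"] == feature].copy()
    ids = df["attrs"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "scaffold": df["scaffold"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "gene_id": ids.fillna(pd.Series("gene_" + df.index.astype(str), index=df.index)),
        }
    ).reset_index(drop=True)
    _validate_intervals(out)
    return out


def _validate_intervals(df: pd.DataFrame) -> None:
    bad = df.index[(df["end"].astype(int) <= df["start"].astype(int))]
    if len(bad):
        raise ValueError(f"malformed interval(s) at row(s) {list(bad[:5])}")


def genes_for_snps(snps: pd.DataFrame, genes: pd.DataFrame, flank: int = 5000) -> pd.DataFrame:
    """Assign each SNP to every gene whose flanked interval contains it.

    ``snps`` carries (scaffold, pos) with 1-based positions; ``genes``
    carries 0-based half-open (scaffold, start, end, gene_id).  Intervals
    are expanded by ``flank`` bp on both sides (clipped at zero).
    Overlapping flanked genes each receive the SNP.  Output: one row per
    (scaffold, pos, gene_id) assignment.
    """
    _validate_intervals(genes)
    rows = []
    for scaf, gene_grp in genes.groupby("scaffold"):
        sub = snps[snps["scaffold"] == scaf]
        if sub.empty:
            continue
        pos0 = sub["pos"].to_numpy(dtype=int) - 1  # to 0-based coordinates
        starts = np.maximum(gene_grp["start"].to_numpy(dtype=int) - flank, 0)
        ends = gene_grp["end"].to_numpy(dtype=int) + flank
        inside = (pos0[:, None] >= starts[None, :]) & (pos0[:, None] < ends[None, :])
        snp_i, gene_j = np.nonzero(inside)
        for i, j in zip(snp_i, gene_j):
            rows.append(
                {
                    "scaffold": scaf,
                    "pos": int(sub["pos"].iloc[i]),
                    "gene_id": gene_grp["gene_id"].iloc[j],
                }
            )
    return pd.DataFrame(rows, columns=["scaffold", "pos", "gene_id"])


def overlap_enrichment(
    sets, universe, n_permutations: int = 10_000, seed: int = 0
) -> dict:
    """k-way candidate-set overlap against the independence expectation.

    ``sets`` is a sequence of gene-id collections, ``universe`` the full
    gene collection they are drawn from.  The expected intersection size
    under independence is N * prod(|S_i| / N); the permutation p-value
    redraws each set uniformly without replacement from the universe and
    counts permutations whose intersection is at least the observed one
    (add-one corrected).  For k = 2 the permutation null is hypergeometric.
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    universe = list(universe)
    N = len(universe)
    for s in sets:
        if len(s) > N:
            raise ValueError("a set is larger than the universe")
        if not s <= set(universe):
            raise ValueError("every set must be a subset of the universe")
    observed = len(set.intersection(*sets))
    expected = N * float(np.prod([len(s) / N for s in sets]))
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in sets]
    universe_arr = np.asarray(universe, dtype=object)
    count = 0
    for _ in range(n_permutations):
        drawn = [
            set(universe_arr[rng.choice(N, size=k, replace=False)]) for k in sizes
        ]
        if len(set.intersection(*drawn)) >= observed:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return {
        "observed": observed,
        "expected": expected,
        "p": p,
        "set_sizes": sizes,
        "universe_size": N,
        "n_permutations": n_permutations,
    }
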