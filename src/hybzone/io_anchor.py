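"""Genotype containers, VCF round-trip, site filters, and linkage-map scaffold anchoring.

The genome assemblies this pipeline targets are highly fragmented, so
chromosome-scale context comes from anchoring scaffolds to a cDNA linkage map
("super-scaffolds"): each mapped cDNA ties its best-matching scaffold to a
linkage group (LG) and centimorgan (cM) position, and scaffolds are ordered
within LGs by that anchor.  SNP "ordinal positions" (1, 2, 3, ... along the
anchored order) are the spatial coordinate used by the autocorrelation
statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SuperScaffold",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "anchor_scaffolds",
    "ordinal_positions",
]


class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with locus coordinates.

    Dosages live in {0, 1, 2} with ``nan`` for missing calls.  Loci are kept
    sorted by (scaffold, position); construction re-sorts if needed so all
    downstream code can rely on genomic order.

    Parameters
    ----------
    dosage : (n_individuals, n_loci) float array
        Counts of the ALT allele per call; ``nan`` marks missing genotypes.
    samples : sequence of str
    loci : DataFrame
        Must carry columns ``scaffold`` (str), ``pos`` (1-based int, VCF
        convention), ``ref``, ``alt``; optional ``qual``.
    gq, dp : optional (n_individuals, n_loci) arrays
        Per-call genotype quality and read depth (``nan`` where absent).
    """

    def __init__(self, dosage, samples, loci, gq=None, dp=None):
        dosage = np.asarray(dosage, dtype=float)
        loci = pd.DataFrame(loci).reset_index(drop=True)
        for col in ("scaffold", "pos", "ref", "alt"):
            if col not in loci.columns:
                raise ValueError(f"loci table missing required column {col!r}")
        if dosage.ndim != 2 or dosage.shape != (len(samples), len(loci)):
            raise ValueError("dosage shape does not match samples x loci")
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (nan)")
        order = np.lexsort((loci["pos"].to_numpy(), loci["scaffold"].to_numpy()))
        if not np.array_equal(order, np.arange(len(loci))):
            loci = loci.iloc[order].reset_index(drop=True)
            dosage = dosage[:, order]
            if gq is not None:
                gq = np.asarray(gq, dtype=float)[:, order]
            if dp is not None:
                dp = np.asarray(dp, dtype=float)[:, order]
        self.dosage = dosage
        self.samples = list(samples)
        self.loci = loci
        self.gq = None if gq is None else np.asarray(gq, dtype=float)
        self.dp = None if dp is None else np.asarray(dp, dtype=float)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_loci} loci)"

    # -- per-site summaries ---------------------------------------------
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """ALT-allele frequency per locus among called genotypes."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def take_loci(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.samples,
            self.loci.iloc[idx],
            None if self.gq is None else self.gq[:, idx],
            None if self.dp is None else self.dp[:, idx],
        )

    def take_samples(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosage[idx],
            [self.samples[i] for i in idx],
            self.loci,
            None if self.gq is None else self.gq[idx],
            None if self.dp is None else self.dp[idx],
        )


@dataclass
class SuperScaffold:
    """Scaffolds anchored to linkage-group positions, ordered within each LG.

    ``table`` has one row per anchored scaffold: ``scaffold``, ``lg``,
    ``cm`` (anchor centimorgan, the median over the scaffold's retained
    cDNAs), ``length_bp`` and ``order`` (0-based rank within the LG).
    ``span_bp`` is the exact sum of member scaffold lengths.  ``report``
    counts what the anchoring filters discarded.
    """

    table: pd.DataFrame
    span_bp: int
    report: dict = field(default_factory=dict)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.table["scaffold"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF round-trip
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix` (via cyvcf2).

    Multiallelic records are rejected with the offending position named.
    ``./.`` genotypes become missing dosages; per-call GQ/DP are kept when
    the FORMAT declares them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, gqs, dps, rows = [], [], [], []
    has_gq = "GQ" in {f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"}
    has_dp = "DP" in {f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; split or drop it first"
            )
        gt = var.gt_types.astype(float)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosages.append(dos)
        if has_gq:
            g = np.asarray(var.format("GQ"), dtype=float)[:, 0]
            g[g < 0] = np.nan
            gqs.append(g)
        if has_dp:
            d = np.asarray(var.format("DP"), dtype=float)[:, 0]
            d[d < 0] = np.nan
            dps.append(d)
        rows.append(
            {
                "scaffold": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "qual": np.nan if var.QUAL is None else float(var.QUAL),
            }
        )
    loci = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "qual"])
    dosage = np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    gq = np.column_stack(gqs) if gqs else None
    dp = np.column_stack(dps) if dps else None
    return GenotypeMatrix(dosage, samples, loci, gq, dp)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a VCF v4.2 with GT:GQ:DP (GQ/DP emitted only when present)."""
    fmt_fields = ["GT"]
    if matrix.gq is not None:
        fmt_fields.append("GQ")
    if matrix.dp is not None:
        fmt_fields.append("DP")
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "GQ" in fmt_fields:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        if "DP" in fmt_fields:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for scaf in matrix.loci["scaffold"].unique():
            fh.write(f"##contig=<ID={scaf}>\n")
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header_cols + matrix.samples) + "\n")
        quals = matrix.loci["qual"] if "qual" in matrix.loci.columns else None
        for j in range(matrix.n_loci):
            row = matrix.loci.iloc[j]
            qual = "." if quals is None or np.isnan(quals.iloc[j]) else f"{quals.iloc[j]:g}"
            fields = [
                str(row["scaffold"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                qual,
                "PASS",
                ".",
                ":".join(fmt_fields),
            ]
            calls = []
            for i in range(matrix.n_individuals):
                d = matrix.dosage[i, j]
                parts = ["./." if np.isnan(d) else gt_strings[d]]
                if "GQ" in fmt_fields:
                    g = matrix.gq[i, j]
                    parts.append("." if np.isnan(g) else str(int(g)))
                if "DP" in fmt_fields:
                    v = matrix.dp[i, j]
                    parts.append("." if np.isnan(v) else str(int(v)))
                calls.append(":".join(parts))
            fh.write("\t".join(fields + calls) + "\n")


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def filter_sites(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.7,
    min_qual: float = 30.0,
    min_gq: float = 20.0,
    min_dp: float = 5.0,
    min_maf: float = 0.05,
    dp_strict: bool = False,
    anchored_only: bool = False,
    anchors: SuperScaffold | None = None,
) -> GenotypeMatrix:
    """Apply the standard post-calling site filters.

    Per-call masking happens first (a call with GQ below ``min_gq``, or DP
    below ``min_dp`` — strictly at-or-below with ``dp_strict`` — becomes
    missing), then site-level criteria are evaluated on the masked matrix:
    call rate at least ``min_call_rate``, QUAL at least ``min_qual``, minor
    allele frequency strictly above ``min_maf``.  With ``anchored_only``,
    sites on scaffolds absent from ``anchors`` are dropped too.

    Idempotent: filtering an already-filtered matrix is a no-op.
    """
    for name, val, lo, hi in (
        ("min_call_rate", min_call_rate, 0, 1),
        ("min_maf", min_maf, 0, 0.5),
    ):
        if not (lo <= val <= hi):
            raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
    dosage = matrix.dosage.copy()
    if matrix.gq is not None:
        dosage[np.nan_to_num(matrix.gq, nan=np.inf) < min_gq] = np.nan
    if matrix.dp is not None:
        dp = np.nan_to_num(matrix.dp, nan=np.inf)
        dosage[(dp <= min_dp) if dp_strict else (dp < min_dp)] = np.nan
    masked = GenotypeMatrix(dosage, matrix.samples, matrix.loci, matrix.gq, matrix.dp)

    keep = masked.call_rate() >= min_call_rate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        keep &= np.nan_to_num(masked.maf(), nan=-1.0) > min_maf
    if "qual" in matrix.loci.columns:
        qual = matrix.loci["qual"].to_numpy(dtype=float)
        keep &= ~(np.nan_to_num(qual, nan=np.inf) < min_qual)
    if anchored_only:
        if anchors is None:
            raise ValueError("anchored_only=True requires anchors")
        keep &= matrix.loci["scaffold"].isin(anchors.scaffolds).to_numpy()
    if not keep.any():
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return masked.take_loci(keep)


# ---------------------------------------------------------------------------
# Scaffold anchoring
# ---------------------------------------------------------------------------

def _as_fraction(values: pd.Series) -> pd.Series:
    # unit auto-detection: anything > 1 is a percentage
    vals = values.astype(float)
    if (vals > 1.0).any():
        return vals / 100.0
    return vals


def anchor_scaffolds(
    alignments: pd.DataFrame,
    linkage_map: pd.DataFrame,
    scaffold_lengths: pd.DataFrame,
    min_coverage: float = 0.50,
    min_identity: float = 0.90,
) -> SuperScaffold:
    """Anchor scaffolds to linkage-group positions via cDNA alignments.

    Per cDNA: alignment rows with coverage or identity at or below the
    thresholds are dropped; among survivors the single best scaffold by
    highest identity is kept, and an exact identity tie across different
    scaffolds discards the cDNA as unresolvable multimapping.  cDNAs absent
    from the linkage map are excluded (counted in the report).  A scaffold's
    anchor is the median cM of its retained cDNAs; conflicting LG
    assignments discard the scaffold with a warning.  Scaffolds are ordered
    within each LG by anchor cM, ties broken by scaffold id.

    ``alignments``: columns cdna_id, scaffold, coverage, identity (fractions
    or percent, auto-detected).  ``linkage_map``: cdna_id, lg, cm.
    ``scaffold_lengths``: scaffold, length_bp.
    """
    aln = alignments.copy()
    aln["coverage"] = _as_fraction(aln["coverage"])
    aln["identity"] = _as_fraction(aln["identity"])
    report = {"alignments_in": len(aln), "cdnas_in": aln["cdna_id"].nunique()}

    aln = aln[(aln["coverage"] > min_coverage) & (aln["identity"] > min_identity)]
    report["alignments_pass_thresholds"] = len(aln)

    best_rows = []
    n_ties = 0
    for cdna, grp in aln.groupby("cdna_id", sort=True):
        top = grp[grp["identity"] == grp["identity"].max()]
        if top["scaffold"].nunique() > 1:
            n_ties += 1  # mapped equally well to multiple scaffolds
            continue
        best_rows.append((cdna, top["scaffold"].iloc[0]))
    report["cdnas_tied_discarded"] = n_ties
    best = pd.DataFrame(best_rows, columns=["cdna_id", "scaffold"])

    lmap = linkage_map.set_index("cdna_id")
    in_map = best["cdna_id"].isin(lmap.index)
    report["cdnas_not_in_map"] = int((~in_map).sum())
    best = best[in_map]
    best = best.join(lmap[["lg", "cm"]], on="cdna_id")
    report["cdnas_retained"] = len(best)

    rows = []
    for scaf, grp in best.groupby("scaffold", sort=True):
        if grp["lg"].nunique() > 1:
            warnings.warn(
                f"scaffold {scaf} has conflicting LG assignments; discarded",
                stacklevel=2,
            )
            continue
        rows.append({"scaffold": scaf, "lg": grp["lg"].iloc[0], "cm": float(grp["cm"].median())})
    table = pd.DataFrame(rows, columns=["scaffold", "lg", "cm"])
    lengths = scaffold_lengths.set_index("scaffold")["length_bp"]
    table["length_bp"] = table["scaffold"].map(lengths).astype("int64")
    table = table.sort_values(["lg", "cm", "scaffold"], kind="stable").reset_index(drop=True)
    table["order"] = table.groupby("lg").cumcount()
    span = int(table["length_bp"].sum())
    report["scaffolds_anchored"] = len(table)
    return SuperScaffold(table=table, span_bp=span, report=report)


def ordinal_positions(matrix: GenotypeMatrix, anchors: SuperScaffold) -> pd.DataFrame:
    """Sequential SNP indices (1, 2, 3, ...) within scaffold and within LG.

    The within-LG index runs across scaffold boundaries in anchor order, so
    it is the coordinate on which blockiness (Moran's I) is measured.
    Raises if any locus sits on an unanchored scaffold.
    """
    tab = anchors.table.set_index("scaffold")
    unknown = sorted(set(matrix.loci["scaffold"]) - set(tab.index))
    if unknown:
        raise ValueError(f"loci on unanchored scaffolds: {unknown}")
    loci = matrix.loci[["scaffold", "pos"]].copy()
    loci["lg"] = loci["scaffold"].map(tab["lg"])
    loci["scaffold_order"] = loci["scaffold"].map(tab["order"])
    loci["ordinal_scaffold"] = (
        loci.sort_values(["scaffold", "pos"]).groupby("scaffold").cumcount().sort_index() + 1
    )
    rank = loci.sort_values(["lg", "scaffold_order", "pos"]).index
    loci["ordinal_lg"] = 0
    lg_counter = loci.loc[rank, "lg"]
    loci.loc[rank, "ordinal_lg"] = lg_counter.groupby(lg_counter).cumcount().to_numpy() + 1
    return loci[["scaffold", "pos", "lg", "ordinal_scaffold", "ordinal_lg"]]
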