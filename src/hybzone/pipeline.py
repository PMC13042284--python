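"""End-to-end convenience layer: per-transect analysis and transect comparison.

One call runs the full desk-scale analysis of a hybrid-zone transect —
hybrid index from reference panels, environment pruning, RDA1, the per-SNP
GEA scan, parental-panel definition, and Bayesian genomic clines on the
ancestry-informative loci — and a second call lines two transects up on
shared SNPs and measures how repeatable their scans are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import HybridIndexEstimator, define_parental_panels
from .clines import BayesianGenomicClines, select_informative_loci
from .core import ParentalFreqs
from .gea import GeaScan, RDA1, prune_env
from .io_anchor import GenotypeMatrix
from .repeatability import intersect_scans, scan_correlations

__all__ = ["TransectAnalysis", "analyze_transect", "compare_transects"]


@dataclass
class TransectAnalysis:
    """Results of one transect: hybrid indexes, GEA table, cline table."""

    h: np.ndarray
    panel_labels: np.ndarray
    panel_freqs: ParentalFreqs
    rda: RDA1
    gea: pd.DataFrame
    clines: pd.DataFrame
    informative_mask: np.ndarray


def analyze_transect(
    matrix: GenotypeMatrix,
    env: pd.DataFrame,
    reference_labels,
    mcmc_iterations: int = 10_000,
    mcmc_burn_in: int | None = None,
    mcmc_thin: int = 10,
    etpi_level: float = 0.95,
    seed: int = 0,
) -> TransectAnalysis:
    """Run the full single-transect analysis.

    ``reference_labels`` designate known pure individuals (1 = parent A,
    0 = parent B, -1 = unknown); they polarize the hybrid index the same
    way across transects.  The Bayesian clines run on the admixed
    individuals at loci with parental differential >= 0.6.
    """
    ref = np.asarray(reference_labels)
    est = HybridIndexEstimator().fit(matrix.dosage[ref >= 0], ref[ref >= 0])
    h = est.predict(matrix.dosage)

    pruned, _ = prune_env(env)
    rda = RDA1().fit(pruned, h)
    scan = GeaScan().fit(matrix.dosage, rda.transform(pruned))
    gea = scan.to_frame(matrix.loci)

    labels, freqs = define_parental_panels(h, matrix)
    mask = select_informative_loci(freqs)
    admixed = labels == "admixed"
    burn = mcmc_iterations // 2 if mcmc_burn_in is None else mcmc_burn_in
    bayes_fit = BayesianGenomicClines(
        n_iterations=mcmc_iterations,
        burn_in=burn,
        thin=mcmc_thin,
        etpi_level=etpi_level,
        seed=seed,
    ).fit(
        matrix.dosage[admixed][:, mask],
        h[admixed],
        parental=ParentalFreqs(freqs.p_a[mask], freqs.p_b[mask]),
    )
    clines = bayes_fit.to_frame(matrix.loci.iloc[np.flatnonzero(mask)])
    return TransectAnalysis(
        h=h,
        panel_labels=labels,
        panel_freqs=freqs,
        rda=rda,
        gea=gea,
        clines=clines,
        informative_mask=mask,
    )


def compare_transects(a: TransectAnalysis, b: TransectAnalysis) -> dict:
    """Cross-transect repeatability of the GEA and cline scans on shared SNPs.

    Returns Pearson correlations of -log10 GEA p and of posterior-mean
    alpha, plus the direction agreement among loci flagged alpha-excess in
    both transects.
    """
    gea = intersect_scans(a.gea, b.gea)
    for side in ("a", "b"):
        gea[f"logp_{side}"] = -np.log10(np.clip(gea[f"p_{side}"], 1e-300, 1.0))
    r_gea = scan_correlations(gea, "logp")

    cl = intersect_scans(a.clines, b.clines)
    r_alpha = scan_correlations(cl, "alpha_mean")
    joint = cl[(cl["alpha_excess_a"] != "0") & (cl["alpha_excess_b"] != "0")]
    agreement = (
        float((joint["alpha_excess_a"] == joint["alpha_excess_b"]).mean())
        if len(joint)
        else float("nan")
    )
    return {
        "n_shared_gea": r_gea["n"],
        "gea_logp_pearson_r": r_gea["pearson_r"],
        "n_shared_clines": r_alpha["n"],
        "alpha_pearson_r": r_alpha["pearson_r"],
        "n_jointly_flagged": int(len(joint)),
        "alpha_sign_agreement": agreement,
    }
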