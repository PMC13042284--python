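"""Synthetic hybrid-zone datasets with known truth.

Two diverged parental gene pools (Balding–Nichols divergence controlled by a
single F parameter) meet along a transect; each simulated individual carries
a true hybrid index h, and each locus may carry genomic-cline distortions
(alpha: directional introgression; beta: cline steepness).  Genotypes are
drawn through the cline function phi(h), so every downstream estimator has a
parameter-recovery target.  Two sampling designs are emulated: a broad
latitudinal transect (many small populations along a smooth gradient) and an
elevational design (locations x {N, S, V} sites, with valley > south-slope >
north-slope parent-A ancestry within a location).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ParentalFreqs, phi
from .io_anchor import GenotypeMatrix, SuperScaffold, write_vcf

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_parental_freqs",
    "simulate_hybrid_zone",
    "simulate_snow_series",
    "simulate_cdna_alignments",
    "simulate_correlated_parental_freqs",
    "simulate_transect_pair",
    "planted_alpha_blocks",
    "simulated_anchors",
    "save_dataset",
]

_SITE_CLASSES = ("N", "S", "V")
# logit-scale offsets for the elevational design: within a location, valleys
# are most parent-A (white spruce), north-facing slopes most parent-B
# (Engelmann).  Free simulator parameters; no empirical within-location
# variance is available to calibrate them.
_SITE_OFFSETS = {"N": -1.5, "S": 0.0, "V": 1.5}


@dataclass
class SimConfig:
    """Parameters of a simulated hybrid zone.

    ``divergence_F`` is the Balding–Nichols F of the two parental pools
    (approximately their F_ST).  ``cline_alpha_truth``/``cline_beta_truth``
    are per-locus distortion vectors (zeros = neutral).  ``env_effect`` is
    the correlation between the one informative environmental variable and
    h.  ``n_loci`` must equal ``n_scaffolds * loci_per_scaffold``.
    """

    n_individuals: int = 300
    n_loci: int = 500
    n_scaffolds: int = 25
    loci_per_scaffold: int = 20
    divergence_F: float = 0.3
    transect_model: str = "latitudinal"
    n_locations: int = 7
    cline_alpha_truth: np.ndarray | None = None
    cline_beta_truth: np.ndarray | None = None
    env_effect: float = 0.9
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_loci != self.n_scaffolds * self.loci_per_scaffold:
            raise ValueError("n_loci must equal n_scaffolds * loci_per_scaffold")
        if not (0.0 < self.divergence_F < 1.0) or not np.isfinite(self.divergence_F):
            raise ValueError("divergence_F must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.transect_model not in ("latitudinal", "elevational"):
            raise ValueError("transect_model must be 'latitudinal' or 'elevational'")
        for name in ("cline_alpha_truth", "cline_beta_truth"):
            vec = getattr(self, name)
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.n_loci,):
                    raise ValueError(f"{name} must have length n_loci")
                setattr(self, name, vec)

    def alpha(self) -> np.ndarray:
        return np.zeros(self.n_loci) if self.cline_alpha_truth is None else self.cline_alpha_truth

    def beta(self) -> np.ndarray:
        return np.zeros(self.n_loci) if self.cline_beta_truth is None else self.cline_beta_truth


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset (what recovery tests score against)."""

    h: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    planted: np.ndarray
    parental: ParentalFreqs
    env_true_variable: str = "temperature"

    def to_json(self, path) -> None:
        payload = {
            "h": self.h.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "planted": self.planted.astype(int).tolist(),
            "p_a": self.parental.p_a.tolist(),
            "p_b": self.parental.p_b.tolist(),
            "env_true_variable": self.env_true_variable,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def simulate_parental_freqs(n_loci: int, divergence_F: float, seed: int) -> ParentalFreqs:
    """Draw diverged parental allele frequencies (Balding–Nichols model).

    Each locus gets an ancestral frequency p ~ Uniform(0.05, 0.95), then the
    two pool frequencies are independent Beta draws with mean p and variance
    parameter F = ``divergence_F``, i.e. shape (p (1-F)/F, (1-p)(1-F)/F).
    The expected Weir–Cockerham F_ST between large samples from the two
    pools is approximately F.
    """
    if not np.isfinite(divergence_F) or not (0.0 < divergence_F < 1.0):
        raise ValueError("divergence_F must be a finite number in (0, 1)")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_loci)
    scale = (1.0 - divergence_F) / divergence_F
    p_a = rng.beta(anc * scale, (1.0 - anc) * scale)
    p_b = rng.beta(anc * scale, (1.0 - anc) * scale)
    return ParentalFreqs(p_a=p_a, p_b=p_b, ancestral=anc)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _assign_hybrid_indexes(config: SimConfig, rng) -> tuple[np.ndarray, pd.DataFrame]:
    n = config.n_individuals
    if config.transect_model == "latitudinal":
        t = np.linspace(0.0, 1.0, n)
        logit = 12.0 * (t - 0.5) + rng.normal(0.0, 0.4, size=n)
        h = _sigmoid(logit)
        pop_size = 2  # small populations along the gradient, as in broad-transect designs
        frame = pd.DataFrame(
            {
                "sample_id": [f"ind_{i:04d}" for i in range(n)],
                "population": [f"pop_{i // pop_size:03d}" for i in range(n)],
                "location": [f"pop_{i // pop_size:03d}" for i in range(n)],
                "site_class": "-",
                "lat": 49.0 + 8.0 * t,
                "lon": -125.0 + 10.0 * t,
                "elevation": np.full(n, 800.0),
            }
        )
        return h, frame
    # elevational: n_locations x {N, S, V} populations
    n_pops = config.n_locations * 3
    per_pop = int(np.ceil(n / n_pops))
    loc_trend = np.linspace(-4.0, 4.0, config.n_locations)
    rows, h = [], []
    i = 0
    for k in range(config.n_locations):
        for site in _SITE_CLASSES:
            for _ in range(per_pop):
                if i >= n:
                    break
                logit = loc_trend[k] + _SITE_OFFSETS[site] + rng.normal(0.0, 0.5)
                h.append(_sigmoid(logit))
                rows.append(
                    {
                        "sample_id": f"ind_{i:04d}",
                        "population": f"loc{k + 1}_{site}",
                        "location": f"loc{k + 1}",
                        "site_class": site,
                        "lat": 51.0 + 0.1 * k,
                        "lon": -116.0 + 0.15 * k,
                        "elevation": 1400.0 if site == "V" else 2100.0,
                    }
                )
                i += 1
    frame = pd.DataFrame(rows)
    return np.asarray(h), frame


def _env_table(h: np.ndarray, env_effect: float, rng) -> pd.DataFrame:
    """One informative variable correlated with h at ``env_effect``, plus decoys."""
    n = len(h)
    z = (h - h.mean()) / max(h.std(), 1e-12)
    noise = rng.normal(size=n)
    true_var = env_effect * z + np.sqrt(max(0.0, 1.0 - env_effect**2)) * noise
    return pd.DataFrame(
        {
            "temperature": 5.0 + 3.0 * true_var,
            "dif": rng.normal(800.0, 60.0, size=n),
            "pvout": rng.normal(3.5, 0.4, size=n),
            "slope": np.abs(rng.normal(12.0, 6.0, size=n)),
        }
    )


def _locus_table(config: SimConfig) -> pd.DataFrame:
    scaffolds = np.repeat(
        [f"scaffold_{k:04d}" for k in range(config.n_scaffolds)], config.loci_per_scaffold
    )
    pos = np.tile(1000 * (np.arange(config.loci_per_scaffold) + 1), config.n_scaffolds)
    return pd.DataFrame(
        {"scaffold": scaffolds, "pos": pos, "ref": "A", "alt": "G", "qual": 999.0}
    )


def simulated_anchors(config: SimConfig) -> SuperScaffold:
    """Super-scaffold ground truth for a simulated dataset.

    Scaffolds are assigned to 12 linkage groups in contiguous blocks and
    ordered by index, so ordinal positions follow the simulation's locus
    order exactly.
    """
    n_lg = min(12, config.n_scaffolds)
    rows = []
    for k in range(config.n_scaffolds):
        lg = int(k * n_lg / config.n_scaffolds) + 1
        rows.append(
            {
                "scaffold": f"scaffold_{k:04d}",
                "lg": f"LG{lg:02d}",
                "cm": float(k),
                "length_bp": 1000 * (config.loci_per_scaffold + 1),
            }
        )
    table = pd.DataFrame(rows)
    table["order"] = table.groupby("lg").cumcount()
    return SuperScaffold(table=table, span_bp=int(table["length_bp"].sum()), report={})


def simulate_hybrid_zone(
    config: SimConfig, parental: ParentalFreqs | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord, pd.DataFrame]:
    """Simulate genotypes, sample metadata, truth and environment for one transect.

    At locus l for an individual with hybrid index h, each of the two
    alleles descends from parent A with probability phi(h; alpha_l, beta_l)
    and is then drawn with that parent's allele frequency, so the dosage is
    Binomial(2, phi p_a + (1 - phi) p_b).  Genotypes are masked missing
    completely at random at ``missing_rate``.

    Returns ``(matrix, sample_frame, truth, env_table)``.  Passing
    ``parental`` overrides the pool frequencies (used to give two transects
    a common parental origin).
    """
    rng = np.random.default_rng(config.seed)
    if parental is None:
        parental = simulate_parental_freqs(config.n_loci, config.divergence_F, config.seed + 1)
    elif parental.n_loci != config.n_loci:
        raise ValueError("parental frequencies must match n_loci")
    h, frame = _assign_hybrid_indexes(config, rng)
    alpha, beta = config.alpha(), config.beta()

    p = phi(h[:, None], alpha[None, :], beta[None, :])
    q = p * parental.p_a[None, :] + (1.0 - p) * parental.p_b[None, :]
    dosage = rng.binomial(2, q).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    gq = rng.integers(30, 100, size=dosage.shape).astype(float)
    dp = rng.poisson(20.0, size=dosage.shape).astype(float)

    loci = _locus_table(config)
    matrix = GenotypeMatrix(dosage, frame["sample_id"].tolist(), loci, gq=gq, dp=dp)
    env = _env_table(h, config.env_effect, rng)
    planted = (np.abs(alpha) > 0) | (np.abs(beta) > 0)
    truth = TruthRecord(h=h, alpha=alpha, beta=beta, planted=planted, parental=parental)
    return matrix, frame, truth, env


def planted_alpha_blocks(
    n_loci: int, n_blocks: int, block_len: int, value: float, seed: int = 0
) -> np.ndarray:
    """Alpha truth vector with contiguous outlier blocks (linkage-block signal).

    Blocks are placed without overlap at random starts; the blocky layout is
    what the chromosomal-autocorrelation comparison detects.
    """
    rng = np.random.default_rng(seed)
    alpha = np.zeros(n_loci)
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_blocks and attempts < 1000:
        s = int(rng.integers(0, n_loci - block_len + 1))
        if all(abs(s - t) >= block_len for t in starts):
            starts.append(s)
        attempts += 1
    for s in starts:
        alpha[s : s + block_len] = value
    return alpha


def simulate_correlated_parental_freqs(
    n_loci: int, correlation_length: int, seed: int, amplitude: float = 0.35
) -> ParentalFreqs:
    """Parental pools whose divergence is autocorrelated along the genome.

    The per-locus frequency differential follows a moving-average Gaussian
    field with window ``correlation_length`` (a stand-in for linkage blocks
    of correlated effects): pools sit at 0.5 +/- f_l with the field scaled
    to standard deviation ``amplitude``.  Longer correlation lengths at the
    same marginal divergence yield blockier genome scans — the contrast
    the chromosomal-autocorrelation comparison is designed to detect.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=n_loci + correlation_length)
    f = np.convolve(raw, np.ones(correlation_length) / np.sqrt(correlation_length), mode="valid")
    f = amplitude * f[:n_loci] / f[:n_loci].std()
    pa = np.clip(0.5 + f, 0.02, 0.98)
    pb = np.clip(0.5 - f, 0.02, 0.98)
    return ParentalFreqs(pa, pb)


def simulate_transect_pair(
    config_a: SimConfig,
    config_b: SimConfig,
    shared: bool = True,
    n_causal: int = 30,
    alpha_value: float = 0.8,
    seed: int = 0,
):
    """Two hybrid-zone transects, with or without a shared parental origin.

    With ``shared=True`` both transects draw genotypes from the same
    parental pools and carry identical planted alpha distortions at
    ``n_causal`` ancestry-informative loci (the replicated-hybrid-zone
    situation).  With ``shared=False`` everything is redrawn independently
    for the second transect — the no-shared-effect control.  Planted loci
    are chosen among loci with parental differential >= 0.6 so the cline
    analysis can see them; signs alternate to cover both introgression
    directions.

    Returns two dataset tuples ``(matrix, frame, truth, env)``.
    """
    from dataclasses import replace

    def build(cfg, pf, causal_seed):
        rng = np.random.default_rng(causal_seed)
        informative = np.flatnonzero(pf.differential >= 0.6)
        chosen = rng.choice(informative, size=min(n_causal, informative.size), replace=False)
        alpha = np.zeros(cfg.n_loci)
        alpha[chosen] = alpha_value * np.where(np.arange(chosen.size) % 2 == 0, 1.0, -1.0)
        return replace(cfg, cline_alpha_truth=alpha)

    pf_a = simulate_parental_freqs(config_a.n_loci, config_a.divergence_F, seed)
    cfg_a = build(config_a, pf_a, seed + 10)
    data_a = simulate_hybrid_zone(cfg_a, parental=pf_a)
    if shared:
        cfg_b = replace(config_b, cline_alpha_truth=cfg_a.cline_alpha_truth)
        data_b = simulate_hybrid_zone(cfg_b, parental=pf_a)
    else:
        pf_b = simulate_parental_freqs(config_b.n_loci, config_b.divergence_F, seed + 20)
        cfg_b = build(config_b, pf_b, seed + 30)
        data_b = simulate_hybrid_zone(cfg_b, parental=pf_b)
    return data_a, data_b


def simulate_snow_series(n_days: int, melt_day_truth: int, noise: float, seed: int) -> np.ndarray:
    """Daily binary snow series: 1 = snow-covered, 0 = snow-free.

    Days 1..melt_day_truth-1 are snow-covered, melt_day_truth..n_days free,
    with isolated flips at rate ``noise``.
    """
    if not (1 <= melt_day_truth <= n_days):
        raise ValueError("melt_day_truth must lie in [1, n_days]")
    rng = np.random.default_rng(seed)
    series = np.zeros(n_days, dtype=int)
    series[: melt_day_truth - 1] = 1
    if noise > 0:
        flips = rng.random(n_days) < noise
        series[flips] = 1 - series[flips]
    return series


def simulate_cdna_alignments(
    n_cdna: int, map_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """cDNA alignment summaries + linkage map + scaffold lengths, with planted edge cases.

    When ``n_cdna >= 4`` the first four cDNAs exercise the anchoring
    filters: low coverage, low identity, an exact-identity tie across two
    scaffolds, and an unmapped cDNA (no alignment row).  The remaining
    cDNAs align uniquely and cleanly, one scaffold each.  A cM map covers
    ``map_fraction`` of the cDNAs across 12 linkage groups.
    """
    if not (0.0 < map_fraction <= 1.0):
        raise ValueError("map_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    cdnas = [f"cdna_{i:04d}" for i in range(n_cdna)]
    scaffolds = [f"scaf_{i:04d}" for i in range(n_cdna + 1)]
    rows = []
    for i, cdna in enumerate(cdnas):
        if n_cdna >= 4 and i == 0:  # low coverage
            rows.append((cdna, scaffolds[i], 0.40, 0.98))
        elif n_cdna >= 4 and i == 1:  # low identity
            rows.append((cdna, scaffolds[i], 0.90, 0.85))
        elif n_cdna >= 4 and i == 2:  # exact tie across two scaffolds
            rows.append((cdna, scaffolds[i], 0.95, 0.97))
            rows.append((cdna, scaffolds[n_cdna], 0.95, 0.97))
        elif n_cdna >= 4 and i == 3:  # unmapped: no alignment row
            continue
        else:
            rows.append(
                (cdna, scaffolds[i], rng.uniform(0.6, 1.0), rng.uniform(0.92, 1.0))
            )
    alignments = pd.DataFrame(rows, columns=["cdna_id", "scaffold", "coverage", "identity"])

    n_mapped = max(1, int(round(map_fraction * n_cdna)))
    mapped = sorted(rng.choice(n_cdna, size=n_mapped, replace=False))
    lmap = pd.DataFrame(
        {
            "cdna_id": [cdnas[i] for i in mapped],
            "lg": [f"LG{(i % 12) + 1:02d}" for i in range(n_mapped)],
            "cm": np.round(rng.uniform(0.0, 120.0, size=n_mapped), 2),
        }
    )
    lengths = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "length_bp": rng.integers(50_000, 500_000, size=len(scaffolds)),
        }
    )
    return alignments, lmap, lengths


def save_dataset(directory, matrix, frame, truth, env) -> None:
    """Write the standard text artefacts of one simulated transect.

    VCF (GT:GQ:DP), sample metadata TSV, environment TSV and truth JSON.
    """
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_vcf(matrix, d / "genotypes.vcf")
    frame.to_csv(d / "samples.tsv", sep="\t", index=False)
    env_out = env.copy()
    env_out.insert(0, "sample_id", frame["sample_id"].to_numpy())
    env_out.to_csv(d / "environment.tsv", sep="\t", index=False)
    truth.to_json(d / "truth.json")
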