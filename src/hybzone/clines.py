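"""Genomic-cline inference: Bayesian alpha/beta estimation and logistic cline tests.

The genomic cline of a locus maps the genome-wide hybrid index h to the
probability that an allele at that locus descends from parent A:

    phi(h) = clamp(h + 2 h (1 - h) (alpha + beta (2 h - 1)), 0, 1)

alpha shifts the cline (directional introgression — positive means excess
parent-A ancestry), beta changes its steepness around the centre.  Given
phi, an allele is drawn with the corresponding parent's frequency, so the
dosage of an individual is Binomial(2, phi p_A + (1 - phi) p_B) (the two
alleles are independent ancestry draws).  Each locus gets an independent
random-walk Metropolis chain over (alpha, beta) with Normal(0, prior_sd^2)
priors; a locus is an outlier when the equal-tail probability interval
(ETPI) of its posterior excludes zero.  h is held fixed at its
point estimate during the MCMC — with thousands of loci informing h this
loses essentially nothing and keeps the modules decoupled.

A faster logistic-regression cline test (dosage ~ Binomial(2, logit) on h,
parametric and permutation p-values) serves as the frequentist cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._glm import fit_binomial_many
from .core import ParentalFreqs

__all__ = [
    "select_informative_loci",
    "McmcConfig",
    "BayesianGenomicClines",
    "LogisticClineTest",
    "logistic_cline_fit",
    "downsample_panels",
]

_Q_EPS = 1e-9


def select_informative_loci(parental: ParentalFreqs, min_differential: float = 0.6) -> np.ndarray:
    """Boolean mask of ancestry-informative loci (|p_A - p_B| >= threshold)."""
    return parental.differential >= min_differential


@dataclass
class McmcConfig:
    """Chain settings for the Bayesian clines model.

    Defaults mirror a standard production run (100,000 generations, 50,000
    burn-in, every 24th retained); tests and desk-scale analyses use
    shorter chains.  ``etpi_level`` is 0.95 by convention here, with 0.99
    available.
    """

    n_iterations: int = 100_000
    burn_in: int = 50_000
    thin: int = 24
    proposal_scale: float = 0.3
    prior_sd: float = 1.0
    etpi_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (self.burn_in < self.n_iterations):
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.etpi_level not in (0.95, 0.99):
            raise ValueError("etpi_level must be 0.95 or 0.99")


class BayesianGenomicClines(BaseEstimator):
    """Per-locus Bayesian genomic clines by random-walk Metropolis.

    ``fit(X, y, parental=...)`` with X the admixed individuals' dosage
    matrix (n x L, nan = missing), y their hybrid indexes, and ``parental``
    the pure-panel allele frequencies for the same L loci.  All loci run as
    independent chains, vectorized: one joint Gaussian proposal on
    (alpha_l, beta_l) per locus per generation, with per-locus proposal
    scales tuned during burn-in toward ~30% acceptance.

    Fitted attributes (length L, nan at excluded loci): ``alpha_mean_``,
    ``alpha_lo_``, ``alpha_hi_``, ``beta_mean_``, ``beta_lo_``,
    ``beta_hi_``, ``alpha_excess_`` / ``beta_excess_`` (``'+'``, ``'-'`` or
    ``'0'``), ``acceptance_rate_``, ``flagged_`` (acceptance outside
    [0.15, 0.6]), ``excluded_`` (monomorphic in both parents), and the
    retained samples ``samples_alpha_`` / ``samples_beta_``.
    """

    def __init__(self, config: McmcConfig | None = None, **overrides):
        self.config = config
        self.overrides = overrides

    def _config(self) -> McmcConfig:
        if self.config is not None and self.overrides:
            raise ValueError("pass either config or keyword overrides, not both")
        return self.config if self.config is not None else McmcConfig(**self.overrides)

    def fit(self, X, y, parental: ParentalFreqs):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        h = np.asarray(y, dtype=float)
        if X.shape[0] != h.shape[0]:
            raise ValueError("X rows must match hybrid-index length")
        if X.shape[1] != parental.n_loci:
            raise ValueError("parental frequencies must cover every locus in X")
        if np.all(h <= 0.0) or np.all(h >= 1.0):
            raise ValueError("no admixed individuals: genomic clines are unidentifiable")
        rng = np.random.default_rng(cfg.seed)
        n, L = X.shape

        pa, pb = parental.p_a, parental.p_b
        excluded = (pa == pb) & ((pa == 0.0) | (pa == 1.0))

        mask = (~np.isnan(X)).astype(float)
        A = np.nan_to_num(X, nan=0.0) * mask          # successes
        B = np.nan_to_num(2.0 - X, nan=0.0) * mask    # failures
        u = 2.0 * h * (1.0 - h)
        v = u * (2.0 * h - 1.0)
        hcol, ucol, vcol = h[:, None], u[:, None], v[:, None]

        def log_posterior(alpha, beta):
            p = np.clip(hcol + ucol * alpha[None, :] + vcol * beta[None, :], 0.0, 1.0)
            q = np.clip(p * pa[None, :] + (1.0 - p) * pb[None, :], _Q_EPS, 1.0 - _Q_EPS)
            ll = (A * np.log(q)).sum(axis=0) + (B * np.log1p(-q)).sum(axis=0)
            return ll - (alpha**2 + beta**2) / (2.0 * cfg.prior_sd**2)

        alpha = np.zeros(L)
        beta = np.zeros(L)
        lp = log_posterior(alpha, beta)
        scale = np.full(L, cfg.proposal_scale)
        adapt_every = 100
        adapt_accepts = np.zeros(L)
        post_accepts = np.zeros(L)
        n_post = 0
        samples_a, samples_b = [], []

        for it in range(1, cfg.n_iterations + 1):
            prop_a = alpha + scale * rng.standard_normal(L)
            prop_b = beta + scale * rng.standard_normal(L)
            lp_prop = log_posterior(prop_a, prop_b)
            accept = np.log(rng.random(L)) < (lp_prop - lp)
            alpha = np.where(accept, prop_a, alpha)
            beta = np.where(accept, prop_b, beta)
            lp = np.where(accept, lp_prop, lp)
            if it <= cfg.burn_in:
                adapt_accepts += accept
                if it % adapt_every == 0:
                    rate = adapt_accepts / adapt_every
                    scale = np.clip(scale * np.exp(0.8 * (rate - 0.3)), 1e-3, 5.0)
                    adapt_accepts[:] = 0.0
            else:
                post_accepts += accept
                n_post += 1
                if (it - cfg.burn_in) % cfg.thin == 0:
                    samples_a.append(alpha.copy())
                    samples_b.append(beta.copy())

        SA = np.array(samples_a)  # (n_samples, L)
        SB = np.array(samples_b)
        lo_q, hi_q = (1.0 - cfg.etpi_level) / 2.0, 1.0 - (1.0 - cfg.etpi_level) / 2.0

        def summarize(S):
            return S.mean(axis=0), np.quantile(S, lo_q, axis=0), np.quantile(S, hi_q, axis=0)

        self.alpha_mean_, self.alpha_lo_, self.alpha_hi_ = summarize(SA)
        self.beta_mean_, self.beta_lo_, self.beta_hi_ = summarize(SB)
        for attr in ("alpha_mean_", "alpha_lo_", "alpha_hi_", "beta_mean_", "beta_lo_", "beta_hi_"):
            getattr(self, attr)[excluded] = np.nan
        self.alpha_excess_ = _excess_flags(self.alpha_lo_, self.alpha_hi_)
        self.beta_excess_ = _excess_flags(self.beta_lo_, self.beta_hi_)
        self.acceptance_rate_ = post_accepts / max(n_post, 1)
        self.flagged_ = (self.acceptance_rate_ < 0.15) | (self.acceptance_rate_ > 0.6)
        self.excluded_ = excluded
        self.samples_alpha_ = SA
        self.samples_beta_ = SB
        self.differential_ = parental.differential
        self.etpi_level_ = cfg.etpi_level
        return self

    def to_frame(self, loci: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "alpha_mean": self.alpha_mean_,
                "alpha_lo": self.alpha_lo_,
                "alpha_hi": self.alpha_hi_,
                "beta_mean": self.beta_mean_,
                "beta_lo": self.beta_lo_,
                "beta_hi": self.beta_hi_,
                "alpha_excess": self.alpha_excess_,
                "beta_excess": self.beta_excess_,
                "acceptance": self.acceptance_rate_,
                "differential": self.differential_,
            }
        )
        if loci is not None:
            out = pd.concat([loci[["scaffold", "pos"]].reset_index(drop=True), out], axis=1)
        return out


def _excess_flags(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    flags = np.full(lo.shape, "0", dtype=object)
    flags[lo > 0.0] = "+"
    flags[hi < 0.0] = "-"
    flags[~np.isfinite(lo)] = "0"
    return flags


class LogisticClineTest(BaseEstimator):
    """Logistic-regression cline test with parametric and permutation p-values.

    Per locus, dosage ~ Binomial(2, logit^-1(a + b h)) is compared against
    one of two nulls.  ``null='intercept'`` tests for any dependence of
    dosage on the hybrid index (df = 1); it is the cheap screen but at
    ancestry-informative loci it mostly measures informativeness.
    ``null='neutral'`` tests the fitted logistic cline against the
    genome-average expectation q = h p_A + (1 - h) p_B with no free
    parameters (df = 2, requires ``parental=`` at fit time); its statistic
    grows with the cline distortion itself, which is what makes it agree
    with the Bayesian alpha estimates.  Permutation p-values shuffle h
    across individuals and count shuffles with an LRT at least as large
    (add-one corrected).
    """

    def __init__(
        self,
        n_permutations: int = 199,
        null: str = "intercept",
        ridge: float = 1e-6,
        seed: int = 0,
    ):
        self.n_permutations = n_permutations
        self.null = null
        self.ridge = ridge
        self.seed = seed

    def _null_loglik(self, yy, mask, h, ones, parental):
        if self.null == "intercept":
            _, ll0, _ = fit_binomial_many(yy, ones[:, None], mask, ridge=self.ridge)
            return ll0
        if self.null == "neutral":
            q0 = np.clip(
                h[:, None] * parental.p_a + (1.0 - h[:, None]) * parental.p_b,
                _Q_EPS,
                1.0 - _Q_EPS,
            ).T
            return ((yy * np.log(q0) + (2.0 - yy) * np.log1p(-q0)) * mask).sum(axis=1)
        raise ValueError("null must be 'intercept' or 'neutral'")

    def fit(self, X, y, parental: ParentalFreqs | None = None):
        if self.null == "neutral" and parental is None:
            raise ValueError("null='neutral' requires parental frequencies")
        X = np.asarray(X, dtype=float)
        h = np.asarray(y, dtype=float)
        n = X.shape[0]
        dosage = X.T
        mask = (~np.isnan(dosage)).astype(float)
        yy = np.nan_to_num(dosage, nan=0.0)
        ones = np.ones(n)
        _, ll1, conv = fit_binomial_many(
            yy, np.column_stack([ones, h]), mask, ridge=self.ridge
        )
        ll0 = self._null_loglik(yy, mask, h, ones, parental)
        self.df_ = 1 if self.null == "intercept" else 2
        self.lrt_ = np.clip(2.0 * (ll1 - ll0), 0.0, None)
        from scipy import stats as _stats

        self.p_parametric_ = np.where(conv, _stats.chi2.sf(self.lrt_, self.df_), np.nan)
        self.converged_ = conv
        rng = np.random.default_rng(self.seed)
        exceed = np.zeros(X.shape[1])
        for _ in range(self.n_permutations):
            hp = rng.permutation(h)
            _, ll1p, _ = fit_binomial_many(
                yy, np.column_stack([ones, hp]), mask, ridge=self.ridge
            )
            ll0p = self._null_loglik(yy, mask, hp, ones, parental)
            exceed += np.clip(2.0 * (ll1p - ll0p), 0.0, None) >= self.lrt_
        self.p_permutation_ = (1.0 + exceed) / (self.n_permutations + 1.0)
        return self


def logistic_cline_fit(
    X, h, n_permutations: int = 199, seed: int = 0, null: str = "intercept", parental=None
) -> pd.DataFrame:
    """Per-locus parametric and permutation cline p-values as a DataFrame."""
    fitted = LogisticClineTest(n_permutations=n_permutations, seed=seed, null=null).fit(
        X, h, parental=parental
    )
    return pd.DataFrame(
        {
            "lrt": fitted.lrt_,
            "p_parametric": fitted.p_parametric_,
            "p_permutation": fitted.p_permutation_,
            "converged": fitted.converged_,
        }
    )


def downsample_panels(
    frame: pd.DataFrame,
    target_counts: dict,
    exclusion_regions=None,
    seed: int = 0,
    panel_column: str = "panel",
    region_column: str = "location",
) -> pd.DataFrame:
    """Random subset matching target per-panel counts, exclusion regions first.

    ``target_counts`` maps panel labels (e.g. pureA/pureB/admixed) to the
    number to keep.  Individuals whose ``region_column`` value is in
    ``exclusion_regions`` are removed preferentially, emulating
    downsampling designs that first drop samples near a comparison
    transect.  Raises if a target exceeds availability.
    """
    rng = np.random.default_rng(seed)
    exclusion = set(exclusion_regions or ())
    keep_idx: list[int] = []
    for panel, target in target_counts.items():
        members = frame.index[frame[panel_column] == panel].to_numpy()
        if target > len(members):
            raise ValueError(
                f"target {target} for panel {panel!r} exceeds available {len(members)}"
            )
        n_remove = len(members) - target
        in_excl = np.array([frame.loc[i, region_column] in exclusion for i in members])
        first = rng.permutation(members[in_excl])
        second = rng.permutation(members[~in_excl])
        removal_order = np.concatenate([first, second])
        removed = set(removal_order[:n_remove].tolist())
        keep_idx.extend(i for i in members if i not in removed)
    return frame.loc[sorted(keep_idx)].copy()
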