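"""Hybrid-index estimation, ancestry classification, PCA, and VanRaden kinship.

The hybrid index h of an individual is the proportion of its genome assigned
to the parent-A pool.  It is estimated by maximum likelihood against
parental allele-frequency panels: given panel frequencies p_A and p_B, the
expected allele frequency in an individual with index h is
q_l(h) = h p_{A,l} + (1 - h) p_{B,l}, and the dosage likelihood is
Binomial(2, q_l(h)) per locus.  The log-likelihood is unimodal in h, so a
bounded golden-section search (plus a short Newton polish) finds the
maximum.  With pure reference panels at K = 2 this estimate tracks
admixture coefficients from model-based clustering very closely.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .core import ParentalFreqs
from .io_anchor import GenotypeMatrix

__all__ = [
    "HybridIndexEstimator",
    "estimate_hybrid_index",
    "classify_ancestry",
    "define_parental_panels",
    "pca",
    "vanraden_kinship",
    "ANCESTRY_CATEGORIES",
]

#: Ancestry categories partition [0, 1] with q = parent-A genome proportion:
#: parentA_pure       q >= 0.95
#: parentA_dominant   0.60 <= q < 0.95
#: balanced           0.40 < q < 0.60
#: parentB_dominant   0.05 <= q <= 0.40
#: parentB_pure       q < 0.05
ANCESTRY_CATEGORIES = (
    "parentB_pure",
    "parentB_dominant",
    "balanced",
    "parentA_dominant",
    "parentA_pure",
)

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _loglik(h: np.ndarray, dosage: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Vectorized log-likelihood of h (one value per row of ``dosage``)."""
    q = h[:, None] * pa[None, :] + (1.0 - h[:, None]) * pb[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ll = dosage * np.log(q) + (2.0 - dosage) * np.log1p(-q)
    return np.nansum(ll, axis=1)


class HybridIndexEstimator(BaseEstimator):
    """Maximum-likelihood hybrid index against parental frequency panels.

    Fit from reference individuals (``fit(X, y)`` with y = 1 for pool A,
    0 for pool B) or from known frequencies (``parental`` in the
    constructor, then ``fit()`` with no data).  ``predict(X)`` returns h in
    [0, 1] per row of X, ``nan`` for individuals with fewer than
    ``min_loci`` usable loci.

    Parameters
    ----------
    parental : ParentalFreqs, optional
        Pre-computed panel frequencies; bypasses learning them from X, y.
    min_loci : int
        Minimum loci with a called genotype and defined panel frequencies.
    tol : float
        Golden-section bracket tolerance on h.
    freq_clamp : float
        Panel frequencies are clamped to [freq_clamp, 1 - freq_clamp] to
        avoid infinite log-likelihoods at fixed loci.
    """

    def __init__(self, parental=None, min_loci=50, tol=1e-6, freq_clamp=1e-4):
        self.parental = parental
        self.min_loci = min_loci
        self.tol = tol
        self.freq_clamp = freq_clamp

    def fit(self, X=None, y=None):
        if self.parental is not None:
            pa, pb = self.parental.p_a, self.parental.p_b
        else:
            if X is None or y is None:
                raise ValueError("either parental= or (X, y) reference data is required")
            X = np.asarray(X, dtype=float)
            y = np.asarray(y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pa = np.nanmean(X[y == 1], axis=0) / 2.0
                pb = np.nanmean(X[y == 0], axis=0) / 2.0
        c = self.freq_clamp
        self.p_a_ = np.clip(pa, c, 1.0 - c)
        self.p_b_ = np.clip(pb, c, 1.0 - c)
        self.n_features_in_ = self.p_a_.shape[0]
        return self

    def _check_usable(self, X):
        defined = np.isfinite(self.p_a_) & np.isfinite(self.p_b_)
        usable = (~np.isnan(X)) & defined[None, :]
        return usable.sum(axis=1)

    def predict(self, X) -> np.ndarray:
        return self.predict_table(X)["h"].to_numpy()

    def predict_table(self, X) -> pd.DataFrame:
        """h, log-likelihood at the optimum, and loci used, per individual."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "p_a_")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        pa, pb = self.p_a_, self.p_b_

        # vectorized golden-section maximization on [0, 1], one bracket per row
        a = np.zeros(n)
        b = np.ones(n)
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc = _loglik(c, X, pa, pb)
        fd = _loglik(d, X, pa, pb)
        while (b - a).max() > self.tol:
            left = fc > fd
            b = np.where(left, d, b)
            a = np.where(left, a, c)
            d_new = np.where(left, c, a + _INVPHI * (b - a))
            c_new = np.where(left, b - _INVPHI * (b - a), d)
            f_at = _loglik(np.where(left, c_new, d_new), X, pa, pb)
            fc, fd = np.where(left, f_at, fd), np.where(left, fc, f_at)
            c, d = c_new, d_new
        h = 0.5 * (a + b)

        # Newton polish: the likelihood is smooth and unimodal, so a few
        # safeguarded steps sharpen the golden-section bracket to machine
        # precision (and land symmetric cases such as a single heterozygote
        # with p_A=1, p_B=0 on h = 1/2 exactly).
        diff = (pa - pb)[None, :]
        f_cur = _loglik(h, X, pa, pb)
        for _ in range(8):
            q = h[:, None] * pa[None, :] + (1.0 - h[:, None]) * pb[None, :]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                g1 = np.nansum((X / q - (2.0 - X) / (1.0 - q)) * diff, axis=1)
                g2 = np.nansum((-X / q**2 - (2.0 - X) / (1.0 - q) ** 2) * diff**2, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(g2 < 0, -g1 / g2, 0.0)
            h_new = np.clip(h + step, 0.0, 1.0)
            f_new = _loglik(h_new, X, pa, pb)
            improve = f_new >= f_cur
            h = np.where(improve, h_new, h)
            f_cur = np.where(improve, f_new, f_cur)

        n_used = self._check_usable(X)
        bad = n_used < self.min_loci
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} individual(s) with < {self.min_loci} usable loci; "
                "hybrid index reported missing",
                stacklevel=2,
            )
        h = np.where(bad, np.nan, h)
        f_cur = np.where(bad, np.nan, f_cur)
        return pd.DataFrame({"h": h, "loglik": f_cur, "n_loci": n_used})


def estimate_hybrid_index(
    matrix: GenotypeMatrix, parental: ParentalFreqs, **kwargs
) -> pd.DataFrame:
    """Per-individual hybrid index table (sample_id, h, loglik, n_loci)."""
    est = HybridIndexEstimator(parental=parental, **kwargs).fit()
    out = est.predict_table(matrix.dosage)
    out.insert(0, "sample_id", matrix.samples)
    return out


def classify_ancestry(h) -> np.ndarray:
    """Ancestry category from the hybrid index (see ANCESTRY_CATEGORIES).

    The five intervals partition [0, 1] exactly; values outside raise.
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    if np.isnan(h).any() or ((h < 0) | (h > 1)).any():
        raise ValueError("hybrid index must lie in [0, 1]")
    out = np.empty(h.shape, dtype=object)
    out[h < 0.05] = "parentB_pure"
    out[(h >= 0.05) & (h <= 0.40)] = "parentB_dominant"
    out[(h > 0.40) & (h < 0.60)] = "balanced"
    out[(h >= 0.60) & (h < 0.95)] = "parentA_dominant"
    out[h >= 0.95] = "parentA_pure"
    return out


def define_parental_panels(
    h, matrix: GenotypeMatrix | None = None, threshold: float = 0.95
) -> tuple[np.ndarray, ParentalFreqs | None]:
    """Partition individuals into pure-A / pure-B / admixed by hybrid index.

    Pure A: h >= threshold; pure B: h <= 1 - threshold; everything in
    between is admixed.  When ``matrix`` is given, panel allele frequencies
    are recomputed from the pure sets and returned as a
    :class:`ParentalFreqs` (``None`` otherwise).
    """
    h = np.asarray(h, dtype=float)
    labels = np.where(
        h >= threshold, "pureA", np.where(h <= 1.0 - threshold, "pureB", "admixed")
    )
    for panel in ("pureA", "pureB"):
        n = int((labels == panel).sum())
        if 0 < n < 10:
            warnings.warn(
                f"{panel} panel has only {n} individuals; cline estimates will be noisy",
                stacklevel=2,
            )
    freqs = None
    if matrix is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pa = np.nanmean(matrix.dosage[labels == "pureA"], axis=0) / 2.0
            pb = np.nanmean(matrix.dosage[labels == "pureB"], axis=0) / 2.0
        freqs = ParentalFreqs(np.nan_to_num(pa, nan=0.5), np.nan_to_num(pb, nan=0.5))
    return labels, freqs


def pca(matrix: GenotypeMatrix, n_components: int = 2):
    """Genotype PCA on mean-imputed, centered (unscaled) dosages.

    Returns ``(scores, explained_variance_ratio)``.
    """
    if n_components > matrix.n_individuals:
        raise ValueError("n_components cannot exceed the number of individuals")
    X = matrix.dosage.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X - col_mean)
    return scores, model.explained_variance_ratio_


def vanraden_kinship(matrix: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix G = Z Z' / (2 sum p(1-p)).

    Z is the dosage matrix centered at 2p (p = sample ALT frequency per
    locus); missing dosages are imputed at 2p (contributing zero).  Loci
    fixed in the sample are excluded.  Diagonal entries average about
    1 + f (about 1 for outbred samples); an entry near 0.25 between two
    individuals indicates a half-sib-level relationship.
    """
    p = matrix.allele_freq()
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("all loci monomorphic; kinship undefined")
    X = matrix.dosage[:, keep]
    p = p[keep]
    Z = X - 2.0 * p[None, :]
    Z[np.isnan(Z)] = 0.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = Z @ Z.T / denom
    return (G + G.T) / 2.0
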