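"""Per-gene expression-variability filter for tumor sample panels.

Flags genes whose expression varies strongly across samples of a tumor
panel: a gene passes when (a) its largest absolute per-sample log2
deviation from its across-sample mean exceeds a log-ratio cutoff and (b) a
variance test against the pooled background is significant.  Thresholds
default to log-ratio > 1.2 and p < 0.01, reported raw (no multiple-testing
correction).

The variance test compares each gene's sample variance with a robust
(trimmed-mean) estimate of the background variance pooled over all genes:
under the null ``(n-1) s_i^2 / sigma_0^2`` is ~ chi-square with ``n-1``
degrees of freedom.  An alternative one-sample t variant on the absolute
deviations is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["VariabilityResult", "variability_filter"]


@dataclass
class VariabilityResult:
    """Per-gene outcome of the variability filter (arrays over genes)."""

    logratio_stat: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    flagged: np.ndarray
    logratio_thresh: float
    p_thresh: float
    background_sd: float

    @property
    def flagged_genes(self) -> np.ndarray:
        return np.flatnonzero(self.flagged)


def variability_filter(
    expr: np.ndarray,
    logratio_thresh: float = 1.2,
    p_thresh: float = 0.01,
    method: str = "variance",
) -> VariabilityResult:
    """Flag highly variable genes in a (genes x samples) log2 matrix.

    method='variance' (default): chi-square test of each gene's variance
    against the 20%-trimmed-mean background variance; the reported
    t_statistic is the standardized variance excess.  method='abs_t':
    one-sample t of the gene's absolute deviations against the background
    mean absolute deviation.

    Constant genes get p = 1 and are never flagged.  Flagging requires both
    ``logratio_stat > logratio_thresh`` and ``p < p_thresh``.
    """
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2:
        raise ValueError("expression matrix must be 2-D (genes x samples)")
    n_genes, n = X.shape
    if n < 3:
        raise ValueError("need at least three samples per gene")
    dev = X - X.mean(axis=1, keepdims=True)
    logratio = np.max(np.abs(dev), axis=1)
    s2 = np.sum(dev**2, axis=1) / (n - 1)
    sigma0_sq = float(stats.trim_mean(s2, 0.2))
    if sigma0_sq <= 0:
        # an (almost) all-constant matrix: nothing can be called variable
        p = np.ones(n_genes)
        t = np.zeros(n_genes)
        flagged = np.zeros(n_genes, dtype=bool)
        return VariabilityResult(
            logratio, t, p, flagged, logratio_thresh, p_thresh, 0.0
        )

    if method == "variance":
        chi2 = (n - 1) * s2 / sigma0_sq
        p = stats.chi2.sf(chi2, df=n - 1)
        t = (s2 - sigma0_sq) / (sigma0_sq * np.sqrt(2.0 / (n - 1)))
    elif method == "abs_t":
        absdev = np.abs(dev)
        mu0 = float(stats.trim_mean(absdev.mean(axis=1), 0.2))
        sd = absdev.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (absdev.mean(axis=1) - mu0) / (sd / np.sqrt(n))
        t = np.where(np.isfinite(t), t, 0.0)
        p = stats.t.sf(t, df=n - 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    constant = s2 <= 1e-15
    p = np.where(constant, 1.0, p)
    flagged = (logratio > logratio_thresh) & (p < p_thresh)
    return VariabilityResult(
        logratio_stat=logratio,
        t_statistic=t,
        p_value=p,
        flagged=flagged,
        logratio_thresh=logratio_thresh,
        p_thresh=p_thresh,
        background_sd=float(np.sqrt(sigma0_sq)),
    )
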