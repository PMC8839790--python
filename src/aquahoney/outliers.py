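"""PCA-based outlier screening (Hotelling T-squared + Q residuals).

A SIMCA-style screen: fit a mean-centred PCA, compute per spectrum the
Hotelling T-squared statistic on the retained scores (leverage within the
model plane) and the Q statistic (squared reconstruction residual,
distance from the model plane). A spectrum is flagged when either exceeds
its confidence limit: an F-distribution limit for T-squared and Box's
chi-square approximation for Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DimensionError
from .spectra import SpectraSet

__all__ = ["OutlierReport", "detect_outliers"]

#: confidence level used for both limits unless overridden
DEFAULT_ALPHA = 0.999
#: explained-variance target used to pick the PCA rank automatically
AUTO_EV_TARGET = 0.95
#: hard cap on the automatically chosen PCA rank
AUTO_MAX_PCS = 10


@dataclass(frozen=True)
class OutlierReport:
    """Per-spectrum screening statistics and the keep/flag decision."""

    keep_mask: np.ndarray
    t2: np.ndarray
    q: np.ndarray
    limits: tuple[float, float]
    n_pcs: int
    alpha: float

    @property
    def n_flagged(self) -> int:
        return int((~self.keep_mask).sum())

    def to_frame(self, s: SpectraSet | None = None) -> pd.DataFrame:
        """Tidy per-spectrum table; metadata columns included when the
        originating SpectraSet is given."""
        df = pd.DataFrame(
            {"t2": self.t2, "q": self.q, "keep": self.keep_mask}
        )
        if s is not None:
            df = pd.concat([s.meta.reset_index(drop=True), df], axis=1)
        return df


def _auto_n_pcs(eigvals: np.ndarray) -> int:
    ratio = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(ratio, AUTO_EV_TARGET) + 1)
    return max(1, min(k, AUTO_MAX_PCS, eigvals.size))


def detect_outliers(
    s: SpectraSet, n_pcs: int | None = None, alpha: float = DEFAULT_ALPHA
) -> OutlierReport:
    """Screen a SpectraSet for outlying spectra.

    Parameters
    ----------
    n_pcs
        PCA rank of the in-model subspace. ``None`` picks the smallest rank
        explaining 95% of variance, capped at 10.
    alpha
        Confidence level of both limits; as ``alpha -> 1`` the limits
        diverge and nothing is flagged.
    """
    X = s.absorbance
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    # economy SVD; eigenvalues of the covariance are s^2/(n-1)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = sv**2 / max(n - 1, 1)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size and sv[0] > 0 else 0
    if n_pcs is None:
        n_pcs = _auto_n_pcs(eigvals[:rank] if rank else eigvals[:1])
    if not 1 <= n_pcs < n:
        raise DimensionError(f"need 1 <= n_pcs < n_spectra, got n_pcs={n_pcs}, n={n}")
    k = min(n_pcs, rank) if rank else n_pcs

    scores = Xc @ Vt[:k].T
    lam = np.maximum(eigvals[:k], 1e-30)
    t2 = np.sum(scores**2 / lam, axis=1)
    if n > k + 1:
        f_crit = stats.f.ppf(alpha, k, n - k)
        t2_limit = k * (n - 1) * (n + 1) / (n * (n - k)) * f_crit
    else:
        t2_limit = np.inf

    resid = Xc - scores @ Vt[:k]
    q = np.sum(resid**2, axis=1)
    # Box's approximation: Q ~ g * chi2(h) with moments from the residual spectrum
    theta1 = eigvals[k:rank].sum() * (n - 1) / max(n - 1, 1)
    theta2 = (eigvals[k:rank] ** 2).sum()
    if theta1 > 1e-12 and theta2 > 0:
        g = theta2 / theta1
        h = theta1**2 / theta2
        q_limit = g * stats.chi2.ppf(alpha, h)
    else:
        q_limit = np.inf

    keep = (t2 <= t2_limit) & (q <= q_limit)
    return OutlierReport(
        keep_mask=keep,
        t2=t2,
        q=q,
        limits=(float(t2_limit), float(q_limit)),
        n_pcs=k,
        alpha=alpha,
    )
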