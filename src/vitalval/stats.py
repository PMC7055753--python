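"""Agreement statistics on comparison pairs.

All statistics operate on the signed per-pair difference
d = investigational - reference.  The headline quantities are the mean
absolute difference (MAD) with the sample SD of |d|, the root mean square
error (RMSE), the mean absolute percent difference, Bland-Altman bias and
limits of agreement, and a normality-gated correlation: Shapiro-Wilk on the
residuals of an ordinary least-squares fit of investigational on reference
decides between Pearson (residuals consistent with normal) and Spearman.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import EmptyInputError
from .vitals import Vital

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class AbsoluteDifferenceSummary:
    mad: float
    sd: float | None  # None when n == 1 (sample SD undefined)
    n: int


@dataclass(frozen=True)
class PercentDifferenceSummary:
    mean: float  # mean of 100*|d|/reference, in %
    sd: float | None
    n: int


@dataclass(frozen=True)
class BlandAltman:
    mean_signed_diff: float
    loa_low: float | None
    loa_high: float | None
    sd_used: float | None
    means: np.ndarray  # per-pair (investigational + reference) / 2
    diffs: np.ndarray  # per-pair signed difference
    absolute_sd_variant: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float | None
    method: str | None  # "pearson" | "spearman"
    p_value: float | None
    normality_p: float | None
    n: int
    reason: str | None = None  # set when the coefficient is undefined

    @property
    def defined(self) -> bool:
        return self.coefficient is not None


@dataclass
class AccuracySummary:
    """Per device x vital agreement summary."""

    device: str
    vital: Vital
    n_pairs: int
    mean_signed_diff: float
    mad: float
    sd_abs_diff: float | None
    mean_abs_pct_diff: float | None
    sd_abs_pct_diff: float | None
    rmse: float
    loa_low: float | None
    loa_high: float | None


def _diffs(diffs) -> np.ndarray:
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise EmptyInputError("no comparison pairs")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite difference encountered")
    return d


def absolute_difference_summary(diffs) -> AbsoluteDifferenceSummary:
    """Mean and sample SD (n-1 denominator) of |d|."""
    d = np.abs(_diffs(diffs))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else None
    return AbsoluteDifferenceSummary(mad=float(d.mean()), sd=sd, n=int(d.size))


def percent_difference_summary(diffs, references) -> PercentDifferenceSummary:
    """Mean and sample SD of the per-pair absolute percent difference."""
    d = _diffs(diffs)
    ref = np.asarray(references, dtype=float)
    if ref.shape != d.shape:
        raise ValueError("diffs and references must have the same length")
    if np.any(ref <= 0):
        raise ValueError("reference values must be > 0 for percent differences")
    pct = 100.0 * np.abs(d) / ref
    sd = float(np.std(pct, ddof=1)) if pct.size > 1 else None
    return PercentDifferenceSummary(mean=float(pct.mean()), sd=sd, n=int(pct.size))


def rmse(diffs) -> float:
    """Root mean square of the signed differences."""
    d = _diffs(diffs)
    return float(np.sqrt(np.mean(d * d)))


def bland_altman(investigational, reference, absolute_sd: bool = False) -> BlandAltman:
    """Bland-Altman bias and 1.96-SD limits of agreement.

    By default the limits use the SD of the signed differences (standard
    Bland-Altman).  ``absolute_sd=True`` selects the variant where the SD of
    the absolute differences is used instead; the bias line is the mean
    signed difference in both variants.
    """
    inv = np.asarray(investigational, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if inv.shape != ref.shape:
        raise ValueError("investigational and reference must have the same length")
    d = _diffs(inv - ref)
    mean_d = float(d.mean())
    if d.size < 2:
        return BlandAltman(mean_d, None, None, None, 0.5 * (inv + ref), d, absolute_sd)
    sd = float(np.std(np.abs(d) if absolute_sd else d, ddof=1))
    return BlandAltman(
        mean_signed_diff=mean_d,
        loa_low=mean_d - 1.96 * sd,
        loa_high=mean_d + 1.96 * sd,
        sd_used=sd,
        means=0.5 * (inv + ref),
        diffs=d,
        absolute_sd_variant=absolute_sd,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_coefficient(x, y) -> float:
    """Spearman rho: Pearson correlation of midranks."""
    rx, ry = _midranks(np.asarray(x, float)), _midranks(np.asarray(y, float))
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0:
        return float("nan")
    return float(rxc @ ryc) / denom


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n).

    Enumerates all n! pairings of the y-ranks against the x-ranks and counts
    those with |rho| >= |rho_obs| (to within floating tolerance).
    """
    rx = _midranks(x)
    ry = _midranks(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    perms = np.array(list(itertools.permutations(range(len(y)))))
    rhos = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


#: Sample sizes at or below which the Spearman p-value is exact.
EXACT_SPEARMAN_N = 9


def _gated_correlation(x, y, alpha: float = 0.05) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = int(x.size)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if n < 4:
        raise ValueError(f"need at least 4 pairs for correlation, got {n}")
    sx, sy = float(np.std(x)), float(np.std(y))
    scale = max(1.0, float(np.max(np.abs(x))), float(np.max(np.abs(y))))
    if sx <= _DEGENERATE_TOL * scale or sy <= _DEGENERATE_TOL * scale:
        which = "x" if sx <= _DEGENERATE_TOL * scale else "y"
        return CorrelationResult(
            None, None, None, None, n, reason=f"zero variance in {which} margin"
        )

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if float(np.std(resid)) <= _DEGENERATE_TOL * scale:
        # Perfect linear fit: normality of residuals is untestable; the
        # correlation is +/-1 under either method.
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(float(r), "pearson", float(p), None, n)
    normality_p = float(sps.shapiro(resid).pvalue)
    if normality_p >= alpha:
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(float(r), "pearson", float(p), normality_p, n)
    rho = spearman_coefficient(x, y)
    if math.isnan(rho):
        return CorrelationResult(
            None, None, None, normality_p, n, reason="constant ranks"
        )
    if n <= EXACT_SPEARMAN_N:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(float(rho), "spearman", p, normality_p, n)


def correlation(investigational, reference, alpha: float = 0.05) -> CorrelationResult:
    """Normality-gated correlation between device and reference readings.

    Shapiro-Wilk is applied to the residuals of the OLS fit of
    investigational on reference; residuals consistent with normality
    (p >= alpha) select Pearson, otherwise Spearman.  Spearman p-values use
    exact permutation enumeration for n <= 9 and the large-sample
    approximation above that.
    """
    return _gated_correlation(reference, investigational, alpha)


def signed_diff_vs_reference(investigational, reference, alpha: float = 0.05) -> CorrelationResult:
    """Proportional-bias check: correlation of d with the reference value.

    A negative coefficient means low values are read high and high values
    read low (slope-below-one behaviour on the scatter).
    """
    inv = np.asarray(investigational, dtype=float)
    ref = np.asarray(reference, dtype=float)
    return _gated_correlation(ref, inv - ref, alpha)


def summarize_pairs(
    device: str,
    vital: Vital,
    investigational,
    reference,
    absolute_sd_loa: bool = False,
) -> AccuracySummary:
    """Full per-device-vital accuracy summary from paired readings."""
    inv = np.asarray(investigational, dtype=float)
    ref = np.asarray(reference, dtype=float)
    d = _diffs(inv - ref)
    abs_sum = absolute_difference_summary(d)
    try:
        pct = percent_difference_summary(d, ref)
        pct_mean, pct_sd = pct.mean, pct.sd
    except ValueError:
        pct_mean, pct_sd = None, None
    ba = bland_altman(inv, ref, absolute_sd=absolute_sd_loa)
    return AccuracySummary(
        device=device,
        vital=Vital(vital),
        n_pairs=abs_sum.n,
        mean_signed_diff=float(d.mean()),
        mad=abs_sum.mad,
        sd_abs_diff=abs_sum.sd,
        mean_abs_pct_diff=pct_mean,
        sd_abs_pct_diff=pct_sd,
        rmse=rmse(d),
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
    )
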