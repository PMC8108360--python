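"""MA-plot comparability check between two ChIP samples.

Following the MAnorm idea, peak signals common to both samples are placed on
the (A, M) plane — M = log2(a/b), A = 0.5*log2(a*b) after a pseudocount — and
a robust (Theil-Sen) line M = intercept + slope*A is fitted.  When the line is
close to M = 0 the two samples are directly comparable and no rescaling is
applied, mirroring the usual decision that "the regression lines are very
similar"; otherwise sample b's track can be rescaled so the refitted line is
flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import SignalTrack

__all__ = ["MAFit", "ma_transform", "fit_ma", "apply_rescale"]

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_SLOPE_TOL = 0.1
DEFAULT_INTERCEPT_TOL = 0.25


@dataclass(frozen=True)
class MAFit:
    """Robust line M = intercept + slope * (A - a_center).

    The line is anchored at ``a_center`` (the median A of the common peaks)
    rather than at A = 0: the intercept then measures the log2 offset at a
    typical intensity instead of an extrapolation far below the data, and
    for a pure global scaling (slope = 0) it equals the classic intercept,
    log2 of the scale factor.
    """

    slope: float
    intercept: float  # log2 units, at A = a_center
    n_common: int
    rescale_needed: bool
    a_center: float = 0.0

    def __post_init__(self) -> None:
        if self.n_common < 2:
            raise ValueError("an MA fit requires at least 2 common peaks")


def ma_transform(
    signal_a: float | np.ndarray,
    signal_b: float | np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """M = log2(a/b), A = 0.5*log2(a*b), after adding a pseudocount.

    Accepts scalars or arrays; returns (M, A) as arrays of the same shape.
    """
    a = np.asarray(signal_a, dtype=float) + pseudocount
    b = np.asarray(signal_b, dtype=float) + pseudocount
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("signals must be positive after pseudocount addition")
    m = np.log2(a) - np.log2(b)
    av = 0.5 * (np.log2(a) + np.log2(b))
    return m, av


def fit_ma(
    common_peaks: Sequence[tuple[float, float]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    slope_tol: float = DEFAULT_SLOPE_TOL,
    intercept_tol: float = DEFAULT_INTERCEPT_TOL,
    trim_m: float | None = None,
) -> MAFit:
    """Theil-Sen fit of M on A over paired (signal_a, signal_b) common peaks.

    ``rescale_needed`` is true when |slope| > slope_tol or
    |intercept| > intercept_tol (log2 units).

    ``trim_m``, when given, drops peaks whose M deviates from the median M by
    more than that many log2 units before fitting.  A global scaling shifts
    every M equally and is unaffected; genuinely differential peaks — which
    carry biology, not scaling — are excluded, keeping the comparability
    check anchored on unchanged common peaks even when the differential
    fraction exceeds the pairwise-estimator breakdown point.
    """
    pairs = np.asarray(common_peaks, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least 2 common peaks as (a, b) pairs")
    m, a = ma_transform(pairs[:, 0], pairs[:, 1], pseudocount=pseudocount)
    n_common = pairs.shape[0]
    if trim_m is not None:
        keep = np.abs(m - np.median(m)) <= trim_m
        if keep.sum() >= 2:
            m, a = m[keep], a[keep]
    a_center = float(np.median(a))
    if np.allclose(a, a[0]):
        # degenerate abscissa: slope undefined, take the median offset
        slope, intercept = 0.0, float(np.median(m))
    else:
        slope, intercept, _, _ = stats.theilslopes(m, a - a_center)
    rescale = abs(slope) > slope_tol or abs(intercept) > intercept_tol
    return MAFit(
        slope=float(slope),
        intercept=float(intercept),
        n_common=n_common,
        rescale_needed=bool(rescale),
        a_center=a_center,
    )


def apply_rescale(
    track: SignalTrack,
    fit: MAFit,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SignalTrack:
    """Rescale sample b's track so the refitted MA line is (approximately) flat.

    Each bin value v becomes v * 2^(intercept + slope * A(v)), where
    A(v) = log2(v + pseudocount) stands in for the bin's mean log intensity
    (exact for a pure global scaling, where slope = 0 and the correction is
    the constant factor 2^intercept).  When ``rescale_needed`` is false the
    input track is returned unchanged.
    """
    if not fit.rescale_needed:
        return track
    out = track.copy()
    for chrom, arr in out.values.items():
        a_self = np.log2(arr + pseudocount)
        factor = np.exp2(fit.intercept + fit.slope * (a_self - fit.a_center))
        out.values[chrom] = np.maximum(arr * factor, 0.0)
    return out
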