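"""Downstream assay quantification math.

Percent non-productive splicing from densitometry band intensities,
relative qPCR quantification (delta-delta-Ct with 2^-ddCt fold change),
quadratic standard-curve interpolation for electrochemiluminescence
(MSD-style) protein assays, and the abundance-versus-upregulation
ordinary least-squares fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation_db import DataError


@dataclass
class DensitometryPair:
    """Background-subtracted band intensities (non-productive, productive)."""

    np_intensity: float
    p_intensity: float

    def __post_init__(self) -> None:
        if self.np_intensity < 0 or self.p_intensity < 0:
            raise DataError("band intensities must be non-negative")
        if self.np_intensity == 0 and self.p_intensity == 0:
            raise DataError("both band intensities are zero")


def percent_nonproductive(pair: DensitometryPair) -> float:
    """Percentage of non-productive splicing: 100 * np / (np + p)."""
    return 100.0 * pair.np_intensity / (pair.np_intensity + pair.p_intensity)


@dataclass
class QpcrMeasurement:
    """Technical-replicate Ct values for target and reference genes."""

    sample_id: str
    ct_target: Sequence[float]
    ct_reference: Sequence[float]
    group: str = "test"  # {control, test}

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            vals = [v for v in getattr(self, name) if math.isfinite(v)]
            if not vals:
                raise DataError(f"{self.sample_id}: {name} has no finite value")

    def delta_ct(self) -> float:
        tgt = [v for v in self.ct_target if math.isfinite(v)]
        ref = [v for v in self.ct_reference if math.isfinite(v)]
        return float(np.mean(tgt) - np.mean(ref))


def ddct_fold_change(samples: Iterable[QpcrMeasurement]) -> dict[str, float]:
    """Per-sample 2^-ddCt fold change relative to the control-group mean.

    dCt = mean(Ct_target) - mean(Ct_reference) per sample; ddCt subtracts
    the mean dCt over control samples; fold = 2^-ddCt.
    """
    samples = list(samples)
    controls = [m for m in samples if m.group == "control"]
    if not controls:
        raise DataError("ddCt requires at least one control sample")
    control_mean = float(np.mean([m.delta_ct() for m in controls]))
    return {
        m.sample_id: 2.0 ** -(m.delta_ct() - control_mean) for m in samples
    }


@dataclass
class MsdStandardCurve:
    """Quadratic (second-order polynomial) standard curve.

    ``signal = a * conc**2 + b * conc + c`` fitted to the standards by
    least squares; concentrations are recovered by root selection on the
    monotone branch covering the standards.
    """

    concentrations: Sequence[float]
    signals: Sequence[float]
    coefficients: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if conc.shape != sig.shape:
            raise DataError("concentrations and signals differ in length")
        if len(np.unique(conc)) < 3:
            raise DataError("quadratic fit needs >= 3 distinct standards")
        a, b, c = np.polyfit(conc, sig, 2)
        self.coefficients = (float(a), float(b), float(c))
        lo, hi = float(conc.min()), float(conc.max())
        # monotone over the interpolation range unless the vertex is inside
        if a != 0.0:
            vertex = -b / (2.0 * a)
            if lo < vertex < hi:
                warnings.warn(
                    "standard curve is non-monotone over the standard range"
                )

    def predict(self, conc: float) -> float:
        a, b, c = self.coefficients
        return a * conc * conc + b * conc + c


def msd_interpolate(curve: MsdStandardCurve, signal: float
                    ) -> tuple[Optional[float], bool]:
    """Invert the standard curve at ``signal``.

    Returns ``(concentration, extrapolated_flag)``.  Signals outside the
    fitted signal range of the standards are flagged; when no real root
    falls on the standards' branch the concentration is None (flagged).
    """
    a, b, c = curve.coefficients
    conc = np.asarray(curve.concentrations, dtype=float)
    lo, hi = float(conc.min()), float(conc.max())
    fitted = np.array([curve.predict(x) for x in conc])
    sig_lo, sig_hi = float(fitted.min()), float(fitted.max())
    sig_tol = 1e-9 * max(1.0, abs(sig_lo), abs(sig_hi))
    extrapolated = not (sig_lo - sig_tol <= signal <= sig_hi + sig_tol)

    if a == 0.0:
        if b == 0.0:
            return None, True
        return (signal - c) / b, extrapolated
    roots = np.roots([a, b, c - signal])
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-9)
    if not real:
        return None, True
    tol = 1e-9 * max(1.0, abs(hi))
    in_range = [r for r in real if lo - tol <= r <= hi + tol]
    if in_range:
        if len(in_range) == 2:
            # both roots in range: pick the monotone branch covering the
            # standards, i.e. the root on the same side of the vertex as
            # the bulk of the standard range
            vertex = -b / (2.0 * a)
            mid = (lo + hi) / 2.0
            in_range.sort(key=lambda r: (r - vertex) * (mid - vertex) < 0)
        return in_range[0], extrapolated
    # no root in range: nearest root, flagged as extrapolation
    nearest = min(real, key=lambda r: min(abs(r - lo), abs(r - hi)))
    return nearest, True


def abundance_upregulation_fit(x: Sequence[float], y: Sequence[float]) -> dict:
    """OLS line for maximal fold upregulation vs post-inhibition abundance.

    Returns slope, intercept, r_squared and the two-sided p-value for the
    slope.  Requires >= 3 paired points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise DataError("fit requires >= 3 paired points")
    if np.ptp(x) == 0:
        raise DataError("x has zero variance; slope undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "p_value": float(res.pvalue),
        "n": int(len(x)),
    }
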