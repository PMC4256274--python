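"""Frameshift-frequency estimation from western blots and GFP reporters.

Two independent estimators are provided:

* **Western.** The two protein variants carry a single N-terminal FLAG epitope
  each, so band intensity is taken proportional to molecule count with no
  length correction. The frameshift frequency is the slippage product's share
  of total signal, f = I_slip / (I_slip + I_other); a 1:3 ratio of full-length
  to truncated product therefore gives f = 25% and a molar ratio of 3:1.

* **GFP three-construct scheme.** A negative-control fusion (in-frame stop, no
  GFP made), a +1 reporter (GFP made only upon +1 slippage), and a 100%
  reference in which the frame is restored constitutively. After blank/OD600
  normalization, f = (f_test - f_neg) / (f_max - f_neg).

Raw plate-reader values are normalized as fluorescence over absorbance after
subtracting a blank from both (the stated and tested convention here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimateError, InputError


@dataclass(frozen=True)
class BandQuant:
    """Western-blot band intensities for one lane (arbitrary units).

    ``slippage_product`` declares which band is made via slippage: the long
    product for a tssM1-like locus (slippage restores the full-length frame),
    the short product for a tssM3-like locus.
    """

    lane_id: str
    intensity_long: float
    intensity_short: float
    slippage_product: str = "long"

    def __post_init__(self) -> None:
        if self.intensity_long < 0 or self.intensity_short < 0:
            raise InputError(f"{self.lane_id}: negative band intensity")
        if self.slippage_product not in ("long", "short"):
            raise InputError(f"{self.lane_id}: slippage_product must be 'long' or 'short'")


@dataclass(frozen=True)
class ReporterSet:
    """Normalized fluorescence of the three reporter constructs.

    f_neg: in-frame-stop negative control; f_test: +1 slippage reporter;
    f_max: constitutively frame-restored 100% reference. ``per_replicate``
    optionally holds per-replicate values (same keys) for uncertainty.
    """

    f_neg: float
    f_test: float
    f_max: float
    replicates: int = 1
    per_replicate: dict | None = None


@dataclass(frozen=True)
class FrameshiftEstimate:
    """A frameshift frequency with its method, variant ratio and uncertainty.

    ``ratio`` is other:slippage-product expressed as a real number, always
    equal to (1 - f_hat)/f_hat. ``se`` is absent for single measurements;
    ``clamped`` marks a GFP estimate pulled back into [0, 1].
    """

    f_hat: float
    method: str
    ratio: float
    se: float | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_hat <= 1.0:
            raise InputError(f"f_hat {self.f_hat} outside [0, 1]")


def _ratio(f_hat: float) -> float:
    return (1.0 - f_hat) / f_hat if f_hat > 0 else math.inf


def western_frequency(b: BandQuant) -> FrameshiftEstimate:
    """Frameshift frequency from one lane: f = I_slip / (I_long + I_short)."""
    total = b.intensity_long + b.intensity_short
    if total == 0:
        raise EstimateError(f"{b.lane_id}: both band intensities are zero")
    i_slip = b.intensity_long if b.slippage_product == "long" else b.intensity_short
    f = i_slip / total
    return FrameshiftEstimate(f_hat=f, method="western", ratio=_ratio(f))


def relative_fluorescence(raw_f: float, od600: float, blank_f: float, blank_od: float) -> float:
    """Blank-subtracted fluorescence per unit absorbance:
    (raw_f - blank_f) / (od600 - blank_od)."""
    denom = od600 - blank_od
    if denom <= 0:
        raise InputError(f"non-positive blank-corrected absorbance ({denom})")
    return (raw_f - blank_f) / denom


def gfp_frequency(r: ReporterSet) -> FrameshiftEstimate:
    """Frameshift frequency from the three-construct reporter comparison.

    f = (f_test - f_neg) / (f_max - f_neg), clamped to [0, 1] with a flag
    (reporter noise can push f_test slightly below f_neg). When per-replicate
    values are available the estimate is the mean of per-replicate estimates
    with its standard error.
    """
    if r.f_max <= r.f_neg:
        raise EstimateError(
            f"undefined estimate: f_max ({r.f_max}) must exceed f_neg ({r.f_neg})"
        )

    def point(neg, test, mx):
        return (test - neg) / (mx - neg)

    se = None
    if r.per_replicate:
        neg = np.asarray(r.per_replicate["f_neg"], dtype=float)
        test = np.asarray(r.per_replicate["f_test"], dtype=float)
        mx = np.asarray(r.per_replicate["f_max"], dtype=float)
        per = point(neg, test, mx)
        f = float(np.mean(per))
        if per.size >= 2:
            se = float(np.std(per, ddof=1) / math.sqrt(per.size))
    else:
        f = point(r.f_neg, r.f_test, r.f_max)
    clamped = not 0.0 <= f <= 1.0
    f = min(1.0, max(0.0, f))
    return FrameshiftEstimate(f_hat=f, method="gfp", ratio=_ratio(f), se=se, clamped=clamped)


def aggregate(estimates) -> FrameshiftEstimate:
    """Mean and standard error over replicate estimates of one method."""
    estimates = list(estimates)
    if len(estimates) < 2:
        raise InputError(f"aggregation needs >= 2 estimates, got {len(estimates)}")
    methods = {e.method for e in estimates}
    if len(methods) != 1:
        raise InputError(f"cannot aggregate mixed methods {sorted(methods)}")
    f = np.asarray([e.f_hat for e in estimates], dtype=float)
    mean = float(np.mean(f))
    se = float(np.std(f, ddof=1) / math.sqrt(f.size))
    return FrameshiftEstimate(f_hat=mean, method=methods.pop(), ratio=_ratio(mean), se=se)
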