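"""Fluorometer chlorophyll conversion and backscatter aggregation flags.

The manufacturer's fluorescence-to-chlorophyll calibration (derived from a
*Thalassiosira weissflogii* mono-culture) overestimates in-situ chlorophyll
by about a factor of two; the community bias factor divides it out. Optical
backscatter at 700 nm is screened per 1-second sample: any sample above
0.002 m-1 sr-1 marks large, potentially aggregated particles rather than
the small-particle background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FLUOR_BIAS = 2.0  # community calibration bias for WetLabs ECO fluorometers
AGGREGATION_THRESHOLD = 0.002  # m-1 sr-1 at 700 nm, per-sample exceedance


@dataclass
class OpticsBurst:
    """One hourly optics burst: fluorometric chl + 1-s backscatter samples."""

    time: object
    fluor_chl: float  # ug l-1 on the manufacturer scale
    backscatter_samples: np.ndarray  # m-1 sr-1, typically 8 per burst

    def __post_init__(self) -> None:
        self.backscatter_samples = np.asarray(self.backscatter_samples, dtype=float)
        if np.any(self.backscatter_samples < 0):
            raise ValueError("backscatter samples must be >= 0")


def fluor_to_chl(fluor_manufacturer, bias: float = FLUOR_BIAS):
    """Chlorophyll a (ug l-1) from manufacturer-scale fluorescence.

    Linear and order-preserving: divides by the calibration ``bias``
    (default 2). The factor is exposed because it varies between waters.
    """
    x = np.asarray(fluor_manufacturer, dtype=float)
    if np.any(x < 0):
        raise ValueError("fluorometric chlorophyll must be >= 0")
    out = x / bias
    return float(out) if out.ndim == 0 else out


def aggregation_flag(
    samples, threshold: float = AGGREGATION_THRESHOLD
) -> bool | None:
    """Whether a burst shows strong backscattering from aggregated particles.

    The rule is per individual 1-second sample, not the burst mean: the
    burst is flagged when ANY sample strictly exceeds ``threshold``.
    Returns None for an empty burst (missing).
    """
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return None
    return bool(np.any(x > threshold))


def aggregation_flags(bursts, threshold: float = AGGREGATION_THRESHOLD):
    """Vectorized :func:`aggregation_flag` over an iterable of bursts."""
    out = []
    for b in bursts:
        samples = b.backscatter_samples if isinstance(b, OpticsBurst) else b
        out.append(aggregation_flag(samples, threshold))
    return out
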