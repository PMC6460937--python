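"""Spectral metrics and neural-vs-artefact component classification.

Components from the group decomposition are sorted using three criteria:
a fALFF-like ratio (low-frequency spectral power below 0.10 Hz over power
between 0.15 and 0.25 Hz), the dynamic range of the power spectrum (peak
power minus the minimum power at frequencies above the peak), and the
overlap of the supra-threshold component map with a gray-matter mask.
Artefactual components (CSF, vascular, edge, motion) score low on all
three; a component is kept as neural only when every criterion passes,
which mirrors the conservative discard-when-in-doubt rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import ValidationError

__all__ = [
    "SpectralMetrics",
    "ComponentLabel",
    "power_spectrum",
    "compute_falff_ratio",
    "compute_dynamic_range",
    "compute_gm_overlap",
    "component_metrics",
    "classify_components",
]

LOW_BAND = (0.0, 0.10)     # Hz, numerator band
HIGH_BAND = (0.15, 0.25)   # Hz, denominator band (clipped at Nyquist)
_EPS = 1e-12


@dataclass
class SpectralMetrics:
    falff_ratio: float
    dynamic_range: float
    gm_overlap: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.falff_ratio, self.dynamic_range, self.gm_overlap]).all():
            raise ValidationError("spectral metrics must be finite")
        if not 0.0 <= self.gm_overlap <= 1.0:
            raise ValidationError("gm_overlap must lie in [0, 1]")


@dataclass
class ComponentLabel:
    component: int
    decision: str                       # "neural" | "artefact"
    reasons: list = field(default_factory=list)
    mixed: bool = False                 # single near-miss failure
    user_label: str | None = None


def power_spectrum(
    timecourse: np.ndarray, tr_seconds: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One-sided PSD on [0, Nyquist] via Welch (Hann, 50% overlap,
    segments of min(T, 64) samples), rescaled so the integral equals the
    series variance exactly (Parseval). Returns (frequencies, power,
    flagged); a constant series yields an all-zero spectrum, flagged.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValidationError("timecourse must be 1D with at least 8 samples")
    if not np.isfinite(x).all():
        raise ValidationError("timecourse must be finite")
    var = x.var()
    nperseg = min(x.size, 64)
    freqs, power = signal.welch(
        x, fs=1.0 / tr_seconds, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    if var == 0:
        return freqs, np.zeros_like(power), True
    integral = np.sum(power) * (freqs[1] - freqs[0])
    if integral > 0:
        power = power * (var / integral)
    return freqs, power, False


def average_power_spectrum(
    timecourses: np.ndarray, tr_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Grand-average PSD over subjects for one component.

    Averaging the per-subject Welch spectra (rather than the spectrum of
    the mean timecourse, which cancels across random phases) cuts estimator
    variance so the sorting metrics reflect the component's spectral shape.
    """
    tcs = np.atleast_2d(np.asarray(timecourses, dtype=float))
    spectra = []
    freqs = None
    for tc in tcs:
        freqs, p, _ = power_spectrum(tc, tr_seconds)
        spectra.append(p)
    return freqs, np.mean(spectra, axis=0)


def _band_integral(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], with linear
    interpolation at the band edges so analytic cases are exact."""
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inside], [hi]))
    p = np.concatenate(
        ([np.interp(lo, freqs, power)], power[inside], [np.interp(hi, freqs, power)])
    )
    return float(np.trapezoid(p, f))


def compute_falff_ratio(freqs: np.ndarray, power: np.ndarray) -> float:
    """Low-frequency power ratio: integral over [0, 0.10) Hz divided by the
    integral over [0.15, 0.25] Hz (denominator clipped at Nyquist)."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs[-1] <= HIGH_BAND[0]:
        raise ValidationError(
            f"denominator band empty: Nyquist {freqs[-1]:.4f} Hz <= {HIGH_BAND[0]} Hz"
        )
    num = _band_integral(freqs, power, *LOW_BAND)
    den = _band_integral(freqs, power, *HIGH_BAND)
    return num / max(den, _EPS)


def compute_dynamic_range(
    freqs: np.ndarray, power: np.ndarray
) -> tuple[float, bool]:
    """Peak power minus the minimum power at frequencies above the peak.

    Returns (range, flagged); a peak at the last bin gives range 0, flagged.
    """
    power = np.asarray(power, dtype=float)
    if power.size < 2:
        raise ValidationError("need at least 2 frequency bins")
    peak = int(np.argmax(power))
    if peak == power.size - 1:
        return 0.0, True
    return float(power[peak] - power[peak + 1 :].min()), False


def compute_gm_overlap(
    component_map: np.ndarray, gm_mask: np.ndarray, z_thresh: float = 2.0
) -> tuple[float, bool]:
    """Fraction of the component's supra-threshold voxels (|z| > z_thresh)
    inside the gray-matter mask. No supra-threshold voxels -> 0, flagged."""
    comp = np.asarray(component_map, dtype=float).ravel()
    gm = np.asarray(gm_mask, dtype=bool).ravel()
    if comp.shape != gm.shape:
        raise ValidationError("component map and gm mask shapes differ")
    supra = np.abs(comp) > z_thresh
    n = int(supra.sum())
    if n == 0:
        return 0.0, True
    return float((supra & gm).sum() / n), False


def component_metrics(
    component_map: np.ndarray,
    timecourse: np.ndarray,
    tr_seconds: float,
    gm_mask: np.ndarray,
    z_thresh: float = 2.0,
) -> SpectralMetrics:
    """All three sorting metrics for one component.

    ``timecourse`` may be a single series or a subjects x T array, in
    which case the per-subject spectra are averaged first.
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.ndim == 2:
        freqs, power = average_power_spectrum(tc, tr_seconds)
    else:
        freqs, power, _ = power_spectrum(tc, tr_seconds)
    falff = compute_falff_ratio(freqs, power)
    drange, _ = compute_dynamic_range(freqs, power)
    gm, _ = compute_gm_overlap(component_map, gm_mask, z_thresh)
    return SpectralMetrics(falff, drange, gm)


def classify_components(
    metrics: list[SpectralMetrics],
    falff_min: float = 2.0,
    dynamic_range_min: float | None = None,
    gm_overlap_min: float = 0.5,
) -> list[ComponentLabel]:
    """Partition components into neural networks and artefacts.

    A component is neural iff all criteria pass (inclusive thresholds);
    any failure discards it, and a single near-miss failure (within 10% of
    its threshold) marks the component as 'mixed' — discarded under the
    conservative rule. ``dynamic_range_min`` defaults to half the batch
    median: flat artefact spectra sit far below typical peaked network
    spectra, and a half-median cut stays scale-free without discarding the
    weakest genuine networks whenever networks are the majority of the
    batch (a strict median would, by construction).
    """
    if dynamic_range_min is None:
        dynamic_range_min = 0.5 * float(np.median([m.dynamic_range for m in metrics]))
    labels = []
    for i, m in enumerate(metrics):
        checks = {
            "falff_ratio": (m.falff_ratio, falff_min),
            "dynamic_range": (m.dynamic_range, dynamic_range_min),
            "gm_overlap": (m.gm_overlap, gm_overlap_min),
        }
        failed = [name for name, (val, thr) in checks.items() if val < thr]
        near_miss = (
            len(failed) == 1
            and checks[failed[0]][0] >= checks[failed[0]][1] * 0.9
        )
        labels.append(
            ComponentLabel(
                component=i,
                decision="neural" if not failed else "artefact",
                reasons=failed,
                mixed=near_miss,
            )
        )
    return labels
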