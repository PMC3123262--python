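"""Track normalization: dye-bias removal and optional GC-wave correction.

Median-centring removes the global dye-bias offset (the log2 median of a
genome-wide track is a robust zero under the assumption that most of the
genome is copy-neutral). GC-wave correction regresses the track on
per-probe local GC with a loess-style local-linear fit and subtracts the
fitted curve; it is off by default — the calling pipeline this reproduces
flagged GC-driven calls post hoc rather than correcting for them — but lets
users quantify how much of the shared-call artifact a wave correction would
remove.
"""

from __future__ import annotations

import warnings

import numpy as np

from .tracks import RatioTrack


def median_center(track: RatioTrack) -> RatioTrack:
    """Shift the track so its median log2 ratio is zero."""
    finite = np.isfinite(track.values)
    if not finite.any():
        raise ValueError("track has no finite values")
    med = float(np.median(track.values[finite]))
    return track.with_values(track.values - med, note=f"median_center({med:+.4g})")


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    bandwidth: float,
    robust_passes: int = 1,
    leave_out: bool = False,
) -> np.ndarray:
    """Local-linear regression with tricube weights at each observed x.

    ``bandwidth`` is a fixed half-width in x units. One bisquare
    reweighting pass (default) damps outliers such as probes inside real
    CNVs. With ``leave_out`` the fit at each point excludes that point
    (leave-one-out residual surface).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    fitted_s = np.empty(n)
    robust_w = np.ones(n)
    for sweep in range(robust_passes + 1):
        for i in range(n):
            lo = np.searchsorted(xs, xs[i] - bandwidth, side="left")
            hi = np.searchsorted(xs, xs[i] + bandwidth, side="right")
            xi, yi = xs[lo:hi], ys[lo:hi]
            d = np.abs(xi - xs[i]) / bandwidth
            w = (1 - d**3) ** 3 * robust_w[lo:hi]
            if leave_out:
                w = w.copy()
                w[i - lo] = 0.0
            sw = w.sum()
            if sw <= 0:
                fitted_s[i] = ys[i]
                continue
            xm = (w * xi).sum() / sw
            ym = (w * yi).sum() / sw
            sxx = (w * (xi - xm) ** 2).sum()
            slope = (w * (xi - xm) * (yi - ym)).sum() / sxx if sxx > 0 else 0.0
            fitted_s[i] = ym + slope * (xs[i] - xm)
        if sweep < robust_passes:
            resid = ys - fitted_s
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = np.clip(resid / (6 * s), -1, 1)
            robust_w = (1 - u**2) ** 2
    fitted = np.empty(n)
    fitted[order] = fitted_s
    return fitted


def gc_wave_correct(
    track: RatioTrack,
    probe_gc: np.ndarray,
    bandwidth_frac: float = 0.2,
    robust_passes: int = 1,
    report_loo: bool = False,
) -> RatioTrack:
    """Subtract a smooth local-regression fit of log2 ratio on local GC.

    ``bandwidth_frac`` sets the loess bandwidth as a fraction of the
    observed GC range. A constant GC vector makes the regression
    unidentifiable; the track is returned unchanged with a warning. When
    ``report_loo`` is set, leave-one-out residual diagnostics are attached
    to the returned track's notes.
    """
    probe_gc = np.asarray(probe_gc, dtype=float)
    if len(probe_gc) != len(track):
        raise ValueError("probe_gc must align with the probe map")
    if np.nanmin(probe_gc) < 0 or np.nanmax(probe_gc) > 1:
        raise ValueError("probe_gc values must lie in [0, 1]")
    gc_range = float(np.nanmax(probe_gc) - np.nanmin(probe_gc))
    if gc_range == 0.0:
        warnings.warn("constant GC vector; wave correction is a no-op")
        return track.with_values(track.values, note="gc_wave_correct(noop)")
    bandwidth = bandwidth_frac * gc_range
    finite = np.isfinite(track.values) & np.isfinite(probe_gc)
    fitted = np.zeros(len(track))
    fitted[finite] = loess_fit(
        probe_gc[finite], track.values[finite], bandwidth, robust_passes
    )
    corrected = track.values - fitted
    out = track.with_values(
        corrected, note=f"gc_wave_correct(bw={bandwidth:.4g})"
    )
    if report_loo:
        loo_fit = np.zeros(len(track))
        loo_fit[finite] = loess_fit(
            probe_gc[finite], track.values[finite], bandwidth,
            robust_passes, leave_out=True,
        )
        out.notes["loo_residual_sd"] = float(
            np.std((track.values - loo_fit)[finite])
        )
    return out
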