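"""SEEG signal conditioning, band decomposition, and functional connectivity.

The conditioning chain mirrors standard intracranial practice: a broad
0.5–300 Hz third-order Butterworth bandpass, cascaded band-stops over
the power-line fundamentals and harmonics, exclusion of flat or
excessively noisy channels, a common average reference over the
white-matter channels, and averaging of ten consecutive 6 s segments
into a single high-SNR trace.  FC is then Pearson correlation of the
band-filtered traces (or band-averaged magnitude-squared coherence).

All filters are applied zero-phase (forward–backward second-order
sections), so conditioning introduces no inter-channel lag that would
distort correlation-based FC.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .datatypes import (
    BandSpec,
    ConnectivityMatrix,
    TimeSeriesPanel,
    WmCouplingError,
)

__all__ = [
    "broadband_filter",
    "powerline_notch",
    "detect_bad_channels",
    "common_average_reference",
    "segment_and_average",
    "band_filter",
    "pearson_fc",
    "coherence_fc",
    "resample_panel",
    "POWERLINE_STOP_BANDS_HZ",
    "SignalError",
]


class SignalError(WmCouplingError):
    """Invalid signal-processing request (band above Nyquist, etc.)."""


#: Power-line fundamental and harmonic stop bands (Hz).
POWERLINE_STOP_BANDS_HZ: tuple[tuple[float, float], ...] = (
    (49.0, 61.0),
    (99.0, 101.0),
    (149.0, 151.0),
    (199.0, 201.0),
    (249.0, 251.0),
    (299.0, 300.0),
)

_BROADBAND = (0.5, 300.0)
_FILTER_ORDER = 3


def _sos_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise SignalError(
            f"band [{low}, {high}] Hz invalid for fs = {fs} Hz (Nyquist {nyq})"
        )
    return signal.butter(_FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")


def _apply_sos(panel: TimeSeriesPanel, sos: np.ndarray) -> TimeSeriesPanel:
    out = signal.sosfiltfilt(sos, panel.values, axis=1)
    return panel.with_values(out)


def broadband_filter(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """0.5–300 Hz third-order Butterworth bandpass, zero-phase."""
    if panel.fs < 620.0:
        raise SignalError(
            f"fs = {panel.fs} Hz too low for the 300 Hz broadband filter"
        )
    return _apply_sos(panel, _sos_bandpass(*_BROADBAND, panel.fs))


def powerline_notch(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Cascaded third-order Butterworth band-stops over line noise bands."""
    if panel.fs / 2.0 <= 300.0:
        raise SignalError("fs must exceed 600 Hz for the power-line stop bands")
    out = panel
    for low, high in POWERLINE_STOP_BANDS_HZ:
        sos = signal.butter(
            _FILTER_ORDER, [low, high], btype="bandstop", fs=panel.fs, output="sos"
        )
        out = _apply_sos(out, sos)
    return out


def detect_bad_channels(
    panel: TimeSeriesPanel,
    flat_tol: float = 1e-12,
    noise_z: float = 5.0,
) -> list[str]:
    """Flag flat or excessively noisy channels; the panel is not mutated.

    A channel is flat when its sample variance falls below ``flat_tol``.
    It is excessively noisy (or drifting) when the robust z-score of its
    log-variance — centred on the median and scaled by 1.4826 x MAD —
    exceeds ``noise_z``.  Thresholds stand in for the visual inspection
    used on clinical recordings.
    """
    if panel.n_channels < 3:
        raise SignalError("bad-channel detection needs at least 3 channels")
    var = panel.values.var(axis=1)
    flat = var < flat_tol
    logv = np.where(flat, np.nan, np.log10(np.maximum(var, 1e-300)))
    med = np.nanmedian(logv)
    mad = np.nanmedian(np.abs(logv - med))
    if mad > 0:
        z = (logv - med) / (1.4826 * mad)
        noisy = np.nan_to_num(z, nan=0.0) > noise_z
    else:
        noisy = np.zeros(panel.n_channels, dtype=bool)
    return [cid for cid, bad in zip(panel.channel_ids, flat | noisy) if bad]


def common_average_reference(
    panel: TimeSeriesPanel, include_ids: list[str] | tuple[str, ...]
) -> TimeSeriesPanel:
    """Re-reference every channel to the mean over ``include_ids``.

    The instantaneous mean over the included (white-matter) channels is
    subtracted from all channels; afterwards that mean is identically 0.
    """
    include = [cid for cid in panel.channel_ids if cid in set(include_ids)]
    if not include:
        raise SignalError("common average reference needs a nonempty include set")
    idx = [panel.channel_ids.index(cid) for cid in include]
    ref = panel.values[idx].mean(axis=0)
    return panel.with_values(panel.values - ref[None, :])


def segment_and_average(
    panel: TimeSeriesPanel, window_s: float = 6.0, n_segments: int = 10
) -> TimeSeriesPanel:
    """Average consecutive non-overlapping segments into one trace.

    The first ``window_s * n_segments`` seconds are split into
    ``n_segments`` equal windows whose pointwise (per-channel) average
    is returned; output duration is ``window_s``.  Defaults (6 s x 10)
    give the 60 s high-SNR trace of the main analysis; 4 s and 8 s are
    the sensitivity variants.
    """
    win = int(round(window_s * panel.fs))
    need = win * n_segments
    if panel.n_samples < need:
        raise SignalError(
            f"panel has {panel.duration:.3f} s; need {need / panel.fs:.3f} s "
            f"for {n_segments} x {window_s} s segments"
        )
    segs = panel.values[:, :need].reshape(panel.n_channels, n_segments, win)
    return panel.with_values(segs.mean(axis=1))


def band_filter(panel: TimeSeriesPanel, band: BandSpec) -> TimeSeriesPanel:
    """Zero-phase third-order Butterworth bandpass into one analysis band."""
    return _apply_sos(panel, _sos_bandpass(band.low, band.high, panel.fs))


def pearson_fc(panel: TimeSeriesPanel, band: str | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation FC over the full retained window.

    Channels with zero variance have undefined correlations; their rows
    and columns are set to NaN (diagonal kept at 1) and the offending
    channels are reported via ``UserWarning`` rather than silently
    propagating NaN.
    """
    if panel.n_channels < 2:
        raise SignalError("FC needs at least 2 channels")
    var = panel.values.var(axis=1)
    degenerate = var == 0.0
    values = panel.values.astype(float).copy()
    if degenerate.any():
        bad = [cid for cid, d in zip(panel.channel_ids, degenerate) if d]
        warnings.warn(f"zero-variance channels with undefined FC: {bad}", stacklevel=2)
        # give the degenerate rows nonzero variance so corrcoef does not
        # divide by zero; their entries are overwritten with NaN below
        values[degenerate, 0] += 1.0
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    if degenerate.any():
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    modality = "bold_fc" if panel.modality == "bold" else "seeg_fc"
    return ConnectivityMatrix(values=r, nodes=panel.channel_ids, modality=modality, band=band)


def coherence_fc(
    panel: TimeSeriesPanel,
    band: BandSpec,
    window_s: float = 1.0,
) -> ConnectivityMatrix:
    """Band-averaged magnitude-squared coherence between channel pairs.

    Welch cross-spectra with a ``window_s`` Hann taper and 50% overlap;
    the coherence spectrum is averaged over the frequency bins falling
    inside [band.low, band.high].  Values lie in [0, 1]; diagonal is 1.
    """
    nperseg = int(round(window_s * panel.fs))
    if panel.n_samples < 2 * nperseg:
        raise SignalError(
            "coherence needs at least 4 averaging windows (>= 2 x window length "
            "of samples at 50% overlap)"
        )
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / panel.fs)
    in_band = (freqs >= band.low) & (freqs <= band.high)
    if not in_band.any():
        raise SignalError(
            f"no frequency bins inside [{band.low}, {band.high}] Hz at "
            f"{window_s} s windows"
        )
    n = panel.n_channels
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, coh = signal.coherence(
                panel.values[i],
                panel.values[j],
                fs=panel.fs,
                window="hann",
                nperseg=nperseg,
                noverlap=nperseg // 2,
            )
            out[i, j] = out[j, i] = float(coh[in_band].mean())
    return ConnectivityMatrix(
        values=out, nodes=panel.channel_ids, modality="coherence_fc", band=band.name
    )


def resample_panel(panel: TimeSeriesPanel, fs_out: float) -> TimeSeriesPanel:
    """Polyphase resampling to a new rate (e.g. 2048 Hz -> 2000 Hz)."""
    from fractions import Fraction

    frac = Fraction(fs_out / panel.fs).limit_denominator(1000)
    out = signal.resample_poly(panel.values, frac.numerator, frac.denominator, axis=1)
    return TimeSeriesPanel(
        values=out, fs=fs_out, channel_ids=panel.channel_ids, modality=panel.modality
    )
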