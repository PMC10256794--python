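"""BOLD ROI extraction and lightweight temporal preprocessing.

ROI time series are the voxel means over contact-centred sphere ROIs
(7, 19 or 27 voxels at 2 mm isotropic; 19 is the 3 mm radius sphere of
the main analysis).  Temporal preprocessing follows the usual
resting-state sequence on the extracted panel: drop initial volumes,
demean/detrend, nuisance regression (e.g. the 24 motion parameters),
and a 0.01–0.2 Hz zero-phase Butterworth bandpass (0.01–0.08 Hz as the
sensitivity variant).  Anatomical preprocessing (registration,
distortion correction, normalization) is deliberately out of scope:
the module consumes already-gridded volumes or pre-extracted panels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, signal

from .datatypes import BoldVolume, ContactSet, TimeSeriesPanel, WmCouplingError
from .geometry import mm_to_voxel, sphere_voxels

__all__ = [
    "extract_roi_timeseries",
    "drop_initial_volumes",
    "detrend_demean",
    "regress_confounds",
    "bandpass_bold",
    "BoldError",
]


class BoldError(WmCouplingError):
    """Invalid BOLD processing request."""


def extract_roi_timeseries(
    vol: BoldVolume, contacts: ContactSet, neighborhood: int = 19
) -> TimeSeriesPanel:
    """Mean sphere-ROI time series at each contact location.

    For every contact the ROI is the ``neighborhood``-voxel sphere around
    the nearest grid voxel; the panel holds the voxel mean at each time
    point, at sampling rate 1/TR, channels in contact order.
    """
    series = np.empty((len(contacts), vol.n_volumes))
    for k, center in enumerate(contacts.coords):
        vox_center = mm_to_voxel(center, vol.voxel_mm, vol.origin_mm)[0]
        if np.any(vox_center < 0) or np.any(vox_center >= vol.grid_shape):
            raise BoldError(
                f"contact {contacts.ids[k]!r} at {tuple(center)} mm is outside the grid"
            )
        vox = sphere_voxels(
            center, neighborhood, vol.voxel_mm, vol.origin_mm, vol.grid_shape
        )
        series[k] = vol.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
    return TimeSeriesPanel(
        values=series, fs=1.0 / vol.tr, channel_ids=contacts.ids, modality="bold"
    )


def drop_initial_volumes(panel: TimeSeriesPanel, n: int = 5) -> TimeSeriesPanel:
    """Remove the first ``n`` time points (scanner equilibration)."""
    if n < 0:
        raise BoldError("cannot drop a negative number of volumes")
    if n >= panel.n_samples:
        raise BoldError(f"cannot drop {n} of {panel.n_samples} volumes")
    return panel.with_values(panel.values[:, n:])


def detrend_demean(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Remove each channel's least-squares linear trend and mean."""
    if panel.n_samples < 3:
        raise BoldError("detrending needs at least 3 time points")
    out = signal.detrend(panel.values, axis=1, type="linear")
    return panel.with_values(out)


def regress_confounds(panel: TimeSeriesPanel, confounds: np.ndarray) -> TimeSeriesPanel:
    """OLS residuals of each channel on [intercept | confound columns].

    Rank-deficient designs are repaired by dropping linearly dependent
    columns (pivoted QR) with a warning.  Residuals are orthogonal to
    every retained confound column and to the intercept.
    """
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != panel.n_samples:
        raise BoldError(
            f"confound rows ({c.shape[0]}) do not match volumes ({panel.n_samples})"
        )
    design = np.column_stack([np.ones(panel.n_samples), c])
    # pivoted QR exposes dependent columns
    _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    keep = np.sort(piv[: int((diag > tol).sum())])
    if len(keep) < design.shape[1]:
        dropped = sorted(set(range(design.shape[1])) - set(keep))
        warnings.warn(
            f"dropping {len(dropped)} linearly dependent confound column(s): "
            f"{dropped}",
            stacklevel=2,
        )
        design = design[:, keep]
    if design.shape[1] >= panel.n_samples:
        raise BoldError("confound rank must be below the number of volumes")
    beta, *_ = np.linalg.lstsq(design, panel.values.T, rcond=None)
    resid = panel.values.T - design @ beta
    return panel.with_values(resid.T)


def bandpass_bold(
    panel: TimeSeriesPanel, low: float = 0.01, high: float = 0.2, order: int = 3
) -> TimeSeriesPanel:
    """Zero-phase Butterworth bandpass of the BOLD panel (Hz)."""
    nyq = panel.fs / 2.0
    if not 0 < low < high < nyq:
        raise BoldError(
            f"band [{low}, {high}] Hz invalid for TR = {1.0 / panel.fs:g} s "
            f"(Nyquist {nyq:g} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=panel.fs, output="sos")
    return panel.with_values(signal.sosfiltfilt(sos, panel.values, axis=1))
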