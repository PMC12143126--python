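"""Source localization and virtual-sensor extraction.

A DICS (dynamic imaging of coherent sources) beamformer localizes power at
the tagging frequency from the sensor cross-spectral density; the top 3%
of voxels are clustered with DBSCAN and consolidated into labeled regions
of interest by a deterministic majority-label rule; an LCMV (linearly
constrained minimum variance) beamformer then extracts per-ROI virtual
sensor time series for connectivity analysis.

Both beamformers use the fixed-orientation unit-gain filter
``w = C_reg^-1 l / (l^T C_reg^-1 l)`` with diagonal loading
``C_reg = Re(C) + lambda * mean(diag(Re(C))) * I``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .exceptions import (
    ConfigurationError,
    IncompleteROIError,
    NumericalError,
    ResolutionError,
)
from .preprocess import EpochedEEG
from .synthio import ToyHeadModel
from .tf import morlet_wavelet

__all__ = [
    "CSD",
    "SourcePowerMap",
    "ROISet",
    "VirtualSensorSeries",
    "compute_csd",
    "dics_power",
    "threshold_top_percent",
    "cluster_voxels",
    "rois_from_clusters",
    "lcmv_virtual_sensors",
    "roi_theta_power",
]


@dataclass
class CSD:
    """Sensor cross-spectral density at one frequency (Hermitian PSD)."""

    matrix: np.ndarray
    freq: float
    window_ms: tuple
    n_trials: int
    taper: str = "hann"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        herm = np.max(np.abs(m - m.conj().T))
        if herm > 1e-10 * max(1.0, np.abs(m).max()):
            raise NumericalError(f"CSD not Hermitian (deviation {herm:.2e})")
        ev = np.linalg.eigvalsh((m + m.conj().T) / 2)
        if ev.min() < -1e-8 * max(ev.max(), 1e-30):
            raise NumericalError("CSD not positive semi-definite")
        self.matrix = m


@dataclass
class SourcePowerMap:
    """Per-voxel beamformer power on a head-model grid."""

    power: np.ndarray
    head: ToyHeadModel
    freq: float
    lambda_frac: float

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.head.n_voxels,):
            raise ConfigurationError("power length must match voxel count")
        if np.any(self.power < 0):
            raise NumericalError("negative source power")


@dataclass
class ROISet:
    """Named, disjoint voxel-index sets with clustering provenance."""

    rois: dict                    # name -> np.ndarray of voxel indices
    provenance: dict | None = None

    def __post_init__(self):
        seen = set()
        for name, idx in self.rois.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise IncompleteROIError(f"ROI {name!r} is empty")
            if seen & set(idx.tolist()):
                raise ConfigurationError("ROIs must be disjoint")
            seen |= set(idx.tolist())
            self.rois[name] = idx

    @property
    def names(self) -> list:
        return list(self.rois)


@dataclass
class VirtualSensorSeries:
    """LCMV output: trials x rois x time, with ROI order fixed."""

    data: np.ndarray
    fs: float
    roi_names: list
    phase: str | None = None
    condition: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be trials x rois x time")
        if self.data.shape[1] != len(self.roi_names):
            raise ConfigurationError("roi axis must match roi_names")
        if not np.all(np.isfinite(self.data)):
            raise NumericalError("virtual sensor series non-finite")


def compute_csd(epochs: EpochedEEG, freq: float, window_ms=None,
                taper: str = "hann") -> CSD:
    """Cross-spectral density at ``freq`` from tapered per-trial Fourier
    coefficients.

    Each trial's analysis window is tapered and projected onto a complex
    exponential at ``freq``; the CSD is the trial average of coefficient
    outer products, Hermitian by construction. Coefficients are amplitude
    calibrated: a unit sinusoid gives unit diagonal power.
    """
    if window_ms is None:
        window_ms = epochs.window_ms
    a, b = window_ms
    times = epochs.times_ms
    sel = (times >= a - 1e-9) & (times < b - 1e-9)
    n_win = int(sel.sum())
    if n_win / epochs.fs < 2.0 / freq:
        raise ResolutionError(
            f"window of {n_win / epochs.fs:.3f} s shorter than two cycles "
            f"of {freq} Hz"
        )
    if taper == "hann":
        w = np.hanning(n_win)
    elif taper == "boxcar":
        w = np.ones(n_win)
    else:
        raise ConfigurationError(f"unknown taper {taper!r}")
    t = np.arange(n_win) / epochs.fs
    basis = np.exp(-2j * np.pi * freq * t) * w
    basis *= 2.0 / w.sum()                      # amplitude calibration
    coeff = epochs.data[:, :, sel] @ basis      # trials x channels
    csd = np.einsum("tc,td->cd", coeff, coeff.conj()) / epochs.n_trials
    csd = (csd + csd.conj().T) / 2.0
    return CSD(csd, freq, (a, b), epochs.n_trials, taper)


def _unit_gain_filters(cov: np.ndarray, leadfield: np.ndarray,
                       lambda_frac: float) -> np.ndarray:
    """All unit-gain spatial filters (sensors x voxels) at once."""
    if lambda_frac < 0:
        raise ConfigurationError("lambda must be >= 0")
    c = np.real(cov).copy()
    c[np.diag_indices_from(c)] += lambda_frac * np.mean(np.diag(c))
    try:
        cinv_l = np.linalg.solve(c, leadfield)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "covariance is singular; increase the regularization "
            "lambda above 0"
        ) from exc
    denom = np.einsum("cv,cv->v", leadfield, cinv_l)
    if np.any(np.abs(denom) < 1e-300) or not np.all(np.isfinite(cinv_l)):
        raise NumericalError(
            "rank-deficient covariance; increase the regularization lambda"
        )
    return cinv_l / denom


def dics_power(csd: CSD, head: ToyHeadModel,
               lambda_frac: float = 0.05) -> SourcePowerMap:
    """DICS source power: ``p(v) = Re(w^H C w)`` per voxel filter."""
    if csd.matrix.shape[0] != head.n_sensors:
        raise ConfigurationError("CSD channels do not match leadfield rows")
    w = _unit_gain_filters(csd.matrix, head.leadfield, lambda_frac)
    power = np.real(np.einsum("cv,cd,dv->v", w.conj(), csd.matrix, w))
    power = np.maximum(power, 0.0)
    return SourcePowerMap(power, head, csd.freq, lambda_frac)


def threshold_top_percent(pmap, pct: float = 3.0) -> np.ndarray:
    """Boolean mask of the top ``pct`` percent most active voxels.

    Selects the ``ceil(pct/100 * n_voxels)`` highest-power voxels; ties
    exactly at the cutoff value are all included.
    """
    power = pmap.power if isinstance(pmap, SourcePowerMap) else np.asarray(pmap)
    if not 0 < pct < 100:
        raise ConfigurationError("pct must lie in (0, 100)")
    n = power.size
    k = int(np.ceil(pct / 100.0 * n))
    cutoff = np.sort(power)[::-1][k - 1]
    return power >= cutoff


def cluster_voxels(coords: np.ndarray, eps: float,
                   min_samples: int = 3) -> np.ndarray:
    """DBSCAN cluster labels for selected voxel coordinates (-1 = noise)."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ConfigurationError("voxel coordinates must be finite")
    if eps <= 0:
        raise ConfigurationError("eps must be positive")
    if len(coords) == 0:
        return np.array([], dtype=int)
    return DBSCAN(eps=eps, min_samples=min_samples).fit(coords).labels_


def rois_from_clusters(cluster_labels: np.ndarray, voxel_indices: np.ndarray,
                       head: ToyHeadModel,
                       roi_names=("ATL", "IC", "IFC"),
                       exclude_labels=("SUBCORTICAL",)) -> ROISet:
    """Consolidate voxel clusters into named ROIs by majority label.

    Noise voxels (cluster -1) and voxels carrying an excluded anatomical
    label (subcortical stand-ins) are dropped. Each remaining cluster is
    assigned the majority anatomical label of its voxels (lexicographic
    tie-break); clusters sharing a target label are merged; only the
    configured ROI names are retained. Raises when a required ROI ends
    empty, naming it.
    """
    cluster_labels = np.asarray(cluster_labels)
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    if cluster_labels.shape != voxel_indices.shape:
        raise ConfigurationError("one cluster label per voxel index")
    anat = np.asarray(head.voxel_labels)
    rois = {name: [] for name in roi_names}
    provenance = {}
    for cl in sorted(set(cluster_labels.tolist()) - {-1}):
        members = voxel_indices[cluster_labels == cl]
        members = members[~np.isin(anat[members], exclude_labels)]
        if members.size == 0:
            continue
        labels, counts = np.unique(anat[members], return_counts=True)
        winners = labels[counts == counts.max()]
        majority = str(np.sort(winners)[0])     # lexicographic tie-break
        provenance[int(cl)] = {
            "majority_label": majority,
            "votes": dict(zip(labels.tolist(), counts.tolist())),
        }
        if majority in rois:
            rois[majority].extend(members.tolist())
    missing = [n for n, v in rois.items() if not v]
    if missing:
        raise IncompleteROIError(
            f"no voxels assigned to required ROI(s): {missing}"
        )
    rois = {n: np.unique(v) for n, v in rois.items()}
    return ROISet(rois, provenance)


def lcmv_virtual_sensors(epochs: EpochedEEG, head: ToyHeadModel,
                         rois: ROISet, lambda_frac: float = 0.05,
                         phase: str | None = None,
                         condition: str | None = None
                         ) -> VirtualSensorSeries:
    """Per-ROI virtual sensor series via the LCMV beamformer.

    The time-domain covariance is estimated over all trials of the
    analysis window. Each ROI voxel gets its unit-gain filter; voxel
    series within an ROI are sign-aligned to the ROI's first voxel
    (beamformer source polarity is arbitrary) and averaged.
    """
    if epochs.data.shape[1] != head.n_sensors:
        raise ConfigurationError("epoch channels do not match leadfield rows")
    n_tr, n_ch, n_time = epochs.data.shape
    flat = epochs.data.transpose(1, 0, 2).reshape(n_ch, n_tr * n_time)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / flat.shape[1]
    out = np.empty((n_tr, len(rois.names), n_time))
    for ri, name in enumerate(rois.names):
        idx = rois.rois[name]
        w = _unit_gain_filters(cov, head.leadfield[:, idx], lambda_frac)
        vox_series = np.einsum("cv,tcn->tvn", w, epochs.data)
        if idx.size > 1:
            ref = vox_series[:, 0, :].ravel()
            for v in range(1, idx.size):
                r = np.dot(vox_series[:, v, :].ravel(), ref)
                if r < 0:
                    vox_series[:, v, :] *= -1.0
        out[:, ri, :] = vox_series.mean(axis=1)
    return VirtualSensorSeries(out, epochs.fs, list(rois.names),
                               phase, condition)


def roi_theta_power(vs: VirtualSensorSeries, freq: float = 4.5,
                    n_cycles: float = 5.0) -> np.ndarray:
    """Mean Morlet power per ROI at ``freq``, averaged over trials and time.

    Edge samples within half the wavelet support are excluded from the
    time average so the estimate is not diluted by convolution roll-off.
    """
    from scipy.signal import fftconvolve

    kern = morlet_wavelet(freq, vs.fs, n_cycles)
    half = len(kern) // 2
    n_tr, n_roi, n_time = vs.data.shape
    if n_time <= 2 * half:
        raise ResolutionError(
            f"series of {n_time} samples too short for {freq} Hz wavelet"
        )
    flat = vs.data.reshape(n_tr * n_roi, n_time)
    conv = fftconvolve(flat, kern[None, :], mode="same", axes=1)
    power = np.abs(conv) ** 2
    interior = power[:, half:n_time - half]
    return interior.reshape(n_tr, n_roi, -1).mean(axis=(0, 2))
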