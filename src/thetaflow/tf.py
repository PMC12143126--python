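"""Morlet time-frequency decomposition and frequency-tagging contrasts.

Power at the two tagged frequencies (4.5 and 8 Hz) is estimated with
complex Morlet wavelets, expressed as relative change against a pre-cue
baseline, and compared pointwise (electrode x time) between measured
frequencies with paired t-tests under Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .exceptions import (
    ConfigurationError,
    NumericalError,
    PairingError,
    ResolutionError,
)
from .preprocess import EpochedEEG

__all__ = [
    "TFR",
    "RelTFR",
    "PhaseWindows",
    "morlet_wavelet",
    "morlet_tfr",
    "relative_power_change",
    "pointwise_paired_contrast",
    "segment_phases",
    "phase_slice",
]


@dataclass
class TFR:
    """Trial-averaged wavelet power: channels x freqs x times (µV²)."""

    power: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    n_cycles: float
    averaged_over: int
    fs: float

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if np.any(self.power < 0):
            raise ConfigurationError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ConfigurationError("freqs must be strictly increasing")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ConfigurationError("times must be strictly increasing")


@dataclass
class RelTFR:
    """Baseline-relative power change, unitless; bounded below by -1."""

    relchange: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    baseline_window_ms: tuple
    fs: float

    def __post_init__(self):
        self.relchange = np.asarray(self.relchange, dtype=float)
        if not np.all(np.isfinite(self.relchange)):
            raise NumericalError("relative change contains non-finite values")
        if np.any(self.relchange < -1.0 - 1e-12):
            raise NumericalError("relative change below -1: negative power?")


@dataclass(frozen=True)
class PhaseWindows:
    """Analysis phases in ms, with the lock event each is defined against.

    Defaults: action planning 0–1000 ms and standby 1000–2000 ms relative
    to cue onset; perception 0–1000 ms relative to action-effect onset.
    Windows are half-open at sample resolution.
    """

    planning: tuple = (0.0, 1000.0)
    standby: tuple = (1000.0, 2000.0)
    perception: tuple = (0.0, 1000.0)
    locks: dict = None

    def __post_init__(self):
        object.__setattr__(self, "locks", self.locks or {
            "planning": "cue", "standby": "cue", "perception": "effect"})
        for name in ("planning", "standby", "perception"):
            a, b = getattr(self, name)
            if not a < b:
                raise ConfigurationError(f"phase {name} window inverted")
        # cue-locked phases must not overlap
        cue = sorted(w for n, w in
                     [("planning", self.planning), ("standby", self.standby)]
                     if self.locks[n] == "cue")
        for (a1, b1), (a2, b2) in zip(cue, cue[1:]):
            if b1 > a2:
                raise ConfigurationError("cue-locked phases overlap")

    def items(self):
        for name in ("planning", "standby", "perception"):
            yield name, getattr(self, name), self.locks[name]


def morlet_wavelet(freq: float, fs: float, n_cycles: float = 5.0,
                   trunc_sigmas: float = 3.0) -> np.ndarray:
    """Complex Morlet kernel, amplitude-calibrated at its center frequency.

    ``w(t) = exp(i 2 pi f t) exp(-t^2 / (2 sigma_t^2))`` with
    ``sigma_t = n_cycles / (2 pi f)``, truncated at ±``trunc_sigmas``
    standard deviations of the Gaussian envelope. The kernel is scaled so
    that convolving a unit-amplitude sinusoid at ``freq`` yields squared
    magnitude 1, i.e. power reads in amplitude-squared units.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.floor(trunc_sigmas * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-t ** 2 / (2.0 * sigma_t ** 2))
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return kernel / (0.5 * envelope.sum())


def morlet_tfr(epochs: EpochedEEG, freqs, n_cycles: float = 5.0,
               trunc_sigmas: float = 3.0) -> TFR:
    """Trial-averaged Morlet power of an epoched recording.

    Power is the squared magnitude of the per-trial complex convolution,
    averaged across trials; units are amplitude-squared (µV²) at each
    frequency. The lowest frequency must complete ``n_cycles`` within the
    epoch.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(np.diff(freqs) <= 0):
        raise ConfigurationError("freqs must be strictly increasing")
    n_time = epochs.data.shape[2]
    epoch_s = n_time / epochs.fs
    if epoch_s < n_cycles / freqs.min():
        raise ResolutionError(
            f"epoch of {epoch_s:.2f} s cannot resolve {freqs.min()} Hz "
            f"with {n_cycles} cycles"
        )
    n_tr, n_ch, _ = epochs.data.shape
    power = np.zeros((n_ch, len(freqs), n_time))
    flat = epochs.data.reshape(n_tr * n_ch, n_time)
    for fi, f in enumerate(freqs):
        kern = morlet_wavelet(f, epochs.fs, n_cycles, trunc_sigmas)
        conv = signal.fftconvolve(flat, kern[None, :], mode="same", axes=1)
        p = np.abs(conv) ** 2
        power[:, fi, :] = p.reshape(n_tr, n_ch, n_time).mean(axis=0)
    return TFR(power, freqs, epochs.times_ms, n_cycles, n_tr, epochs.fs)


def relative_power_change(tfr: TFR, baseline_window_ms=(-350.0, -150.0)
                          ) -> RelTFR:
    """Relative change against the mean baseline power.

    ``rel(c,f,t) = (P(c,f,t) - B(c,f)) / B(c,f)`` with ``B`` the mean
    power over the baseline samples (endpoints inclusive at sample
    resolution).
    """
    a, b = baseline_window_ms
    if not a < b:
        raise ConfigurationError("baseline window inverted")
    sel = (tfr.times_ms >= a) & (tfr.times_ms <= b)
    if not sel.any():
        raise ConfigurationError("baseline window outside epoch")
    base = tfr.power[:, :, sel].mean(axis=2)
    bad = np.argwhere(base <= 0)
    if bad.size:
        c, f = bad[0]
        raise NumericalError(
            f"zero baseline power at channel {c}, {tfr.freqs[f]} Hz"
        )
    rel = (tfr.power - base[:, :, None]) / base[:, :, None]
    return RelTFR(rel, tfr.freqs, tfr.times_ms, (a, b), tfr.fs)


def pointwise_paired_contrast(rel_a: np.ndarray, rel_b: np.ndarray,
                              alpha: float = 0.05) -> dict:
    """Pointwise paired t-test between two per-subject maps, FDR-masked.

    ``rel_a`` and ``rel_b`` are (n_subjects, ...) arrays aligned by
    subject (e.g. electrode x time maps of relative power at the two
    measured frequencies). A two-sided paired t is computed per point and
    Benjamini-Hochberg correction is applied jointly across all tested
    points. Points with zero within-pair variance have no defined t; they
    are reported as NaN and excluded from the FDR family.

    Returns a dict with ``t``, ``p``, ``p_fdr`` and boolean ``mask``
    arrays of the map shape, plus ``n_undefined``.
    """
    rel_a, rel_b = np.asarray(rel_a, float), np.asarray(rel_b, float)
    if rel_a.shape != rel_b.shape:
        raise PairingError("inputs must have identical (subject-aligned) shape")
    n = rel_a.shape[0]
    if n < 3:
        raise PairingError("need at least 3 subjects for a paired contrast")
    diff = rel_a - rel_b
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = mean / (sd / np.sqrt(n))
    defined = sd > 0
    pval = np.full(tval.shape, np.nan)
    pval[defined] = 2.0 * stats.t.sf(np.abs(tval[defined]), df=n - 1)
    p_fdr = np.full(tval.shape, np.nan)
    mask = np.zeros(tval.shape, dtype=bool)
    if defined.any():
        from .stats import fdr_bh

        adj = fdr_bh(pval[defined])
        p_fdr[defined] = adj
        mask[defined] = adj < alpha
    tval = np.where(defined, tval, np.nan)
    return {"t": tval, "p": pval, "p_fdr": p_fdr, "mask": mask,
            "n_undefined": int((~defined).sum())}


def phase_slice(window_ms, times_ms) -> slice:
    """Half-open sample slice [start, end) of a phase window in an epoch."""
    a, b = window_ms
    times_ms = np.asarray(times_ms)
    if a < times_ms[0] - 1e-9 or b > times_ms[-1] + 1000.0 / _fs_of(times_ms):
        raise ConfigurationError(
            f"phase window ({a}, {b}) ms outside epoch "
            f"({times_ms[0]}, {times_ms[-1]}) ms"
        )
    i0 = int(np.searchsorted(times_ms, a - 1e-9))
    i1 = int(np.searchsorted(times_ms, b - 1e-9))
    return slice(i0, i1)


def _fs_of(times_ms: np.ndarray) -> float:
    return 1000.0 / float(np.median(np.diff(times_ms)))


def segment_phases(data: np.ndarray, times_ms, phases: PhaseWindows,
                   lock: str) -> dict:
    """Slice the trailing time axis of ``data`` into this lock's phases.

    Only phases defined against ``lock`` are returned; requesting a
    perception slice from cue-locked data simply yields no perception
    entry, and a window falling outside the epoch raises. Slices of the
    same lock are guaranteed gap-free and equal length when the windows
    are (half-open convention).
    """
    if lock not in ("cue", "effect"):
        raise ConfigurationError(f"unknown lock {lock!r}")
    out = {}
    for name, window, phase_lock in phases.items():
        if phase_lock != lock:
            continue
        sl = phase_slice(window, times_ms)
        out[name] = np.asarray(data)[..., sl]
    if not out:
        raise ConfigurationError(f"no phases are defined against lock {lock!r}")
    return out
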