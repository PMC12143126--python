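"""Synthetic inputs with known ground truth.

This module generates everything the analysis pipeline consumes:

* trial timelines for the forced-choice action–effect task (fixation →
  colored cue → response window → flickering action effect),
* coupled source dynamics from a ground-truth nonlinear multivariate
  autoregressive network, so directed-connectivity estimates can be
  validated against a known adjacency,
* continuous frequency-tagged sensor EEG (steady-state visually evoked
  activity at the trial's flicker frequency on posterior sensors, source
  activity projected through a toy leadfield, 1/f sensor noise),
* a toy spherical head model with labeled voxel regions standing in for a
  template forward model, and
* a within-subject two-condition study (placebo vs an active condition
  modeled purely as a labeled coupling change) whose connectivity
  asymmetry per phase is configurable, giving the inference layer a known
  direction of truth.

All generators are deterministic given their seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GeometryError, StabilityError
from .preprocess import RawRecording

__all__ = [
    "TaskConfig",
    "NonlinearTerm",
    "GroundTruthNetwork",
    "ToyHeadModel",
    "StudyConfig",
    "default_network",
    "simulate_trial_events",
    "simulate_source_dynamics",
    "simulate_tagged_eeg",
    "make_toy_leadfield",
    "simulate_study_cell",
    "simulate_behavior",
    "save_head_model",
    "load_head_model",
]

NODE_NAMES = ("ATL", "IC", "IFC")


@dataclass
class TaskConfig:
    """Timing and counts of the action–effect binding task.

    Durations are in ms. Defaults mirror the task this pipeline targets:
    300 trials, 150 per flicker frequency (4.5 and 8 Hz), 2000 ms
    fixation, 2000 ms cue, a 1000 ms response window after cue offset, and
    a 2000 ms flickering action effect triggered by a correct response.
    """

    n_trials: int = 300
    flicker_freqs: tuple = (4.5, 8.0)
    trials_per_freq: tuple = (150, 150)
    cue_duration_ms: float = 2000.0
    response_window_ms: float = 1000.0
    effect_duration_ms: float = 2000.0
    pre_cue_fixation_ms: float = 2000.0

    def __post_init__(self):
        if sum(self.trials_per_freq) != self.n_trials:
            raise ConfigurationError("trials_per_freq must sum to n_trials")
        if len(self.flicker_freqs) != len(self.trials_per_freq):
            raise ConfigurationError("one trial count per flicker frequency")
        if len(set(self.flicker_freqs)) != len(self.flicker_freqs):
            raise ConfigurationError("flicker frequencies must be distinct")
        for name in ("cue_duration_ms", "response_window_ms",
                     "effect_duration_ms", "pre_cue_fixation_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def trial_duration_ms(self) -> float:
        return (self.pre_cue_fixation_ms + self.cue_duration_ms
                + self.response_window_ms + self.effect_duration_ms)


@dataclass(frozen=True)
class NonlinearTerm:
    """One nonlinear coupling term feeding node ``target``.

    form:
      * ``"quadratic"``: gain * x_src(t-lag)**2  (even nonlinearity,
        invisible to cross-correlation)
      * ``"product"``:   gain * x_src(t-lag) * x_src2(t-lag)
      * ``"tanh"``:      gain * tanh(x_src(t-lag))  (saturating)
    """

    form: str
    target: int
    source: int
    gain: float
    lag: int = 1
    source2: int | None = None

    def __post_init__(self):
        if self.form not in ("quadratic", "product", "tanh"):
            raise ConfigurationError(f"unknown nonlinear form {self.form!r}")
        if self.form == "product" and self.source2 is None:
            raise ConfigurationError("product term needs source2")
        if self.lag < 1:
            raise ConfigurationError("lag must be >= 1")
        if not np.isfinite(self.gain):
            raise ConfigurationError("gain must be finite")


@dataclass
class GroundTruthNetwork:
    """Ground-truth nonlinear MVAR system.

    ``lin_coeffs`` has shape (order, K, K) with the target-row convention
    used throughout the package: ``lin_coeffs[k-1, i, j]`` is the weight of
    ``x_j(t-k)`` in the update of ``x_i(t)``. Stationarity of the linear
    part is enforced via the spectral radius of the companion matrix.
    """

    lin_coeffs: np.ndarray
    nl_terms: tuple = ()
    noise_sd: float = 1.0
    node_names: tuple = NODE_NAMES

    def __post_init__(self):
        self.lin_coeffs = np.asarray(self.lin_coeffs, dtype=float)
        if self.lin_coeffs.ndim != 3 or (
                self.lin_coeffs.shape[1] != self.lin_coeffs.shape[2]):
            raise ConfigurationError("lin_coeffs must be (order, K, K)")
        if self.order < 1:
            raise ConfigurationError("model order must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for term in self.nl_terms:
            for node in (term.target, term.source,
                         term.source2 if term.source2 is not None else 0):
                if not 0 <= node < self.n_nodes:
                    raise ConfigurationError("nonlinear term node out of range")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StabilityError(
                f"linear part is unstable: spectral radius {rho:.4f} >= 1"
            )

    @property
    def n_nodes(self) -> int:
        return self.lin_coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.lin_coeffs.shape[0]

    @property
    def max_lag(self) -> int:
        lags = [self.order] + [t.lag for t in self.nl_terms]
        return max(lags)

    def spectral_radius(self) -> float:
        """Spectral radius of the VAR companion matrix of the linear part."""
        p, k = self.order, self.n_nodes
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = np.concatenate(list(self.lin_coeffs), axis=1)
        if p > 1:
            comp[k:, :-k] = np.eye(k * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def adjacency(self) -> dict:
        """Boolean K x K adjacency ([i, j] True iff j drives i).

        Exactly the support of the nonzero coupling parameters; the
        ``"linear"`` entry covers the autoregressive coefficients, the
        ``"nonlinear"`` entry the nonlinear terms (a product term marks
        both of its sources).
        """
        lin = np.any(self.lin_coeffs != 0.0, axis=0)
        nl = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for term in self.nl_terms:
            if term.gain != 0.0:
                nl[term.target, term.source] = True
                if term.source2 is not None:
                    nl[term.target, term.source2] = True
        return {"linear": lin, "nonlinear": nl}

    def to_json(self) -> str:
        payload = {
            "node_names": list(self.node_names),
            "lin_coeffs": self.lin_coeffs.tolist(),
            "noise_sd": self.noise_sd,
            "nl_terms": [
                {"form": t.form, "target": t.target, "source": t.source,
                 "gain": t.gain, "lag": t.lag, "source2": t.source2}
                for t in self.nl_terms
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthNetwork":
        d = json.loads(text)
        terms = tuple(NonlinearTerm(**t) for t in d["nl_terms"])
        return cls(np.asarray(d["lin_coeffs"]), terms, d["noise_sd"],
                   tuple(d["node_names"]))


def default_network(order: int = 3, noise_sd: float = 1.0) -> GroundTruthNetwork:
    """The canonical 3-node validation network (ATL, IC, IFC).

    Each node has a stable self-autoregression; two directed linear edges
    (ATL->IFC at lag 1, IC->ATL at lag 2) and two even-nonlinear terms
    (quadratic IC->IFC at lag 1, and an ATL x IC product into IFC at
    lag 2) form the mixed ground truth the connectivity estimator must
    disentangle. The directed graph is acyclic (IFC is a sink), so the
    unbounded quadratic terms cannot enter a feedback loop and the
    recursion stays stable for any innovation draw.
    """
    k = 3
    A = np.zeros((order, k, k))
    self_coeffs = [0.45, -0.25, 0.1][:order]
    for lag, c in enumerate(self_coeffs):
        A[lag, np.arange(k), np.arange(k)] = c
    A[0, 2, 0] = 0.45            # ATL -> IFC, lag 1
    if order >= 2:
        A[1, 0, 1] = 0.35        # IC -> ATL, lag 2
    else:
        A[0, 0, 1] = 0.35
    nl = (
        NonlinearTerm("quadratic", target=2, source=1, gain=0.40, lag=1),
        NonlinearTerm("product", target=2, source=0, gain=0.35,
                      lag=min(2, order), source2=1),
    )
    return GroundTruthNetwork(A, nl, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Trial timeline
# ---------------------------------------------------------------------------

def simulate_trial_events(task: TaskConfig, seed: int,
                          accuracy: float = 0.97, fs: float = 500.0,
                          rt_mean_ms: float = 290.0,
                          rt_sd_ms: float = 60.0) -> pd.DataFrame:
    """Draw one session's trial timeline.

    Each trial occupies ``task.trial_duration_ms``; within it, fixation is
    followed by the cue, the response falls inside the post-cue response
    window, and a correct response triggers the action-effect onset at the
    response sample. Incorrect (or would-be late) responses carry no
    effect onset.

    Returns a DataFrame with columns ``trial, flicker_freq, correct,
    trial_start_sample, cue_onset_sample, response_sample,
    effect_onset_sample`` (effect onset is NaN on incorrect trials).
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ConfigurationError("accuracy must be within [0, 1]")
    rng = np.random.default_rng(seed)
    trial_smp = int(round(task.trial_duration_ms / 1000.0 * fs))
    pre_smp = int(round(task.pre_cue_fixation_ms / 1000.0 * fs))
    cue_smp = int(round(task.cue_duration_ms / 1000.0 * fs))
    resp_win_smp = int(round(task.response_window_ms / 1000.0 * fs))

    freqs = np.repeat(task.flicker_freqs, task.trials_per_freq)
    rng.shuffle(freqs)
    correct = rng.random(task.n_trials) < accuracy

    rows = []
    for t in range(task.n_trials):
        start = t * trial_smp
        cue_on = start + pre_smp
        rt_smp = int(round(np.clip(rng.normal(rt_mean_ms, rt_sd_ms), 80.0,
                                   task.response_window_ms - 20.0)
                           / 1000.0 * fs))
        rt_smp = min(rt_smp, resp_win_smp - 1)
        response = cue_on + cue_smp + rt_smp
        effect = float(response) if correct[t] else np.nan
        rows.append((t, freqs[t], bool(correct[t]), start, cue_on,
                     response, effect))
    return pd.DataFrame(rows, columns=[
        "trial", "flicker_freq", "correct", "trial_start_sample",
        "cue_onset_sample", "response_sample", "effect_onset_sample"])


# ---------------------------------------------------------------------------
# Source dynamics
# ---------------------------------------------------------------------------

def _nl_contribution(term: NonlinearTerm, hist: np.ndarray) -> float:
    """Evaluate one nonlinear term given the lag history (max_lag x K)."""
    x = hist[term.lag - 1, term.source]
    if term.form == "quadratic":
        return term.gain * x * x
    if term.form == "product":
        return term.gain * x * hist[term.lag - 1, term.source2]
    return term.gain * np.tanh(x)


def simulate_source_dynamics(net: GroundTruthNetwork, n_samples: int,
                             fs: float, seed: int,
                             theta_amp=0.0, theta_freq: float = 4.5,
                             burn_in: int = 500):
    """Simulate the nonlinear MVAR recursion.

    ``x_i(t) = sum_k sum_j A[k,i,j] x_j(t-k) + sum(nl terms -> i) +
    theta drive_i(t) + eps_i(t)`` with Gaussian innovations of SD
    ``net.noise_sd``. ``theta_amp`` (scalar or per-node array) adds a
    deterministic sinusoidal drive at ``theta_freq`` Hz, giving each node
    an oscillatory theta component for source-localization fixtures.

    Returns ``(x, adjacency)`` where ``x`` is (K, n_samples) and
    ``adjacency`` is the ground-truth boolean edge dict.
    """
    rng = np.random.default_rng(seed)
    k, lag_max = net.n_nodes, net.max_lag
    total = n_samples + burn_in
    theta_amp = np.broadcast_to(np.asarray(theta_amp, dtype=float), (k,))
    phases = rng.uniform(0, 2 * np.pi, size=k)
    tgrid = np.arange(total) / fs
    drive = theta_amp[:, None] * np.sin(
        2 * np.pi * theta_freq * tgrid[None, :] + phases[:, None])
    eps = rng.normal(0.0, net.noise_sd, size=(k, total))

    x = np.zeros((k, total))
    nl_by_target = {}
    for term in net.nl_terms:
        nl_by_target.setdefault(term.target, []).append(term)
    for t in range(lag_max, total):
        # hist[k-1] is x(t-k) as a K-vector
        hist = x[:, t - lag_max:t][:, ::-1].T
        new = eps[:, t] + drive[:, t]
        for lag in range(net.order):
            new = new + net.lin_coeffs[lag] @ hist[lag]
        for i, terms in nl_by_target.items():
            for term in terms:
                new[i] += _nl_contribution(term, hist)
        if not np.all(np.isfinite(new)):
            raise StabilityError(
                "simulation diverged; nonlinear gains too large for the "
                f"linear backbone (spectral radius "
                f"{net.spectral_radius():.3f})"
            )
        x[:, t] = new
    return x[:, burn_in:], net.adjacency()


# ---------------------------------------------------------------------------
# Toy head model
# ---------------------------------------------------------------------------

@dataclass
class ToyHeadModel:
    """Spherical-shell sensor array over a cubic voxel grid.

    The gain of voxel ``v`` at sensor ``s`` is a smooth decreasing function
    of their distance, so nearby voxels have similar (but never collinear)
    topographies — enough structure for beamformer validation without any
    boundary-element modeling.
    """

    leadfield: np.ndarray         # sensors x voxels
    voxel_coords: np.ndarray      # voxels x 3, mm
    voxel_labels: list            # region label per voxel
    sensor_names: list
    sensor_coords: np.ndarray     # sensors x 3, mm
    grid_spacing: float

    def __post_init__(self):
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=float)
        if self.leadfield.shape != (len(self.sensor_names),
                                    len(self.voxel_labels)):
            raise ConfigurationError("leadfield shape inconsistent with names")
        if self.voxel_coords.shape != (self.leadfield.shape[1], 3):
            raise ConfigurationError("voxel_coords must be (n_voxels, 3)")
        norms = np.linalg.norm(self.leadfield, axis=0)
        if np.any(norms == 0.0):
            raise ConfigurationError("leadfield has an all-zero column")
        if len(np.unique(self.voxel_coords, axis=0)) != len(self.voxel_coords):
            raise ConfigurationError("voxel coordinates must be unique")

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.leadfield.shape[1]

    def region_voxels(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.voxel_labels) == label)

    def region_seed_voxel(self, label: str) -> int:
        """Voxel of a region closest to the region's centroid."""
        idx = self.region_voxels(label)
        if idx.size == 0:
            raise ConfigurationError(f"no voxels labeled {label!r}")
        centroid = self.voxel_coords[idx].mean(axis=0)
        d = np.linalg.norm(self.voxel_coords[idx] - centroid, axis=1)
        return int(idx[np.argmin(d)])

    def posterior_sensors(self, n: int = 6) -> np.ndarray:
        """Indices of the ``n`` most posterior sensors (lowest y)."""
        return np.argsort(self.sensor_coords[:, 1])[:n]


def _fibonacci_hemisphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere of a sphere."""
    i = np.arange(n)
    z = (i + 0.5) / n                       # upper hemisphere only
    phi = np.pi * (1 + 5 ** 0.5) * i
    r_xy = np.sqrt(1 - z ** 2)
    pts = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    return pts * radius


def _label_voxel(coord: np.ndarray, r_subcortical: float) -> str:
    x, y, z = coord
    if np.linalg.norm(coord) < r_subcortical:
        return "SUBCORTICAL"
    if x <= 0:
        return "OTHER"
    if y > 15:
        return "IFC"
    if z <= 0:
        return "ATL"
    return "IC"


def make_toy_leadfield(n_sensors: int = 60, grid_shape=(6, 6, 6),
                       seed: int = 0, head_radius: float = 100.0,
                       grid_extent: float = 60.0,
                       r_subcortical: float = 25.0) -> ToyHeadModel:
    """Build a deterministic toy head model.

    Sensors sit on the upper hemisphere of a 100 mm shell (Fibonacci
    layout plus a small seeded jitter); voxels form a cubic grid spanning
    ±``grid_extent`` mm. Gains fall off as a bounded inverse square of the
    sensor–voxel distance. Voxels are partitioned into right-hemisphere
    ``ATL``/``IC``/``IFC`` stand-ins plus ``OTHER`` and a central
    ``SUBCORTICAL`` core that downstream ROI construction excludes.
    """
    if n_sensors < 8:
        raise ConfigurationError("need at least 8 sensors")
    if min(grid_shape) < 4:
        raise ConfigurationError("grid must be at least 4 x 4 x 4")
    rng = np.random.default_rng(seed)
    sens = _fibonacci_hemisphere(n_sensors, head_radius)
    sens = sens + rng.normal(0.0, 0.5, size=sens.shape)
    d_sens = np.linalg.norm(sens[:, None] - sens[None, :], axis=-1)
    np.fill_diagonal(d_sens, np.inf)
    if d_sens.min() < 1.0:     # mm: physically coincident electrodes
        raise GeometryError("coincident sensors in generated layout")

    axes = [np.linspace(-grid_extent, grid_extent, s) for s in grid_shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    spacing = float(np.min([np.diff(a).min() for a in axes]))
    labels = [_label_voxel(c, r_subcortical) for c in grid]

    d = np.linalg.norm(sens[:, None, :] - grid[None, :, :], axis=-1)
    # bounded inverse-square falloff; the 60 mm scale keeps the gain
    # dynamic range moderate so the beamformer's depth bias stays bounded
    gain = 1.0 / (1.0 + (d / 60.0) ** 2)
    names = [f"E{i + 1:02d}" for i in range(n_sensors)]
    return ToyHeadModel(gain, grid, labels, names, sens, spacing)


def save_head_model(head: ToyHeadModel, directory: str) -> None:
    """Persist a head model as a TSV/JSON bundle (plain text)."""
    import os

    os.makedirs(directory, exist_ok=True)
    pd.DataFrame(head.leadfield, index=head.sensor_names).to_csv(
        os.path.join(directory, "leadfield.tsv"), sep="\t", header=False)
    vox = pd.DataFrame(head.voxel_coords, columns=["x", "y", "z"])
    vox["label"] = head.voxel_labels
    vox.to_csv(os.path.join(directory, "voxels.tsv"), sep="\t", index=False)
    sens = pd.DataFrame(head.sensor_coords, columns=["x", "y", "z"])
    sens.insert(0, "name", head.sensor_names)
    sens.to_csv(os.path.join(directory, "sensors.tsv"), sep="\t", index=False)
    with open(os.path.join(directory, "meta.json"), "w") as f:
        json.dump({"grid_spacing": head.grid_spacing}, f)


def load_head_model(directory: str) -> ToyHeadModel:
    import os

    lf = pd.read_csv(os.path.join(directory, "leadfield.tsv"), sep="\t",
                     header=None, index_col=0)
    vox = pd.read_csv(os.path.join(directory, "voxels.tsv"), sep="\t")
    sens = pd.read_csv(os.path.join(directory, "sensors.tsv"), sep="\t")
    with open(os.path.join(directory, "meta.json")) as f:
        meta = json.load(f)
    return ToyHeadModel(lf.to_numpy(), vox[["x", "y", "z"]].to_numpy(),
                        vox["label"].tolist(), lf.index.tolist(),
                        sens[["x", "y", "z"]].to_numpy(),
                        meta["grid_spacing"])


# ---------------------------------------------------------------------------
# Tagged sensor EEG
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, shape, exponent: float = 1.0
                      ) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit SD."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = scale[1] if len(scale) > 1 else 1.0
    shaped = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd == 0, 1.0, sd)


def simulate_tagged_eeg(task: TaskConfig, head: ToyHeadModel,
                        net: GroundTruthNetwork, ssvep_amp: float = 3.0,
                        snr: float = 3.0, seed: int = 0, fs: float = 500.0,
                        accuracy: float = 0.97, source_rms: float = 1.5,
                        source_theta_amp: float = 1.0,
                        n_tagged_sensors: int = 6,
                        alpha_sd_ratio: float = 2.0,
                        alpha_band=(8.0, 12.0),
                        anticipatory_frac: float = 0.6,
                        anticipatory_ramp_ms=(150.0, 650.0),
                        return_components: bool = False):
    """Simulate one continuous frequency-tagged session.

    During the action-effect interval of correct trials the
    ``n_tagged_sensors`` most posterior sensors carry a sinusoid at the
    trial's flicker frequency (amplitude ``ssvep_amp`` µV) plus its first
    harmonic 6 dB down — the physically driven steady-state response.
    During the cue period the same sensors carry an *anticipatory*
    frequency-tagged component at ``anticipatory_frac`` of the flicker
    amplitude, ramping up linearly over ``anticipatory_ramp_ms`` after
    cue onset: endogenous reactivation of the expected action effect
    builds up after the cue rather than switching on instantaneously, and
    an instantaneous onset would smear tagged power backwards (by the
    wavelet length) into the pre-cue normalization window. Network source dynamics are projected through the
    leadfield at each region's seed voxel and scaled to ``source_rms`` µV.
    Sensor noise is 1/f-shaped Gaussian with SD ``ssvep_amp / snr`` (or
    1 µV when ``ssvep_amp`` is zero) plus an ongoing narrowband alpha
    background (``alpha_band``, SD ``alpha_sd_ratio`` times the broadband
    noise SD) — without that resting alpha floor, harmonic leakage from
    the flicker would dominate relative power change at the upper
    measured frequency, which is not the regime of human occipital EEG.

    Event codes: ``"S  1"``/``"S  2"`` at cue onset for the first/second
    flicker frequency, ``"R  1"``/``"R  2"`` at effect onset.

    Returns ``(raw, events_df)``; with ``return_components=True`` a third
    element holds the additive parts (``source``, ``ssvep``, ``noise``)
    for energy accounting.
    """
    if net.n_nodes != len(net.node_names):
        raise ConfigurationError("network node names inconsistent")
    missing = [nm for nm in net.node_names
               if nm not in set(head.voxel_labels)]
    if missing:
        raise ConfigurationError(
            f"head model has no voxels for node regions {missing}"
        )
    rng = np.random.default_rng(seed)
    events_df = simulate_trial_events(task, seed=int(rng.integers(2 ** 31)),
                                      accuracy=accuracy, fs=fs)
    trial_smp = int(round(task.trial_duration_ms / 1000.0 * fs))
    total = task.n_trials * trial_smp

    src, _ = simulate_source_dynamics(
        net, total, fs, seed=int(rng.integers(2 ** 31)),
        theta_amp=source_theta_amp)
    node_vox = [head.region_seed_voxel(nm) for nm in net.node_names]
    proj = head.leadfield[:, node_vox] @ src
    rms = np.sqrt(np.mean(proj ** 2))
    if rms > 0:
        proj *= source_rms / rms

    tagged = head.posterior_sensors(n_tagged_sensors)
    ssvep = np.zeros((head.n_sensors, total))
    cue_smp = int(round(task.cue_duration_ms / 1000.0 * fs))
    eff_smp = int(round(task.effect_duration_ms / 1000.0 * fs))
    tgrid = np.arange(total) / fs
    if ssvep_amp > 0:
        r0, r1 = anticipatory_ramp_ms
        for _, row in events_df.iterrows():
            f = row.flicker_freq
            cue_a = int(row.cue_onset_sample)
            spans = [(cue_a, cue_a + cue_smp, True)]
            if np.isfinite(row.effect_onset_sample):
                a = int(row.effect_onset_sample)
                spans.append((a, min(a + eff_smp, total), False))
            for a, b, anticipatory in spans:
                t = tgrid[a:b]
                amp = ssvep_amp
                if anticipatory:
                    rel_ms = (np.arange(b - a) / fs) * 1000.0
                    ramp = np.clip((rel_ms - r0) / (r1 - r0), 0.0, 1.0)
                    amp = ssvep_amp * anticipatory_frac * ramp
                wave = (amp * np.sin(2 * np.pi * f * t)
                        + 0.5 * amp * np.sin(2 * np.pi * 2 * f * t))
                ssvep[np.ix_(tagged, np.arange(a, b))] += wave[None, :]

    noise_sd = ssvep_amp / snr if ssvep_amp > 0 else 1.0
    noise = noise_sd * _one_over_f_noise(rng, (head.n_sensors, total))
    if alpha_sd_ratio > 0:
        from scipy import signal as _sig

        sos = _sig.butter(4, alpha_band, btype="bandpass", fs=fs,
                          output="sos")
        alpha = _sig.sosfiltfilt(
            sos, rng.standard_normal((head.n_sensors, total)), axis=1)
        alpha /= alpha.std(axis=1, keepdims=True)
        noise = noise + alpha_sd_ratio * noise_sd * alpha

    data = proj + ssvep + noise
    events = []
    for _, row in events_df.iterrows():
        code_idx = list(task.flicker_freqs).index(row.flicker_freq) + 1
        events.append((int(row.cue_onset_sample), f"S  {code_idx}"))
        if np.isfinite(row.effect_onset_sample):
            events.append((int(row.effect_onset_sample), f"R  {code_idx}"))
    raw = RawRecording(data, fs, list(head.sensor_names), sorted(events))
    if return_components:
        return raw, events_df, {"source": proj, "ssvep": ssvep,
                                "noise": noise}
    return raw, events_df


# ---------------------------------------------------------------------------
# Two-condition study generator
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Within-subject two-condition study with a phase-specific coupling
    asymmetry.

    ``asymmetry`` maps ``(condition, phase)`` to the linear gains
    ``(g_ab, g_ba)`` of the ATL->IFC / IFC->ATL edge pair. The default
    places a strong asymmetry only in the active condition's perception
    phase, emulating a condition-by-phase reorganization of directed
    communication with a known direction of truth; every other cell is
    symmetric.
    """

    n_subjects: int = 12
    conditions: tuple = ("placebo", "mph")
    phases: tuple = ("planning", "standby", "perception")
    n_samples_per_cell: int = 2000
    fs: float = 256.0
    order: int = 3
    sym_gain: float = 0.25
    asym_gains: tuple = (0.45, 0.08)
    subject_jitter_sd: float = 0.08
    reversed_cell: tuple = ("mph", "perception")

    def edge_gains(self, condition: str, phase: str):
        if (condition, phase) == tuple(self.reversed_cell):
            return self.asym_gains
        return (self.sym_gain, self.sym_gain)


def _study_network(cfg: StudyConfig, condition: str, phase: str,
                   subject_rng: np.random.Generator) -> GroundTruthNetwork:
    """One cell's ground-truth network.

    All background coupling is bidirectionally symmetric in expectation
    (independent per-subject jitter on each direction), so the only
    systematic directional asymmetry in the whole study is the configured
    ATL<>IFC gain pair of the reversed cell. A symmetric saturating
    (tanh) pair on IC<>IFC gives the nonlinear estimator genuine but
    direction-balanced curvature to chew on.
    """
    g_ab, g_ba = cfg.edge_gains(condition, phase)
    jit = 1.0 + cfg.subject_jitter_sd * subject_rng.standard_normal(6)
    A = np.zeros((cfg.order, 3, 3))
    for lag, c in enumerate([0.4, -0.2, 0.08][:cfg.order]):
        A[lag, np.arange(3), np.arange(3)] = c
    A[0, 2, 0] = g_ab * jit[0]          # ATL -> IFC
    A[0, 0, 2] = g_ba * jit[1]          # IFC -> ATL
    A[0, 1, 0] = 0.15 * jit[2]          # ATL <> IC, symmetric background
    A[0, 0, 1] = 0.15 * jit[3]
    nl = (NonlinearTerm("tanh", target=2, source=1, gain=0.3 * jit[4], lag=1),
          NonlinearTerm("tanh", target=1, source=2, gain=0.3 * jit[5], lag=1))
    return GroundTruthNetwork(A, nl, noise_sd=1.0)


def simulate_study_cell(cfg: StudyConfig, subject: int, condition: str,
                        phase: str, seed: int):
    """ROI-level node series for one subject x condition x phase cell.

    The subject's coupling jitter is derived from ``(seed, subject)`` only,
    so a subject keeps the same idiosyncratic network across conditions and
    phases (a within-subject design); innovation noise differs per cell.

    Returns ``(series, network)`` with ``series`` shaped (3, n_samples).
    """
    if condition not in cfg.conditions or phase not in cfg.phases:
        raise ConfigurationError(f"unknown cell ({condition!r}, {phase!r})")
    subj_rng = np.random.default_rng(
        np.random.SeedSequence([seed, subject, 9151]))
    net = _study_network(cfg, condition, phase, subj_rng)
    cell_seed = int(np.random.default_rng(np.random.SeedSequence(
        [seed, subject, cfg.conditions.index(condition),
         cfg.phases.index(phase)])).integers(2 ** 31))
    x, _ = simulate_source_dynamics(net, cfg.n_samples_per_cell, cfg.fs,
                                    seed=cell_seed, theta_amp=0.8)
    return x, net


def simulate_behavior(n_subjects: int = 54, seed: int = 0,
                      rt_means=(293.24, 276.69), rt_between_sd: float = 50.0,
                      rt_diff_sd: float = 31.0,
                      acc_means=(0.97, 0.98), acc_diff_sd: float = 0.042
                      ) -> pd.DataFrame:
    """Per-subject behavioral summaries for a paired two-condition design.

    Defaults encode a ~16.5 ms reaction-time speedup in the second
    (active) condition with a between-subject SD of 50 ms and a paired
    difference SD of 31 ms, and a 1-percentage-point accuracy difference
    whose paired SD (0.042) leaves it at the edge of detectability — the
    regime of a mild pharmacological effect on speed without a clear
    accuracy trade-off. The difference SDs are matched to the paired
    statistics such a study reports at n = 54.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(np.mean(rt_means), rt_between_sd, size=n_subjects)
    half = (rt_means[0] - rt_means[1]) / 2.0
    e = rng.normal(0.0, rt_diff_sd / np.sqrt(2), size=(2, n_subjects))
    rt_a = base + half + e[0]
    rt_b = base - half + e[1]
    acc_e = rng.normal(0.0, acc_diff_sd / np.sqrt(2), size=(2, n_subjects))
    acc_a = np.clip(acc_means[0] + acc_e[0], 0.0, 1.0)
    acc_b = np.clip(acc_means[1] + acc_e[1], 0.0, 1.0)
    return pd.DataFrame({
        "subject": np.arange(n_subjects),
        "rt_placebo": rt_a, "rt_mph": rt_b,
        "acc_placebo": acc_a, "acc_mph": acc_b,
    })
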