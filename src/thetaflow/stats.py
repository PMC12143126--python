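"""Surrogate significance testing and the paired/Bayesian inference layer.

Edge-level significance uses circular time-shift surrogates: the series is
cut into consecutive windows of half a cycle of the lowest frequency of
interest (4.5 Hz), each window of each channel is circularly shifted by an
independent uniform offset, and the connectivity estimator is re-run with
identical configuration on each surrogate; an edge is significant when the
observed value exceeds the 95th percentile of its surrogate null.

Group inference on bidirectional connectivity differences uses paired
t-tests with Benjamini-Hochberg FDR, the paired effect size d = |t|/sqrt(n),
and the default two-sided JZS Bayes factor (Cauchy effect-size prior of
scale sqrt(2)/2) with Jeffreys evidence labels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    CompletenessError,
    ConfigurationError,
    NumericalError,
    PairingError,
)
from . import ncreann

__all__ = [
    "StatRow",
    "circular_shift_surrogate",
    "surrogate_edge_test",
    "paired_bidirectional_test",
    "fdr_bh",
    "cohens_d_paired",
    "jzs_bayes_factor",
    "bf_evidence_label",
    "behavioral_stats",
    "build_table1_report",
    "report_to_markdown",
]

JZS_PRIOR_SCALE = np.sqrt(2.0) / 2.0


@dataclass
class StatRow:
    """One bidirectional connectivity comparison (one report row)."""

    condition: str
    linearity: str                # "linear" or "nonlinear"
    phase: str
    connection: str               # e.g. "ATL <> IFC"
    mean_ab: float
    sem_ab: float
    mean_ba: float
    sem_ba: float
    t: float
    df: int
    p: float
    p_fdr: float
    d: float
    bf10: float
    evidence: str
    significant: bool


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

def circular_shift_surrogate(series: np.ndarray, fs: float,
                             f_min: float = 4.5, seed=0) -> np.ndarray:
    """Segment-wise circular time-shift surrogate.

    The series is divided into consecutive windows of
    ``round(fs / (2 f_min))`` samples — half a cycle of the lowest
    frequency of interest. Within each window, every channel is rolled by
    an independent uniform circular shift, which preserves each window's
    sample multiset (hence mean and variance exactly, and local spectra
    approximately) while destroying consistent cross-channel lag
    structure. A trailing partial window is shifted within its own length.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ConfigurationError("series must be K x T")
    rng = seed if hasattr(seed, "integers") else np.random.default_rng(seed)
    k, t_len = series.shape
    seg = int(round(fs / (2.0 * f_min)))
    if seg < 1 or t_len < seg:
        raise ConfigurationError(
            f"series of {t_len} samples shorter than one {seg}-sample window"
        )
    out = series.copy()
    for a in range(0, t_len, seg):
        b = min(a + seg, t_len)
        length = b - a
        if length < 2:
            continue
        shifts = rng.integers(0, length, size=k)
        for ch in range(k):
            out[ch, a:b] = np.roll(out[ch, a:b], shifts[ch])
    return out


def surrogate_edge_test(series, fs: float, n_surr: int = 100, seed: int = 0,
                        f_min: float = 4.5, percentile: float = 95.0,
                        model_kwargs: dict | None = None) -> dict:
    """Edge significance against a circular-shift surrogate null.

    Fits the nonlinear MVAR network once on the observed series and once
    per surrogate with *identical* hyperparameters and initialization
    seed, collecting linear and nonlinear connectivity matrices. An edge
    is significant when its observed value exceeds the ``percentile``-th
    percentile (linear-interpolation definition) of its ``n_surr``
    surrogate values. A divergent surrogate fit is redrawn once; a second
    failure is a hard error.

    Returns observed matrices, null arrays (n_surr x K x K), thresholds
    and boolean significance flags per edge, keyed by
    ``"linear"``/``"nonlinear"``.
    """
    if n_surr < 1:
        raise ConfigurationError("n_surr must be >= 1")
    series = np.asarray(series, dtype=float)
    model_kwargs = dict(model_kwargs or {})
    model_kwargs.setdefault("seed", 12345)
    rng = np.random.default_rng(seed)

    model = ncreann.train_nmvar(series, **model_kwargs)
    observed = {"linear": ncreann.linear_connectivity(model, series),
                "nonlinear": ncreann.nonlinear_connectivity(model, series)}
    k = series.shape[0]
    null = {"linear": np.empty((n_surr, k, k)),
            "nonlinear": np.empty((n_surr, k, k))}
    for s in range(n_surr):
        for attempt in range(2):
            surr = circular_shift_surrogate(series, fs, f_min, seed=rng)
            try:
                smodel = ncreann.train_nmvar(surr, **model_kwargs)
                null["linear"][s] = ncreann.linear_connectivity(smodel, surr)
                null["nonlinear"][s] = ncreann.nonlinear_connectivity(
                    smodel, surr)
                break
            except NumericalError:
                if attempt == 1:
                    raise NumericalError(
                        f"surrogate fit {s} diverged twice"
                    ) from None
    result = {"observed": observed, "null": null, "n_surr": n_surr,
              "percentile": percentile, "threshold": {}, "significant": {}}
    for key in ("linear", "nonlinear"):
        thresh = np.percentile(null[key], percentile, axis=0)
        sig = observed[key] > thresh
        sig &= ~np.isnan(observed[key])
        result["threshold"][key] = thresh
        result["significant"][key] = sig
    return result


# ---------------------------------------------------------------------------
# Frequentist and Bayesian paired inference
# ---------------------------------------------------------------------------

def paired_bidirectional_test(values_ab, values_ba) -> dict:
    """Two-sided paired t-test of edge a->b against edge b->a.

    Returns ``t``, ``df``, ``p`` plus per-direction mean and SEM. Zero
    variance of the paired differences yields an undefined statistic
    (``defined=False``, NaNs) that callers must exclude from any FDR
    family.
    """
    a = np.asarray(values_ab, dtype=float)
    b = np.asarray(values_ba, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError("paired vectors must be 1-D and equal length")
    n = len(a)
    if n < 3:
        raise PairingError("need at least 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    out = {
        "n": n, "df": n - 1,
        "mean_ab": float(a.mean()), "sem_ab": float(sps.sem(a)),
        "mean_ba": float(b.mean()), "sem_ba": float(sps.sem(b)),
    }
    if sd == 0:
        if diff.mean() == 0:
            # identical directions: no evidence of a difference
            out.update({"t": 0.0, "p": 1.0, "defined": True})
        else:
            # constant nonzero shift: t is undefined, exclude from FDR
            out.update({"t": np.nan, "p": np.nan, "defined": False})
        return out
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    out.update({"t": float(t), "p": float(p), "defined": True})
    return out


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigurationError("p-values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d_paired(t: float, n: int) -> float:
    """Paired-design effect size from the t statistic: d = |t| / sqrt(n)."""
    if n < 2:
        raise ConfigurationError("need n >= 2")
    return abs(float(t)) / np.sqrt(n)


def jzs_bayes_factor(t: float, n: int,
                     prior_scale: float = JZS_PRIOR_SCALE) -> float:
    """Default two-sided JZS Bayes factor for a one-sample/paired t test.

    The alternative places a Cauchy(0, ``prior_scale``) prior on the
    standardized effect size, equivalently a normal prior with variance g
    mixed over g ~ InverseGamma(1/2, prior_scale^2/2). BF10 is the ratio
    of the marginal likelihood of the observed t under that mixture to its
    likelihood under the point null, evaluated by adaptive quadrature.
    """
    if n < 2:
        raise ConfigurationError("need n >= 2")
    t = float(t)
    nu = n - 1
    r2 = prior_scale ** 2

    def integrand(g):
        ig = (np.sqrt(r2 / 2.0) / np.sqrt(np.pi) * g ** -1.5
              * np.exp(-r2 / (2.0 * g)))
        return ((1.0 + n * g) ** -0.5
                * (1.0 + t * t / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
                * ig)

    num, err = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-9,
                              epsabs=0.0, limit=300)
    if num <= 0 or not np.isfinite(num) or err > 1e-6 * num:
        raise NumericalError(
            f"Bayes-factor quadrature failed (value {num!r}, error {err!r})"
        )
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return float(num / den)


def bf_evidence_label(bf10: float) -> str:
    """Jeffreys evidence label, e.g. ``"strong H1"`` or ``"moderate H0"``.

    Direction is H1 when BF10 > 1, H0 otherwise (BF10 = 1 counts as
    anecdotal H0 by convention); strength bands apply to
    ``max(BF10, 1/BF10)``: 1-3 anecdotal, 3-10 moderate, 10-30 strong,
    30-100 very strong, above 100 extreme.
    """
    bf10 = float(bf10)
    if not bf10 > 0:
        raise ConfigurationError("BF10 must be positive")
    direction = "H1" if bf10 > 1.0 else "H0"
    mag = max(bf10, 1.0 / bf10)
    if mag <= 3.0:
        label = "anecdotal"
    elif mag <= 10.0:
        label = "moderate"
    elif mag <= 30.0:
        label = "strong"
    elif mag <= 100.0:
        label = "very strong"
    else:
        label = "extreme"
    return f"{label} {direction}"


def behavioral_stats(behavior: pd.DataFrame,
                     conditions=("placebo", "mph")) -> pd.DataFrame:
    """Paired comparison of per-subject mean RT and accuracy.

    Expects columns ``rt_<condition>`` and ``acc_<condition>`` with one
    row per subject. Returns one row per measure with per-condition
    mean ± SEM, paired t, df, p, and d.
    """
    rows = []
    for measure, prefix in (("rt", "rt"), ("accuracy", "acc")):
        cols = [f"{prefix}_{c}" for c in conditions]
        for col in cols:
            if col not in behavior.columns:
                raise PairingError(f"missing column {col!r}")
        a = behavior[cols[0]].to_numpy(dtype=float)
        b = behavior[cols[1]].to_numpy(dtype=float)
        if np.any(np.isnan(a)) or np.any(np.isnan(b)):
            raise PairingError("unpaired subjects (NaN entries)")
        res = paired_bidirectional_test(a, b)
        d = cohens_d_paired(res["t"], res["n"]) if res["defined"] else np.nan
        rows.append({
            "measure": measure,
            f"mean_{conditions[0]}": res["mean_ab"],
            f"sem_{conditions[0]}": res["sem_ab"],
            f"mean_{conditions[1]}": res["mean_ba"],
            f"sem_{conditions[1]}": res["sem_ba"],
            "t": res["t"], "df": res["df"], "p": res["p"], "d": d,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["condition", "linearity", "phase", "connection",
                  "mean_ab", "sem_ab", "mean_ba", "sem_ba", "t", "df",
                  "p", "p_fdr", "d", "bf10", "evidence", "significant"]


def build_table1_report(rows, conditions=("placebo", "mph"),
                        linearities=("linear", "nonlinear"),
                        phases=("planning", "standby", "perception"),
                        connections=("ATL <> IC", "ATL <> IFC", "IC <> IFC")
                        ) -> pd.DataFrame:
    """Assemble the full bidirectional-connectivity report.

    ``rows`` is an iterable of :class:`StatRow` (or dicts with the same
    fields). Every cell of condition x linearity x phase x connection must
    be present exactly once; missing cells raise a
    :class:`CompletenessError` listing them.
    """
    records = []
    for r in rows:
        records.append(r.__dict__ if isinstance(r, StatRow) else dict(r))
    if not records:
        raise CompletenessError("report received no rows")
    df = pd.DataFrame(records)
    expected = {(c, l, ph, co) for c in conditions for l in linearities
                for ph in phases for co in connections}
    got = set(zip(df.condition, df.linearity, df.phase, df.connection))
    missing = sorted(expected - got)
    if missing:
        raise CompletenessError(f"missing report cells: {missing}")
    df = df[REPORT_COLUMNS].copy()
    for col, cats in (("linearity", linearities), ("condition", conditions),
                      ("phase", phases), ("connection", connections)):
        df[col] = pd.Categorical(df[col], categories=list(cats), ordered=True)
    df = df.sort_values(["linearity", "condition", "phase", "connection"],
                        kind="stable").reset_index(drop=True)
    for col in ("linearity", "condition", "phase", "connection"):
        df[col] = df[col].astype(str)
    return df


def report_to_markdown(report: pd.DataFrame) -> str:
    """Markdown rendering; significant rows (p_fdr < .05) are bolded."""
    lines = ["| " + " | ".join(REPORT_COLUMNS) + " |",
             "|" + "---|" * len(REPORT_COLUMNS)]
    for _, r in report.iterrows():
        cells = []
        for col in REPORT_COLUMNS:
            v = r[col]
            if isinstance(v, float):
                v = f"{v:.3g}"
            cells.append(f"**{v}**" if r["significant"] and col in
                         ("t", "p_fdr", "connection") else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
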