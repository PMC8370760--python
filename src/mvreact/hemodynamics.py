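"""Single-trial amplitude estimation from windowed vertex time-series.

Retrieval trials are 16-sample windows on a 2-s grid spanning -2 s to
+30 s around the cue.  Each trial window is modelled with two regressors
— the expected hemodynamic response to the 6-s imagery period and to the
3-s old/new probe — built by convolving dense impulse trains (10/s) with
the canonical double-gamma response.  The per-trial OLS "recall" beta is
the amplitude used by all downstream decoding.

Encoding runs use the least-squares-sum (LSS) scheme: one GLM per trial
with the target trial's regressor plus the summed regressor of every
other trial, which stabilises single-trial betas under overlapping
responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "TrialWindow",
    "Regressor",
    "canonical_hrf",
    "build_regressor",
    "estimate_recall_betas",
    "lss_betas",
    "trial_window_times",
]

# Canonical double-gamma parameters (response delay 6, undershoot delay 16,
# unit dispersions, undershoot ratio 1/6).
_PEAK_DELAY = 6.0
_UNDER_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDER_DISP = 1.0
_RATIO = 6.0

_IMPULSE_RATE = 10.0  # impulses per second in the task-period delta train


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    ``h(t) = g(t; 6, 1) - g(t; 16, 1)/6`` with gamma densities, evaluated
    at ``t`` seconds post-impulse.  ``h(0) = 0`` and the peak sits near 5 s.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("canonical_hrf is defined for t >= 0")
    h = (_gamma.pdf(t, _PEAK_DELAY / _PEAK_DISP, scale=_PEAK_DISP)
         - _gamma.pdf(t, _UNDER_DELAY / _UNDER_DISP, scale=_UNDER_DISP) / _RATIO)
    # normalize by the analytic peak on a dense grid (cached)
    return h / _hrf_peak()


_PEAK_CACHE: list[float] = []


def _hrf_peak() -> float:
    if not _PEAK_CACHE:
        tt = np.arange(0.0, 32.0, 0.001)
        raw = (_gamma.pdf(tt, _PEAK_DELAY, scale=_PEAK_DISP)
               - _gamma.pdf(tt, _UNDER_DELAY, scale=_UNDER_DISP) / _RATIO)
        _PEAK_CACHE.append(float(raw.max()))
    return _PEAK_CACHE[0]


def trial_window_times(cue_onset_s: float = 0.0, n_samples: int = 16,
                       spacing_s: float = 2.0, pre_s: float = 2.0) -> np.ndarray:
    """Sample times of a trial window: 16 samples from -2 s to +28 s on a 2-s grid."""
    return cue_onset_s - pre_s + spacing_s * np.arange(n_samples)


@dataclass
class TrialWindow:
    """One trial's windowed activity: 16 samples x vertices on a 2-s grid."""

    samples: np.ndarray = field(repr=False)  # n_samples x n_vertices
    cue_onset_s: float = 0.0
    sample_spacing_s: float = 2.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != 16:
            raise ValueError(
                f"a trial window has exactly 16 samples, got {self.samples.shape[0]}"
            )

    @property
    def times(self) -> np.ndarray:
        return trial_window_times(self.cue_onset_s, self.samples.shape[0],
                                  self.sample_spacing_s)


@dataclass
class Regressor:
    """An HRF-convolved impulse-train regressor sampled on the trial grid."""

    task: str
    impulse_times_s: np.ndarray
    sample_times_s: np.ndarray
    values: np.ndarray

    @property
    def n_impulses(self) -> int:
        return len(self.impulse_times_s)


def build_regressor(onset_s: float, duration_s: float,
                    sample_times: np.ndarray, task: str = "recall",
                    rate: float = _IMPULSE_RATE) -> Regressor:
    """Expected response to a task period: impulses every 1/rate s, HRF-convolved.

    Impulses run from ``onset_s`` to ``onset_s + duration_s`` inclusive, so a
    6-s period at 10/s gives 61 impulses and a 3-s period gives 31.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    n_imp = int(round(duration_s * rate)) + 1
    impulses = onset_s + np.arange(n_imp) / rate
    sample_times = np.asarray(sample_times, dtype=float)
    lags = sample_times[:, None] - impulses[None, :]
    vals = np.zeros_like(lags)
    pos = lags >= 0
    if pos.any():
        vals[pos] = canonical_hrf(lags[pos])
    return Regressor(task=task, impulse_times_s=impulses,
                     sample_times_s=sample_times, values=vals.sum(axis=1))


def _ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    return beta


def estimate_recall_betas(window: TrialWindow, recall_reg: Regressor,
                          probe_reg: Regressor) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex OLS betas for the recall and probe regressors of one trial.

    The 16-sample window is regressed on [intercept, recall, probe]; the
    recall beta is the amplitude carried forward to decoding.  A collinear
    design raises.
    """
    X = np.column_stack([
        np.ones(window.samples.shape[0]),
        recall_reg.values,
        probe_reg.values,
    ])
    beta = _ols(X, window.samples)
    return beta[1], beta[2]


def lss_betas(run_series: np.ndarray, trial_onsets: np.ndarray,
              sample_times: np.ndarray, duration_s: float = 1.8,
              task: str = "encode") -> np.ndarray:
    """Least-squares-sum single-trial betas for an encoding run.

    For each trial the GLM has three columns: the target trial's regressor,
    the sum of all other trials' regressors, and an intercept; the target
    beta is retained.  Returns a trials x vertices matrix.
    """
    run_series = np.atleast_2d(np.asarray(run_series, dtype=float))
    trial_onsets = np.asarray(trial_onsets, dtype=float)
    n_trials = len(trial_onsets)
    if n_trials < 2:
        raise ValueError("LSS needs at least 2 trials (one target, one 'others' sum)")
    regs = np.column_stack([
        build_regressor(t0, duration_s, sample_times, task=task).values
        for t0 in trial_onsets
    ])
    total = regs.sum(axis=1)
    betas = np.empty((n_trials, run_series.shape[1]))
    ones = np.ones(len(sample_times))
    for i in range(n_trials):
        X = np.column_stack([regs[:, i], total - regs[:, i], ones])
        betas[i] = _ols(X, run_series)[0]
    return betas
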