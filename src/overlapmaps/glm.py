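"""Single-trial (least-squares-separate) and run-level GLM estimation.

Each single-trial model regresses the run's time series on the trial of
interest and a second regressor pooling all other trials, alongside optional
nuisance terms (motion parameters, one unit-impulse column per flagged
outlier frame), discrete-cosine high-pass drift regressors (100 s cutoff)
and an intercept.  Events are convolved with a double-gamma canonical HRF.
The per-voxel t statistic of the trial regressor (beta / SE under OLS) is the
trial's pattern value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor


@dataclass
class DesignMatrixSpec:
    """Options shared by the single-trial and run-level designs."""

    hrf_model: str = "spm"  # SPM-style double gamma (peak ~6 s, undershoot ~16 s)
    highpass_cutoff_s: float | None = 100.0
    motion: np.ndarray | None = None  # (n_scans, 6)
    outlier_frames: tuple[int, ...] = ()


def hrf_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times: np.ndarray,
    amplitudes: np.ndarray | None = None,
    hrf_model: str = "spm",
) -> np.ndarray:
    """One HRF-convolved boxcar regressor for a set of events."""
    onsets = np.atleast_1d(np.asarray(onsets, float))
    durations = np.atleast_1d(np.asarray(durations, float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    reg, _ = compute_regressor(
        np.vstack([onsets, durations, amplitudes]), hrf_model, frame_times
    )
    return reg[:, 0]


def trial_design(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times: np.ndarray,
    hrf_model: str = "spm",
) -> np.ndarray:
    """(n_scans, n_trials) matrix: one HRF-convolved column per trial."""
    cols = [
        hrf_regressor(o, d, frame_times, hrf_model=hrf_model)
        for o, d in zip(np.asarray(onsets, float), np.asarray(durations, float))
    ]
    return np.column_stack(cols)


def dct_drift(frame_times: np.ndarray, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass set: periods longer than ``cutoff_s``."""
    n = len(frame_times)
    span = frame_times[-1] - frame_times[0]
    order = int(max(0, math.floor(2.0 * span / cutoff_s)))
    i = np.arange(n)
    cols = [np.cos(np.pi * (k + 1) * (2 * i + 1) / (2.0 * n)) for k in range(order)]
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def _nuisance_columns(spec: DesignMatrixSpec, frame_times: np.ndarray) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if spec.motion is not None:
        m = np.asarray(spec.motion, float)
        if m.shape[0] != len(frame_times):
            raise ValueError("motion parameters must have one row per scan")
        cols.append(m)
        names += [f"motion{j}" for j in range(m.shape[1])]
    for f in spec.outlier_frames:
        spike = np.zeros(len(frame_times))
        spike[f] = 1.0
        cols.append(spike[:, None])
        names.append(f"spike{f}")
    if spec.highpass_cutoff_s:
        drift = dct_drift(frame_times, spec.highpass_cutoff_s)
        if drift.shape[1]:
            cols.append(drift)
            names += [f"drift{j}" for j in range(drift.shape[1])]
    if cols:
        return np.hstack(cols), names
    return np.empty((len(frame_times), 0)), names


def _ols_t(Y: np.ndarray, X: np.ndarray, col: int, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """OLS betas and t for one column of X, vectorized over voxels.

    Degenerate voxels (zero residual variance) yield NaN t values.
    """
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank}/{p}); most collinear columns: "
            f"{names[i]!r} and {names[j]!r}"
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    s2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * xtx_inv[col, col])
        t = np.where(se > 0, beta[col] / np.where(se > 0, se, 1.0), np.nan)
    return beta[col], t


def fit_lss(
    timeseries: np.ndarray,
    events: pd.DataFrame,
    frame_times: np.ndarray,
    spec: DesignMatrixSpec | None = None,
    trial_index: int | None = None,
    return_betas: bool = False,
) -> np.ndarray:
    """Least-squares-separate single-trial t patterns for one run.

    One GLM per trial: [trial of interest, all other trials, nuisance,
    drift, intercept].  Returns (n_trials, n_voxels) of t statistics, or a
    single row when ``trial_index`` is given.
    """
    spec = spec or DesignMatrixSpec()
    Y = np.asarray(timeseries, float)
    onsets = events["onset"].to_numpy(float)
    durations = events["duration"].to_numpy(float)
    per_trial = trial_design(onsets, durations, frame_times, spec.hrf_model)
    nuis, nuis_names = _nuisance_columns(spec, frame_times)
    intercept = np.ones((len(frame_times), 1))

    indices = range(len(events)) if trial_index is None else [trial_index]
    rows_t, rows_b = [], []
    for i in indices:
        cols = [per_trial[:, i]]
        names = ["trial_of_interest"]
        if per_trial.shape[1] > 1:
            others = per_trial[:, [j for j in range(per_trial.shape[1]) if j != i]]
            cols.append(others.sum(axis=1))
            names.append("all_other_trials")
        X = np.column_stack([*cols, nuis, intercept])
        names += [*nuis_names, "intercept"]
        b, t = _ols_t(Y, X, 0, names)
        rows_t.append(t)
        rows_b.append(b)
    out_t = np.vstack(rows_t)
    out_b = np.vstack(rows_b)
    if trial_index is not None:
        out_t, out_b = out_t[0], out_b[0]
    return (out_t, out_b) if return_betas else out_t


def fit_full_ols(
    timeseries: np.ndarray,
    events: pd.DataFrame,
    frame_times: np.ndarray,
    spec: DesignMatrixSpec | None = None,
) -> np.ndarray:
    """All-trials-at-once OLS betas (n_trials, n_voxels): the LS-A oracle."""
    spec = spec or DesignMatrixSpec()
    Y = np.asarray(timeseries, float)
    per_trial = trial_design(
        events["onset"].to_numpy(float), events["duration"].to_numpy(float),
        frame_times, spec.hrf_model,
    )
    nuis, _ = _nuisance_columns(spec, frame_times)
    X = np.column_stack([per_trial, nuis, np.ones(len(frame_times))])
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    return beta[: per_trial.shape[1]]


def fit_run_glm(
    timeseries: np.ndarray,
    events: pd.DataFrame,
    frame_times: np.ndarray,
    spec: DesignMatrixSpec | None = None,
) -> np.ndarray:
    """Run-level t map for the remembered-trials regressor.

    Remembered = correct and uncensored; forgotten and censored trials are
    modeled as separate regressors when present.
    """
    spec = spec or DesignMatrixSpec()
    Y = np.asarray(timeseries, float)
    remembered = events["correct"].to_numpy(bool) & ~events["censored"].to_numpy(bool)
    if not remembered.any():
        raise ValueError("run contains no remembered trials")

    def cond(mask: np.ndarray) -> np.ndarray | None:
        if not mask.any():
            return None
        return hrf_regressor(
            events.loc[mask, "onset"].to_numpy(float),
            events.loc[mask, "duration"].to_numpy(float),
            frame_times, hrf_model=spec.hrf_model,
        )

    cols = [cond(remembered)]
    names = ["remembered"]
    other = cond(~remembered)
    if other is not None:
        cols.append(other)
        names.append("not_remembered")
    nuis, nuis_names = _nuisance_columns(spec, frame_times)
    X = np.column_stack([*cols, nuis, np.ones(len(frame_times))])
    _, t = _ols_t(Y, X, 0, names + nuis_names + ["intercept"])
    return t


def estimate_run_maps(
    bold_by_run: dict[int, tuple[np.ndarray, np.ndarray]],
    schedule: pd.DataFrame,
    spec: DesignMatrixSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run-level t maps for every run: returns (maps (n_runs, n_vox), cities)."""
    maps, cities = [], []
    for run in sorted(bold_by_run):
        Y, frame_times = bold_by_run[run]
        ev = schedule[schedule["run"] == run].reset_index(drop=True)
        maps.append(fit_run_glm(Y, ev, frame_times, spec))
        cities.append(int(ev["city"].iloc[0]))
    return np.vstack(maps), np.asarray(cities)
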