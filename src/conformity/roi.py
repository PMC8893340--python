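"""Event-locked ROI time-course statistics.

The event-locked region-of-interest analysis chain: per run,
motion nuisance is regressed out of the ROI signal; the residual is
upsampled to 0.2 s by cubic spline; for each event of interest a
15-second epoch of 75 samples is extracted, time-locked to 1 s before
onset; a linear regression across trials at every time point produces a
beta-weight time course per predictor; group inference uses a
leave-one-out peak procedure (the left-out participant's beta is read
out at the time of the group's peak absolute effect, and the collected
values are tested against zero with a Wilcoxon signed-rank test).  The
psychophysiological-interaction (PPI) variant regresses a target
region's epochs on a seed region's epochs, the behavioural modulators,
and all seed x modulator interactions, and summarises coupling on a
(confidence, influence) z-score grid using group coefficients averaged
over the 2-3 s post-onset window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .behaviour import TestResult, signed_rank

__all__ = [
    "EPOCH_POINTS",
    "EPOCH_DT",
    "EPOCH_PRE",
    "EpochMatrix",
    "BetaTimecourse",
    "LooPeakResult",
    "PpiResult",
    "ConnectivityGrid",
    "residualize",
    "upsample",
    "extract_epochs",
    "beta_timecourse",
    "loo_peak_test",
    "ppi_timecourse",
    "group_ppi",
    "connectivity_grid",
    "window_columns",
]

EPOCH_DT = 0.2  # seconds between epoch samples after upsampling
EPOCH_PRE = 1.0  # epoch starts 1 s before event onset
EPOCH_POINTS = 75  # 15-second window


def residualize(values, nuisance) -> np.ndarray:
    """OLS residual of a signal on the nuisance matrix plus an intercept.

    Rank-deficient nuisance columns are handled by a minimum-norm least
    squares solve (collinear columns contribute nothing extra) with a
    warning.
    """
    y = np.asarray(values, float)
    N = np.atleast_2d(np.asarray(nuisance, float))
    if N.shape[0] != y.size:
        raise ValueError(
            f"nuisance has {N.shape[0]} rows but the signal has {y.size} samples"
        )
    X = np.column_stack([np.ones(y.size), N])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("nuisance matrix is rank deficient; collinear columns ignored",
                      stacklevel=2)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def upsample(values, tr: float, dt: float = EPOCH_DT):
    """Cubic-spline interpolation of a TR-resolution series onto a ``dt`` grid.

    Returns ``(times, values)``; the grid spans [0, (n-1)*tr] so no
    extrapolation occurs.
    """
    y = np.asarray(values, float)
    if y.size < 4:
        raise ValueError("need at least 4 samples to upsample")
    coarse = np.arange(y.size) * tr
    fine = np.arange(0.0, coarse[-1] + dt / 2, dt)
    fine = fine[fine <= coarse[-1]]
    return fine, CubicSpline(coarse, y)(fine)


@dataclass
class EpochMatrix:
    """Trials x 75 event-locked epochs at 0.2 s resolution."""

    data: np.ndarray
    rel_times: np.ndarray  # 75 values from -1.0 to +13.8 s relative to onset
    kept: np.ndarray  # boolean mask into the onsets passed to extract_epochs
    event: str = ""

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def extract_epochs(times, values, onsets, event: str = "") -> EpochMatrix:
    """Cut 75-point epochs starting 1 s before each onset.

    ``times``/``values`` are the upsampled (0.2 s) signal.  Onsets are
    aligned to the nearest grid sample (alignment error <= 0.1 s); epochs
    that would run off either end of the run are dropped with a warning.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    onsets = np.asarray(onsets, float)
    dt = EPOCH_DT
    start_idx = np.rint((onsets - EPOCH_PRE - times[0]) / dt).astype(int)
    ok = (start_idx >= 0) & (start_idx + EPOCH_POINTS <= values.size)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} epoch(s) extending outside the run",
            stacklevel=2,
        )
    rows = np.stack([values[s : s + EPOCH_POINTS] for s in start_idx[ok]]) if ok.any() else np.empty((0, EPOCH_POINTS))
    rel = -EPOCH_PRE + dt * np.arange(EPOCH_POINTS)
    return EpochMatrix(data=rows, rel_times=rel, kept=ok, event=event)


@dataclass
class BetaTimecourse:
    """Per-timepoint regression coefficients for one participant."""

    coefs: pd.DataFrame  # predictors x 75
    rel_times: np.ndarray
    participant_id: str = ""

    def curve(self, name: str) -> np.ndarray:
        return self.coefs.loc[name].to_numpy()


def _design(modulators: pd.DataFrame, standardize: bool):
    X = [np.ones(len(modulators))]
    names = ["intercept"]
    degenerate = []
    for c in modulators.columns:
        x = np.asarray(modulators[c], float)
        sd = np.nanstd(x)
        if not np.isfinite(sd) or sd == 0:
            degenerate.append(c)
            x = np.zeros_like(x)
        elif standardize:
            x = (x - np.nanmean(x)) / sd
        X.append(x)
        names.append(c)
    return np.column_stack(X), names, degenerate


def beta_timecourse(
    epochs: EpochMatrix,
    modulators: pd.DataFrame,
    standardize: bool = True,
    participant_id: str = "",
) -> BetaTimecourse:
    """Across-trial OLS at each of the 75 epoch time points.

    Modulators are z-scored within participant (coefficients then share
    units across participants, as group averaging requires) and are not
    orthogonalised.  Degenerate (constant) modulators yield NaN
    coefficient rows with a warning.
    """
    if len(modulators) != epochs.n_trials:
        raise ValueError(
            f"{len(modulators)} modulator rows for {epochs.n_trials} epochs"
        )
    X, names, degenerate = _design(modulators, standardize)
    if degenerate:
        warnings.warn(
            f"constant modulator(s) {degenerate}: coefficients undefined (NaN)",
            stacklevel=2,
        )
    B, *_ = np.linalg.lstsq(X, epochs.data, rcond=None)  # predictors x 75
    coefs = pd.DataFrame(B, index=names, columns=range(EPOCH_POINTS))
    for c in degenerate:
        coefs.loc[c] = np.nan
    return BetaTimecourse(coefs=coefs, rel_times=epochs.rel_times, participant_id=participant_id)


@dataclass
class LooPeakResult:
    """Leave-one-out peak read-outs and their group test vs zero.

    ``test.p`` is calibrated against the exact sign-flip null of the whole
    procedure; ``table_p`` is the independence-assuming Wilcoxon table
    p-value of the collected values (anticonservative under noise nulls,
    kept for comparison with conventional reports).
    """

    values: np.ndarray  # one left-out beta per participant
    peak_times: np.ndarray  # group-peak time (s, relative to onset) per left-out participant
    test: TestResult
    table_p: float = np.nan


def _loo_values(B):
    """Left-out values and peak indices for a (participants x time) stack."""
    n = B.shape[0]
    total = B.sum(axis=0)
    ks = np.empty(n, dtype=int)
    for i in range(n):
        mean_wo = (total - B[i]) / (n - 1)
        ks[i] = np.argmax(np.abs(mean_wo))  # argmax takes the earliest tie
    return B[np.arange(n), ks], ks


def _w_plus(values):
    ranks = stats.rankdata(np.abs(values))
    return float(ranks[values > 0].sum())


def loo_peak_test(
    betas, rel_times=None, description: str = "", n_flips: int = 1000, flip_seed: int = 0
) -> LooPeakResult:
    """Group inference on a stack of beta time courses without selection bias.

    ``betas`` is (participants x 75).  For each participant the group
    mean curve excluding them is computed; the peak is the time of
    maximal absolute mean (earliest sample on ties); the left-out
    participant's beta at that time is collected; the collected values
    are summarised by the signed-rank statistic W+ and tested against
    zero, two-sided.

    Because every left-out peak is selected on (nearly) the same group
    curve, the collected values share a selection-conditioned shift under
    the null, and the Wilcoxon reference table is badly anticonservative
    for pure-noise curves.  The reported p therefore comes from the exact
    null of the *entire* procedure: each participant's curve is sign-
    flipped (curves are exchangeable and symmetric about zero under the
    null), the LOO read-out and W+ are recomputed per flip, and the
    two-sided tail probability is taken with add-one smoothing.  The
    flip stream is internally seeded, so results are deterministic.
    """
    B = np.asarray(betas, float)
    if B.ndim != 2 or B.shape[0] < 3:
        raise ValueError("need a (participants x time) array with at least 3 participants")
    n, T = B.shape
    if rel_times is None:
        rel_times = -EPOCH_PRE + EPOCH_DT * np.arange(T)
    values, ks = _loo_values(B)
    peak_times = np.asarray(rel_times, float)[ks]
    w_obs = _w_plus(values)
    try:
        table_p = signed_rank(values, mu=0.0).p
    except Exception:
        table_p = np.nan

    rng = np.random.default_rng(flip_seed)
    S = rng.choice([-1.0, 1.0], size=(n_flips, n))
    # flipped leave-one-out means for all flips at once: (flips, left-out, time)
    total_flip = S @ B
    M = (total_flip[:, None, :] - S[:, :, None] * B[None, :, :]) / (n - 1)
    kf = np.argmax(np.abs(M), axis=2)
    vals_f = S * B[np.arange(n)[None, :], kf]
    ranks_f = stats.rankdata(np.abs(vals_f), axis=1)
    w_f = (ranks_f * (vals_f > 0)).sum(axis=1)
    lo = (1 + np.sum(w_f <= w_obs)) / (n_flips + 1)
    hi = (1 + np.sum(w_f >= w_obs)) / (n_flips + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    test = TestResult(
        statistic=w_obs,
        p=p,
        n=n,
        description=description or "left-out peak betas vs 0 (sign-flip calibrated)",
    )
    return LooPeakResult(values=values, peak_times=peak_times, test=test, table_p=table_p)


PPI_TERMS = (
    "seed",
    "conf_norm",
    "prev_influence",
    "conf_x_infl",
    "seed:conf_norm",
    "seed:prev_influence",
    "seed:conf_norm:prev_influence",
)


@dataclass
class PpiResult:
    """Per-timepoint PPI coefficients for one participant."""

    coefs: pd.DataFrame  # terms x 75
    rel_times: np.ndarray
    participant_id: str = ""

    def curve(self, name: str) -> np.ndarray:
        return self.coefs.loc[name].to_numpy()


def ppi_timecourse(
    target_epochs: EpochMatrix,
    seed_epochs: EpochMatrix,
    modulators: pd.DataFrame,
    include_triple: bool = True,
    participant_id: str = "",
) -> PpiResult:
    """Psychophysiological interaction per epoch time point.

    At each time point, the target region's activity across trials is
    regressed on the seed region's activity, confidence, influence and
    their product, and every seed x modulator interaction (the main
    effect of each interacting term is always present).  Seed activity
    and modulators are z-scored across trials.
    """
    if target_epochs.data.shape != seed_epochs.data.shape:
        raise ValueError("seed and target epoch matrices must share trials and time grid")
    need = ("conf_norm", "prev_influence")
    missing = [c for c in need if c not in modulators.columns]
    if missing:
        raise ValueError(f"modulators missing required columns {missing}")
    n = target_epochs.n_trials
    if len(modulators) != n:
        raise ValueError(f"{len(modulators)} modulator rows for {n} epochs")
    c = _z(np.asarray(modulators["conf_norm"], float))
    f = _z(np.asarray(modulators["prev_influence"], float))
    terms = [t for t in PPI_TERMS if include_triple or t != "seed:conf_norm:prev_influence"]
    T = target_epochs.data.shape[1]
    out = np.empty((1 + len(terms), T))
    for k in range(T):
        s = _z(seed_epochs.data[:, k])
        cols = {
            "seed": s,
            "conf_norm": c,
            "prev_influence": f,
            "conf_x_infl": c * f,
            "seed:conf_norm": s * c,
            "seed:prev_influence": s * f,
            "seed:conf_norm:prev_influence": s * c * f,
        }
        X = np.column_stack([np.ones(n)] + [cols[t] for t in terms])
        out[:, k] = np.linalg.lstsq(X, target_epochs.data[:, k], rcond=None)[0]
    coefs = pd.DataFrame(out, index=["intercept"] + terms, columns=range(T))
    return PpiResult(coefs=coefs, rel_times=target_epochs.rel_times, participant_id=participant_id)


def _z(x):
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def window_columns(rel_times, lo: float = 2.0, hi: float = 3.0) -> np.ndarray:
    """Boolean mask of epoch samples whose post-onset time lies in [lo, hi]."""
    rel = np.asarray(rel_times, float)
    return (rel >= lo - 1e-9) & (rel <= hi + 1e-9)


def group_ppi(results: Sequence[PpiResult], window=(2.0, 3.0)) -> dict:
    """Group-level PPI summary: LOO peak tests and window-averaged coefficients.

    Returns ``{"loo": {term: LooPeakResult}, "window_coefs": {term:
    group-mean coefficient averaged over the window}}``.
    """
    if not results:
        raise ValueError("need at least one participant PpiResult")
    rel = results[0].rel_times
    terms = [t for t in results[0].coefs.index if t != "intercept"]
    stack = {t: np.stack([r.curve(t) for r in results]) for t in terms}
    win = window_columns(rel, *window)
    out = {"loo": {}, "window_coefs": {}}
    for t in terms:
        if len(results) >= 3:
            out["loo"][t] = loo_peak_test(stack[t], rel, description=f"PPI {t}")
        out["window_coefs"][t] = float(stack[t][:, win].mean())
    return out


@dataclass
class ConnectivityGrid:
    """Predicted seed-target coupling over a (influence, confidence) z grid."""

    influence_z: np.ndarray
    confidence_z: np.ndarray
    grid: np.ndarray  # confidence (rows) x influence (columns)


def connectivity_grid(window_coefs: dict, lo: float = -2.0, hi: float = 2.0,
                      step: float = 0.25) -> ConnectivityGrid:
    """Coupling surface implied by window-averaged PPI coefficients.

    The modulator-dependent seed slope b_seed + b_(seed:c) c + b_(seed:i) i
    + b_(seed:c:i) c i evaluated on the z-score grid.  A pure c x i
    interaction yields a saddle symmetric under a joint sign flip.
    """
    z = np.arange(lo, hi + step / 2, step)
    I, C = np.meshgrid(z, z)
    g = (
        window_coefs.get("seed", 0.0)
        + window_coefs.get("seed:conf_norm", 0.0) * C
        + window_coefs.get("seed:prev_influence", 0.0) * I
        + window_coefs.get("seed:conf_norm:prev_influence", 0.0) * C * I
    )
    return ConnectivityGrid(influence_z=z, confidence_z=z, grid=g)
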