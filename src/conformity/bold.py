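"""Synthetic ROI BOLD signals with known trial-modulator encodings.

This module turns a simulated session into (a) an event schedule with
the task's timing structure (inter-event jitters uniform on [1.5, 4.5] s,
1.5 s partner-estimate display, 3 s outcome display, TR = 3.74 s) and
(b) region-of-interest BOLD time series built by impulse-convolving each
event with a canonical double-gamma haemodynamic response whose
amplitude is a linear function of standardised trial modulators, plus
AR(1) noise, white measurement noise, and a small admixture of six
synthetic motion regressors (so nuisance residualisation is exercised
non-trivially).  A coupled-pair mode generates a seed/target region pair
whose coupling gain varies with trial modulators — ground truth for the
psychophysiological-interaction analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .task import ConfigError

__all__ = [
    "TR",
    "EventTiming",
    "EventSchedule",
    "EncodingSpec",
    "NoiseParams",
    "CouplingSpec",
    "RoiSignal",
    "build_event_schedule",
    "hrf",
    "synthesize_roi_signal",
    "synthesize_coupled_pair",
]

TR = 3.74  # seconds, repetition time
JITTER = (1.5, 4.5)  # seconds, uniform inter-event blank
EVENT_TYPES = ("t1", "t2", "t3", "t4", "t5", "t6")

# modulator columns the schedule carries for every trial
MODULATOR_COLUMNS = (
    "conf_norm",
    "prev_influence",
    "conf_x_infl",
    "conf_x_curr_infl",
    "influence_stat",
    "revision_stat",
    "log_rt_estimate",
    "log_rt_confidence",
    "log_rt_revision",
    "block",
)


@dataclass(frozen=True)
class EventTiming:
    """Fixed display durations (seconds) of the non-response events."""

    photo: float = 2.0  # partner photo at trial start
    stimulus: float = 1.38  # 91-blob stream: 30 ms + 90 x 15 ms
    partner_estimate: float = 1.5
    outcome: float = 3.0
    jitter: tuple = JITTER


@dataclass
class EventSchedule:
    """Event onsets/durations for one participant, one run per block."""

    events: pd.DataFrame  # onset, duration, event_type, block, trial_index, role, modulators
    tr: float
    run_lengths: dict  # block -> run length (s), a whole number of TRs
    n_volumes: dict  # block -> volume count

    def for_block(self, block: int) -> pd.DataFrame:
        return self.events[self.events["block"] == block]

    def onsets(self, event_type: str, block: int, role: Optional[str] = None) -> pd.DataFrame:
        ev = self.for_block(block)
        ev = ev[ev["event_type"] == event_type]
        if role is not None:
            ev = ev[ev["role"] == role]
        return ev


def build_event_schedule(
    trials: pd.DataFrame, rng, tr: float = TR, timing: EventTiming = EventTiming()
) -> EventSchedule:
    """Lay out the six trial events in time for each block of one session.

    Per trial: partner photo, stimulus stream (t1), initial estimate
    (t2, duration = estimation RT), confidence report (t3, duration =
    confidence RT), jitter, partner estimate display (t4, 1.5 s), jitter,
    revision / observation phase (t5, duration = revision RT), outcome
    display (t6, 3 s), jitter.  Jitters are uniform draws from
    [1.5, 4.5] s.  Runs end with a 12 s rest padded to a whole number of
    TRs (runs land near the 12-17 min range of the scan protocol).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    need = {"block", "trial_index", "role", "rt_estimate", "rt_confidence", "rt_revision"}
    missing = need - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    rows = []
    run_lengths, n_volumes = {}, {}
    for block, g in trials.groupby("block", sort=True):
        g = g.sort_values("trial_index")
        t = 0.0
        for _, tr_row in g.iterrows():
            jit = rng.uniform(*timing.jitter, size=3)
            mods = _trial_modulators(tr_row)
            t += timing.photo
            onsets = {}
            onsets["t1"] = (t, timing.stimulus)
            t += timing.stimulus
            onsets["t2"] = (t, float(tr_row["rt_estimate"]))
            t += float(tr_row["rt_estimate"])
            onsets["t3"] = (t, float(tr_row["rt_confidence"]))
            t += float(tr_row["rt_confidence"]) + jit[0]
            onsets["t4"] = (t, timing.partner_estimate)
            t += timing.partner_estimate + jit[1]
            onsets["t5"] = (t, float(tr_row["rt_revision"]))
            t += float(tr_row["rt_revision"])
            onsets["t6"] = (t, timing.outcome)
            t += timing.outcome + jit[2]
            for ev, (onset, dur) in onsets.items():
                rows.append(
                    {
                        "onset": onset,
                        "duration": dur,
                        "event_type": ev,
                        "block": int(block),
                        "trial_index": int(tr_row["trial_index"]),
                        "role": tr_row["role"],
                        **mods,
                    }
                )
        length = (np.ceil((t + 12.0) / tr)) * tr
        run_lengths[int(block)] = float(length)
        n_volumes[int(block)] = int(round(length / tr))
    events = pd.DataFrame(rows).sort_values(["block", "onset"]).reset_index(drop=True)
    return EventSchedule(events=events, tr=tr, run_lengths=run_lengths, n_volumes=n_volumes)


def _trial_modulators(row) -> dict:
    conf = float(row.get("conf_norm", row.get("confidence", np.nan) / 6.0))
    prev = float(row.get("prev_influence", np.nan))
    curr = float(row.get("influence_stat", np.nan))
    mods = {
        "conf_norm": conf,
        "prev_influence": prev,
        "conf_x_infl": conf * prev,
        "conf_x_curr_infl": conf * curr,
        "influence_stat": float(row.get("influence_stat", np.nan)),
        "revision_stat": float(row.get("revision_stat", np.nan)),
        "log_rt_estimate": float(np.log(row["rt_estimate"])),
        "log_rt_confidence": float(np.log(row["rt_confidence"])),
        "log_rt_revision": float(np.log(row["rt_revision"])),
        "block": float(row["block"]),
    }
    return mods


_HRF_CACHE: dict = {}


def hrf(t, peak: float = 5.0, undershoot: float = 15.0, ratio: float = 6.0):
    """Canonical double-gamma haemodynamic response, unit peak amplitude.

    Difference of two gamma densities (shapes ``peak + 1`` and
    ``undershoot + 1``, unit scale): response peaking near ``peak``
    seconds with an undershoot near ``undershoot`` seconds at relative
    depth 1/``ratio``; zero for t <= 0.
    """
    from scipy import stats as _st

    key = (peak, undershoot, ratio)
    if key not in _HRF_CACHE:
        grid = np.linspace(0.0, 40.0, 4001)
        raw = _st.gamma.pdf(grid, peak + 1.0) - _st.gamma.pdf(grid, undershoot + 1.0) / ratio
        _HRF_CACHE[key] = float(raw.max())
    t = np.asarray(t, float)
    out = np.where(
        t > 0.0,
        (_st.gamma.pdf(t, peak + 1.0) - _st.gamma.pdf(t, undershoot + 1.0) / ratio)
        / _HRF_CACHE[key],
        0.0,
    )
    return out.item() if out.ndim == 0 else out


@dataclass
class EncodingSpec:
    """Ground-truth linear encoding of trial modulators at chosen events.

    ``baseline`` maps event type -> response amplitude present on every
    trial; ``weights`` is a list of (event_type, modulator, weight)
    triples giving the amplitude change per standard deviation of the
    modulator (modulators are z-scored within run before injection).
    ``role`` optionally restricts encoded events to observe/revise trials.
    ``standardize=False`` uses the modulator columns as-is (for callers
    that pre-standardise over a wider scope than one run).
    """

    baseline: dict = field(default_factory=dict)
    weights: list = field(default_factory=list)
    role: Optional[str] = None
    latency: float = 0.0
    standardize: bool = True

    def validate(self):
        for ev in self.baseline:
            if ev not in EVENT_TYPES:
                raise ConfigError(f"unknown event type {ev!r} in baseline")
        for ev, mod, _ in self.weights:
            if ev not in EVENT_TYPES:
                raise ConfigError(f"unknown event type {ev!r} in weights")
            if mod not in MODULATOR_COLUMNS:
                raise ConfigError(
                    f"unknown modulator {mod!r}; available: {MODULATOR_COLUMNS}"
                )


@dataclass
class NoiseParams:
    """AR(1) + white noise and motion-admixture settings."""

    ar_rho: float = 0.3
    ar_sd: float = 0.3
    white_sd: float = 0.1
    motion_sd: float = 0.1  # sd of the mixing weights on the 6 motion regressors
    motion_step_sd: float = 0.05


@dataclass
class RoiSignal:
    """One region's time series for one run, with its nuisance matrix."""

    label: str
    values: np.ndarray
    tr: float
    nuisance: np.ndarray  # samples x 6 synthetic motion regressors
    block: int

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.tr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def _ar1(n, rho, sd, rng):
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 1e-12)), size=n + 100)
    from scipy.signal import lfilter

    x = lfilter([1.0], [1.0, -rho], innov)
    return x[100:]


def _motion(n, rng, step_sd):
    walk = np.cumsum(rng.normal(0.0, step_sd, size=(n, 6)), axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return walk / sd


def _standardize(x):
    x = np.asarray(x, float)
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(x)
    return (np.nan_to_num(x, nan=mu) - mu) / sd


def event_amplitudes(events: pd.DataFrame, encoding: EncodingSpec) -> np.ndarray:
    """Per-event response amplitudes implied by an encoding spec."""
    encoding.validate()
    amps = np.zeros(len(events))
    etype = events["event_type"].to_numpy()
    roles = events["role"].to_numpy()
    for ev, base in encoding.baseline.items():
        amps[etype == ev] += base
    for ev, mod, w in encoding.weights:
        sel = etype == ev
        if encoding.role is not None:
            sel &= roles == encoding.role
        if not sel.any():
            continue
        x = events.loc[sel, mod].to_numpy()
        amps[sel] += w * (_standardize(x) if encoding.standardize else np.nan_to_num(x))
    if encoding.role is not None:
        # baseline still applies everywhere; modulation is role-specific
        pass
    return amps


def synthesize_roi_signal(
    schedule: EventSchedule,
    encoding: EncodingSpec,
    noise: NoiseParams,
    rng,
    label: str = "roi",
    block: int = 1,
) -> RoiSignal:
    """Sample one run's ROI time series at TR resolution.

    signal(t) = sum_events amplitude_e * hrf(t - onset_e - latency)
    + AR(1) noise + white noise + motion admixture, where amplitude_e =
    baseline + sum_m weight * z(modulator).
    """
    events = schedule.for_block(block)
    n = schedule.n_volumes[block]
    tgrid = np.arange(n) * schedule.tr
    amps = event_amplitudes(events, encoding)
    onsets = events["onset"].to_numpy()
    lags = tgrid[None, :] - onsets[:, None] - encoding.latency
    clean = amps @ hrf(lags)
    drift = _ar1(n, noise.ar_rho, noise.ar_sd, rng) + rng.normal(0.0, noise.white_sd, n)
    motion = _motion(n, rng, noise.motion_step_sd)
    mixed = motion @ rng.normal(0.0, noise.motion_sd, 6)
    return RoiSignal(label=label, values=clean + drift + mixed, tr=schedule.tr,
                     nuisance=motion, block=block)


@dataclass
class CouplingSpec:
    """Modulator-dependent coupling from a seed to a target region.

    target(t) = gain(t) * seed(t) + noise, with gain(t) = alpha +
    sum_m gamma_m * z(modulator of the trial active at t) during a window
    of ``window`` seconds from each coupling event's onset, and alpha
    elsewhere.
    """

    alpha: float = 1.0
    gammas: dict = field(default_factory=dict)
    event: str = "t5"
    role: Optional[str] = "revise"
    window: float = 8.0

    def validate(self):
        if self.event not in EVENT_TYPES:
            raise ConfigError(f"unknown event type {self.event!r}")
        for mod in self.gammas:
            if mod not in MODULATOR_COLUMNS:
                raise ConfigError(f"unknown modulator {mod!r} in coupling gammas")


def synthesize_coupled_pair(
    schedule: EventSchedule,
    coupling: CouplingSpec,
    rng,
    seed_encoding: Optional[EncodingSpec] = None,
    noise: Optional[NoiseParams] = None,
    block: int = 1,
    labels=("seed", "target"),
):
    """Generate a (seed, target) region pair with known coupling gammas."""
    coupling.validate()
    noise = noise or NoiseParams()
    seed_encoding = seed_encoding or EncodingSpec(baseline={coupling.event: 1.0})
    seed = synthesize_roi_signal(schedule, seed_encoding, noise, rng, labels[0], block)

    n = seed.values.size
    tgrid = np.arange(n) * schedule.tr
    gain = np.full(n, coupling.alpha)
    ev = schedule.onsets(coupling.event, block, coupling.role)
    # the product modulator is built as the product of the two standardised
    # factors, matching how the PPI regression constructs its interaction terms
    zmods = {}
    for m in coupling.gammas:
        if m == "conf_x_infl":
            zmods[m] = _standardize(ev["conf_norm"].to_numpy()) * _standardize(
                ev["prev_influence"].to_numpy()
            )
        else:
            zmods[m] = _standardize(ev[m].to_numpy())
    for i, onset in enumerate(ev["onset"].to_numpy()):
        in_win = (tgrid >= onset) & (tgrid < onset + coupling.window)
        for m, gamma in coupling.gammas.items():
            gain[in_win] += gamma * zmods[m][i]
    drift = _ar1(n, noise.ar_rho, noise.ar_sd, rng) + rng.normal(0.0, noise.white_sd, n)
    motion = _motion(n, rng, noise.motion_step_sd)
    mixed = motion @ rng.normal(0.0, noise.motion_sd, 6)
    target = RoiSignal(
        label=labels[1], values=gain * seed.values + drift + mixed, tr=schedule.tr,
        nuisance=motion, block=block,
    )
    return seed, target
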