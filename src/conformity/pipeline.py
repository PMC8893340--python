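"""End-to-end study composition: simulate, analyse, report.

``run_pipeline`` executes the full simulate-then-analyse chain on one
configuration: cohort simulation, behavioural mixed-model fits,
sliding-window dynamics, synthetic ROI BOLD with injected encodings, the
event-locked ROI regression with leave-one-out group inference, and the
seed-target PPI with its connectivity surface.  Intermediate tables are
written as plain CSV/JSON so any stage can be re-run from disk.

``roi_recovery_study`` and ``ppi_recovery_study`` are the reusable
building blocks: they generate a synthetic fMRI cohort with known
encoding/coupling ground truth and push it through the ROI pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import agents, behaviour, bold, roi, task

__all__ = [
    "RunConfig",
    "run_pipeline",
    "default_encoding",
    "roi_recovery_study",
    "ppi_recovery_study",
]

logger = logging.getLogger(__name__)

# dACC-style reference encoding at the revision phase: negative confidence
# weight in both conditions; negative confidence x influence weight in the
# human condition only; a reaction-time nuisance weight everywhere.
ENCODING_WEIGHTS = {
    "human": [("t5", "conf_norm", -0.5), ("t5", "conf_x_infl", -0.5), ("t5", "log_rt_revision", 0.2)],
    "computer": [("t5", "conf_norm", -0.5), ("t5", "log_rt_revision", 0.2)],
}


def default_encoding(condition: str) -> bold.EncodingSpec:
    """Reference ROI encoding for one partner type (revision-phase locked)."""
    if condition not in ENCODING_WEIGHTS:
        raise task.ConfigError(f"condition must be 'human' or 'computer', got {condition!r}")
    return bold.EncodingSpec(
        baseline={"t2": 0.5, "t4": 0.5, "t5": 1.0, "t6": 0.5},
        weights=list(ENCODING_WEIGHTS[condition]),
        role="revise",
    )


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    seed: int = 0
    n_participants: int = 12
    n_fmri: int = 8
    setting: str = "fmri"
    agent: dict = field(default_factory=dict)  # AgentParams overrides
    noise: dict = field(default_factory=dict)  # NoiseParams overrides
    coupling: dict = field(default_factory=dict)  # CouplingSpec overrides
    lock_event: str = "t5"
    include_triple: bool = True
    outdir: str = "conformity_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise task.ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def agent_params(self) -> agents.AgentParams:
        return agents.AgentParams(**self.agent)

    def noise_params(self) -> bold.NoiseParams:
        return bold.NoiseParams(**self.noise)


# regressors of the event-locked ROI model: confidence, previous-trial
# influence, their product, log reaction time, and block number
ROI_MODULATORS = {
    "revise": ["conf_norm", "prev_influence", "conf_x_infl", "log_rt_revision", "block"],
    "observe": ["conf_norm", "influence_stat", "conf_x_curr_infl", "log_rt_revision", "block"],
}


def _condition_standardized(schedule, encoding, blocks, lock):
    """Z-score the encoded modulators over the whole condition (both runs).

    The analysis standardises modulators per participant and condition,
    pooling that condition's runs; injecting with per-run z-scores would
    leave run-mean offsets that leak into correlated regressors (block in
    particular).  Standardising injection over the same scope keeps null
    regressors null.
    """
    mods = {m for _, m, _ in encoding.weights}
    if not mods:
        return schedule, encoding
    ev = schedule.events.copy()
    sel = (
        (ev["event_type"] == lock)
        & (ev["block"].isin(blocks))
        & ((ev["role"] == encoding.role) if encoding.role else True)
    )
    for m in mods:
        x = ev.loc[sel, m].to_numpy(float)
        mu, sd = np.nanmean(x), np.nanstd(x)
        ev.loc[sel, m] = 0.0 if (not np.isfinite(sd) or sd == 0) else (
            np.nan_to_num(x, nan=mu) - mu
        ) / sd
    zsched = bold.EventSchedule(ev, schedule.tr, schedule.run_lengths, schedule.n_volumes)
    zenc = dataclasses.replace(encoding, standardize=False)
    return zsched, zenc


def _participant_betas(trials, schedule, encodings, noise, rng, lock, conditions,
                       role="revise"):
    """One participant: synth each block's signal, pool epochs per condition, regress."""
    modulators = ROI_MODULATORS[role]
    out = {}
    for condition in conditions:
        blocks = sorted(trials.loc[trials["condition"] == condition, "block"].unique())
        zsched, zenc = _condition_standardized(
            schedule, encodings[condition], blocks, lock
        )
        epoch_rows, mod_rows = [], []
        for b in blocks:
            sig = bold.synthesize_roi_signal(
                zsched, zenc, noise, rng, label="dACC", block=int(b)
            )
            clean = roi.residualize(sig.values, sig.nuisance)
            times, up = roi.upsample(clean, sig.tr)
            ev = schedule.onsets(lock, int(b), role=role)
            ep = roi.extract_epochs(times, up, ev["onset"].to_numpy(), event=lock)
            epoch_rows.append(ep.data)
            mod_rows.append(ev.loc[ep.kept, modulators])
        epochs = roi.EpochMatrix(
            data=np.vstack(epoch_rows),
            rel_times=-roi.EPOCH_PRE + roi.EPOCH_DT * np.arange(roi.EPOCH_POINTS),
            kept=np.ones(sum(e.shape[0] for e in epoch_rows), dtype=bool),
            event=lock,
        )
        mods = pd.concat(mod_rows, ignore_index=True)
        out[condition] = roi.beta_timecourse(epochs, mods)
    return out


def roi_recovery_study(
    n_participants: int = 20,
    seed: int = 0,
    encodings: Optional[dict] = None,
    noise: Optional[bold.NoiseParams] = None,
    agent_params: Optional[agents.AgentParams] = None,
    lock: str = "t5",
    conditions=("human", "computer"),
    role: str = "revise",
) -> dict:
    """Synthetic fMRI cohort through the full ROI pipeline.

    Returns ``{"betas": {condition: {predictor: participants x 75}},
    "loo": {condition: {predictor: LooPeakResult}}}`` for the
    revision-locked regression with the reference (or given) encodings.
    """
    encodings = encodings or {c: default_encoding(c) for c in conditions}
    noise = noise or bold.NoiseParams()
    agent_params = agent_params or agents.AgentParams()
    session = task.SessionConfig(setting="fmri")
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    per_cond: dict = {c: [] for c in conditions}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        agent = agents.ParticipantAgent(agent_params, f"p{i:03d}", rng)
        trials = task.build_session(session, agent, rng, participant_id=f"p{i:03d}")
        trials = behaviour.annotate(trials)
        schedule = bold.build_event_schedule(trials, rng)
        betas = _participant_betas(
            trials, schedule, encodings, noise, rng, lock, conditions, role=role
        )
        for c in conditions:
            per_cond[c].append(betas[c])
    out = {"betas": {}, "loo": {}}
    for c in conditions:
        stacks = {
            name: np.stack([b.curve(name) for b in per_cond[c]])
            for name in per_cond[c][0].coefs.index
            if name != "intercept"
        }
        out["betas"][c] = stacks
        out["loo"][c] = {
            name: roi.loo_peak_test(B, description=f"{c}: {name}")
            for name, B in stacks.items()
        }
    return out


def ppi_recovery_study(
    n_participants: int = 20,
    seed: int = 0,
    coupling: Optional[bold.CouplingSpec] = None,
    noise: Optional[bold.NoiseParams] = None,
    lock: str = "t5",
    condition: str = "human",
) -> dict:
    """Seed-target pairs with known coupling, through the PPI pipeline.

    Returns the per-participant PPI results plus the group summary
    (LOO tests, 2-3 s window coefficients, connectivity grid).
    """
    coupling = coupling or bold.CouplingSpec(
        alpha=1.0, gammas={"conf_x_infl": 0.5}, event=lock, role="revise"
    )
    noise = noise or bold.NoiseParams()
    session = task.SessionConfig(setting="fmri")
    params = agents.AgentParams()
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    results = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        agent = agents.ParticipantAgent(params, f"p{i:03d}", rng)
        trials = task.build_session(session, agent, rng, participant_id=f"p{i:03d}")
        trials = behaviour.annotate(trials)
        schedule = bold.build_event_schedule(trials, rng)
        blocks = sorted(trials.loc[trials["condition"] == condition, "block"].unique())
        seed_rows, targ_rows, mod_rows = [], [], []
        for b in blocks:
            s_sig, t_sig = bold.synthesize_coupled_pair(
                schedule, coupling, rng, noise=noise, block=int(b), labels=("TPJ", "dACC")
            )
            ev = schedule.onsets(lock, int(b), role="revise")
            pair = []
            for sig in (s_sig, t_sig):
                clean = roi.residualize(sig.values, sig.nuisance)
                times, up = roi.upsample(clean, sig.tr)
                pair.append(roi.extract_epochs(times, up, ev["onset"].to_numpy(), event=lock))
            seed_rows.append(pair[0].data)
            targ_rows.append(pair[1].data)
            mod_rows.append(ev.loc[pair[0].kept, ["conf_norm", "prev_influence"]])
        rel = -roi.EPOCH_PRE + roi.EPOCH_DT * np.arange(roi.EPOCH_POINTS)
        kept = np.ones(sum(m.shape[0] for m in seed_rows), dtype=bool)
        seed_ep = roi.EpochMatrix(np.vstack(seed_rows), rel, kept, lock)
        targ_ep = roi.EpochMatrix(np.vstack(targ_rows), rel, kept, lock)
        mods = pd.concat(mod_rows, ignore_index=True)
        results.append(
            roi.ppi_timecourse(targ_ep, seed_ep, mods, participant_id=f"p{i:03d}")
        )
    summary = roi.group_ppi(results)
    summary["grid"] = roi.connectivity_grid(summary["window_coefs"])
    return {"participants": results, "summary": summary}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write tables, fits, and figure panels.

    Returns a dict of the main in-memory results; files are written
    under ``config.outdir``.  Deterministic given ``config.seed``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed}

    # --- behaviour -------------------------------------------------------
    logger.info("simulating cohort of %d participants", config.n_participants)
    cohort = agents.generate_cohort(
        config.n_participants,
        task.SessionConfig(setting=config.setting),
        config.agent_params(),
        seed=config.seed,
    )
    table = behaviour.annotate(cohort.trials)
    table.to_csv(out / "cohort.csv", index=False)
    with open(out / "cohort.truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, default=float)

    fits = {
        "pooled": behaviour.fit_lmm1(table),
        "human": behaviour.fit_lmm2(table, "human"),
        "computer": behaviour.fit_lmm2(table, "computer"),
    }
    with open(out / "fits.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh, indent=1, default=float)
    report["fits"] = fits

    windows = behaviour.sliding_window_revision(table)
    windows.to_csv(out / "sliding_windows.csv", index=False)
    report["windows"] = windows

    # susceptible vs insusceptible revision, human condition, late windows
    human = windows[windows["condition"] == "human"]
    last = human[human["window_index"] == human["window_index"].max()]
    pivot = last.pivot_table(index="participant_id", columns="susceptibility",
                             values="mean_revision")
    try:
        report["late_window_test"] = behaviour.signed_rank(
            pivot["susceptible"], pivot["insusceptible"],
            description="late-window revision: susceptible vs insusceptible (human)",
        )
    except behaviour.DegenerateTestError:
        report["late_window_test"] = None

    # --- ROI + PPI -------------------------------------------------------
    logger.info("synthesising BOLD and running ROI pipeline (n=%d)", config.n_fmri)
    study = roi_recovery_study(
        n_participants=config.n_fmri,
        seed=config.seed + 1,
        noise=config.noise_params(),
        lock=config.lock_event,
    )
    report["roi"] = study
    ppi = ppi_recovery_study(
        n_participants=config.n_fmri,
        seed=config.seed + 2,
        noise=config.noise_params(),
        lock=config.lock_event,
    )
    report["ppi"] = ppi

    roi_json = {
        cond: {
            name: {
                "p": res.test.p,
                "W": res.test.statistic,
                "median_beta": float(np.median(res.values)),
            }
            for name, res in study["loo"][cond].items()
        }
        for cond in study["loo"]
    }
    ppi_json = {
        "window_coefs": ppi["summary"]["window_coefs"],
        "loo_p": {t: r.test.p for t, r in ppi["summary"]["loo"].items()},
    }
    with open(out / "roi_ppi.json", "w") as fh:
        json.dump({"roi_loo": roi_json, "ppi": ppi_json}, fh, indent=1, default=float)

    _write_figures(out, table, windows, study, ppi)
    _write_report(out / "report.md", config, fits, report, roi_json, ppi_json)
    return report


def _write_figures(out, table, windows, study, ppi):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    # revision by binned confidence x influence (human)
    sub = table[(table["role"] == "revise") & (table["condition"] == "human")].copy()
    sub = sub[np.isfinite(sub["prev_influence"])]
    bins = [0.0, 1 / 3, 2 / 3, 1.0001]
    sub["conf_bin"] = pd.cut(sub["conf_norm"], bins, labels=["low", "mid", "high"])
    sub["infl_bin"] = pd.cut(sub["prev_influence"], bins, labels=["low", "mid", "high"])
    cell = sub.groupby(["conf_bin", "infl_bin"], observed=False)["revision_stat"].mean().unstack()
    im = axes[0, 0].imshow(cell.to_numpy(), cmap="viridis", origin="lower")
    axes[0, 0].set_xticks(range(3), cell.columns)
    axes[0, 0].set_yticks(range(3), cell.index)
    axes[0, 0].set_xlabel("influence (binned)")
    axes[0, 0].set_ylabel("confidence (binned)")
    axes[0, 0].set_title("mean revision, human condition")
    fig.colorbar(im, ax=axes[0, 0])

    for (cond, susc), g in windows.groupby(["condition", "susceptibility"]):
        m = g.groupby("window_index")["mean_revision"].mean()
        axes[0, 1].plot(m.index, m.to_numpy(), label=f"{cond}/{susc}")
    axes[0, 1].set_xlabel("window index")
    axes[0, 1].set_ylabel("mean revision")
    axes[0, 1].legend(fontsize=7)
    axes[0, 1].set_title("sliding-window revision")

    rel = -roi.EPOCH_PRE + roi.EPOCH_DT * np.arange(roi.EPOCH_POINTS)
    for cond, stacks in study["betas"].items():
        for name in ("conf_norm", "conf_x_infl"):
            if name in stacks:
                axes[1, 0].plot(rel, stacks[name].mean(axis=0), label=f"{cond}: {name}")
    axes[1, 0].axvline(0, ls="--", c="k", lw=0.5)
    axes[1, 0].set_xlabel("time from revision onset (s)")
    axes[1, 0].set_ylabel("beta")
    axes[1, 0].legend(fontsize=7)
    axes[1, 0].set_title("ROI beta time courses")

    grid = ppi["summary"]["grid"]
    im = axes[1, 1].imshow(
        grid.grid, origin="lower", cmap="inferno",
        extent=[grid.influence_z[0], grid.influence_z[-1],
                grid.confidence_z[0], grid.confidence_z[-1]],
    )
    axes[1, 1].set_xlabel("influence (z)")
    axes[1, 1].set_ylabel("confidence (z)")
    axes[1, 1].set_title("seed-target coupling")
    fig.colorbar(im, ax=axes[1, 1])
    fig.tight_layout()
    fig.savefig(Path(out) / "figures.png", dpi=120)
    plt.close(fig)


def _write_report(path, config, fits, report, roi_json, ppi_json):
    lines = [
        "# Conformity pipeline report",
        "",
        f"seed: {config.seed}; cohort n = {config.n_participants}; fMRI n = {config.n_fmri}",
        "",
        "## Mixed-model fits",
    ]
    for name, fit in fits.items():
        lines += ["", f"### {name}", "", fit.terms.round(4).to_markdown()]
    if report.get("late_window_test") is not None:
        t = report["late_window_test"]
        lines += [
            "",
            "## Late-window reciprocity (human condition)",
            f"susceptible vs insusceptible: W = {t.statistic:.0f}, p = {t.p:.4f}, n = {t.n}",
        ]
    lines += ["", "## ROI leave-one-out tests", "", "```json",
              json.dumps(roi_json, indent=1), "```",
              "", "## PPI (2-3 s window)", "", "```json",
              json.dumps(ppi_json, indent=1), "```", ""]
    Path(path).write_text("\n".join(lines))
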