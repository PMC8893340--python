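"""Synthetic participants whose behaviour follows the revision models.

Each agent perceives the target with subject-level von Mises noise,
reports an ordinal confidence (1-6) derived from a noisy read-out of its
own error, and — on revision trials — shifts towards the partner by a
fraction generated from a linear mixed model: fixed effects of
normalised confidence (c = confidence/6), the influence exerted over the
partner on the preceding observation trial, and their interaction, plus
per-participant Gaussian random effects and a Gaussian residual,
truncated to [0, 1] because the task forces the revised estimate to lie
between the two initial estimates.

Two generative modes mirror the two analysis models:

``"per_condition"``
    separate coefficient sets for human and computer partners, with
    random intercept and random confidence and influence slopes
    (the single-condition model's structure);
``"pooled"``
    one coefficient set over both conditions with a condition dummy
    (1 = human, 2 = computer) and its interactions, with random
    intercept and random confidence slope only (the pooled model's
    structure).

The default fixed effects are the package's reference coefficient sets,
so that fitting the corresponding model to a generated cohort is a
parameter-recovery experiment against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .task import SessionConfig, build_session

__all__ = [
    "AgentParams",
    "ParticipantAgent",
    "CohortTable",
    "HUMAN_BETA",
    "COMPUTER_BETA",
    "POOLED_BETA",
    "sample_initial_estimate",
    "report_confidence",
    "decide_revision",
    "generate_cohort",
]

# Reference fixed effects (intercept, confidence, influence, confidence x influence)
# for the per-condition revision model.  Slopes are the package's reference values
# for each partner type; intercepts keep the linear predictor inside [0, 1] so the
# task-rule truncation stays rare (see docs/methods.md).
HUMAN_BETA = (0.5, -0.3, 0.17, -0.21)
COMPUTER_BETA = (0.55, -0.37, 0.01, -0.03)

# Reference fixed effects for the pooled two-condition model, ordered
# (intercept, c, inf, cond, c:inf, c:cond, inf:cond, c:inf:cond) with the
# condition dummy coded 1 = human, 2 = computer.
POOLED_BETA = (0.65, -0.33, 0.11, 0.07, -0.4, -0.1, -0.09, 0.21)

# Perceptual concentration calibrated so mean |angular error| ~ 57 deg,
# and confidence cutpoints calibrated on the -|error| + noise read-out to give
# level shares ~ (.10, .15, .20, .25, .20, .10): levels 5-6 occur on ~30% of
# trials, so the partner's high-confidence branch is exercised.
KAPPA_SUBJECT = 1.0
META_NOISE_SD = 10.0
CONFIDENCE_CUTPOINTS = (-127.1, -84.3, -53.0, -26.3, -7.1)


@dataclass
class AgentParams:
    """Generative parameters of a synthetic participant cohort.

    Parameters
    ----------
    kappa_subject : von Mises concentration of initial estimates around the
        target (dimensionless; ``inf`` = perfect perception).
    meta_noise_sd : sd (degrees) of the noise on the -|error| read-out that
        feeds the confidence report.
    confidence_cutpoints : 5 increasing thresholds binning the read-out
        into confidence levels 1..6.
    model : ``"per_condition"`` or ``"pooled"`` generative mode.
    human_beta, computer_beta : per-condition fixed effects
        (intercept, c, inf, c:inf); used when ``model="per_condition"``.
    pooled_beta : 8 fixed effects of the pooled model; used when
        ``model="pooled"``.
    random_effect_sd : sds of the per-participant random intercept and
        slopes (slope entries beyond the mode's random structure are ignored).
    residual_sd : sd of the trial-level Gaussian revision noise.
    reciprocity_ramp : optional within-block growth of the influence slope
        (0 = stationary; g multiplies the slope by ``1 + g * trial_frac``),
        used to emulate reciprocity that builds up over a block.
    rt_lognormal : (mu, sigma) of log RT per timed event, seconds.
    """

    kappa_subject: float = KAPPA_SUBJECT
    meta_noise_sd: float = META_NOISE_SD
    confidence_cutpoints: tuple = CONFIDENCE_CUTPOINTS
    model: str = "per_condition"
    human_beta: tuple = HUMAN_BETA
    computer_beta: tuple = COMPUTER_BETA
    pooled_beta: tuple = POOLED_BETA
    random_effect_sd: dict = field(
        default_factory=lambda: {"intercept": 0.03, "confidence": 0.03, "influence": 0.025}
    )
    residual_sd: float = 0.035
    reciprocity_ramp: float = 0.0
    rt_lognormal: dict = field(
        default_factory=lambda: {
            "estimate": (1.0, 0.3),
            "confidence": (0.2, 0.3),
            "revision": (0.8, 0.3),
        }
    )

    def __post_init__(self):
        cuts = tuple(self.confidence_cutpoints)
        if len(cuts) != 5 or any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("confidence_cutpoints must be 5 strictly increasing values")
        if self.model not in ("per_condition", "pooled"):
            raise ValueError(f"model must be 'per_condition' or 'pooled', got {self.model!r}")
        if self.residual_sd < 0 or any(v < 0 for v in self.random_effect_sd.values()):
            raise ValueError("standard deviations must be non-negative")
        if len(self.human_beta) != 4 or len(self.computer_beta) != 4:
            raise ValueError("per-condition beta vectors must have 4 entries")
        if len(self.pooled_beta) != 8:
            raise ValueError("pooled beta vector must have 8 entries")


def sample_initial_estimate(target, params: AgentParams, rng):
    """One (estimate, internal_precision) draw; see ParticipantAgent for the batch API."""
    agent = ParticipantAgent(params, "scalar", rng)
    est, prec = agent.sample_initial_estimates(np.atleast_1d(np.asarray(target, float)), rng)
    return float(est[0]), float(prec[0])


def report_confidence(internal_precision, cutpoints=CONFIDENCE_CUTPOINTS) -> int:
    """Ordinal confidence level 1..6 for an internal precision read-out."""
    return int(np.searchsorted(np.asarray(cutpoints, float), internal_precision) + 1)


def decide_revision(conf_norm, prev_influence, condition, params: AgentParams, rng,
                    random_effects=None):
    """One revision fraction from the generative model (scalar convenience API).

    ``random_effects`` maps 'intercept'/'confidence'/'influence' to the
    participant's deviations (default all zero).  Missing (NaN)
    ``prev_influence`` is a hard error: with strict role alternation every
    revision trial has a preceding observation trial.
    """
    if not np.isfinite(prev_influence):
        raise ValueError("prev_influence is missing; revision trials always follow an observation trial")
    agent = ParticipantAgent(params, "scalar", None, random_effects=random_effects)
    out = agent.decide_revisions(
        np.atleast_1d(float(conf_norm)),
        np.atleast_1d(float(prev_influence)),
        condition,
        np.zeros(1),
        rng,
    )
    return float(out[0])


class ParticipantAgent:
    """A single synthetic participant with drawn random effects.

    In ``per_condition`` mode random effects are drawn independently per
    condition (the model is fitted separately per condition); in
    ``pooled`` mode one intercept and confidence-slope deviation are
    shared across conditions, matching each model's random structure.
    """

    def __init__(self, params: AgentParams, participant_id: str, rng, random_effects=None):
        self.params = params
        self.participant_id = participant_id
        sd = params.random_effect_sd
        if random_effects is not None:
            self.random_effects = dict(random_effects)
        elif rng is None:
            self.random_effects = {}
        elif params.model == "per_condition":
            self.random_effects = {
                cond: {
                    "intercept": rng.normal(0.0, sd.get("intercept", 0.0)),
                    "confidence": rng.normal(0.0, sd.get("confidence", 0.0)),
                    "influence": rng.normal(0.0, sd.get("influence", 0.0)),
                }
                for cond in ("human", "computer")
            }
        else:
            self.random_effects = {
                "intercept": rng.normal(0.0, sd.get("intercept", 0.0)),
                "confidence": rng.normal(0.0, sd.get("confidence", 0.0)),
            }

    def _effects_for(self, condition: str) -> dict:
        re = self.random_effects
        if self.params.model == "per_condition" and condition in re:
            return re[condition]
        return re

    def sample_initial_estimates(self, targets, rng):
        """Vectorised perception: von Mises estimates and the precision read-out."""
        targets = np.asarray(targets, dtype=float)
        k = self.params.kappa_subject
        if np.isinf(k):
            err = np.zeros_like(targets)
        else:
            err = np.degrees(rng.vonmises(0.0, k, size=targets.shape))
        estimates = (targets + err) % 360.0
        precision = -np.abs(err) + rng.normal(0.0, self.params.meta_noise_sd, size=targets.shape)
        return estimates, precision

    def report_confidences(self, precision):
        cuts = np.asarray(self.params.confidence_cutpoints, dtype=float)
        return np.searchsorted(cuts, np.asarray(precision, dtype=float)) + 1

    def decide_revisions(self, conf_norm, prev_influence, condition, trial_frac, rng):
        """Vectorised revision fractions for one block's revision trials."""
        conf_norm = np.asarray(conf_norm, dtype=float)
        prev_influence = np.asarray(prev_influence, dtype=float)
        if np.any(~np.isfinite(prev_influence)):
            raise ValueError(
                "prev_influence missing on a revision trial; roles must alternate "
                "observe/revise within a block"
            )
        p = self.params
        re = self._effects_for(condition)
        ramp = 1.0 + p.reciprocity_ramp * np.asarray(trial_frac, dtype=float)
        if p.model == "per_condition":
            b0, bc, bi, bci = p.human_beta if condition == "human" else p.computer_beta
            lp = (
                (b0 + re.get("intercept", 0.0))
                + (bc + re.get("confidence", 0.0)) * conf_norm
                + (bi + re.get("influence", 0.0)) * ramp * prev_influence
                + bci * conf_norm * prev_influence
            )
        else:
            cond = 1.0 if condition == "human" else 2.0
            b0, bc, bi, bcond, bci, bccond, bicond, bcicond = p.pooled_beta
            lp = (
                (b0 + re.get("intercept", 0.0))
                + (bc + re.get("confidence", 0.0)) * conf_norm
                + bi * ramp * prev_influence
                + bcond * cond
                + bci * conf_norm * prev_influence
                + bccond * conf_norm * cond
                + bicond * ramp * prev_influence * cond
                + bcicond * conf_norm * prev_influence * cond
            )
        noise = 0.0 if rng is None else rng.normal(0.0, p.residual_sd, size=lp.shape)
        return np.clip(lp + noise, 0.0, 1.0)

    def sample_rts(self, n, rng):
        rts = []
        for event in ("estimate", "confidence", "revision"):
            mu, sigma = self.params.rt_lognormal[event]
            rts.append(rng.lognormal(mu, sigma, size=n))
        return tuple(rts)

    def truth(self) -> dict:
        return {"participant_id": self.participant_id, "random_effects": self.random_effects}


@dataclass
class CohortTable:
    """Trial records for a cohort plus the generating ground truth."""

    trials: pd.DataFrame
    truth: dict

    @property
    def n_participants(self) -> int:
        return self.trials["participant_id"].nunique()


def generate_cohort(
    n_participants: int,
    session_config: Optional[SessionConfig] = None,
    params: Optional[AgentParams] = None,
    seed: int = 0,
) -> CohortTable:
    """Simulate a full cohort: one complete session per participant.

    Deterministic given ``seed``; per-participant streams are spawned
    from one seed sequence, so the table is byte-identical across runs.
    Ground-truth random effects are recorded for recovery tests.
    """
    session_config = session_config or SessionConfig()
    params = params or AgentParams()
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    frames, truths = [], []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"p{i:03d}"
        agent = ParticipantAgent(params, pid, rng)
        frames.append(build_session(session_config, agent, rng, participant_id=pid))
        truths.append(agent.truth())
    trials = pd.concat(frames, ignore_index=True)
    truth = {
        "params": {
            "model": params.model,
            "human_beta": list(params.human_beta),
            "computer_beta": list(params.computer_beta),
            "pooled_beta": list(params.pooled_beta),
            "random_effect_sd": dict(params.random_effect_sd),
            "residual_sd": params.residual_sd,
            "kappa_subject": params.kappa_subject,
        },
        "participants": truths,
    }
    return CohortTable(trials=trials, truth=truth)
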