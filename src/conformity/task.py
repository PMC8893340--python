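"""Task environment: partners, influence draws, and session schedules.

A session pairs one participant with four simulated partners — the 2x2
of cover story (human / computer) by susceptibility (susceptible /
insusceptible) — one partner per block of 30 trials.  Roles alternate
strictly: on odd (observation) trials the partner revises towards the
participant; on even (revision) trials the participant revises.

Partner behaviour follows the generative rules of the task:

* first estimates are von Mises around the target with concentration
  kappa = 7.4, except on high-confidence trials (participant confidence
  5 or 6), where they are uniform within +/-20 deg (behavioural setting)
  or +/-50 deg (fMRI setting) of the participant's estimate;
* the influence a partner lets the participant exert is drawn from
  U[0, 0.2] for insusceptible partners and, for susceptible partners,
  from the mixture 0.5*U[0.7, 1] + 0.2*U[0.3, 0.7] + 0.3*U[0, 0.3];
* the partner's revised estimate interpolates along the shorter arc
  towards the participant's initial estimate by the drawn influence, so
  the recorded influence statistic equals the draw by construction.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .circular import arc_distance, move_toward, shift_fraction

__all__ = [
    "ConfigError",
    "PartnerConfig",
    "SessionConfig",
    "KAPPA_PARTNER",
    "HIGH_CONFIDENCE_LEVELS",
    "HIGH_CONF_HALF_WIDTH",
    "INSUSCEPTIBLE_BOUND",
    "SUSCEPTIBLE_MIXTURE",
    "sample_partner_initial",
    "sample_influence",
    "partner_revision",
    "build_session",
]

KAPPA_PARTNER = 7.4
HIGH_CONFIDENCE_LEVELS = (5, 6)
HIGH_CONF_HALF_WIDTH = {"behavioural": 20.0, "fmri": 50.0}
INSUSCEPTIBLE_BOUND = 0.2
# (weight, low, high) of each uniform component for susceptible partners
SUSCEPTIBLE_MIXTURE = ((0.5, 0.7, 1.0), (0.2, 0.3, 0.7), (0.3, 0.0, 0.3))

COVER_STORIES = ("human", "computer")
SUSCEPTIBILITIES = ("susceptible", "insusceptible")
SETTINGS = tuple(HIGH_CONF_HALF_WIDTH)


class ConfigError(ValueError):
    """Malformed session, partner, or encoding configuration."""


@dataclass(frozen=True)
class PartnerConfig:
    """One simulated partner: its cover story and how susceptible it is."""

    label: str
    cover_story: str
    susceptibility: str
    setting: str = "fmri"

    def __post_init__(self):
        if self.cover_story not in COVER_STORIES:
            raise ConfigError(f"cover_story must be one of {COVER_STORIES}, got {self.cover_story!r}")
        if self.susceptibility not in SUSCEPTIBILITIES:
            raise ConfigError(
                f"susceptibility must be one of {SUSCEPTIBILITIES}, got {self.susceptibility!r}"
            )
        if self.setting not in SETTINGS:
            raise ConfigError(f"setting must be one of {SETTINGS}, got {self.setting!r}")


@dataclass(frozen=True)
class SessionConfig:
    """Block order and trial counts for one session (4 blocks x 30 trials).

    The four partners must realise the full cover-story x susceptibility
    design.  The default order interleaves human and computer blocks.
    """

    partners: tuple = ()
    n_trials: int = 30
    setting: str = "fmri"

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ConfigError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        partners = tuple(self.partners) or _default_partners(self.setting)
        object.__setattr__(self, "partners", partners)
        if len(partners) != 4:
            raise ConfigError(f"a session needs exactly 4 partners, got {len(partners)}")
        cells = {(p.cover_story, p.susceptibility) for p in partners}
        if len(cells) != 4:
            raise ConfigError(
                "the 4 partners must cover the 2x2 of cover_story x susceptibility; got "
                + ", ".join(f"{p.cover_story}/{p.susceptibility}" for p in partners)
            )
        if self.n_trials < 2 or self.n_trials % 2:
            raise ConfigError(f"n_trials must be a positive even number, got {self.n_trials}")

    @property
    def n_blocks(self) -> int:
        return len(self.partners)


def _default_partners(setting: str) -> tuple:
    return (
        PartnerConfig("human_susceptible", "human", "susceptible", setting),
        PartnerConfig("computer_susceptible", "computer", "susceptible", setting),
        PartnerConfig("human_insusceptible", "human", "insusceptible", setting),
        PartnerConfig("computer_insusceptible", "computer", "insusceptible", setting),
    )


def sample_partner_initial(target, self_initial, confidence, setting, rng, *, kappa=KAPPA_PARTNER):
    """Partner first estimates (degrees), vectorised over trials.

    Low-confidence trials (confidence <= 4) draw from a von Mises centred
    on the target with concentration ``kappa``; high-confidence trials
    (5 or 6) draw uniformly within the setting's half-width of the
    participant's own estimate, wrap-aware.  ``kappa=np.inf`` is the
    degenerate hook returning the target exactly.
    """
    if setting not in SETTINGS:
        raise ConfigError(f"setting must be one of {SETTINGS}, got {setting!r}")
    target = np.asarray(target, dtype=float)
    self_initial = np.asarray(self_initial, dtype=float)
    confidence = np.asarray(confidence)
    if np.any((confidence < 1) | (confidence > 6)):
        raise ValueError("confidence must lie in 1..6")
    shape = np.broadcast_shapes(target.shape, self_initial.shape, confidence.shape)
    target, self_initial, confidence = np.broadcast_to(target, shape), np.broadcast_to(
        self_initial, shape
    ), np.broadcast_to(confidence, shape)

    if np.isinf(kappa):
        vm = target.copy()
    else:
        vm = (target + np.degrees(rng.vonmises(0.0, kappa, size=shape))) % 360.0
    half_width = HIGH_CONF_HALF_WIDTH[setting]
    uni = (self_initial + rng.uniform(-half_width, half_width, size=shape)) % 360.0
    out = np.where(np.isin(confidence, HIGH_CONFIDENCE_LEVELS), uni, vm)
    return out.item() if out.ndim == 0 else out


def sample_influence(susceptibility, rng, size=None):
    """Draw influence fractions for one partner type.

    Insusceptible partners: U[0, 0.2].  Susceptible partners: the
    three-component uniform mixture with weights (0.5, 0.2, 0.3) on
    [0.7, 1], [0.3, 0.7] and [0, 0.3].
    """
    n = 1 if size is None else int(size)
    if susceptibility == "insusceptible":
        out = rng.uniform(0.0, INSUSCEPTIBLE_BOUND, size=n)
    elif susceptibility == "susceptible":
        weights = np.array([w for w, _, _ in SUSCEPTIBLE_MIXTURE])
        lows = np.array([lo for _, lo, _ in SUSCEPTIBLE_MIXTURE])
        highs = np.array([hi for _, _, hi in SUSCEPTIBLE_MIXTURE])
        comp = rng.choice(len(weights), size=n, p=weights)
        out = rng.uniform(lows[comp], highs[comp])
    else:
        raise ConfigError(
            f"susceptibility must be one of {SUSCEPTIBILITIES}, got {susceptibility!r}"
        )
    return out[0] if size is None else out


def partner_revision(partner_initial, self_initial, influence):
    """Partner revised estimate: shorter-arc interpolation by the drawn influence.

    Constructed so that ``shift_fraction(partner_initial, result,
    self_initial)`` equals ``influence``.  When the two initial estimates
    coincide there is nothing to revise towards and the partner keeps its
    estimate (the influence statistic is then undefined/missing).
    """
    moved = move_toward(partner_initial, self_initial, influence)
    zero = np.asarray(arc_distance(partner_initial, self_initial)) == 0
    out = np.where(zero, partner_initial, moved)
    return out.item() if np.ndim(out) == 0 else out


def build_session(config: SessionConfig, agent, rng, participant_id: str = "p000") -> pd.DataFrame:
    """Simulate one participant's full session as a trial table.

    ``agent`` supplies the participant side (initial estimates,
    confidence reports, revision decisions); see
    :class:`conformity.agents.ParticipantAgent`.  Targets are uniform on
    the circle.  Deterministic given ``rng``'s state.

    Returns a DataFrame with one row per trial (blocks x trials rows) and
    the full trial-record column dictionary (angles in degrees, RTs in
    seconds, statistics as fractions with NaN for undefined).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    frames = []
    for block_idx, partner in enumerate(config.partners, start=1):
        n = config.n_trials
        trial_index = np.arange(1, n + 1)
        role = np.where(trial_index % 2 == 1, "observe", "revise")
        targets = rng.uniform(0.0, 360.0, size=n)
        self_initial, precision = agent.sample_initial_estimates(targets, rng)
        confidence = agent.report_confidences(precision)
        partner_initial = sample_partner_initial(
            targets, self_initial, confidence, config.setting, rng
        )

        obs = role == "observe"
        influence_draw = np.full(n, np.nan)
        influence_draw[obs] = sample_influence(partner.susceptibility, rng, size=int(obs.sum()))

        reviser_final = np.full(n, np.nan)
        reviser_final[obs] = partner_revision(
            partner_initial[obs], self_initial[obs], influence_draw[obs]
        )
        influence_stat = np.full(n, np.nan)
        influence_stat[obs] = shift_fraction(
            partner_initial[obs], reviser_final[obs], self_initial[obs]
        )

        # each revision trial reciprocates the immediately preceding observation trial
        prev_influence = np.full(n, np.nan)
        prev_influence[~obs] = influence_stat[obs]

        conf_norm = confidence / 6.0
        trial_frac = (trial_index - 1) / max(n - 1, 1)
        revision = agent.decide_revisions(
            conf_norm[~obs],
            prev_influence[~obs],
            partner.cover_story,
            trial_frac[~obs],
            rng,
        )
        reviser_final[~obs] = move_toward(self_initial[~obs], partner_initial[~obs], revision)
        revision_stat = np.full(n, np.nan)
        revision_stat[~obs] = shift_fraction(
            self_initial[~obs], reviser_final[~obs], partner_initial[~obs]
        )

        rt_estimate, rt_confidence, rt_revision = agent.sample_rts(n, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "block": block_idx,
                    "trial_index": trial_index,
                    "role": role,
                    "partner_label": partner.label,
                    "condition": partner.cover_story,
                    "susceptibility": partner.susceptibility,
                    "setting": config.setting,
                    "target": targets,
                    "self_initial": self_initial,
                    "confidence": confidence,
                    "partner_initial": partner_initial,
                    "reviser_final": reviser_final,
                    "revision_stat": revision_stat,
                    "influence_stat": influence_stat,
                    "prev_influence": prev_influence,
                    "rt_estimate": rt_estimate,
                    "rt_confidence": rt_confidence,
                    "rt_revision": rt_revision,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
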