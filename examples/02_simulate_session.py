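"""Simulate one participant's session: 4 blocks x 30 trials.

Each block pairs the participant with one simulated partner from the
2x2 design of cover story (human/computer) x susceptibility.  Roles
alternate: on odd trials the partner revises towards the participant
(observation), on even trials the participant revises (revision).
"""

import numpy as np

from conformity import AgentParams, ParticipantAgent, SessionConfig, build_session

rng = np.random.default_rng(7)
agent = ParticipantAgent(AgentParams(), "p000", rng)
trials = build_session(SessionConfig(setting="fmri"), agent, rng)

print(trials[["block", "trial_index", "role", "partner_label", "confidence",
              "revision_stat", "influence_stat"]].head(8).to_string(index=False))

by_partner = trials.groupby("partner_label")[["revision_stat", "influence_stat"]].mean()
print("\nmean statistics per partner:")
print(by_partner.round(3).to_string())
print("\nThe susceptible partners let the participant pull their estimates")
print("(high mean influence); the insusceptible ones barely move (< 0.2 by design).")
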