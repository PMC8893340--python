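"""Annotation, nonparametric statistics, sliding windows, mixed models."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import conformity as cf
from conformity.behaviour import (
    DegenerateTestError,
    annotate,
    holm_adjust,
    signed_rank,
    sliding_window_revision,
)


def _tiny_table():
    rows = [
        # block 1, human: observe then revise
        dict(participant_id="p0", block=1, trial_index=1, role="observe",
             condition="human", susceptibility="susceptible", confidence=4,
             target=10.0, self_initial=60.0, partner_initial=0.0, reviser_final=30.0),
        dict(participant_id="p0", block=1, trial_index=2, role="revise",
             condition="human", susceptibility="susceptible", confidence=3,
             target=10.0, self_initial=0.0, partner_initial=60.0, reviser_final=30.0),
    ]
    return pd.DataFrame(rows)


class TestAnnotate:
    def test_shift_statistics_and_normalised_confidence(self):
        out = annotate(_tiny_table())
        obs, rev = out.iloc[0], out.iloc[1]
        assert obs["influence_stat"] == pytest.approx(0.5)  # partner 0 -> 30, gap 60
        assert np.isnan(obs["revision_stat"])
        assert rev["revision_stat"] == pytest.approx(0.5)  # self 0 -> 30, gap 60
        assert np.isnan(rev["influence_stat"])
        assert rev["conf_norm"] == pytest.approx(0.5)  # confidence 3 / 6
        assert rev["prev_influence"] == pytest.approx(0.5)
        assert rev["cond"] == 1.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            annotate(_tiny_table().drop(columns=["partner_initial"]))

    def test_zero_disagreement_trials_dropped(self):
        t = _tiny_table()
        t.loc[1, "partner_initial"] = 0.0  # same as self_initial
        t.loc[1, "reviser_final"] = 0.0
        out = annotate(t)
        assert len(out) == 1
        assert out.iloc[0]["role"] == "observe"

    def test_recomputes_what_the_simulator_recorded(self, one_session):
        out = annotate(one_session)
        rev = out[out["role"] == "revise"]
        assert np.allclose(
            rev["revision_stat"], one_session.loc[rev.index, "revision_stat"], atol=1e-9
        )


class TestSignedRank:
    def test_exact_p_matches_exhaustive_enumeration(self):
        """Two-sided exact p against brute force over all sign assignments."""
        d = np.array([1.2, -0.4, 2.3, 0.7, -1.9, 3.1, 0.2, -0.6])
        res = signed_rank(d, mu=0.0)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
        dist = np.asarray(dist, float)
        p_exact = min(
            1.0,
            2.0 * min(np.mean(dist <= w_obs), np.mean(dist >= w_obs)),
        )
        assert res.statistic == pytest.approx(w_obs)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_flip_symmetry(self):
        x = np.array([0.3, -1.2, 0.8, 2.1, -0.5, 0.9, 1.7])
        assert signed_rank(x).p == pytest.approx(signed_rank(-x).p)

    def test_paired_form_and_scalar_null_agree(self):
        x = np.array([1.0, 2.0, 3.0, 2.5, 1.5])
        y = np.array([0.5, 2.5, 2.0, 2.0, 0.5])
        assert signed_rank(x, y).p == pytest.approx(signed_rank(x - y, mu=0.0).p)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            signed_rank(np.ones(10), np.ones(10))

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(0.3, 1.0, 200)
        res = signed_rank(x)
        ref = stats.wilcoxon(x, correction=True, method="approx")
        assert res.p == pytest.approx(ref.pvalue)
        assert res.n == 200


class TestHolm:
    def test_hand_computed_step_down(self):
        assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_scale_with_family_size(self):
        m, q = 5, 0.03
        adj = holm_adjust([q] * m)
        assert adj[0] == pytest.approx(min(m * q, 1.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_adjusted_ps_dominate_raw_and_cap_at_one(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestSlidingWindow:
    def test_window_count(self):
        n_rev = 15  # 30-trial block
        t = pd.DataFrame(
            dict(
                participant_id="p0",
                block=1,
                trial_index=np.arange(2, 2 * n_rev + 1, 2),
                role="revise",
                condition="human",
                susceptibility="susceptible",
                revision_stat=0.4,
            )
        )
        w = sliding_window_revision(t, window=5, step=1)
        assert len(w) == n_rev - 5 + 1
        assert np.allclose(w["mean_revision"], 0.4)

    def test_too_few_trials_warns_and_returns_empty(self):
        t = pd.DataFrame(
            dict(participant_id="p0", block=1, trial_index=[2, 4], role="revise",
                 condition="human", susceptibility="susceptible", revision_stat=[0.1, 0.2])
        )
        with pytest.warns(UserWarning):
            w = sliding_window_revision(t, window=5)
        assert w.empty

    def test_reciprocity_ramp_raises_late_windows(self):
        """Agents whose influence slope grows within a block show rising
        revision towards the susceptible human partner."""
        params = cf.AgentParams(reciprocity_ramp=1.5)
        co = cf.generate_cohort(40, params=params, seed=5)
        w = sliding_window_revision(annotate(co.trials))
        sub = w[(w["condition"] == "human") & (w["susceptibility"] == "susceptible")]
        first = sub[sub["window_index"] == 0]["mean_revision"].mean()
        last = sub[sub["window_index"] == sub["window_index"].max()]["mean_revision"].mean()
        assert last > first + 0.02


class TestMixedModels:
    def test_near_noiseless_cohort_identifies_generating_coefficients(self):
        params = cf.AgentParams(
            residual_sd=1e-4,
            random_effect_sd={"intercept": 0, "confidence": 0, "influence": 0},
        )
        co = cf.generate_cohort(8, params=params, seed=3)
        fit = cf.fit_lmm2(annotate(co.trials), "human", dof="residual")
        est = fit.terms["estimate"]
        for got, want in zip(est, params.human_beta):
            assert got == pytest.approx(want, abs=1e-4)

    def test_relabelling_and_rotation_invariance(self, small_cohort):
        t1 = annotate(small_cohort.trials)
        rotated = small_cohort.trials.copy()
        for col in ("target", "self_initial", "partner_initial", "reviser_final"):
            rotated[col] = (rotated[col] + 123.456) % 360.0
        relabel = {p: f"z{i}" for i, p in enumerate(t1["participant_id"].unique())}
        rotated["participant_id"] = rotated["participant_id"].map(relabel)
        t2 = annotate(rotated)
        f1 = cf.fit_lmm2(t1, "human", dof="residual")
        f2 = cf.fit_lmm2(t2, "human", dof="residual")
        assert np.allclose(f1.terms["estimate"], f2.terms["estimate"], atol=1e-6)

    def test_lmm1_needs_both_conditions(self, annotated_small):
        human_only = annotated_small[annotated_small["condition"] == "human"]
        with pytest.raises(ValueError):
            cf.fit_lmm1(human_only)

    def test_random_structure_preferred_by_bic(self):
        """The shipped random structure (confidence slope random) beats the
        confidence-fixed variant on a default cohort by BIC."""
        co = cf.generate_cohort(30, seed=21)
        table = annotate(co.trials)
        from conformity.mixed import fit_mixed

        sub = table[(table["role"] == "revise") & (table["condition"] == "human")]
        sub = sub[np.isfinite(sub["prev_influence"])]
        full = fit_mixed(
            sub, "revision_stat",
            [(), ("conf_norm",), ("prev_influence",), ("conf_norm", "prev_influence")],
            ["conf_norm", "prev_influence"], "participant_id", dof="residual",
        )
        conf_fixed = fit_mixed(
            sub, "revision_stat",
            [(), ("conf_norm",), ("prev_influence",), ("conf_norm", "prev_influence")],
            ["prev_influence"], "participant_id", dof="residual",
        )
        assert full.bic < conf_fixed.bic

    def test_estimates_and_satterthwaite_match_lmer(self, tmp_path):
        """Independent oracle: lme4/lmerTest on the identical data."""
        co = cf.generate_cohort(20, seed=13)
        table = annotate(co.trials)
        fit = cf.fit_lmm2(table, "human")
        sub = table[(table["role"] == "revise") & (table["condition"] == "human")]
        sub = sub[np.isfinite(sub["prev_influence"])]
        csv = tmp_path / "d.csv"
        sub[["participant_id", "revision_stat", "conf_norm", "prev_influence"]].to_csv(
            csv, index=False
        )
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(revision_stat ~ conf_norm * prev_influence
                      + (1 | participant_id) + (0 + conf_norm | participant_id)
                      + (0 + prev_influence | participant_id), data = d, REML = TRUE)
            co <- summary(m)$coefficients
            write.csv(co, "{tmp_path / 'out.csv'}")
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert np.allclose(fit.terms["estimate"], ref["Estimate"], atol=2e-4)
        assert np.allclose(fit.terms["se"], ref["Std. Error"], rtol=0.02)
        assert np.allclose(fit.terms["df_den"], ref["df"], rtol=0.05)
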