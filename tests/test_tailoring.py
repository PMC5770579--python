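"""Tailoring: target selection vs brute-force oracle, staging, session flow."""

import itertools
from datetime import date, timedelta

import pytest
from hypothesis import given, strategies as st

from sbirtkit.errors import ConfigError, GoalNotInMenuError, StagingError
from sbirtkit.screening import RiskCategory
from sbirtkit.substances import CORE_SUBSTANCES, Substance
from sbirtkit.tailoring import (
    IntentionWindow,
    Purpose,
    Stage,
    StagingAnswers,
    Track,
    assign_track,
    build_session,
    record_goal_plan,
    select_stage_modules,
    select_target_drug,
    stage_from_answers,
)

REF = date(2020, 6, 1)


def oracle_select(scores, ranking_order, eligible):
    """Brute-force argmax with harm-ranking tie-break."""
    candidates = [
        (s, scores.get(s, 0)) for s in eligible if scores.get(s, 0) >= 4
    ]
    if not candidates:
        return None
    best_score = max(v for _, v in candidates)
    tied = [s for s, v in candidates if v == best_score]
    return min(tied, key=ranking_order.index)


class TestSelectTargetDrug:
    def test_strict_maximum(self, config):
        scores = {Substance.OPIOIDS: 30, Substance.COCAINE: 12}
        assert (
            select_target_drug(scores, config.ranking, config.eligible)
            is Substance.OPIOIDS
        )

    def test_tie_broken_by_harm_ranking(self, config):
        scores = {Substance.OPIOIDS: 21, Substance.CANNABIS: 21}
        assert (
            select_target_drug(scores, config.ranking, config.eligible)
            is Substance.OPIOIDS
        )

    def test_all_low_screens_out(self, config):
        scores = {s: 3 for s in CORE_SUBSTANCES}
        assert select_target_drug(scores, config.ranking, config.eligible) is None

    def test_empty_eligible_set_rejected(self, config):
        with pytest.raises(ValueError):
            select_target_drug({}, config.ranking, frozenset())

    def test_tobacco_and_alcohol_not_targeted_by_default(self, config):
        scores = {Substance.TOBACCO: 39, Substance.ALCOHOL: 39, Substance.CANNABIS: 5}
        assert (
            select_target_drug(scores, config.ranking, config.eligible)
            is Substance.CANNABIS
        )

    def test_exhaustive_agreement_with_oracle(self, config):
        # every eligible-substance score vector over the boundary values
        eligible = sorted(config.eligible, key=lambda s: s.value)
        order = config.ranking.order
        values = (0, 3, 4, 26, 27)
        for combo in itertools.product(values, repeat=len(eligible)):
            scores = dict(zip(eligible, combo))
            assert select_target_drug(
                scores, config.ranking, config.eligible
            ) is oracle_select(scores, order, eligible)

    @given(
        tobacco=st.integers(0, 39),
        alcohol=st.integers(0, 39),
        cannabis=st.sampled_from([0, 3, 4, 26, 27]),
        opioids=st.sampled_from([0, 3, 4, 26, 27]),
    )
    def test_ineligible_scores_never_change_the_choice(
        self, tobacco, alcohol, cannabis, opioids
    ):
        from sbirtkit.tailoring import TailoringConfig

        config = TailoringConfig.default()
        base = {Substance.CANNABIS: cannabis, Substance.OPIOIDS: opioids}
        with_extras = {
            **base,
            Substance.TOBACCO: tobacco,
            Substance.ALCOHOL: alcohol,
        }
        assert select_target_drug(
            base, config.ranking, config.eligible
        ) is select_target_drug(with_extras, config.ranking, config.eligible)


class TestAssignTrack:
    @pytest.mark.parametrize(
        "category,track",
        [
            (RiskCategory.NONE, Track.SCREENED_OUT),
            (RiskCategory.LOW, Track.SCREENED_OUT),
            (RiskCategory.MODERATE, Track.MODERATE),
            (RiskCategory.HIGH, Track.HIGH),
            (None, Track.SCREENED_OUT),
        ],
    )
    def test_mapping(self, category, track):
        assert assign_track(category) is track


def answers(changed=False, days_ago=None, window=None):
    return StagingAnswers(
        behavior_changed=changed,
        change_date=REF - timedelta(days=days_ago) if days_ago is not None else None,
        intention_window=window,
        reference_date=REF,
    )


class TestStaging:
    def test_changed_two_months_ago_is_action(self):
        assert stage_from_answers(answers(True, days_ago=61)) is Stage.ACTION

    def test_changed_eight_months_ago_is_maintenance(self):
        assert stage_from_answers(answers(True, days_ago=244)) is Stage.MAINTENANCE

    def test_six_month_boundary(self):
        assert stage_from_answers(answers(True, days_ago=182)) is Stage.ACTION
        assert stage_from_answers(answers(True, days_ago=183)) is Stage.MAINTENANCE

    def test_intends_within_30_days_is_preparation(self):
        assert (
            stage_from_answers(answers(window=IntentionWindow.WITHIN_30D))
            is Stage.PREPARATION
        )

    def test_intends_within_6_months_is_contemplation(self):
        assert (
            stage_from_answers(answers(window=IntentionWindow.WITHIN_6MO))
            is Stage.CONTEMPLATION
        )

    def test_no_intention_is_precontemplation(self):
        assert (
            stage_from_answers(answers(window=IntentionWindow.NONE_6MO))
            is Stage.PRECONTEMPLATION
        )

    def test_change_date_after_reference_rejected(self):
        with pytest.raises(StagingError):
            stage_from_answers(answers(True, days_ago=-3))

    def test_change_date_required_when_changed(self):
        with pytest.raises(ValueError):
            StagingAnswers(behavior_changed=True, reference_date=REF)

    @given(
        changed=st.booleans(),
        days_ago=st.integers(0, 2000),
        window=st.sampled_from(list(IntentionWindow)),
    )
    def test_staging_is_total_and_exclusive(self, changed, days_ago, window):
        a = answers(changed, days_ago if changed else None, None if changed else window)
        stage = stage_from_answers(a)
        assert stage in list(Stage)
        # exclusivity: re-deriving gives the same single stage
        assert stage_from_answers(a) is stage


class TestStageModules:
    def test_precontemplation_quit_includes_pros_module(self, config):
        modules = select_stage_modules(Stage.PRECONTEMPLATION, Purpose.QUIT, config)
        assert "pros_of_change" in modules.module_ids

    @pytest.mark.parametrize("stage", list(Stage))
    @pytest.mark.parametrize("purpose", list(Purpose))
    def test_exactly_three_modules_everywhere(self, config, stage, purpose):
        assert len(select_stage_modules(stage, purpose, config).module_ids) == 3

    def test_deterministic(self, config):
        a = select_stage_modules(Stage.ACTION, Purpose.QUIT, config)
        b = select_stage_modules(Stage.ACTION, Purpose.QUIT, config)
        assert a == b

    def test_missing_mapping_raises(self, config):
        broken = object.__new__(type(config))
        broken.__dict__.update(config.__dict__)
        broken.stage_modules = {Purpose.QUIT: {}}
        with pytest.raises(ConfigError):
            select_stage_modules(Stage.ACTION, Purpose.QUIT, broken)


class TestBuildSession:
    def test_high_risk_session_has_treatment_branch(self, session_factory):
        session = session_factory(
            target=Substance.COCAINE, score=29, quit_stage=Stage.CONTEMPLATION
        )
        assert session.track is Track.HIGH
        assert session.treatment_needed
        assert session.treatment_stage is not None
        assert session.treatment_modules.purpose is Purpose.SEEK_TREATMENT
        assert session.quit_modules is not None

    def test_moderate_session_has_no_treatment_branch(self, session_factory):
        session = session_factory(target=Substance.OPIOIDS, score=21)
        assert session.track is Track.MODERATE
        assert not session.treatment_needed
        assert session.treatment_stage is None
        assert session.treatment_modules is None

    def test_all_never_interview_is_screened_out(self, weights, config):
        from sbirtkit.cohort import simulate_interview

        interview = simulate_interview({}, weights)
        session = build_session(interview, None, weights=weights, config=config)
        assert session.track is Track.SCREENED_OUT
        assert session.target_drug is None
        assert session.quit_modules is None
        assert len(session.assessments) == 9

    def test_treatment_branch_iff_score_at_least_27(self, weights, config):
        from tests.conftest import make_session

        for score in range(4, 40):
            session = make_session(weights, config, score=score)
            assert session.treatment_needed is (score >= 27)
            assert (session.treatment_stage is not None) is (score >= 27)

    def test_missing_treatment_answers_raises(self, weights, config):
        from sbirtkit.cohort import simulate_interview, staging_for_stage

        interview = simulate_interview({Substance.COCAINE: 30}, weights)
        with pytest.raises(StagingError):
            build_session(
                interview,
                staging_for_stage(Stage.CONTEMPLATION, 1),
                None,
                weights=weights,
                config=config,
            )

    def test_education_payload_present_for_target(self, session_factory):
        session = session_factory(target=Substance.OPIOIDS, score=21)
        assert session.education  # configured bullets for the target drug

    def test_session_json_round_trip(self, session_factory):
        from sbirtkit.tailoring import TailoredSession

        session = session_factory(score=29)
        assert TailoredSession.from_json(session.to_json()) == session


class TestGoalPlan:
    def test_record_valid_goal(self, session_factory):
        session = session_factory(score=21)
        goal = session.goal_menu[0]
        updated = record_goal_plan(session, goal, when="tonight", how="call a friend")
        assert updated.goal_plan.chosen_goal == goal

    def test_goal_from_other_stage_menu_rejected(self, session_factory, config):
        session = session_factory(score=21, quit_stage=Stage.CONTEMPLATION)
        foreign_goal = config.goal_menus[Purpose.QUIT][Stage.ACTION][0]
        with pytest.raises(GoalNotInMenuError):
            record_goal_plan(session, foreign_goal)

    def test_idempotent_re_record(self, session_factory):
        session = session_factory(score=21)
        goal = session.goal_menu[0]
        once = record_goal_plan(session, goal, when="x")
        twice = record_goal_plan(once, goal, when="x")
        assert once == twice
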