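import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogload._errors import (
    DegenerateMeasureError,
    DomainError,
    InsufficientDataError,
    MissingDataError,
    SchemaError,
)
from cogload.marginals import TABLE1_MARGINALS
from cogload.scoring import (
    AL_DOMAINS,
    ZReference,
    affective_state,
    allostatic_load,
    cognitive_reserve,
    creatinine_correct,
    leisure_score,
    occupation_score,
    pacc5,
    physical_activity_score,
    rmssd,
    score_cohort,
    sdann,
    sdnn,
    sleep_quality,
    zscore_composite,
)
from cogload.synthetic import (
    PACC5_TESTS,
    LeisureBlock,
    LifestyleHistory,
    OccupationEpisode,
    SportEpisode,
)

SQRT_HALF = 1.0 / np.sqrt(2.0)  # z-score of two points under the n-1 convention


def empty_leisure():
    return tuple(() for _ in range(9))


class TestZScoreComposite:
    def test_two_participant_convention_factor(self):
        """Pins the sample-SD (n-1) convention: two values give z = ±1/√2."""
        table = pd.DataFrame({"m": [1.0, 3.0]})
        out = zscore_composite(table, ["m"])
        assert out.tolist() == pytest.approx([-SQRT_HALF, SQRT_HALF])

    def test_degenerate_measure_named(self):
        table = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateMeasureError, match="flat"):
            zscore_composite(table, ["flat", "ok"])

    def test_sign_flip_negates_that_measures_contribution(self, rng):
        """Flipping a measure's sign equals negating its z-score in the
        pre-restandardization average (checked against a numpy oracle)."""
        table = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        out = zscore_composite(table, ["a", "b"], signs={"b": -1})
        za = (table["a"] - table["a"].mean()) / table["a"].std(ddof=1)
        zb = (table["b"] - table["b"].mean()) / table["b"].std(ddof=1)
        avg = (za - zb) / 2.0  # a participant above the mean on b is pulled down
        expected = (avg - avg.mean()) / avg.std(ddof=1)
        assert out.to_numpy() == pytest.approx(expected.to_numpy())

    def test_cohort_mean_zero_sd_one(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        out = zscore_composite(table, list("abc"))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("ab"))
        base = zscore_composite(table, list("ab"))
        perm = rng.permutation(30)
        shuffled = zscore_composite(table.iloc[perm].reset_index(drop=True), list("ab"))
        assert shuffled.to_numpy() == pytest.approx(base.to_numpy()[perm])


class TestPACC5:
    def test_at_reference_means_is_zero_and_one_sd_is_one(self):
        means = {m: TABLE1_MARGINALS[m].mean for m in PACC5_TESTS}
        sds = {m: TABLE1_MARGINALS[m].sd for m in PACC5_TESTS}
        ref = ZReference(means, sds)
        row = pd.DataFrame([means])
        assert pacc5(row, ref=ref).iloc[0] == pytest.approx(0.0)
        bumped = row.copy()
        bumped["fcsrt"] += sds["fcsrt"]
        assert pacc5(bumped, ref=ref).iloc[0] == pytest.approx(1.0)

    def test_is_sum_not_mean(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 5)), columns=list(PACC5_TESTS))
        out = pacc5(table)
        zsum = sum(
            (table[m] - table[m].mean()) / table[m].std(ddof=1) for m in PACC5_TESTS
        )
        assert out.to_numpy() == pytest.approx(zsum.to_numpy())

    def test_missing_column_raises(self):
        with pytest.raises(MissingDataError, match="mattis"):
            pacc5(pd.DataFrame({m: [1.0] for m in PACC5_TESTS[:-1]}))


class TestLifestyleScores:
    def test_occupation_examples(self):
        h1 = LifestyleHistory((OccupationEpisode(3, 40, 10),), (), empty_leisure())
        assert occupation_score(h1) == 1200.0
        h2 = LifestyleHistory(
            (OccupationEpisode(2, 20, 5), OccupationEpisode(4, 38, 20)), (), empty_leisure()
        )
        assert occupation_score(h2) == 3240.0
        assert occupation_score(LifestyleHistory()) == 0.0

    def test_sport_period_averaging(self):
        all_periods = LifestyleHistory(
            (), tuple(SportEpisode(8, 3, p) for p in (1, 2, 3, 4)), empty_leisure()
        )
        assert physical_activity_score(all_periods) == 24.0
        one_period = LifestyleHistory((), (SportEpisode(8, 3, 1),), empty_leisure())
        assert physical_activity_score(one_period) == 6.0

    def test_leisure_examples(self):
        slots = [(LeisureBlock(1, 52, 10),)] + [()] * 8
        h = LifestyleHistory((), (), tuple(slots))
        assert leisure_score(h) == pytest.approx(520.0 / 9.0)
        assert leisure_score(LifestyleHistory()) == 0.0

    def test_leisure_slot_count_enforced(self):
        with pytest.raises(SchemaError):
            LifestyleHistory((), (), tuple(() for _ in range(8)))

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            OccupationEpisode(3, -1, 10)
        with pytest.raises(DomainError):
            SportEpisode(8, 3, 5)
        with pytest.raises(DomainError):
            LeisureBlock(1, -52, 10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 9), st.floats(0, 60), st.floats(0, 45)),
            max_size=6,
        )
    )
    def test_occupation_matches_bruteforce(self, episodes):
        h = LifestyleHistory(
            tuple(OccupationEpisode(c, hw, y) for c, hw, y in episodes), (), empty_leisure()
        )
        expected = 0.0
        for c, hw, y in episodes:
            expected += c * hw * y
        assert occupation_score(h) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(1, 12), st.floats(0, 20), st.integers(1, 4)),
            max_size=8,
        )
    )
    def test_sport_matches_bruteforce(self, episodes):
        h = LifestyleHistory(
            (), tuple(SportEpisode(m, t, p) for m, t, p in episodes), empty_leisure()
        )
        per_period = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
        for m, t, p in episodes:
            per_period[p] += m * t
        assert physical_activity_score(h) == pytest.approx(sum(per_period.values()) / 4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.floats(0, 5), st.floats(0, 365), st.floats(0, 50)),
                max_size=3,
            ),
            min_size=9,
            max_size=9,
        )
    )
    def test_leisure_matches_bruteforce(self, slots):
        h = LifestyleHistory(
            (), (),
            tuple(tuple(LeisureBlock(f, t, p) for f, t, p in blocks) for blocks in slots),
        )
        expected = sum(sum(f * t * p for f, t, p in blocks) for blocks in slots) / 9.0
        assert leisure_score(h) == pytest.approx(expected)


class TestHeartRateVariability:
    def test_constant_series(self):
        const = np.full(100, 800.0)
        assert rmssd(const) == 0.0
        assert sdann(const) == 0.0

    def test_alternating_rmssd(self):
        rr = np.tile([800.0, 850.0], 50)
        assert rmssd(rr) == pytest.approx(50.0)

    def test_matches_bruteforce_formulas(self, rng):
        rr = rng.uniform(700, 1100, 500)
        diffs = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
        assert rmssd(rr) == pytest.approx(np.sqrt(np.mean(np.square(diffs))))
        assert sdnn(rr) == pytest.approx(np.std(rr, ddof=1))

    def test_sdann_degenerates_to_sdnn_on_short_recording(self, rng):
        rr = rng.uniform(700, 1100, 300)  # ~4.5 min of beats
        assert sdann(rr) == sdnn(rr)

    def test_sdann_uses_segment_means_on_long_recording(self, rng):
        rr = rng.uniform(700, 1100, 4000)
        seg = (np.cumsum(rr) - rr) // (5 * 60_000.0)
        means = [rr[seg == k].mean() for k in range(int(seg[-1]) + 1)]
        assert sdann(rr) == pytest.approx(np.std(means, ddof=1))

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            rmssd([800.0])


class TestCreatinineCorrection:
    def test_examples_and_scale_invariance(self):
        assert creatinine_correct(48.0, 1.0) == 48.0
        assert creatinine_correct(48.0, 2.0) == 24.0
        assert creatinine_correct(96.0, 2.0) == creatinine_correct(48.0, 1.0)
        with pytest.raises(DomainError):
            creatinine_correct(48.0, 0.0)


class TestAllostaticLoad:
    def test_hand_computed_three_participant_panel(self, default_cohort):
        """The full z pipeline on a 3-participant panel equals an independent
        hand computation (standardize, sign, average, re-standardize)."""
        table = default_cohort.head(3).reset_index(drop=True)
        global_score, subs = allostatic_load(table)

        work = table.copy()
        for name in ("cortisol", "adrenaline", "noradrenaline"):
            work[f"{name}_corrected"] = work[name] / work["serum_creatinine"]
        expected_subs = {}
        for domain, members in AL_DOMAINS.items():
            zs = []
            for m, sign in members.items():
                col = work[m].to_numpy()
                zs.append(sign * (col - col.mean()) / col.std(ddof=1))
            avg = np.mean(zs, axis=0)
            expected_subs[domain] = (avg - avg.mean()) / avg.std(ddof=1)
        for domain in AL_DOMAINS:
            assert subs[domain].to_numpy() == pytest.approx(expected_subs[domain])
        avg = np.mean([expected_subs[d] for d in AL_DOMAINS], axis=0)
        expected_global = (avg - avg.mean()) / avg.std(ddof=1)
        assert global_score.to_numpy() == pytest.approx(expected_global)

    def test_raising_hdl_lowers_lipid_and_global_load(self, default_cohort):
        base_global, base_subs = allostatic_load(default_cohort)
        bumped = default_cohort.copy()
        bumped.loc[0, "hdl"] += 10.0
        new_global, new_subs = allostatic_load(bumped)
        assert new_subs["al_lipid"].iloc[0] < base_subs["al_lipid"].iloc[0]
        assert new_global.iloc[0] < base_global.iloc[0]

    def test_missing_constituent_column(self, default_cohort):
        with pytest.raises(MissingDataError, match="hdl"):
            allostatic_load(default_cohort.drop(columns=["hdl"]))

    def test_strict_mode_names_participant_and_measure(self, default_cohort):
        table = default_cohort.copy()
        table.loc[4, "crp"] = np.nan
        with pytest.raises(MissingDataError, match="crp"):
            allostatic_load(table, strict=True)


class TestOtherComposites:
    def test_affective_monotone_in_bdi(self, default_cohort):
        base = affective_state(default_cohort)
        bumped = default_cohort.copy()
        bumped.loc[0, "bdi"] += 3.0
        assert affective_state(bumped).iloc[0] > base.iloc[0]

    def test_affective_out_of_range(self, default_cohort):
        table = default_cohort.copy()
        table.loc[0, "bdi"] = 70.0
        with pytest.raises(DomainError):
            affective_state(table)

    def test_sleep_monotone_in_iv_and_range_checked(self, default_cohort):
        base = sleep_quality(default_cohort)
        bumped = default_cohort.copy()
        bumped.loc[0, "iv"] += 0.2
        assert sleep_quality(bumped).iloc[0] > base.iloc[0]
        bad = default_cohort.copy()
        bad.loc[0, "psqi"] = 25.0
        with pytest.raises(DomainError):
            sleep_quality(bad)

    def test_reserve_monotone_in_fnart(self, default_cohort):
        base, _ = cognitive_reserve(default_cohort)
        bumped = default_cohort.copy()
        bumped.loc[0, "fnart"] += 4.0
        new, _ = cognitive_reserve(bumped)
        assert new.iloc[0] > base.iloc[0]


class TestScoreCohort:
    def test_adds_all_composites_with_unit_scale(self, scored_cohort):
        for col in ("cr_global", "affective_global", "al_global", "sleep_global"):
            assert scored_cohort[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert scored_cohort[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert scored_cohort["pacc5"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_manifest_documents_signs(self, default_cohort):
        _, manifest = score_cohort(default_cohort)
        assert manifest["al_global"]["subdomains"]["al_lipid"]["hdl"] == -1
        assert manifest["pacc5"]["aggregation"] == "sum of z-scores"
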