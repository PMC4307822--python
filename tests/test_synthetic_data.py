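import numpy as np
import pytest

from vrdot.scoring import count_errors, efficacy_ratio, score_cohort
from vrdot.session_model import DEFAULT_PROTOCOL, ScoreParams
from vrdot.synthetic_data import (
    default_config,
    generate_cohort,
    generate_session,
    make_pilot,
    make_recovery_pilot,
)


@pytest.fixture(scope="module")
def cohort1():
    return generate_cohort(default_config(), seed=1)


class TestDefaultConfig:
    def test_group_sizes_and_anchors(self):
        cfg = default_config()
        assert tuple(cfg.groups[g].n for g in ("control", "aMCI", "mildAD")) == (72, 65, 68)
        assert cfg.dropout == pytest.approx(0.116)

    def test_error_rates_ordered_by_severity(self):
        cfg = default_config()
        c = cfg.groups["control"].error_rates
        m = cfg.groups["aMCI"].error_rates
        a = cfg.groups["mildAD"].error_rates
        assert all(x < y < z for x, y, z in zip(c, m, a))


class TestGenerateCohort:
    def test_enrolment_and_completion_counts(self, cohort1):
        assert len(cohort1) == 232
        completers = [s for s in cohort1.subjects if not s.dropout]
        assert len(completers) == 205
        assert sum(s.dropout for s in cohort1.subjects) == 27

    def test_determinism(self):
        c1 = generate_cohort(default_config(), seed=5)
        c2 = generate_cohort(default_config(), seed=5)
        assert c1 == c2

    def test_seeds_differ(self):
        assert generate_cohort(default_config(), seed=5) != generate_cohort(
            default_config(), seed=6
        )

    def test_dropouts_have_single_visit(self, cohort1):
        for s in cohort1.subjects:
            expected = 1 if s.dropout else 3
            assert len(s.visits) == expected
            assert len(s.sessions) == expected

    def test_control_mmse_moments_match_config(self, cohort1):
        vals = np.array(
            [s.visits[1]["mmse"] for s in cohort1.by_group("control")]
        )
        # truncation at 30 pulls the realised mean slightly below 29.1
        assert abs(vals.mean() - 29.1) < 4 * (1.0 / np.sqrt(len(vals))) + 0.25
        assert 0.5 < vals.std() < 1.5

    def test_scale_moments_within_4se(self, cohort1):
        # scales far from their bounds: sample mean ~ configured mean
        for scale, mean, sd in [("tmt_a_s", 44.2, 21.7), ("digit_symbol", 37.0, 11.1)]:
            vals = np.array([s.visits[1][scale] for s in cohort1.by_group("aMCI")])
            assert abs(vals.mean() - mean) < 4 * sd / np.sqrt(len(vals))

    def test_conversion_labels_amci_only(self, cohort1):
        for s in cohort1.subjects:
            if s.group == "aMCI" and not s.dropout:
                assert s.converted_to_ad in (True, False)
            else:
                assert s.converted_to_ad is None

    def test_mmse_declines_in_ad_group(self, cohort1):
        ad = [s for s in cohort1.by_group("mildAD") if not s.dropout]
        deltas = [s.visits[3]["mmse"] - s.visits[1]["mmse"] for s in ad]
        assert np.mean(deltas) < -1.0


class TestGeneratorScorerInverse:
    def test_thousand_sessions_round_trip(self):
        rng = np.random.default_rng(2024)
        n_act = len(DEFAULT_PROTOCOL.activities)
        for _ in range(1000):
            o = int(rng.integers(0, n_act))
            m = n_act - o
            r = int(rng.integers(0, 4)) if m else 0
            w = int(rng.integers(0, m)) if m > 1 else 0
            a = int(rng.integers(0, 5)) if m else 0
            reff = float(rng.uniform(0.1, 0.99))
            sess = generate_session("x", 1, (o, r, w, a), reff, DEFAULT_PROTOCOL, rng)
            assert count_errors(sess, DEFAULT_PROTOCOL).as_tuple() == (o, r, w, a)
            if m:
                assert efficacy_ratio(sess, DEFAULT_PROTOCOL) == pytest.approx(
                    reff, abs=0.005
                )

    def test_zero_error_draw(self):
        rng = np.random.default_rng(0)
        sess = generate_session("x", 1, (0, 0, 0, 0), 0.8, DEFAULT_PROTOCOL, rng)
        assert count_errors(sess, DEFAULT_PROTOCOL).as_tuple() == (0, 0, 0, 0)

    def test_infeasible_order_errors_capped(self):
        rng = np.random.default_rng(0)
        # 7 omissions leave one activity: no order error is performable
        sess = generate_session("x", 1, (7, 1, 5, 2), 0.5, DEFAULT_PROTOCOL, rng)
        assert count_errors(sess, DEFAULT_PROTOCOL).as_tuple() == (7, 1, 0, 2)


class TestGroupSeparation:
    def test_fi_ordering_over_seeds(self):
        params = ScoreParams(0.3, 0.2, 0.4, 0.1)
        for seed in range(5):
            cohort = generate_cohort(default_config(), seed=seed)
            df = score_cohort(cohort, params)
            base = df[df.visit_year == 1].copy()
            groups = {s.subject_id: s.group for s in cohort.subjects}
            base["group"] = base.subject_id.map(groups)
            means = base.groupby("group").fi.mean()
            assert means["control"] > means["aMCI"] > means["mildAD"]

    def test_reff_ordering_control_vs_ad(self):
        cohort = generate_cohort(default_config(), seed=1)
        df = score_cohort(cohort, ScoreParams(0, 0, 0, 0))
        base = df[df.visit_year == 1].copy()
        groups = {s.subject_id: s.group for s in cohort.subjects}
        base["group"] = base.subject_id.map(groups)
        means = base.groupby("group").reff.mean()
        assert means["control"] > means["mildAD"]


class TestPilots:
    def test_pilot_sizes_and_single_visit(self):
        pilot = make_pilot(seed=3)
        assert len(pilot) == 75
        sizes = {g: len(pilot.by_group(g)) for g in ("control", "aMCI", "mildAD")}
        assert sizes == {"control": 25, "aMCI": 26, "mildAD": 24}
        assert all(len(s.visits) == 1 and len(s.sessions) == 1 for s in pilot.subjects)

    def test_pilot_ages_anchored(self):
        pilot = make_pilot(seed=3)
        for g, mean, sd in [("control", 73.7, 4.0), ("aMCI", 74.2, 2.0), ("mildAD", 76.7, 3.0)]:
            ages = np.array([s.age for s in pilot.by_group(g)])
            assert abs(ages.mean() - mean) < 4 * sd / np.sqrt(len(ages)) + 0.1

    def test_recovery_pilot_deterministic(self):
        p1 = make_recovery_pilot((0.3, 0.2, 0.4, 0.1), n=30, seed=9)
        p2 = make_recovery_pilot((0.3, 0.2, 0.4, 0.1), n=30, seed=9)
        assert p1 == p2
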