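"""Adjudication, agreement, GEE stage means, Spearman, repeatability, windows."""

import numpy as np
import pandas as pd
import pytest

from ridgemetry import (
    CohortParams,
    ExamRecord,
    GraderLabels,
    TreatmentParams,
    adjudicate,
    filter_min_stage,
    gee_stage_means,
    generate_cohort,
    generate_repeat_captures,
    generate_treated_cohort,
    grader_agreement,
    repeatability,
    spearman_stage_thickness,
    treatment_window_summary,
)
from ridgemetry.stats import _assign_window


def make_record(mean_cont=2.0, stage=2, thickness=300.0, patient="P0", eye="OD",
                session="S0", a=None, b=None, treated=False, weeks=None):
    a = mean_cont if a is None else a
    b = mean_cont if b is None else b
    labels = GraderLabels.from_continuous(a, b)
    mc, adj = adjudicate(labels)
    return ExamRecord(
        patient_id=patient, eye=eye, session_id=session, postmenstrual_week=37.0,
        labels=labels, adjudicated_ordinal=adj, mean_continuous=mc,
        max_thickness_um=thickness, treated=treated, weeks_from_treatment=weeks,
        stage_true=stage,
    )


class TestAdjudication:
    @pytest.mark.parametrize(
        "a_ord,b_ord,a_cont,b_cont,expect_mean,expect_stage",
        [
            (2, 2, 2.0, 2.2, 2.1, 2),  # agreement passes through
            (2, 3, 2.3, 2.6, 2.45, 2),  # disagreement: round(2.45) = 2
            (1, 2, 1.4, 1.6, 1.5, 2),  # half rounds up
        ],
    )
    def test_rule(self, a_ord, b_ord, a_cont, b_cont, expect_mean, expect_stage):
        labels = GraderLabels(a_ord, b_ord, a_cont, b_cont)
        mean_cont, stage = adjudicate(labels)
        assert mean_cont == pytest.approx(expect_mean)
        assert stage == expect_stage

    def test_idempotent_on_agreement(self):
        for cont in (0.9, 1.1, 2.4, 3.0):
            labels = GraderLabels.from_continuous(cont, cont)
            _, stage = adjudicate(labels)
            assert stage == labels.grader_a_ordinal

    def test_inconsistent_labels_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GraderLabels(1, 2, 2.3, 2.0)  # a_ordinal should be 2


class TestMinStageFilter:
    def test_below_threshold_excluded(self):
        records = [make_record(a=0.4, b=0.5)]  # mean 0.45
        kept, n_excluded = filter_min_stage(records)
        assert kept == [] and n_excluded == 1

    def test_exact_threshold_retained(self):
        records = [make_record(a=0.4, b=0.6)]  # mean exactly 0.5
        kept, n_excluded = filter_min_stage(records)
        assert len(kept) == 1 and n_excluded == 0

    def test_empty_input(self):
        assert filter_min_stage([]) == ([], 0)


def hand_weighted_kappa(table, weights="linear"):
    """Independent contingency-table oracle for weighted kappa."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    k = table.shape[0]
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    w = d if weights == "linear" else d**2  # disagreement weights
    p_obs = (w * table / n).sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n**2
    p_exp = (w * expected).sum()
    return 1 - p_obs / p_exp


class TestAgreement:
    def test_identical_labels(self):
        records = [make_record(mean_cont=c) for c in (1.0, 1.5, 2.0, 2.5, 3.0) for _ in range(2)]
        res = grader_agreement(records)
        assert res.percent_agreement == 100.0
        assert res.weighted_kappa == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_matches_hand_computed_contingency_oracle(self):
        # 8 exact agreements and 2 one-step disagreements on labels {1, 2}
        pairs = [(1, 1)] * 4 + [(2, 2)] * 4 + [(1, 2), (2, 1)]
        records = [
            make_record(a=float(a), b=float(b)) for a, b in pairs
        ]
        res = grader_agreement(records)
        table = np.zeros((2, 2))
        for a, b in pairs:
            table[a - 1, b - 1] += 1
        assert res.percent_agreement == pytest.approx(80.0)
        assert res.weighted_kappa == pytest.approx(hand_weighted_kappa(table), abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_four_level_table_matches_oracle(self, weights):
        rng = np.random.default_rng(31)
        pairs = [
            (float(np.clip(c, 0, 3)), float(np.clip(c + rng.integers(-1, 2), 0, 3)))
            for c in rng.integers(0, 4, size=120)
        ]
        records = [make_record(a=a, b=b) for a, b in pairs]
        res = grader_agreement(records, kappa_weights=weights)
        table = np.zeros((4, 4))
        for a, b in pairs:
            table[int(a), int(b)] += 1
        assert res.weighted_kappa == pytest.approx(hand_weighted_kappa(table, weights), abs=1e-10)

    def test_independent_graders_have_near_zero_kappa(self):
        rng = np.random.default_rng(41)
        records = [
            make_record(a=float(rng.integers(0, 4)), b=float(rng.integers(0, 4)))
            for _ in range(2000)
        ]
        res = grader_agreement(records)
        assert abs(res.weighted_kappa) < 0.06  # ~3 SE at n=2000

    def test_kappa_decreases_with_marginal_imbalance(self):
        """At fixed observed disagreement pattern, concentrating the marginals
        reduces chance-corrected agreement."""
        balanced = np.array([[40, 5], [5, 50]])
        imbalanced = np.array([[85, 5], [5, 5]])
        assert hand_weighted_kappa(imbalanced) < hand_weighted_kappa(balanced)
        for table in (balanced, imbalanced):
            pairs = [(i + 1, j + 1) for i in range(2) for j in range(2)
                     for _ in range(int(table[i, j]))]
            records = [make_record(a=float(a), b=float(b)) for a, b in pairs]
            res = grader_agreement(records)
            assert res.weighted_kappa == pytest.approx(hand_weighted_kappa(table), abs=1e-10)

    def test_zero_variance_pearson_reported_as_nan(self):
        records = [make_record(a=2.0, b=float(b)) for b in (1.8, 2.0, 2.2, 2.4)]
        res = grader_agreement(records)
        assert np.isnan(res.pearson_r)
        assert any("Pearson" in n for n in res.notes)


class TestGEE:
    def test_reduces_to_per_stage_means_without_clustering(self):
        rng = np.random.default_rng(51)
        records = []
        for i in range(60):
            stage = 1 + i % 3
            records.append(
                make_record(
                    mean_cont=float(stage), stage=stage,
                    thickness=float(200 + 80 * stage + rng.normal(0, 30)),
                    patient=f"P{i:03d}",
                )
            )
        res = gee_stage_means(records)
        df = pd.DataFrame(
            {"stage": [r.adjudicated_ordinal for r in records],
             "y": [r.max_thickness_um for r in records]}
        )
        for stage, est in res.estimates.items():
            assert est.estimate_um == pytest.approx(
                df.loc[df["stage"] == stage, "y"].mean(), abs=1e-8
            )

    def test_single_cluster_rejected(self):
        records = [make_record(patient="P0", thickness=300.0 + i) for i in range(6)]
        with pytest.raises(ValueError, match="2 clusters"):
            gee_stage_means(records)

    def test_thin_stage_level_named(self):
        records = [make_record(patient=f"P{i}", mean_cont=2.0) for i in range(4)]
        records.append(make_record(patient="P9", mean_cont=3.0))
        with pytest.raises(ValueError, match=r"\[3\]"):
            gee_stage_means(records)

    def test_recovers_generating_stage_means_on_nested_cohort(self):
        """On one large nested cohort, every stage estimate lands within 3
        robust SEs of the generating mean (full replicate study in the
        acceptance suite)."""
        params = CohortParams(n_patients=100, seed=61)
        records = generate_cohort(params)
        res = gee_stage_means(records, stage_col="stage_true")
        for stage, est in res.estimates.items():
            truth = params.stage_thickness_means_um[stage - 1]
            assert abs(est.estimate_um - truth) <= 3 * est.se_um


class TestSpearman:
    def test_perfect_monotone(self):
        records = [make_record(a=c, b=c, thickness=100.0 * c**2) for c in (1.0, 1.5, 2.0, 2.5, 3.0)]
        rho, _ = spearman_stage_thickness(records)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        records = [make_record(a=c, b=c, thickness=500.0 - 100.0 * c) for c in (1.0, 1.5, 2.0, 2.5, 3.0)]
        rho, _ = spearman_stage_thickness(records)
        assert rho == pytest.approx(-1.0)

    def test_tied_values_match_average_rank_formula(self):
        stage = [1.0, 1.0, 2.0, 2.5, 3.0]
        thick = [250.0, 260.0, 300.0, 310.0, 480.0]
        records = [make_record(a=s, b=s, thickness=t) for s, t in zip(stage, thick)]
        rho, _ = spearman_stage_thickness(records)

        def avg_ranks(values):
            values = np.asarray(values)
            order = np.argsort(values, kind="stable")
            ranks = np.empty(len(values), dtype=float)
            ranks[order] = np.arange(1, len(values) + 1)
            for v in np.unique(values):
                ranks[values == v] = ranks[values == v].mean()
            return ranks

        rx, ry = avg_ranks(stage), avg_ranks(thick)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(71)
        stages = rng.uniform(0.5, 3.0, size=30).round(1)
        thicks = 200 + 100 * stages + rng.normal(0, 40, size=30)
        base = [make_record(a=s, b=s, thickness=float(t)) for s, t in zip(stages, thicks)]
        warped = [
            make_record(a=s, b=s, thickness=float(np.exp(t / 100)))
            for s, t in zip(stages, thicks)
        ]
        assert spearman_stage_thickness(base)[0] == pytest.approx(
            spearman_stage_thickness(warped)[0], abs=1e-12
        )

    def test_constant_column_undefined(self):
        records = [make_record(a=2.0, b=2.0, thickness=300.0 + i) for i in range(5)]
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_stage_thickness(records)
        assert np.isnan(rho)


class TestRepeatability:
    def test_identical_duplicates_are_perfectly_repeatable(self):
        df = pd.DataFrame(
            {"eye_id": np.repeat([f"E{i}" for i in range(20)], 2),
             "max_thickness_um": np.repeat(np.linspace(250, 500, 20), 2)}
        )
        res = repeatability(df)
        assert res.icc == pytest.approx(1.0)
        assert res.mean_cov_percent == 0.0
        assert res.n_eyes == 20 and res.n_measurements == 40

    def test_closed_form_variance_components(self):
        """sigma_b=100, sigma_w=10 gives ICC ~ 100^2/(100^2+10^2) ~ 0.99."""
        df = generate_repeat_captures(
            n_eyes=300, n_captures=2, between_eye_sd_um=100.0, within_eye_sd_um=10.0, seed=81
        )
        res = repeatability(df)
        assert res.icc == pytest.approx(100**2 / (100**2 + 10**2), abs=0.02)

    def test_matches_pingouin_icc1_on_balanced_data(self):
        import pingouin as pg

        df = generate_repeat_captures(n_eyes=25, n_captures=3, seed=91)
        res = repeatability(df)
        long = df.rename(
            columns={"eye_id": "targets", "capture": "raters", "max_thickness_um": "ratings"}
        )
        icc1 = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type").loc["ICC(1,1)", "ICC"]
        assert res.icc == pytest.approx(icc1, abs=1e-6)

    def test_single_capture_eyes_excluded_with_warning(self):
        df = pd.DataFrame(
            {"eye_id": ["E0", "E0", "E1", "E2"],
             "max_thickness_um": [300.0, 310.0, 400.0, 500.0]}
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = repeatability(df)
        assert res.n_eyes == 1 and res.n_measurements == 2
        assert np.isnan(res.icc)  # one eye cannot separate variance components

    def test_cov_is_mean_of_per_eye_cov(self):
        df = pd.DataFrame(
            {"eye_id": ["A", "A", "B", "B"],
             "max_thickness_um": [100.0, 110.0, 200.0, 180.0]}
        )
        res = repeatability(df)
        cov_a = np.std([100, 110], ddof=1) / 105 * 100
        cov_b = np.std([200, 180], ddof=1) / 190 * 100
        assert res.mean_cov_percent == pytest.approx((cov_a + cov_b) / 2)


class TestTreatmentWindows:
    def test_window_assignment_boundaries(self):
        assert _assign_window(-2.0) == "pre"
        assert _assign_window(-1.0) == "pre"
        assert _assign_window(-0.99) == "at"
        assert _assign_window(0.0) == "at"
        assert _assign_window(0.99) == "at"
        assert _assign_window(1.0) == "post"
        assert _assign_window(2.0) == "post"
        assert _assign_window(2.1) is None
        assert _assign_window(-3.0) is None

    def test_noise_free_rise_then_fall_ordering(self):
        params = TreatmentParams(visit_noise_sd_um=0.0)
        treated = generate_treated_cohort(
            params, n_patients=4, baseline_sd_um=0.0, within_patient_sd_um=0.0, seed=1
        )
        res = treatment_window_summary(treated)
        assert res.windows["pre"].mean_um < res.windows["at"].mean_um
        assert res.windows["post"].mean_um < res.windows["at"].mean_um

    def test_out_of_window_records_counted(self):
        params = TreatmentParams(observation_weeks=(-4.0, -2.0, 0.0, 2.0, 5.0))
        treated = generate_treated_cohort(params, n_patients=3, seed=2)
        res = treatment_window_summary(treated)
        assert res.n_excluded == 3 * 2 * 2  # weeks -4 and +5, both eyes

    def test_single_infant_falls_back_to_simple_means(self):
        treated = generate_treated_cohort(n_patients=1, seed=3)
        with pytest.warns(UserWarning, match="single infant"):
            res = treatment_window_summary(treated)
        assert set(res.windows) == {"pre", "at", "post"}

    def test_eyes_averaged_within_infant(self):
        """A patient's two eyes count once per visit, not twice."""
        params = TreatmentParams(visit_noise_sd_um=0.0)
        treated = generate_treated_cohort(
            params, n_patients=2, baseline_sd_um=0.0, within_patient_sd_um=50.0, seed=4
        )
        res = treatment_window_summary(treated)
        assert res.windows["at"].n_obs == 2  # one collapsed value per infant
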