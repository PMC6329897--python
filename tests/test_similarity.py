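"""Jaccard and ICC(3,1) against set-counting and ANOVA oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import paindraw as pdw
from paindraw.similarity import (
    ICCResult,
    InsufficientSubjectsError,
    MissingDataError,
    compare_cohort,
    icc31,
    jaccard_index,
    similarity_report,
)
from .conftest import make_drawing


# --- oracles -------------------------------------------------------------


def jaccard_by_sets(a_mask, b_mask):
    A = {tuple(p) for p in np.argwhere(a_mask)}
    B = {tuple(p) for p in np.argwhere(b_mask)}
    if not A | B:
        return None
    return len(A & B) / len(A | B)


def icc31_sums_of_squares(table):
    """ICC(3,1) from first-principles sums of squares (explicit loops)."""
    n, k = len(table), len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    bms = ss_rows / (n - 1)
    ems = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


# --- Jaccard -------------------------------------------------------------


class TestJaccard:
    def test_identity_is_one(self, toy_template):
        m = np.zeros((20, 20), bool)
        m[2:8, 3:9] = True
        a = make_drawing(toy_template, [{"front": m}])
        per_view, mean = jaccard_index(a, a, toy_template)
        assert per_view["front"] == 1.0
        assert mean == 1.0

    def test_disjoint_is_zero(self, toy_template):
        a = np.zeros((20, 20), bool); a[:3, :3] = True
        b = np.zeros((20, 20), bool); b[10:13, 10:13] = True
        da = make_drawing(toy_template, [{"front": a}])
        db = make_drawing(toy_template, [{"front": b}])
        _, mean = jaccard_index(da, db, toy_template)
        assert mean == 0.0

    def test_counting_example(self, toy_template):
        a = np.zeros((20, 20), bool); a[0, :12] = True          # 12 pixels
        b = np.zeros((20, 20), bool); b[0, 8:16] = True         # 8 pixels, 4 shared
        da = make_drawing(toy_template, [{"front": a}])
        db = make_drawing(toy_template, [{"front": b}])
        _, mean = jaccard_index(da, db, toy_template)
        assert mean == pytest.approx(4 / 16)

    def test_matches_set_oracle_and_symmetry(self, template):
        rng = np.random.default_rng(23)
        for _ in range(25):
            masks = []
            for _d in range(2):
                m = {
                    v: (rng.random(template.shape(v)) < 0.1)
                    & template.outline[v]
                    for v in template.views
                }
                masks.append(m)
            da = make_drawing(template, [masks[0]])
            db = make_drawing(template, [masks[1]])
            pv_ab, mean_ab = jaccard_index(da, db, template)
            pv_ba, mean_ba = jaccard_index(db, da, template)
            assert mean_ab == pytest.approx(mean_ba)
            for v in template.views:
                want = jaccard_by_sets(masks[0][v], masks[1][v])
                if want is None:
                    assert np.isnan(pv_ab[v])
                else:
                    assert pv_ab[v] == pytest.approx(want)

    def test_intensity_invariance(self, toy_template):
        m1 = np.zeros((20, 20), bool); m1[:5, :5] = True
        m2 = np.zeros((20, 20), bool); m2[3:8, 3:8] = True
        lo = make_drawing(toy_template, [{"front": m1}], intensities=[1.0])
        hi = make_drawing(toy_template, [{"front": m1}], intensities=[9.9])
        other = make_drawing(toy_template, [{"front": m2}], intensities=[5.0])
        assert jaccard_index(lo, other, toy_template)[1] == pytest.approx(
            jaccard_index(hi, other, toy_template)[1]
        )

    def test_both_empty_views_excluded(self, template):
        m = np.zeros(template.shape("front"), bool)
        m[tuple(np.argwhere(template.outline["front"])[:20].T)] = True
        a = make_drawing(template, [{"front": m}])
        per_view, mean = jaccard_index(a, a, template)
        assert per_view["front"] == 1.0
        assert np.isnan(per_view["back"])
        assert mean == 1.0  # only the drawn view contributes

    def test_all_views_empty_gives_nan(self, template):
        z = {v: np.zeros(template.shape(v), bool) for v in template.views}
        a = make_drawing(template, [z])
        _, mean = jaccard_index(a, a, template)
        assert np.isnan(mean)


# --- ICC(3,1) ------------------------------------------------------------


class TestICC31:
    def test_identical_columns(self):
        x = np.array([[1, 1], [4, 4], [2, 2], [9, 9]], float)
        assert icc31(x).estimate == pytest.approx(1.0)

    def test_shift_invariance_perfect_consistency(self):
        x = np.array([[1.0, 3.0], [4.0, 6.0], [2.0, 4.0], [9.0, 11.0]])
        res = icc31(x)
        assert res.estimate == pytest.approx(1.0)

    def test_small_integer_table_vs_oracle(self):
        table = [[9, 2], [6, 1], [8, 4], [7, 1], [10, 5], [6, 2]]
        res = icc31(np.array(table, float))
        assert res.estimate == pytest.approx(icc31_sums_of_squares(table), abs=1e-12)

    def test_random_tables_vs_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            x = rng.normal(size=(10, 2)) * rng.uniform(0.5, 3) + rng.uniform(-5, 5)
            assert icc31(x).estimate == pytest.approx(
                icc31_sums_of_squares(x.tolist()), abs=1e-10
            )

    def test_matches_pingouin_estimate_and_ci(self):
        import pingouin
        import pandas as pd

        rng = np.random.default_rng(37)
        x = rng.normal(size=(15, 2))
        x[:, 1] = 0.6 * x[:, 0] + 0.8 * x[:, 1]
        res = icc31(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile(["a", "b"], 15),
                "score": x.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        # consistency / single rater row (naming differs across versions)
        key = "ICC3" if "ICC3" in table.index else "ICC(C,1)"
        ref = table.loc[key]
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert res.estimate == pytest.approx(ref["ICC"], abs=1e-6)
        assert res.ci_low == pytest.approx(ref[ci_col][0], abs=6e-3)
        assert res.ci_high == pytest.approx(ref[ci_col][1], abs=6e-3)

    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 5),
        b=st.floats(-10, 10),
        c=st.floats(-10, 10),
    )
    def test_affine_invariance(self, seed, a, b, c):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 2))
        base = icc31(x).estimate
        shifted = x.copy()
        shifted[:, 1] += c                   # constant added to one column
        common = a * x + b                   # common affine transform
        assert icc31(shifted).estimate == pytest.approx(base, abs=1e-9)
        assert icc31(common).estimate == pytest.approx(base, abs=1e-9)

    def test_degenerate_table_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = icc31(np.full((5, 2), 3.0))
        assert res.estimate == 0.0
        assert np.isnan(res.ci_low) and np.isnan(res.ci_high)

    def test_input_contract_errors(self):
        with pytest.raises(InsufficientSubjectsError):
            icc31(np.ones((2, 2)))
        bad = np.ones((5, 2))
        bad[0, 0] = np.nan
        with pytest.raises(MissingDataError):
            icc31(bad)


# --- cohort comparison ---------------------------------------------------


class TestCompareCohort:
    def test_identical_pairs_give_perfect_agreement(self, template, default_cohort):
        import dataclasses

        records = [
            pdw.CohortRecord(
                patient_drawing=r.patient_drawing,
                doctor_drawing=dataclasses.replace(r.patient_drawing, role="doctor"),
            )
            for r in default_cohort[:10]
        ]
        res = compare_cohort(records, template)
        assert res.cohort_jaccard_mean == pytest.approx(1.0)
        assert res.icc_extent["whole"].estimate == pytest.approx(1.0)
        assert res.icc_clusters["whole"].estimate == pytest.approx(1.0)

    def test_independent_drawings_have_near_zero_extent_icc(self, template):
        # doctor drawings from an unrelated simulation stream
        cfg_a = pdw.SimulationConfig(template_size=(96, 64), n_subjects=200, seed=101)
        cfg_b = pdw.SimulationConfig(template_size=(96, 64), n_subjects=200, seed=909)
        _, recs_a = pdw.simulate_cohort(cfg_a, template=template)
        _, recs_b = pdw.simulate_cohort(cfg_b, template=template)
        import dataclasses

        records = [
            pdw.CohortRecord(
                patient_drawing=ra.patient_drawing,
                doctor_drawing=dataclasses.replace(
                    rb.patient_drawing, role="doctor",
                    subject_id=ra.patient_drawing.subject_id,
                ),
            )
            for ra, rb in zip(recs_a, recs_b)
        ]
        res = compare_cohort(records, template)
        assert abs(res.icc_extent["whole"].estimate) < 0.2

    def test_default_generator_extent_agrees_more_than_clusters(
        self, template, default_cohort
    ):
        res = compare_cohort(default_cohort, template)
        assert res.icc_extent["whole"].estimate > res.icc_clusters["whole"].estimate

    def test_report_structure(self, template, default_cohort):
        res = compare_cohort(default_cohort, template)
        rep = similarity_report(res)
        assert set(rep["analysis"]) == {"jaccard", "icc_extent", "icc_clusters"}
        # whole drawing + 4 views for each ICC family
        assert (rep["analysis"] == "icc_extent").sum() == 5
        ci_rows = rep.dropna(subset=["ci_low"])
        assert (ci_rows["ci_low"] <= ci_rows["estimate"]).all()
        assert (ci_rows["estimate"] <= ci_rows["ci_high"]).all()
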