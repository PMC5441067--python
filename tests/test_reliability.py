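import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musclefat import (
    RatingsMatrix,
    agreement_report,
    bland_altman,
    icc_2_1,
    interpret_icc,
    sem,
)
from oracles import icc_2_1_brute_force

# printed (SD, ICC, SEM) triples that are internally consistent under
# SEM = S * sqrt(1 - r); drawn from the inter-method and intra-rater
# reliability tables of a paraspinal-muscle thresholding validation study
CONSISTENT_ROWS = [
    # (sd, icc, printed_sem) -- ICC <= 0.97: exact after 2-decimal rounding
    (1.58, 0.84, 0.63),
    (1.38, 0.83, 0.57),
    (0.12, 0.79, 0.05),
    (1.55, 0.90, 0.49),
    (1.10, 0.80, 0.49),
    (2.47, 0.96, 0.49),
    (2.28, 0.94, 0.56),
    (0.10, 0.91, 0.03),
    (2.32, 0.94, 0.57),
    (2.33, 0.91, 0.70),
    (0.10, 0.85, 0.04),
    (1.75, 0.97, 0.30),
    (1.94, 0.93, 0.51),
    (1.27, 0.86, 0.48),
    (0.13, 0.90, 0.04),
    (1.65, 0.90, 0.52),
    (1.21, 0.78, 0.57),
    (0.11, 0.82, 0.05),
    (4.06, 0.97, 0.70),
    (2.22, 0.91, 0.67),
    (2.37, 0.97, 0.41),
    (4.40, 0.95, 0.98),
    (0.10, 0.78, 0.05),
    (1.79, 0.97, 0.31),
    (1.42, 0.95, 0.32),
    (0.13, 0.95, 0.03),
    (0.11, 0.95, 0.02),
    (2.55, 0.97, 0.44),
    (1.52, 0.95, 0.34),
    (0.14, 0.97, 0.02),
    (2.36, 0.97, 0.41),
    (0.12, 0.97, 0.02),
    (2.21, 0.97, 0.38),
    (0.10, 0.97, 0.02),
]
HIGH_ICC_ROWS = [
    # ICC 0.98-0.99: the printed ICC is rounded, so check within +/-0.04
    (1.83, 0.99, 0.18),
    (1.44, 0.98, 0.20),
    (3.39, 0.98, 0.48),
    (3.88, 0.99, 0.39),
    (1.53, 0.98, 0.22),
    (1.81, 0.99, 0.18),
    (1.85, 0.99, 0.19),
    (3.38, 0.99, 0.34),
    (2.51, 0.98, 0.35),
    (3.53, 0.98, 0.49),
    (1.72, 0.99, 0.17),
    (1.82, 0.98, 0.26),
    (3.97, 0.99, 0.40),
    (2.21, 0.98, 0.31),
    (4.05, 0.98, 0.57),
    (2.43, 0.98, 0.34),
    (2.45, 0.99, 0.25),
]


class TestIcc:
    def test_identical_columns_give_one(self):
        m = RatingsMatrix(np.column_stack([[1.0, 2, 3, 4, 5]] * 2))
        res = icc_2_1(m)
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_fixture_matrix_matches_anova_oracle(self):
        vals = np.array(
            [[9, 10], [6, 7], [8, 8], [7, 9], [10, 12], [6, 5]], dtype=float
        )
        res = icc_2_1(RatingsMatrix(vals))
        assert res.icc == pytest.approx(icc_2_1_brute_force(vals), rel=1e-12)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_systematic_offset_lowers_absolute_agreement(self):
        base = np.column_stack([[1.0, 2, 3, 4, 5]] * 2)
        offset = base.copy()
        offset[:, 1] += 2.0
        assert icc_2_1(RatingsMatrix(offset)).icc < 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        k = int(rng.integers(2, 4))
        vals = rng.normal(10, 3, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        res = icc_2_1(RatingsMatrix(vals))
        assert res.icc == pytest.approx(icc_2_1_brute_force(vals), rel=1e-12)

    def test_matches_pingouin_estimate_and_ci(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        vals = rng.normal(10, 2, size=(12, 1)) + rng.normal(0, 1, size=(12, 3))
        res = icc_2_1(RatingsMatrix(vals))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": vals.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin prints the CI rounded to 2 decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.006)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.006)

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_equivariance_shift_and_scale(self, shift, scale):
        rng = np.random.default_rng(7)
        vals = rng.normal(5, 2, size=(8, 2)) + rng.normal(0, 0.5, size=(8, 1))
        base = icc_2_1(RatingsMatrix(vals)).icc
        assert icc_2_1(RatingsMatrix(vals + shift)).icc == pytest.approx(base, abs=1e-9)
        assert icc_2_1(RatingsMatrix(vals * scale)).icc == pytest.approx(base, abs=1e-9)

    def test_constant_matrix_degenerate(self):
        res = icc_2_1(RatingsMatrix(np.full((4, 2), 3.0)))
        assert res.icc == 1.0 and res.degenerate

    @pytest.mark.parametrize("shape", [(1, 2), (5, 1)])
    def test_too_small_rejected(self, shape):
        with pytest.raises(ValueError):
            RatingsMatrix(np.zeros(shape))


class TestSem:
    @pytest.mark.parametrize(
        "sd,icc,printed",
        [(1.83, 0.99, 0.18), (1.58, 0.84, 0.63)],
    )
    def test_published_rows_reproduce(self, sd, icc, printed):
        assert round(sem(sd, icc).sem, 2) == pytest.approx(printed)

    def test_perfect_reliability_gives_zero(self):
        assert sem(3.7, 1.0).sem == 0.0

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValueError):
            sem(1.0, 1.01)

    @pytest.mark.parametrize("sd,icc,printed", CONSISTENT_ROWS)
    def test_consistency_sweep_exact_rows(self, sd, icc, printed):
        assert round(sem(sd, icc).sem, 2) == pytest.approx(printed)

    @pytest.mark.parametrize("sd,icc,printed", HIGH_ICC_ROWS)
    def test_consistency_sweep_rounded_icc_rows(self, sd, icc, printed):
        assert sem(sd, icc).sem == pytest.approx(printed, abs=0.04)


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2, 3, 4])
        res = bland_altman(x, x)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_pure_offset(self):
        x = np.array([1.0, 2, 3])
        res = bland_altman(x, x + 2)
        assert res.bias == pytest.approx(-2)
        assert res.sd_diff == 0
        assert res.loa_low == res.loa_high == pytest.approx(-2)

    def test_fixture_matches_direct_arithmetic(self):
        x = np.array([10.2, 11.5, 9.8, 12.1, 10.9, 11.7, 9.5, 10.0, 12.4, 11.1])
        y = np.array([10.0, 11.9, 9.5, 12.5, 10.4, 11.9, 9.9, 10.3, 12.0, 11.5])
        d = x - y
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(d.mean())
        assert res.sd_diff == pytest.approx(d.std(ddof=1))
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        # limits-of-agreement width identity
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "icc,expected",
        [
            (0.79, "excellent"),
            (0.99, "excellent"),
            (0.75, "excellent"),
            (0.50, "moderate"),
            (0.74, "moderate"),
            (0.49, "poor"),
            (0.0, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_portney_watkins_bands(self, icc, expected):
        assert interpret_icc(icc) == expected


def _make_table(values_by_param, subjects):
    rows = []
    for i, s in enumerate(subjects):
        row = {
            "subject_id": s,
            "slice_id": 1,
            "muscle": "multifidus",
            "side": "right",
            "level": "L4-L5",
        }
        for param, vals in values_by_param.items():
            row[param] = vals[i]
        rows.append(row)
    return pd.DataFrame(rows)


class TestAgreementReport:
    def _cohort_table(self, rng, n=20, noise=0.0):
        base = {
            "csa_cm2": rng.normal(10, 2, n),
            "fcsa_cm2": rng.normal(5, 1.5, n),
            "fat_csa_cm2": rng.normal(5, 1.2, n),
            "fat_fraction": rng.uniform(0.3, 0.7, n),
        }
        subjects = [f"S{i:03d}" for i in range(n)]
        a = _make_table(base, subjects)
        b = _make_table(
            {k: v + rng.normal(0, noise, n) if noise else v.copy() for k, v in base.items()},
            subjects,
        )
        return a, b

    def test_identical_tables_perfect_agreement(self, rng):
        a, b = self._cohort_table(rng)
        rep = agreement_report(a, b)
        assert (rep["icc"] == 1.0).all()
        assert (rep["sem"] == 0.0).all()
        assert (rep["bias"] == 0.0).all()

    def test_noise_injection_recovers_icc_and_sem(self):
        """With Gaussian re-measurement noise, ICC approaches
        sigma_s^2 / (sigma_s^2 + sigma_e^2) and the SEM estimates the
        injected noise SD (SEM = SD * sqrt(1-ICC) targets the within-subject
        error of a single measurement)."""
        rng = np.random.default_rng(1234)
        n, sigma_s, sigma_e = 60, 2.0, 0.6
        truth = rng.normal(10, sigma_s, n)
        tbl = {
            "csa_cm2": truth,
            "fcsa_cm2": truth * 0.5,
            "fat_csa_cm2": truth * 0.5,
            "fat_fraction": np.clip(truth / 20, 0, 1),
        }
        subjects = [f"S{i:03d}" for i in range(n)]
        a = _make_table({k: v + rng.normal(0, sigma_e if k == "csa_cm2" else 0.0, n) for k, v in tbl.items()}, subjects)
        b = _make_table({k: v + rng.normal(0, sigma_e if k == "csa_cm2" else 0.0, n) for k, v in tbl.items()}, subjects)
        rep = agreement_report(a, b)
        row = rep[rep["parameter"] == "csa_cm2"].iloc[0]
        expected_icc = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        assert row["icc"] == pytest.approx(expected_icc, abs=0.05)
        assert row["sem"] == pytest.approx(sigma_e, rel=0.25)

    def test_unmatched_subjects_warned_and_excluded(self, rng):
        a, b = self._cohort_table(rng, n=10)
        b = b.iloc[:8]
        with pytest.warns(UserWarning, match="unmatched"):
            rep = agreement_report(a, b)
        assert (rep["n"] == 8).all()

    def test_grouped_report_has_group_columns(self, rng):
        a, b = self._cohort_table(rng, n=12, noise=0.1)
        a2, b2 = a.copy(), b.copy()
        a2.loc[:5, "level"] = "L5-S1"
        b2.loc[:5, "level"] = "L5-S1"
        rep = agreement_report(a2, b2, by=["level"])
        assert set(rep["level"]) == {"L4-L5", "L5-S1"}
        assert len(rep) == 8  # 2 groups x 4 parameters
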