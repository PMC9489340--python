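import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfoutcomes.cohort import (
    DEFAULT_THRESHOLDS,
    ConfigError,
    DomainError,
    EchoIndices,
    FollowUpRecord,
    SchemaError,
    baseline_table,
    categorize_covariates,
    compute_bsa,
    compute_lvm,
    compute_lvmi,
    load_thresholds,
    patients_frame,
    read_cohort,
    write_cohort,
)
from tests.conftest import make_patient


def lvm_oracle(a, b, c):
    # expanded cubic difference, evaluated monomial by monomial
    w = b + c
    return 0.8 * 1.04 * (3 * a * a * w + 3 * a * w * w + w * w * w) + 0.6


class TestDerivedIndices:
    def test_lvm_hand_value(self):
        assert compute_lvm(5.0, 1.0, 1.0) == pytest.approx(181.976, abs=1e-9)

    def test_lvm_vanishing_walls_limit(self):
        assert compute_lvm(4.0, 1e-9, 1e-9) == pytest.approx(0.6, abs=1e-5)

    def test_lvm_matches_expanded_oracle(self):
        assert compute_lvm(4.7, 0.9, 1.1) == pytest.approx(
            lvm_oracle(4.7, 0.9, 1.1), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [
        dict(lvidd_cm=0.0, pwtd_cm=1, swtd_cm=1),
        dict(lvidd_cm=5, pwtd_cm=-1, swtd_cm=1),
        dict(lvidd_cm=5, pwtd_cm=1, swtd_cm=0),
    ])
    def test_lvm_rejects_nonpositive_naming_field(self, bad):
        with pytest.raises(DomainError) as err:
            compute_lvm(**bad)
        field = next(k for k, v in bad.items() if v <= 0)
        assert field in str(err.value)

    def test_bsa_hand_values(self):
        assert compute_bsa(170, 70) == pytest.approx(1.7801, abs=1e-9)
        assert compute_bsa(160, 50) == pytest.approx(1.4631, abs=1e-9)

    def test_bsa_rejects_tiny_inputs(self):
        # the intercept makes BSA negative near the origin; post-check fires
        with pytest.raises(DomainError):
            compute_bsa(1e-9, 1e-9)
        with pytest.raises(DomainError):
            compute_bsa(0, 70)

    def test_lvmi_division(self):
        assert compute_lvmi(181.976, 1.7801) == pytest.approx(102.228, abs=1e-3)
        assert compute_lvmi(133.7, 1.0) == 133.7
        with pytest.raises(DomainError):
            compute_lvmi(100.0, 0.0)

    @given(
        a=st.floats(2.5, 8.5), b=st.floats(0.4, 2.0), c=st.floats(0.4, 2.0),
        h=st.floats(140, 200), w=st.floats(40, 140),
    )
    @settings(max_examples=200, deadline=None)
    def test_derived_fields_recheckable(self, a, b, c, h, w):
        e = EchoIndices.from_measurements(50.0, a, b, c, h, w)
        assert e.lvm == pytest.approx(lvm_oracle(a, b, c), rel=1e-9)
        assert e.bsa == pytest.approx(0.0061 * h + 0.0128 * w - 0.1529, rel=1e-9)
        assert e.lvmi == pytest.approx(e.lvm / e.bsa, rel=1e-12)

    def test_plausibility_gate_rejects_mm(self):
        with pytest.raises(DomainError, match="plausible"):
            EchoIndices.from_measurements(50.0, 50.0, 10.0, 10.0, 170, 70)

    def test_cohort_derived_fields_consistent(self, default_cohort):
        patients, _, _ = default_cohort
        for p in patients[:200]:
            assert p.echo.lvm == pytest.approx(
                compute_lvm(p.echo.lvidd_cm, p.echo.pwtd_cm, p.echo.swtd_cm), abs=1e-9
            )
            assert p.echo.lvmi == pytest.approx(p.echo.lvm / p.echo.bsa, abs=1e-9)

    def test_generated_lvmi_near_target(self, default_cohort):
        patients, _, _ = default_cohort
        f = patients_frame(patients)
        lvmi = f.loc[f["arm"] == "integrative", "lvmi"].mean()
        assert lvmi == pytest.approx(122.20, abs=12.0)


class TestCategorization:
    def test_single_cut_low(self):
        f = pd.DataFrame({"ldl_c": [2.41]})
        out = categorize_covariates(f, {"ldl_c": [3.4]})
        assert out["ldl_c_cat"].iloc[0] == "low"

    def test_boundary_goes_to_upper_halfopen_bin(self):
        # [low, cut) / [cut, high): the cut-point itself starts the upper bin
        f = pd.DataFrame({"ldl_c": [3.4, 3.3999999]})
        out = categorize_covariates(f, {"ldl_c": [3.4]})
        assert list(out["ldl_c_cat"]) == ["high", "low"]

    def test_empty_config_identity(self):
        f = pd.DataFrame({"ldl_c": [1.0, 2.0]})
        out = categorize_covariates(f, {})
        pd.testing.assert_frame_equal(out, f)

    def test_unknown_variable_raises(self):
        with pytest.raises(ConfigError):
            categorize_covariates(pd.DataFrame({"x": [1]}), {"nope": [1.0]})

    def test_partition_property(self, default_cohort):
        patients, _, _ = default_cohort
        f = patients_frame(patients)
        out = categorize_covariates(f, DEFAULT_THRESHOLDS)
        for var in DEFAULT_THRESHOLDS:
            counts = out[f"{var}_cat"].value_counts(dropna=False)
            assert counts.sum() == len(f)
            assert int(counts.reindex(out[f"{var}_cat"].cat.categories).fillna(0).sum()) == len(f)

    def test_two_cuts_three_labels(self):
        f = pd.DataFrame({"k": [3.0, 4.0, 6.0]})
        out = categorize_covariates(f, {"k": [3.5, 5.5]})
        assert list(out["k_cat"]) == ["low", "medium", "high"]

    def test_load_thresholds_yaml(self, tmp_path):
        p = tmp_path / "thr.yaml"
        p.write_text("ldl_c: [3.4]\nhcy: 15\n")
        thr = load_thresholds(p)
        assert thr == {"ldl_c": [3.4], "hcy": [15.0]}
        p.write_text("k: [5.5, 3.5]\n")
        with pytest.raises(ConfigError):
            load_thresholds(p)


def chi2_oracle(table):
    """Brute-force sum((O-E)^2/E) with margins-based expectations."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestBaselineTable:
    def _frame_from_counts(self, counts_a, counts_b, levels):
        rows = []
        for arm, counts in (("integrative", counts_a), ("conventional", counts_b)):
            for lv, c in zip(levels, counts):
                rows += [{"arm": arm, "v": lv}] * c
        return pd.DataFrame(rows)

    def test_nyha_2x3_matches_oracle_and_reference_p(self):
        f = self._frame_from_counts([19, 73, 89], [27, 116, 70], ["II", "III", "IV"])
        out = baseline_table(f, [("v", "count")])
        row = out.iloc[0]
        assert row["test"] == "chi-square"
        assert row["statistic"] == pytest.approx(
            chi2_oracle([[19, 73, 89], [27, 116, 70]]), rel=1e-12
        )
        assert round(row["p"], 3) == 0.004

    def test_identical_groups_p_one(self):
        f = self._frame_from_counts([10, 20], [10, 20], ["no", "yes"])
        out = baseline_table(f, [("v", "count")])
        assert out.iloc[0]["p"] == 1.0
        assert out.iloc[0]["statistic"] == 0.0

    @given(
        table=st.lists(
            st.tuples(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50)),
            min_size=2, max_size=2,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_chi2_equals_bruteforce_oracle(self, table):
        f = self._frame_from_counts(table[0], table[1], ["x", "y", "z"])
        out = baseline_table(f, [("v", "count")])
        assert out.iloc[0]["statistic"] == pytest.approx(chi2_oracle(table), rel=1e-10)

    def test_summary_vs_raw_t_equivalence(self, rng):
        # construct raw data matching target summaries exactly, then compare
        # the raw-data t statistic with the closed-form summary formula
        def with_moments(n, m, s):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return m + s * x

        m1, s1, n1, m2, s2, n2 = 63.98, 10.44, 181, 60.85, 11.25, 213
        a, b = with_moments(n1, m1, s1), with_moments(n2, m2, s2)
        f = pd.DataFrame({"arm": ["integrative"] * n1 + ["conventional"] * n2,
                          "v": np.concatenate([a, b])})
        out = baseline_table(f, [("v", "normal")])
        sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        t_summary = (m1 - m2) / (sp * np.sqrt(1 / n1 + 1 / n2))
        assert out.iloc[0]["statistic"] == pytest.approx(t_summary, rel=1e-9)
        assert out.iloc[0]["test"] == "t-test"

    def test_nonnormal_uses_kruskal(self, rng):
        f = pd.DataFrame({"arm": ["integrative"] * 30 + ["conventional"] * 30,
                          "v": rng.lognormal(size=60)})
        out = baseline_table(f, [("v", "nonnormal")])
        assert out.iloc[0]["test"] == "kruskal-wallis"
        assert "(" in out.iloc[0]["summary_integrative"]  # median (Q1, Q3)

    def test_untestable_row_not_dropped(self):
        f = pd.DataFrame({"arm": ["integrative", "conventional", "conventional"],
                          "v": [1.0, 2.0, 3.0]})
        out = baseline_table(f, [("v", "normal")])
        assert len(out) == 1
        assert out.iloc[0]["test"] == "untestable"

    def test_deterministic(self, default_cohort):
        patients, _, _ = default_cohort
        f = patients_frame(patients)
        t1 = baseline_table(f)
        t2 = baseline_table(f)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_arm_raises(self):
        with pytest.raises(SchemaError):
            baseline_table(pd.DataFrame({"arm": ["integrative"], "v": [1.0]}),
                           [("v", "normal")])


class TestIO:
    def test_roundtrip_identity(self, hand_cohort, tmp_path):
        patients, followups = hand_cohort
        write_cohort(patients, followups, tmp_path / "p.csv", tmp_path / "f.csv")
        p2, f2 = read_cohort(tmp_path / "p.csv", tmp_path / "f.csv")
        assert p2 == patients
        assert f2 == followups

    def test_roundtrip_with_missing_lab_and_death(self, tmp_path):
        labs = dict(make_patient().labs)
        labs["hcy"] = None
        patients = [
            make_patient("d1", labs=labs),
            make_patient("d2", died_in_hospital=True, nyha_discharge=None),
        ]
        write_cohort(patients, [], tmp_path / "p.csv", tmp_path / "f.csv")
        p2, _ = read_cohort(tmp_path / "p.csv", tmp_path / "f.csv")
        assert p2 == patients

    def test_off_grid_month_rejected(self, hand_cohort, tmp_path):
        patients, followups = hand_cohort
        write_cohort(patients, followups, tmp_path / "p.csv", tmp_path / "f.csv")
        text = (tmp_path / "f.csv").read_text().replace("a1,6,", "a1,7,")
        (tmp_path / "f.csv").write_text(text)
        with pytest.raises(SchemaError, match="multiple of 6"):
            read_cohort(tmp_path / "p.csv", tmp_path / "f.csv")

    def test_missing_column_is_schema_error(self, hand_cohort, tmp_path):
        patients, followups = hand_cohort
        write_cohort(patients, followups, tmp_path / "p.csv", tmp_path / "f.csv")
        lines = (tmp_path / "p.csv").read_text().splitlines()
        lines[0] = lines[0].replace("age,", "years,")
        (tmp_path / "p.csv").write_text("\n".join(lines))
        with pytest.raises(SchemaError, match="age"):
            read_cohort(tmp_path / "p.csv")

    def test_bad_nyha_value_reports_line(self, hand_cohort, tmp_path):
        patients, followups = hand_cohort
        write_cohort(patients, followups, tmp_path / "p.csv", tmp_path / "f.csv")
        lines = (tmp_path / "f.csv").read_text().splitlines()
        lines[1] = lines[1].rsplit(",", 2)[0] + ",9,0"
        (tmp_path / "f.csv").write_text("\n".join(lines))
        with pytest.raises(SchemaError, match="line 2"):
            read_cohort(tmp_path / "p.csv", tmp_path / "f.csv")

    def test_mm_units_flag(self, hand_cohort, tmp_path):
        patients, followups = hand_cohort
        write_cohort(patients, followups, tmp_path / "p.csv", tmp_path / "f.csv")
        text = (tmp_path / "p.csv").read_text()
        # rescale the echo dimension columns to millimetres
        import csv as _csv
        rows = list(_csv.DictReader(text.splitlines()))
        for r in rows:
            for c in ("lvidd_cm", "pwtd_cm", "swtd_cm"):
                r[c] = repr(float(r[c]) * 10)
        with open(tmp_path / "p_mm.csv", "w", newline="") as fh:
            w = _csv.DictWriter(fh, fieldnames=rows[0].keys())
            w.writeheader()
            w.writerows(rows)
        with pytest.raises(SchemaError):
            read_cohort(tmp_path / "p_mm.csv")
        p_mm, _ = read_cohort(tmp_path / "p_mm.csv", units="mm")
        assert p_mm[0].echo.lvidd_cm == pytest.approx(patients[0].echo.lvidd_cm)

    def test_large_cohort_parses_quickly(self, default_cohort, tmp_path):
        import time

        patients, followups, _ = default_cohort
        write_cohort(patients, followups, tmp_path / "p.csv", tmp_path / "f.csv")
        t0 = time.perf_counter()
        p2, f2 = read_cohort(tmp_path / "p.csv", tmp_path / "f.csv")
        assert time.perf_counter() - t0 < 1.0
        assert len(p2) == 394

    def test_record_validation(self):
        with pytest.raises(DomainError):
            make_patient(age=80.0)
        with pytest.raises(DomainError):
            make_patient(arm="placebo")
        with pytest.raises(DomainError):
            FollowUpRecord("x", 42, "I", False)
        with pytest.raises(DomainError):
            FollowUpRecord("x", 12, "V", False)
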