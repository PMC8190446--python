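import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocurse import (
    FEMALE,
    MALE,
    AnalysisError,
    SimulationConfig,
    curse_sign_test,
    line_means,
    mito_cv,
    nuclear_cv,
    sign_test_pvalue,
    simulate_panel,
    standardize,
)


def _means_table(values, nuc="A", sex=FEMALE):
    """Phenotype table whose per-mito line means equal `values` exactly
    (one individual per line mean)."""
    rows = []
    for i, v in enumerate(values):
        rows.append(
            {"individual_id": f"i{i}", "nuc": nuc, "mito": f"m{i}", "sex": sex,
             "replicate": "v1", "trait": float(v)}
        )
    return pd.DataFrame(rows)


class TestLineMeans:
    def test_cell_mean_and_count(self, table_factory):
        table = table_factory([("A", "x", FEMALE, v) for v in (2.0, 4.0, 6.0)])
        means = line_means(table)
        assert means.loc[("A", FEMALE, "x"), "mean"] == 4.0
        assert means.loc[("A", FEMALE, "x"), "n"] == 3

    def test_zero_noise_means_equal_cell_expectations(self, small_design):
        cfg = SimulationConfig(
            design=small_design, n_per_cell=5, grand_mean=3.0, sex_effect=0.5,
            sigma_resid=0.0, seed=9,
        )
        table = simulate_panel(cfg)
        means = line_means(table)
        # with no residual noise every individual equals its cell mean
        per_cell = table.groupby(["nuc", "sex", "mito"])["trait"].first()
        assert np.allclose(means["mean"], per_cell.loc[means.index])

    def test_agrees_with_groupby_oracle(self, default_panel):
        means = line_means(default_panel)
        oracle = (
            default_panel.pivot_table(
                index=["nuc", "sex", "mito"], values="trait", aggfunc="mean"
            )["trait"]
        )
        assert np.allclose(means["mean"], oracle.loc[means.index])

    def test_empty_table_rejected(self):
        with pytest.raises(AnalysisError, match="empty"):
            line_means(pd.DataFrame(columns=["nuc", "sex", "mito", "trait"]))


class TestStandardize:
    def test_division_by_group_mean(self, table_factory):
        table = table_factory([("A", "x", FEMALE, 2.0), ("A", "y", FEMALE, 4.0)])
        out = standardize(table)
        assert np.allclose(sorted(out["trait"]), [2 / 3, 4 / 3])

    def test_group_means_become_one(self, default_panel):
        out = standardize(default_panel)
        gm = out.groupby(["nuc", "sex"])["trait"].mean()
        assert np.allclose(gm, 1.0, atol=1e-10)

    def test_zero_group_mean_names_group(self, table_factory):
        table = table_factory(
            [("A", "x", FEMALE, 1.0), ("A", "y", FEMALE, -1.0),
             ("B", "x", FEMALE, 2.0)]
        )
        with pytest.raises(AnalysisError, match="nuc='A'"):
            standardize(table)

    def test_cv_unchanged_by_standardization(self, default_panel):
        """CV is scale-free within each (nuc, sex) group, so dividing the
        group by its mean leaves every mito CV untouched."""
        std = standardize(default_panel)
        for nuc in ("A", "E"):
            for sex in (FEMALE, MALE):
                raw = mito_cv(default_panel, nuc, sex, n_boot=10, seed=0)
                post = mito_cv(std, nuc, sex, n_boot=10, seed=0)
                assert raw.cv_point == pytest.approx(post.cv_point, abs=1e-12)


class TestMitoCV:
    def test_constant_line_means_give_zero_cv(self):
        est = mito_cv(_means_table([5.0] * 6), "A", FEMALE, n_boot=50, seed=1)
        assert est.cv_point == 0.0
        assert np.all(est.bootstrap_cvs == 0.0)
        assert est.ci_low == est.ci_high == 0.0

    def test_hand_computed_two_line_cv(self):
        """means (2, 4): SD = sqrt(2), mean = 3, CV = sqrt(2)/3."""
        est = mito_cv(_means_table([2.0, 4.0]), "A", FEMALE, n_boot=10, seed=0)
        assert est.cv_point == pytest.approx(np.sqrt(2) / 3)
        assert est.raw_variance == pytest.approx(2.0)
        assert est.raw_sd == pytest.approx(np.sqrt(2.0))

    def test_scale_invariance_with_shared_seed(self):
        a = mito_cv(_means_table([2.0, 3.0, 7.0]), "A", FEMALE, n_boot=200, seed=4)
        b = mito_cv(_means_table([20.0, 30.0, 70.0]), "A", FEMALE, n_boot=200, seed=4)
        assert a.cv_point == pytest.approx(b.cv_point, abs=1e-12)
        assert np.allclose(a.bootstrap_cvs, b.bootstrap_cvs)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        values=st.lists(
            st.floats(min_value=1.0, max_value=100.0), min_size=2, max_size=8
        ),
    )
    def test_cv_scale_invariance_property(self, scale, values):
        a = mito_cv(_means_table(values), "A", FEMALE, n_boot=20, seed=0)
        b = mito_cv(
            _means_table([v * scale for v in values]), "A", FEMALE, n_boot=20, seed=0
        )
        assert a.cv_point == pytest.approx(b.cv_point, rel=1e-9, abs=1e-12)

    def test_bootstrap_deterministic_under_seed(self, default_panel):
        a = mito_cv(default_panel, "B", MALE, n_boot=300, seed=7)
        b = mito_cv(default_panel, "B", MALE, n_boot=300, seed=7)
        assert np.array_equal(a.bootstrap_cvs, b.bootstrap_cvs)
        assert len(a.bootstrap_cvs) == 300

    def test_bootstrap_centers_on_point_estimate(self):
        """On symmetric line means the bootstrap mean CV sits within 3
        bootstrap SEs of the point CV."""
        est = mito_cv(
            _means_table([8.0, 9.0, 10.0, 11.0, 12.0]), "A", FEMALE,
            n_boot=2000, seed=3,
        )
        se = est.bootstrap_cvs.std(ddof=1) / np.sqrt(len(est.bootstrap_cvs))
        # bootstrap CV of small samples is biased low; allow bias ~ 1/n plus SE
        assert abs(est.bootstrap_cvs.mean() - est.cv_point) < 0.15 * est.cv_point + 3 * se

    def test_single_haplotype_rejected(self):
        with pytest.raises(AnalysisError, match=">= 2"):
            mito_cv(_means_table([2.0]), "A", FEMALE, n_boot=10, seed=0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(AnalysisError, match="non-positive"):
            mito_cv(_means_table([-2.0, 1.0]), "A", FEMALE, n_boot=10, seed=0)

    def test_unknown_group_rejected(self, default_panel):
        with pytest.raises(AnalysisError, match="no rows"):
            mito_cv(default_panel, "Z", FEMALE, n_boot=10, seed=0)


class TestSignTest:
    def test_eight_of_nine_worked_example(self):
        """8 positive of 9 paired differences: exact two-sided P = 20/512 =
        0.0390625 (prints as 0.03906)."""
        assert sign_test_pvalue(8, 9) == pytest.approx(20 / 512)
        assert f"{sign_test_pvalue(8, 9):.5f}" == "0.03906"

    def test_nine_of_nine(self):
        assert sign_test_pvalue(9, 9) == pytest.approx(2 / 512)

    def test_balanced_case_capped_at_one(self):
        assert sign_test_pvalue(2, 4) == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=12), data=st.data())
    def test_exact_agreement_with_enumeration(self, n, data):
        """p equals brute-force enumeration over all 2^n sign patterns of the
        probability of a count at least as extreme (two-sided) as observed."""
        k = data.draw(st.integers(min_value=0, max_value=n))
        from itertools import product

        counts = [sum(bits) for bits in product((0, 1), repeat=n)]
        lower = sum(c <= k for c in counts) / 2**n
        upper = sum(c >= k for c in counts) / 2**n
        expected = min(1.0, 2.0 * min(lower, upper))
        assert sign_test_pvalue(k, n) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=40), data=st.data())
    def test_symmetry_and_bounds(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        p = sign_test_pvalue(k, n)
        assert p == pytest.approx(sign_test_pvalue(n - k, n), abs=1e-12)
        assert 0 < p <= 1

    def test_zero_informative_rejected(self):
        with pytest.raises(AnalysisError, match="informative"):
            sign_test_pvalue(0, 0)


class TestCurseSignTest:
    def test_detects_male_biased_variance(self, panel_design):
        """A panel with doubled male mitochondrial SD (mito-dominant
        structure) yields mostly positive male-female CV differences."""
        cfg = SimulationConfig(
            design=panel_design, n_per_cell=15, seed=5,
            sigma_nuc=0.05, sigma_mito_f=0.025, sigma_mito_m=0.05,
            sigma_epi_f=0.005, sigma_epi_m=0.005, sigma_resid=0.025,
        )
        res = curse_sign_test(simulate_panel(cfg), n_boot=200, seed=0)
        assert res.n_informative == 9
        assert res.n_positive >= 8
        assert res.p_value <= sign_test_pvalue(8, 9)
        assert len(res.difference_summary) == 9

    def test_deterministic_under_seed(self, default_panel):
        a = curse_sign_test(default_panel, n_boot=100, seed=3)
        b = curse_sign_test(default_panel, n_boot=100, seed=3)
        assert a == b

    def test_missing_sex_rejected(self, default_panel):
        with pytest.raises(AnalysisError, match="lacks one sex"):
            curse_sign_test(default_panel[default_panel["sex"] == MALE], n_boot=10)

    def test_ci_brackets_mean_difference_under_curse(self, default_panel):
        res = curse_sign_test(default_panel, n_boot=500, seed=1)
        lo, hi = res.mean_diff_ci
        assert lo <= res.mean_diff <= hi


class TestNuclearCV:
    def test_constant_coevolved_means_flagged_degenerate(self, table_factory):
        rows = [
            (n, n, s, 5.0)
            for n in "ABC"
            for s in (FEMALE, MALE)
            for _ in range(2)
        ]
        from mitocurse import PanelDesign

        design = PanelDesign.fully_crossed(list("ABC"))
        res = nuclear_cv(table_factory(rows), design, n_boot=50, seed=0)
        assert res.degenerate
        assert res.female.cv_point == 0.0
        assert res.male.cv_point == 0.0

    def test_nuclear_cv_exceeds_mito_cv_when_nuclear_dominates(self, panel_design):
        """sigma_nuc >> sigma_mito: the across-nuclei coevolved CV is larger
        than every within-nucleus mitochondrial CV, in both sexes."""
        cfg = SimulationConfig(
            design=panel_design, n_per_cell=15, seed=21,
            sigma_nuc=0.12, sigma_mito_f=0.004, sigma_mito_m=0.004,
            sigma_epi_f=0.004, sigma_epi_m=0.004, sigma_resid=0.02,
        )
        table = simulate_panel(cfg)
        res = nuclear_cv(table, panel_design, n_boot=50, seed=0)
        for sex, est in ((FEMALE, res.female), (MALE, res.male)):
            for nuc in panel_design.nuc_labels:
                m = mito_cv(table, nuc, sex, n_boot=10, seed=0)
                assert est.cv_point > m.cv_point, (sex, nuc)

    def test_sex_comparison_calibrated_under_symmetric_simulation(self, panel_design):
        """With identical nuclear structure in both sexes, the point nuclear
        CVs differ only by sampling noise: the male-female gap is small
        relative to the bootstrap spread in nearly all replicate panels."""
        n_small = 0
        reps = 100
        for rep in range(reps):
            cfg = SimulationConfig(
                design=panel_design, n_per_cell=6, seed=40_000 + rep,
                sex_effect=0.0, sigma_nuc=0.06,
                sigma_mito_f=0.005, sigma_mito_m=0.005,
                sigma_epi_f=0.005, sigma_epi_m=0.005, sigma_resid=0.02,
            )
            res = nuclear_cv(simulate_panel(cfg), panel_design, n_boot=60, seed=rep)
            spread = np.std(
                np.concatenate([res.female.bootstrap_cvs, res.male.bootstrap_cvs]),
                ddof=1,
            )
            if abs(res.male.cv_point - res.female.cv_point) < 3 * spread:
                n_small += 1
        assert n_small >= 0.90 * reps

    def test_caveat_always_present(self, default_panel, panel_design):
        res = nuclear_cv(default_panel, panel_design, n_boot=50, seed=0)
        assert "not independent" in res.caveat

    def test_missing_coevolved_entry_rejected(self, default_panel):
        from mitocurse import PanelDesign

        design = PanelDesign(
            mito_labels=tuple("ABCDEFGHI"),
            nuc_labels=tuple("ABCDEFGHI"),
            coevolved={c: c for c in "ABCDEFGH"},  # no entry for I
            incompatible=frozenset({("F", "A")}),
        )
        with pytest.raises(AnalysisError, match="coevolved map lacks"):
            nuclear_cv(default_panel, design, n_boot=10, seed=0)
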