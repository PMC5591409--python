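"""Biomarker layer: S-plot and VIP against hand formulas, threshold
selection, shift-based metabolite mapping, TSP-referenced quantification
round trips, and the univariate statistics (with enumeration and step-down
oracles)."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrmetab import (
    OPLSDA,
    AcquisitionParams,
    CohortDesign,
    holm_bonferroni,
    mann_whitney_u,
    map_bins_to_metabolites,
    quantify_against_tsp,
    quantify_cohort,
    render_spectrum,
    select_discriminants,
    simulate_cohort,
    univariate_table,
)
from nmrmetab.biomarkers import compute_s_plot, compute_vip

from conftest import make_library


def _fit(x, y, n_orth=1):
    labels = ["B" if v else "A" for v in y]
    return OPLSDA(x, labels, classes=("A", "B"), n_orth=n_orth).fit(cv=False)


class TestSPlot:
    def test_bin_proportional_to_score_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        n = 30
        y = np.array([0.0] * 15 + [1.0] * 15)
        base = y + rng.normal(scale=0.1, size=n)
        x = np.column_stack([base, rng.normal(size=n)])
        res = _fit(x, y, n_orth=0)
        sp = compute_s_plot(res)
        # bin 0 drives the model, so t is (almost) collinear with it
        assert abs(sp.loc[0, "pcorr1"]) > 0.999

    def test_noise_bin_correlation_bounded(self):
        rng = np.random.default_rng(1)
        n = 1000
        y = np.array([0.0, 1.0] * (n // 2))
        x = np.column_stack([y + rng.normal(scale=0.2, size=n),
                             rng.normal(size=n)])
        res = _fit(x, y, n_orth=0)
        sp = compute_s_plot(res)
        assert abs(sp.loc[1, "pcorr1"]) < 3 / math.sqrt(n)

    def test_hand_computed_fixture(self):
        """4-sample, 2-bin fixture: p1/pcorr1 equal the direct covariance and
        correlation of each scaled column with the predictive score."""
        x = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 4.0], [3.0, 3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        res = _fit(x, y, n_orth=0)
        sp = compute_s_plot(res)
        t = res.core.t
        for j in range(2):
            col = res.x_scaled[:, j]
            cov = ((t - t.mean()) * (col - col.mean())).sum() / 3
            corr = cov / (t.std(ddof=1) * col.std(ddof=1))
            assert sp.loc[j, "p1"] == pytest.approx(cov, abs=1e-12)
            assert sp.loc[j, "pcorr1"] == pytest.approx(corr, abs=1e-12)

    def test_sign_consistency_and_zero_variance_flag(self):
        rng = np.random.default_rng(2)
        n = 24
        y = np.array([0.0] * 12 + [1.0] * 12)
        x = np.column_stack([y + rng.normal(scale=0.3, size=n),
                             np.full(n, 7.0),
                             rng.normal(size=n)])
        sp = compute_s_plot(_fit(x, y, n_orth=0))
        nz = sp[~sp["zero_variance"] & (sp["p1"] != 0)]
        assert (np.sign(nz["p1"]) == np.sign(nz["pcorr1"])).all()
        assert sp.loc[1, "zero_variance"]
        assert sp.loc[1, "pcorr1"] == 0.0


class TestVIP:
    def test_mean_squared_vip_is_one(self, small_matrix):
        res = OPLSDA(small_matrix, classes=("C", "NR"), n_orth=1).fit(cv=False)
        for flag in (True, False):
            v = compute_vip(res, include_orthogonal=flag)["vip"].to_numpy()
            assert (v**2).mean() == pytest.approx(1.0, abs=1e-8)
            assert (v >= 0).all()

    def test_informative_bin_ranks_above_noise_bin(self):
        rng = np.random.default_rng(3)
        n = 40
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.column_stack([y + rng.normal(scale=0.1, size=n),
                             rng.normal(size=n)])
        v = compute_vip(_fit(x, y, n_orth=0))["vip"]
        assert v[0] > 1 > v[1]
        # brute-force the formula for the 2-bin predictive-only case
        core = _fit(x, y, n_orth=0).core
        expected = np.sqrt(2 * core.w**2)
        assert np.allclose(v, expected, atol=1e-10)


class TestSelection:
    def test_zero_thresholds_select_all(self, small_matrix):
        res = OPLSDA(small_matrix, classes=("C", "NR"), n_orth=1).fit(cv=False)
        sel = select_discriminants(res.s_plot(), res.vip(), 0.0, 0.0)
        assert len(sel) == small_matrix.n_bins

    def test_impossible_thresholds_select_none(self, small_matrix):
        res = OPLSDA(small_matrix, classes=("C", "NR"), n_orth=1).fit(cv=False)
        sel = select_discriminants(res.s_plot(), res.vip(), 1.01, np.inf)
        assert sel.empty

    def test_directions_follow_covariance_sign(self, small_matrix):
        res = OPLSDA(small_matrix, classes=("C", "NR"), n_orth=1).fit(cv=False)
        sel = select_discriminants(res.s_plot(), res.vip(), classes=("C", "NR"))
        up = sel[sel["p1"] > 0]
        assert (up["direction"] == "higher_in_NR").all()


class TestMapping:
    def test_lactate_bin(self, library, standard_grid):
        disc = pd.DataFrame({"bin": ["1.3400"]})
        out = map_bins_to_metabolites(disc, standard_grid, library)
        assert out.loc[0, "metabolites"] == "lactate"
        assert not out.loc[0, "ambiguous"]

    def test_overlapping_092_bin_ambiguous(self, library, standard_grid):
        disc = pd.DataFrame({"bin": ["0.9400"]})
        out = map_bins_to_metabolites(disc, standard_grid, library)
        assert out.loc[0, "ambiguous"]
        assert set(out.loc[0, "metabolites"].split(";")) == {
            "2-OH-butyrate", "2-OH-valerate"
        }

    def test_far_bin_unassigned(self, library, standard_grid):
        disc = pd.DataFrame({"bin": ["8.4200"]})
        out = map_bins_to_metabolites(disc, standard_grid, library)
        assert out.loc[0, "metabolites"] == "unassigned"


class TestQuantification:
    def _render(self, lib, conc, **acq_kw):
        acq = AcquisitionParams(noise_sd=0.0, jitter_sd_ppm=0.0,
                                water_amplitude=0.0, **acq_kw)
        return render_spectrum(conc, lib, acq, np.random.default_rng(0))

    def test_equal_per_proton_area_gives_reference_concentration(self):
        """A singlet whose per-proton area equals TSP's quantifies to exactly
        the reference 0.507 mM (window widths match, so truncation cancels)."""
        lib = make_library([("probe", 3.0, 1, 0.0, 4, {"C": (0.0, 0.0)})])
        conc = {"probe": 0.507}  # same per-proton area as the reference
        s = self._render(lib, conc)
        got = quantify_against_tsp(s, lib["probe"], lib)
        assert got == pytest.approx(0.507, rel=1e-6)

    def test_double_per_proton_area(self):
        lib = make_library([("probe", 3.0, 1, 0.0, 4, {"C": (0.0, 0.0)})])
        s = self._render(lib, {"probe": 1.014})
        got = quantify_against_tsp(s, lib["probe"], lib)
        assert got == pytest.approx(1.014, rel=1e-6)

    def test_lactate_roundtrip_within_2_percent(self, library):
        conc = {name: 0.0 for name in library.names}
        conc["lactate"] = 1.88
        s = self._render(library, conc)
        got = quantify_against_tsp(s, library["lactate"], library)
        assert got == pytest.approx(1.88, rel=0.02)

    def test_raw_ratio_without_correction(self):
        """With the lineshape correction off the estimate is the plain area
        ratio, biased low by the truncated tails."""
        lib = make_library([("probe", 3.0, 1, 0.0, 4, {"C": (0.0, 0.0)})])
        s = self._render(lib, {"probe": 0.507})
        raw = quantify_against_tsp(s, lib["probe"], lib, lineshape_correction=False)
        assert raw == pytest.approx(0.507, rel=0.02)

    def test_overlap_window_warns(self, library):
        conc = {name: 0.0 for name in library.names}
        conc["2-OH-butyrate"] = 0.1
        s = self._render(library, conc)
        with pytest.warns(UserWarning, match="overlap"):
            quantify_against_tsp(s, library["2-OH-butyrate"], library)

    def test_negative_area_clipped_with_warning(self, library):
        conc = {name: 0.0 for name in library.names}
        s = self._render(library, conc, baseline_coeffs=(0.0,))
        s.intensity = s.intensity - 0.5 * (np.abs(s.ppm - 2.23) < 0.05)
        with pytest.warns(UserWarning, match="clipped"):
            got = quantify_against_tsp(s, library["acetone"], library)
        assert got == 0.0

    def test_missing_reference_rejected(self, library):
        conc = {name: 0.0 for name in library.names}
        s = self._render(library, conc)
        s.intensity = np.zeros_like(s.intensity)
        with pytest.raises(ValueError, match="reference"):
            quantify_against_tsp(s, library["acetone"], library)

    def test_cohort_roundtrip_and_univariate_flags(self, library):
        """End-to-end on (35, 18, 17) cohorts: quantified group means track
        the generator's drawn concentrations within 3 SE for every published
        metabolite, and the C-vs-NR screen flags acetone and lactate at
        Holm-adjusted p < 0.05 in >= 9 of 10 seeds."""
        flagged = 0
        n_seeds = 10
        acq = AcquisitionParams()
        quantified_names = [
            m.name for m in library.metabolites
            if not m.quantification.overlap and "paper" in m.sources.values()
        ]
        for seed in range(n_seeds):
            spectra, truth = simulate_cohort(
                CohortDesign(35, 18, 17, seed=200 + seed), library, acq
            )
            conc = quantify_cohort(spectra, library)
            if seed == 0:
                merged = conc.merge(
                    truth, on=["sample_id", "group", "metabolite"],
                    suffixes=("", "_true"),
                )
                for (name, grp), sub in merged.groupby(["metabolite", "group"]):
                    if name not in quantified_names:
                        continue
                    se = sub["conc_mM"].std(ddof=1) / np.sqrt(len(sub))
                    err = sub["conc_mM"].mean() - sub["conc_mM_true"].mean()
                    assert abs(err) < 3 * se, (name, grp, err, se)
            uni = univariate_table(conc, [("C", "NR")],
                                   metabolites=quantified_names)
            uni = uni.set_index("metabolite")
            flagged += (uni.loc["acetone", "p_holm"] < 0.05
                        and uni.loc["lactate", "p_holm"] < 0.05)
        assert flagged >= 9


def exact_mw_oracle(a, b):
    """Full-enumeration two-sided Mann-Whitney p for tie-free samples."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    u_min = min(u_obs, n1 * len(b) - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp_a = pooled[list(comb)]
        grp_b = np.delete(pooled, list(comb))
        u = sum(1 for x in grp_a for y in grp_b if x > y)
        count += min(u, n1 * len(b) - u) <= u_min
        total += 1
    return count / total


class TestMannWhitney:
    def test_textbook_case(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0
        assert p == pytest.approx(1 / 3, abs=1e-10)

    def test_identical_groups_not_significant(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_matches_enumeration_oracle_sample(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = vals[:n1], vals[n1:]
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(exact_mw_oracle(a, b), abs=1e-9)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(5)
        a = np.round(rng.normal(size=40), 1)
        b = np.round(rng.normal(loc=1.0, size=40), 1)
        u, p = mann_whitney_u(a, b)
        assert 0 <= u <= 40 * 40 / 2
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def holm_oracle(ps):
    """Step-down Holm by the definition: sort ascending, adjusted p_(i) =
    min(1, max_{j<=i} (m-j+1) p_(j)), back in input order."""
    ps = np.asarray(ps, float)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj_sorted[rank] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestHolm:
    def test_three_value_fixture(self):
        assert np.allclose(holm_bonferroni([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_value_unchanged(self):
        assert holm_bonferroni([0.2]).tolist() == [0.2]

    def test_cap_at_one(self):
        assert holm_bonferroni([0.5, 0.9]).tolist() == [1.0, 1.0]

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            ps = rng.uniform(size=rng.integers(1, 12))
            assert np.allclose(holm_bonferroni(ps), holm_oracle(ps), atol=1e-12)

    def test_ties_get_equal_adjustment(self):
        adj = holm_bonferroni([0.01, 0.01, 0.5])
        assert adj[0] == adj[1]

    def test_monotonicity_and_bonferroni_bound(self):
        rng = np.random.default_rng(7)
        ps = rng.uniform(size=10)
        adj = holm_bonferroni(ps)
        assert np.all(adj >= ps)
        assert np.all(adj <= np.minimum(1.0, len(ps) * ps) + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_properties_hold_for_arbitrary_p_vectors(self, ps):
        adj = holm_bonferroni(ps)
        ps = np.asarray(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0)
        assert np.all(adj <= np.minimum(1.0, len(ps) * ps) + 1e-12)
        assert np.allclose(adj, holm_oracle(ps), atol=1e-12)


class TestUnivariateTable:
    def test_columns_and_family_size(self, library):
        rng = np.random.default_rng(8)
        rows = []
        for grp, shift in (("C", 0.0), ("NR", 1.0)):
            for i in range(8):
                for name in ("lactate", "glucose", "citrate"):
                    rows.append((f"{grp}{i}", grp, name, rng.normal(loc=shift)))
        conc = pd.DataFrame(rows, columns=["sample_id", "group", "metabolite",
                                           "conc_mM"])
        uni = univariate_table(conc, [("C", "NR")])
        assert len(uni) == 3
        assert {"metabolite", "comparison", "U", "p_raw", "p_holm"} <= set(uni.columns)
        assert (uni["p_holm"] >= uni["p_raw"] - 1e-12).all()
        assert np.allclose(
            uni["p_holm"], holm_oracle(uni["p_raw"].to_numpy()), atol=1e-12
        )
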