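"""Monte Carlo uncertainty propagation: intervals, triangular sampling,
rank distributions, banding, sensitivity and summaries."""

import dataclasses

import numpy as np
import pytest

import ppp
from ppp import (
    ConfidenceGrade,
    DataValidationError,
    PriorityRecord,
    RankDistribution,
    SimulationConfig,
    SpeciesProject,
    ManagementAction,
)

ZERO_WIDTHS = {g: 0.0 for g in ConfidenceGrade}


class TestIntervalFor:
    def test_confident_grade_is_plus_minus_0p1(self):
        assert ppp.interval_for(0.5, ConfidenceGrade.CONFIDENT) == (0.4, 0.6)

    def test_grades_map_to_their_half_widths(self):
        assert ppp.interval_for(0.5, "very confident") == (0.45, 0.55)
        assert ppp.interval_for(0.5, "not confident") == (0.3, 0.7)

    def test_clipping_to_unit_interval(self):
        lo, hi = ppp.interval_for(0.93, ConfidenceGrade.VERY_CONFIDENT)
        assert (lo, hi) == (pytest.approx(0.88), pytest.approx(0.98))
        lo, hi = ppp.interval_for(0.98, ConfidenceGrade.NOT_CONFIDENT)
        assert lo == pytest.approx(0.78) and hi == 1.0

    def test_cost_rules(self):
        assert ppp.interval_for(100.0, "cost") == (70.0, 130.0)
        assert ppp.interval_for(100.0, "cost-stale") == (70.0, 200.0)

    def test_unknown_grade_rejected(self):
        with pytest.raises(DataValidationError):
            ppp.interval_for(0.5, "somewhat sure")


class TestSampleTriangular:
    def test_degenerate_interval_returns_mode(self):
        rng = np.random.default_rng(0)
        assert ppp.sample_triangular(0.0, 0.0, 0.0, rng) == 0.0
        out = ppp.sample_triangular(0.5, 0.5, 0.5, rng, size=(10,))
        assert np.all(out == 0.5)

    def test_support_is_respected(self):
        rng = np.random.default_rng(1)
        draws = ppp.sample_triangular(0.4, 0.5, 0.6, rng, size=(10_000,))
        assert draws.min() >= 0.4 and draws.max() <= 0.6

    def test_mean_matches_closed_form_within_3_se(self):
        """Triangular mean is (lo + mode + hi) / 3."""
        rng = np.random.default_rng(2)
        n = 100_000
        for lo, mode, hi in [(0.0, 0.5, 1.0), (0.0, 0.1, 1.0), (2.0, 2.0, 5.0)]:
            draws = ppp.sample_triangular(lo, mode, hi, rng, size=(n,))
            expected = (lo + mode + hi) / 3.0
            se = draws.std(ddof=1) / np.sqrt(n)
            assert abs(draws.mean() - expected) < 3 * se

    def test_density_peaks_at_mode(self):
        rng = np.random.default_rng(3)
        draws = ppp.sample_triangular(0.0, 0.8, 1.0, rng, size=(200_000,))
        hist, edges = np.histogram(draws, bins=20, range=(0.0, 1.0), density=True)
        assert 0.7 < edges[np.argmax(hist)] < 0.9

    def test_disordered_bounds_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DataValidationError):
            ppp.sample_triangular(1.0, 0.5, 0.8, rng)


class TestMonteCarloRanks:
    def test_zero_width_intervals_collapse_to_deterministic_ranks(self, fixture_projects):
        config = SimulationConfig(
            n_sims=200, seed=5, confidence_half_widths=ZERO_WIDTHS,
            cost_interval_symmetric=0.0, cost_interval_stale=(0.0, 0.0),
            l_floor=0.0,
        )
        dists = ppp.monte_carlo_ranks(fixture_projects, config)
        ranked = ppp.rank_projects(ppp.score_projects(fixture_projects))
        det = {r.project_id: r.rank for r in ranked}
        for d in dists:
            assert d.interval_length == 0
            assert d.interval == (det[d.project_id], det[d.project_id])
            assert np.all(d.simulated_ranks == det[d.project_id])

    def test_non_overlapping_score_ranges_give_certain_ranks(self):
        def project(pid, pn, cost):
            return SpeciesProject(
                project_id=pid, species_name=pid, taxon_group="plant", p_without=pn,
                benefit_confidence=ConfidenceGrade.VERY_CONFIDENT,
                actions=(ManagementAction(
                    action_id=f"{pid}-A", project_id=pid, site_id="S",
                    location_key=pid, action_type="fencing",
                    schedule=frozenset([1]), annual_cost=cost,
                    input_success=0.95, threat_outcome_success=0.95,
                    species_outcome_success=0.95,
                    confidence=ConfidenceGrade.VERY_CONFIDENT,
                ),),
            )

        # score ranges stay disjoint even at the interval extremes
        projects = [project("CHEAP", 0.05, 100.0), project("DEAR", 0.05, 1_000_000.0)]
        dists = ppp.monte_carlo_ranks(projects, SimulationConfig(n_sims=500, seed=9))
        by_id = {d.project_id: d.interval for d in dists}
        assert by_id["CHEAP"] == (1, 1)
        assert by_id["DEAR"] == (2, 2)

    def test_fixed_seed_is_bit_reproducible(self, fixture_projects):
        config = SimulationConfig(n_sims=300, seed=123)
        a = ppp.monte_carlo_ranks(fixture_projects, config)
        b = ppp.monte_carlo_ranks(fixture_projects, config)
        for da, db in zip(a, b):
            assert np.array_equal(da.simulated_ranks, db.simulated_ranks)
            assert da.interval == db.interval

    def test_each_replicate_is_a_permutation(self, fixture_projects):
        dists = ppp.monte_carlo_ranks(fixture_projects, SimulationConfig(n_sims=50, seed=7))
        ranks = np.stack([d.simulated_ranks for d in dists], axis=1)
        n = len(fixture_projects)
        for row in ranks:
            assert sorted(row) == list(range(1, n + 1))

    def test_intervals_shrink_as_half_widths_shrink(self, fixture_projects):
        """Mean interval length decreases toward 0 as all confidence
        half-widths scale toward zero."""
        lengths = []
        for scale in (1.0, 0.5, 0.0):
            config = SimulationConfig(
                n_sims=400, seed=21,
                confidence_half_widths={g: scale * g.half_width for g in ConfidenceGrade},
                cost_interval_symmetric=0.30 * scale,
                cost_interval_stale=(1.0 * scale, 0.30 * scale),
                l_floor=0.0,
            )
            dists = ppp.monte_carlo_ranks(fixture_projects, config)
            lengths.append(np.mean([d.interval_length for d in dists]))
        assert lengths[0] >= lengths[1] >= lengths[2] == 0.0

    def test_l_floor_truncates_sampled_likelihood(self):
        p = SpeciesProject(
            project_id="LOW", species_name="x", taxon_group="plant", p_without=0.05,
            actions=(ManagementAction(
                action_id="A", project_id="LOW", site_id="S", location_key="L",
                action_type="fencing", schedule=frozenset([1]), annual_cost=100.0,
                input_success=0.2, threat_outcome_success=0.2,
                species_outcome_success=0.2,  # L = 0.008, far below the floor
            ),),
        )
        q = dataclasses.replace(p, project_id="REF", actions=(dataclasses.replace(
            p.actions[0], project_id="REF", action_id="B", location_key="L2"),))
        config = SimulationConfig(n_sims=100, seed=1)
        # no error, and simulation runs with the floored values
        dists = ppp.monte_carlo_ranks([p, q], config)
        assert len(dists) == 2


class TestBanding:
    def test_cutoffs_half_even_rounding(self):
        assert ppp.band_cutoffs(10) == (3, 7)
        assert ppp.band_cutoffs(368) == (110, 258)

    def test_cutoff_rounding_variants(self):
        cfg_floor = SimulationConfig(cutoff_rounding="floor")
        cfg_ceil = SimulationConfig(cutoff_rounding="ceil")
        assert ppp.band_cutoffs(368, cfg_floor) == (110, 257)
        assert ppp.band_cutoffs(368, cfg_ceil) == (111, 258)

    @pytest.mark.parametrize("interval,band", [
        ((1, 2), 1),    # worst case inside top 30%
        ((1, 3), 1),    # boundary: hi == k30
        ((4, 6), 3),    # fully inside the middle 40%
        ((2, 5), 2),    # straddles k30 only
        ((4, 9), 4),    # straddles k70 only
        ((8, 9), 5),    # best case beyond top 70%
        ((2, 9), 5),    # spans both cutoffs -> lowest relevant band
    ])
    def test_band_rules_at_n10(self, interval, band):
        d = RankDistribution("X", np.array([interval[0]]), interval)
        assert ppp.assign_bands([d], n_projects=10) == {"X": band}

    def test_printed_band5_variant_absorbs_band4(self):
        config = SimulationConfig(band5_rule="printed")
        d = RankDistribution("X", np.array([4]), (4, 9))
        assert ppp.assign_bands([d], config, n_projects=10) == {"X": 5}

    def test_every_project_gets_exactly_one_band(self, small_portfolio):
        config = SimulationConfig(n_sims=300, seed=3)
        dists = ppp.monte_carlo_ranks(small_portfolio, config)
        bands = ppp.assign_bands(dists, config)
        assert set(bands) == {p.project_id for p in small_portfolio}
        assert set(bands.values()) <= {1, 2, 3, 4, 5}


class TestSensitivity:
    def test_mc_agrees_with_analytic_linear_derivatives(self, fixture_projects):
        """P is linear in B and L, so the MC perturbation means sit near
        0.1*L/C and 0.1*B/C.  The residual gap is the E[1/C] Jensen bias of
        the triangular cost draw: small for the symmetric ±30% interval,
        larger (and negative) for the asymmetric +100%/-30% stale-site
        interval, whose mean cost exceeds the point estimate."""
        config = SimulationConfig(n_sims=20_000, seed=11)
        sens = ppp.sensitivity(fixture_projects, config)
        recs = {r.project_id: r for r in ppp.score_projects(fixture_projects)}

        # independent oracle: numpy's own triangular sampler; the MC estimator
        # factorises as 0.1 * E[other param] * E[1/C]
        rng = np.random.default_rng(99)
        n = 200_000
        for _, row in sens.iterrows():
            p = next(q for q in fixture_projects if q.project_id == row["project_id"])
            r = recs[p.project_id]
            b_lo, b_hi = ppp.interval_for(r.benefit, p.benefit_confidence, config)
            l_hw = max(a.confidence.half_width for a in p.actions)
            l_lo, l_hi = max(0.0, r.likelihood - l_hw), min(1.0, r.likelihood + l_hw)
            rule = "cost" if p.recent_site_confirmation else "cost-stale"
            c_lo, c_hi = ppp.interval_for(r.cost, rule, config)
            e_b = rng.triangular(b_lo, r.benefit, b_hi, n).mean() if b_hi > b_lo else r.benefit
            l_draws = np.maximum(rng.triangular(l_lo, r.likelihood, l_hi, n), config.l_floor)
            e_inv_c = (1.0 / rng.triangular(c_lo, r.cost, c_hi, n)).mean()
            assert row["b_sensitivity"] == pytest.approx(0.1 * l_draws.mean() * e_inv_c, rel=0.05)
            assert row["l_sensitivity"] == pytest.approx(0.1 * e_b * e_inv_c, rel=0.05)

        # where no clipping occurs and the cost interval is symmetric, the
        # point-estimate analytic values agree with the MC means directly
        clean = sens["project_id"].isin(["PRJ-A", "PRJ-B"]).to_numpy()
        np.testing.assert_allclose(
            sens["b_sensitivity"][clean], sens["b_sensitivity_analytic"][clean], rtol=0.05
        )
        np.testing.assert_allclose(
            sens["l_sensitivity"][clean], sens["l_sensitivity_analytic"][clean], rtol=0.05
        )

    def test_b_sensitivity_analytic_value(self):
        """+0.1 in B moves P by 0.1*L/C: at L = 0.5, C = 1e6 that is 5e-8."""
        p = SpeciesProject(
            project_id="P", species_name="x", taxon_group="plant", p_without=0.05,
            actions=(ManagementAction(
                action_id="A", project_id="P", site_id="S", location_key="L",
                action_type="fencing", schedule=frozenset([1]), annual_cost=1.0,
                input_success=1.0, threat_outcome_success=1.0,
                species_outcome_success=0.5,
            ),), cost_total_npv=1_000_000.0,
        )
        sens = ppp.sensitivity([p], SimulationConfig(n_sims=10, seed=0))
        assert sens["b_sensitivity_analytic"][0] == pytest.approx(5e-8)

    def test_cost_sensitivity_negative_everywhere(self, small_portfolio):
        sens = ppp.sensitivity(small_portfolio, SimulationConfig(n_sims=500, seed=2))
        assert (sens["c_sensitivity"] < 0).all()
        assert (sens["c_sensitivity_analytic"] < 0).all()


class TestSummaryStatistics:
    def test_degenerate_identical_projects_give_nan_correlation(self):
        records = [PriorityRecord(f"P{i}", 0.9, 0.5, 1e6, 4.5e-7) for i in range(2)]
        with pytest.warns(UserWarning, match="constant"):
            out = ppp.summary_statistics(records)
        assert np.isnan(out["correlations"]["log_c_vs_log_p"])

    def test_log_cost_anticorrelates_with_log_score(self, small_portfolio):
        """With B, L generated independently of C, log P = log B + log L - log C
        forces a strong negative log C - log P correlation."""
        recs = ppp.score_projects(small_portfolio)
        out = ppp.summary_statistics(recs)
        assert out["correlations"]["log_c_vs_log_p"] < -0.3

    def test_moments_and_totals(self, fixture_projects):
        recs = ppp.score_projects(fixture_projects)
        out = ppp.summary_statistics(recs)
        costs = [r.cost for r in recs]
        assert out["n_projects"] == 5
        assert out["total_cost_npv"] == pytest.approx(sum(costs))
        assert out["sum_mean_annual_cost"] == pytest.approx(sum(costs) / 50.0)
        assert out["cost"]["min"] == pytest.approx(min(costs))

    def test_interval_stats_split_by_band_group(self, small_portfolio):
        config = SimulationConfig(n_sims=300, seed=3)
        ranked, dists, bands = ppp.apply_uncertainty(small_portfolio, config)
        out = ppp.summary_statistics(ranked, dists, bands)
        assert sum(out["band_counts"].values()) == len(small_portfolio)
        assert "rank_interval_length" in out
        n_outer = sum(1 for b in bands.values() if b in (1, 5))
        if n_outer:
            assert out["rank_interval_length_bands_1_5"] is not None


def test_apply_uncertainty_fills_records(fixture_projects):
    ranked, dists, bands = ppp.apply_uncertainty(
        fixture_projects, SimulationConfig(n_sims=200, seed=4)
    )
    for r in ranked:
        assert r.rank_interval is not None
        lo, hi = r.rank_interval
        assert 1 <= lo <= hi <= len(fixture_projects)
        assert r.band == bands[r.project_id]
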