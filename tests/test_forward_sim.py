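"""Wright-Fisher engine calibration, grid bookkeeping and accepted statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from balscan.forward_sim import (
    AcceptanceRule,
    accepted_statistics,
    grid_rejection_inference,
    grid_values,
    sample_accepted_panels,
    scheduled_simulations,
    wf_simulate,
)


class TestWfSimulate:
    def test_neutral_fixation_probability_is_one_over_2n(self, single_pop_dem):
        dem = single_pop_dem(n=25)
        reps = 50_000
        rng = np.random.default_rng(8)
        fixed = 0
        for _ in range(reps):
            # 20N generations: a neutral single copy is resolved long before
            res = wf_simulate(dem, s=0.0, age=500, seed=rng, intro_pop="P")
            fixed += res.fixed
        p_hat = fixed / reps
        p_exp = 1 / (2 * 25)
        se = math.sqrt(p_exp * (1 - p_exp) / reps)
        assert abs(p_hat - p_exp) <= 3 * se

    def test_one_generation_selection_response(self, single_pop_dem):
        # deterministic selection-equation oracle: E[dp] = (s/2) p (1-p)
        n, p0, s = 20_000, 0.3, 0.02
        dem = single_pop_dem(n=n)
        rng = np.random.default_rng(9)
        dps = []
        for _ in range(1500):
            res = wf_simulate(
                dem, s=s, age=1, seed=rng, intro_pop="P",
                intro_count=int(2 * n * p0),
            )
            dps.append(res.final_freqs["P"] - p0)
        dps = np.array(dps)
        expected = (s / 2) * p0 * (1 - p0) / (1 + s * p0)  # wbar correction
        se = dps.std(ddof=1) / math.sqrt(dps.size)
        assert abs(dps.mean() - expected) <= 3 * se

    def test_fixed_seed_reproduces_trajectory_and_panel(self, single_pop_dem):
        dem = single_pop_dem(n=100, mu=1e-6, r=1e-7)
        kwargs = dict(
            s=0.1, age=50, region_length=5_000, sample_sizes={"P": 10},
            intro_pop="P", intro_count=5, record_trajectory=True,
        )
        a = wf_simulate(dem, seed=33, **kwargs)
        b = wf_simulate(dem, seed=33, **kwargs)
        assert a.final_freqs == b.final_freqs
        assert a.trajectory == b.trajectory
        assert a.panel == b.panel

    def test_allele_counts_stay_within_bounds(self, single_pop_dem):
        dem = single_pop_dem(n=50)
        res = wf_simulate(
            dem, s=0.5, age=200, seed=4, intro_pop="P", record_trajectory=True
        )
        for _, freq in res.trajectory["P"]:
            assert 0.0 <= freq <= 1.0

    def test_invalid_inputs(self, single_pop_dem):
        dem = single_pop_dem(n=50)
        with pytest.raises(ValueError):
            wf_simulate(dem, s=-0.1, age=10, seed=0, intro_pop="P")
        with pytest.raises(ValueError):
            wf_simulate(dem, s=0.1, age=0, seed=0, intro_pop="P")

    def test_rescaling_leaves_final_frequencies_invariant(self, single_pop_dem):
        """lambda-rescaled runs are statistically interchangeable."""
        dem = single_pop_dem(n=400)
        resc = dem.rescaled(2)
        rng = np.random.default_rng(10)
        full, scaled = [], []
        for _ in range(600):
            r1 = wf_simulate(dem, s=0.01, age=200, seed=rng,
                             intro_pop="P", intro_count=40)
            full.append(r1.final_freqs["P"])
            r2 = wf_simulate(resc, s=0.02, age=100, seed=rng,
                             intro_pop="P", intro_count=20)
            scaled.append(r2.final_freqs["P"])
        assert sps.ks_2samp(full, scaled).pvalue > 0.01


class TestGridRejection:
    def test_grid_values_are_inclusive_and_exact(self):
        assert len(grid_values((0.0, 0.0039, 0.0001))) == 40
        assert len(grid_values((900.0, 2100.0, 50.0))) == 25
        assert grid_values((0.0, 0.2, 0.05)).tolist() == [0.0, 0.05, 0.1, 0.15, 0.2]

    def test_cell_count_is_cartesian_product(self, single_pop_dem):
        dem = single_pop_dem(n=30)
        rule = AcceptanceRule(observed={"P": 0.5}, tolerance_pp=100.0)
        cells = grid_rejection_inference(
            dem, (0.0, 0.1, 0.05), (10.0, 30.0, 10.0),
            n_reps=3, rule=rule, seed=0, intro_pop="P",
        )
        assert len(cells) == 3 * 3

    def test_vacuous_tolerance_accepts_every_replicate(self, single_pop_dem):
        dem = single_pop_dem(n=30)
        rule = AcceptanceRule(observed={"P": 0.5}, tolerance_pp=100.0)
        cells = grid_rejection_inference(
            dem, (0.0, 0.05, 0.05), (20.0, 20.0, 10.0),
            n_reps=20, rule=rule, seed=1, intro_pop="P",
        )
        for c in cells:
            assert c.accepted.all()

    def test_acceptance_flags_match_stored_frequencies(self, single_pop_dem):
        dem = single_pop_dem(n=30)
        rule = AcceptanceRule(observed={"P": 0.3}, tolerance_pp=5.0)
        cells = grid_rejection_inference(
            dem, (0.0, 0.1, 0.1), (15.0, 30.0, 15.0),
            n_reps=25, rule=rule, seed=2, intro_pop="P",
        )
        for c in cells:
            expected = np.abs(c.final_freqs[:, 0] - 0.3) <= 0.05
            assert np.array_equal(c.accepted, expected)

    def test_fixed_seed_reproduces_grid(self, single_pop_dem):
        dem = single_pop_dem(n=30)
        rule = AcceptanceRule(observed={"P": 0.3}, tolerance_pp=10.0)
        args = (dem, (0.0, 0.1, 0.05), (10.0, 20.0, 10.0))
        a = grid_rejection_inference(*args, n_reps=10, rule=rule, seed=3, intro_pop="P")
        b = grid_rejection_inference(*args, n_reps=10, rule=rule, seed=3, intro_pop="P")
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.final_freqs, cb.final_freqs)

    def test_paper_scale_bookkeeping(self):
        assert scheduled_simulations(
            (0.0, 0.0039, 0.0001), (900.0, 2100.0, 50.0), 1_000
        ) == 1_000_000


class TestAcceptedStatistics:
    def test_singleton_accepted_set(self, single_pop_dem):
        dem = single_pop_dem(n=100, mu=1.5e-6, r=5e-7)
        res = wf_simulate(
            dem, s=0.3, age=60, region_length=5_000, seed=11,
            sample_sizes={"P": 20}, intro_pop="P", intro_count=10,
        )
        out = accepted_statistics([res.panel])
        assert out["P"]["tajima_d"].size <= 1
        assert out["P"]["nsl"].size <= 1

    def test_sweep_scenario_gives_negative_median_nsl(self, single_pop_dem):
        """Selection on the derived allele lengthens derived-class tracts."""
        dem = single_pop_dem(n=200, mu=1.5e-6, r=5e-7)
        rule = AcceptanceRule(observed={"P": 0.5}, tolerance_pp=40.0)
        rng = np.random.default_rng(13)
        panels = []
        while len(panels) < 100:
            res = wf_simulate(
                dem, s=0.25, age=60, region_length=8_000, seed=rng,
                sample_sizes={"P": 40}, intro_pop="P", abort_on_loss=True,
            )
            if not res.lost and res.panel is not None and rule.accepts(res.final_freqs):
                panels.append(res.panel)
        out = accepted_statistics(panels)
        nsl = out["P"]["nsl"]
        assert nsl.size >= 100 * 0.8
        assert np.median(nsl) < 0

    def test_neutral_accepted_runs_match_coalescent_null(self, single_pop_dem):
        """Cross-engine consistency restricted to the accepted pathway."""
        from balscan.coalescent_sim import simulate_sample
        from balscan.panel import GenomicWindow
        from balscan.sfs_scan import tajimas_d_components

        dem = single_pop_dem(n=100, mu=2.5e-6, r=2.5e-7)
        L, nsamp = 5_000, 30
        rng = np.random.default_rng(14)
        fwd = []
        while len(fwd) < 150:
            res = wf_simulate(
                dem, s=0.0, age=50, region_length=L, seed=rng,
                sample_sizes={"P": nsamp}, intro_pop="P",
            )
            st = tajimas_d_components(res.panel, GenomicWindow("sim", 0, L))
            if st.defined:
                fwd.append(st.tajima_d)
        coal = []
        while len(coal) < 150:
            samp = simulate_sample(dem, {"P": nsamp}, L, seed=rng)
            st = tajimas_d_components(samp.panel, GenomicWindow("sim", 0, L))
            if st.defined:
                coal.append(st.tajima_d)
        fwd, coal = np.array(fwd), np.array(coal)
        se = math.hypot(fwd.std(ddof=1) / math.sqrt(fwd.size),
                        coal.std(ddof=1) / math.sqrt(coal.size))
        assert abs(fwd.mean() - coal.mean()) <= 3 * se

    def test_empty_accepted_set_errors(self):
        with pytest.raises(ValueError):
            accepted_statistics([])


class TestSampleAcceptedPanels:
    def test_panels_resatisfy_rule(self, single_pop_dem):
        dem = single_pop_dem(n=80, mu=1.5e-6, r=5e-7)
        rule = AcceptanceRule(observed={"P": 0.5}, tolerance_pp=45.0)
        cells = grid_rejection_inference(
            dem, (0.1, 0.2, 0.1), (40.0, 60.0, 20.0),
            n_reps=30, rule=rule, seed=6, intro_pop="P",
        )
        panels = sample_accepted_panels(
            dem, cells, rule, sample_sizes={"P": 20}, region_length=4_000,
            max_panels=3, seed=7, intro_pop="P",
        )
        assert panels
        for panel in panels:
            f = panel.derived_frequency(panel.focal_index)
            assert panel.focal_index is not None
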