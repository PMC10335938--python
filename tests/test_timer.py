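"""Gene-state dynamics: Wnt firing, loading feedback, contact-driven
activation, expression proxies and calibration plumbing."""

import dataclasses
import math

import numpy as np
import pytest

from hoxtimer.core import Axis, Track
from hoxtimer.extrusion import SimulationParams
from hoxtimer.locus import (
    ClusterDomain,
    Gene,
    GenomicInterval,
    LocusAnnotation,
    RegulatoryRegion,
    discretize,
)
from hoxtimer.timer import (
    ACTIVE,
    SILENT,
    ChromatinState,
    TimerParams,
    activation_update,
    calibrate_defaults,
    expression_proxy,
    init_chromatin,
    loading_profile,
    run_timer,
    wnt_activation,
)


def many_gene_locus(n_genes, domain=ClusterDomain.CENTRAL, gene_len=5_000, gap=5_000):
    """Toy locus with n identical genes for Monte-Carlo firing statistics."""
    pitch = gene_len + gap
    genes = tuple(
        Gene(f"g{i}", GenomicInterval("chrT", i * pitch, i * pitch + gene_len), domain)
        for i in range(n_genes)
    )
    axis = GenomicInterval("chrT", 0, n_genes * pitch + gap)
    regions = (RegulatoryRegion("cluster", GenomicInterval("chrT", 0, axis.end)),)
    return LocusAnnotation(axis_interval=axis, genes=genes, ctcf_sites=(), regions=regions)


class TestInitChromatin:
    def test_all_silent_repressed(self, wt_locus, wt_lattice):
        chrom = init_chromatin(wt_locus, wt_lattice)
        assert chrom.k27ac.values.sum() == 0.0
        assert all(s == SILENT for s in chrom.gene_states.values())
        for g in wt_locus.genes:
            lo, hi = wt_lattice.gene_bins[g.name]
            assert np.all(chrom.k27me3.values[lo : hi + 1] > 0)
        chrom.assert_mutual_exclusion()


class TestWntActivation:
    def test_before_pulse_no_change(self, wt_locus, wt_lattice):
        chrom = init_chromatin(wt_locus, wt_lattice)
        params = TimerParams()
        rng = np.random.default_rng(0)
        wnt_activation(chrom, wt_locus, params.t_wnt - 1.0, params, wt_lattice, 0.01, rng)
        assert all(s == SILENT for s in chrom.gene_states.values())

    def test_infinite_rate_fires_all_at_once(self, wt_locus, wt_lattice):
        chrom = init_chromatin(wt_locus, wt_lattice)
        params = TimerParams(anterior_activation_rate=math.inf)
        rng = np.random.default_rng(0)
        wnt_activation(chrom, wt_locus, params.t_wnt, params, wt_lattice, 0.01, rng)
        for g in wt_locus.genes:
            expected = ACTIVE if g.cluster_domain is ClusterDomain.ANTERIOR else SILENT
            assert chrom.gene_states[g.name] == expected

    def test_firing_probability_matches_closed_form(self):
        """One step fires each gene with P = 1 - exp(-r dt)."""
        locus = many_gene_locus(10_000, domain=ClusterDomain.ANTERIOR)
        lmap = discretize(locus, 1_000)
        rate, dt = 3.0, 0.2
        params = TimerParams(anterior_activation_rate=rate, t_wnt=0.0)
        chrom = init_chromatin(locus, lmap)
        rng = np.random.default_rng(42)
        wnt_activation(chrom, locus, 0.0, params, lmap, dt, rng)
        frac = np.mean([chrom.gene_states[g.name] == ACTIVE for g in locus.genes])
        assert frac == pytest.approx(1.0 - math.exp(-rate * dt), rel=0.02)

    def test_activation_flips_chromatin_marks(self, wt_locus, wt_lattice):
        chrom = init_chromatin(wt_locus, wt_lattice)
        params = TimerParams(anterior_activation_rate=math.inf)
        wnt_activation(chrom, wt_locus, 72.0, params, wt_lattice, 0.01,
                       np.random.default_rng(0))
        lo, hi = wt_lattice.gene_bins["Hoxd4"]
        assert np.all(chrom.k27ac.values[lo : hi + 1] == 1.0)
        assert np.all(chrom.k27me3.values[lo : hi + 1] == 0.0)
        chrom.assert_mutual_exclusion()


class TestLoadingProfile:
    def test_no_active_genes_background_outside_repressed(self, wt_locus, wt_lattice):
        chrom = init_chromatin(wt_locus, wt_lattice)
        sp = SimulationParams()
        w = loading_profile(chrom, wt_locus, wt_lattice, sp).values
        clo, chi = wt_lattice.region_bins["cluster"]
        # repressed cluster takes no loading; T-DOM keeps background weight
        assert np.all(w[clo : chi + 1] == 0.0)
        assert np.all(w[chi + 1 :] == sp.w_background)
        assert np.all(w[:clo] == 0.0)  # C-DOM inert

    def test_active_gene_bins_weighted(self, wt_locus, wt_lattice):
        chrom = init_chromatin(wt_locus, wt_lattice)
        params = TimerParams(anterior_activation_rate=math.inf)
        wnt_activation(chrom, wt_locus, 72.0, params, wt_lattice, 0.01,
                       np.random.default_rng(0))
        sp = SimulationParams()
        w = loading_profile(chrom, wt_locus, wt_lattice, sp).values
        lo, hi = wt_lattice.gene_bins["Hoxd1"]
        assert np.all(w[lo : hi + 1] == sp.w_active)

    def test_activation_never_decreases_weights(self, wt_locus, wt_lattice):
        sp = SimulationParams()
        chrom = init_chromatin(wt_locus, wt_lattice)
        before = loading_profile(chrom, wt_locus, wt_lattice, sp).values.copy()
        params = TimerParams(anterior_activation_rate=math.inf)
        wnt_activation(chrom, wt_locus, 72.0, params, wt_lattice, 0.01,
                       np.random.default_rng(0))
        after = loading_profile(chrom, wt_locus, wt_lattice, sp).values
        assert np.all(after >= before)


class TestActivationUpdate:
    def _chromatin(self, locus, lmap):
        return init_chromatin(locus, lmap)

    def test_zero_contact_never_fires(self, wt_locus, wt_lattice):
        chrom = self._chromatin(wt_locus, wt_lattice)
        params = TimerParams(k_act=5.0)
        rng = np.random.default_rng(1)
        contact = {g.name: 0.0 for g in wt_locus.genes}
        for _ in range(200):
            activation_update(chrom, contact, wt_locus, params, wt_lattice, 0.01, 100.0, rng)
        assert all(s == SILENT for s in chrom.gene_states.values())

    def test_infinite_hazard_fires_immediately(self, wt_locus, wt_lattice):
        chrom = self._chromatin(wt_locus, wt_lattice)
        params = TimerParams(k_act=math.inf)
        rng = np.random.default_rng(1)
        contact = {g.name: 1.0 for g in wt_locus.genes}
        activation_update(chrom, contact, wt_locus, params, wt_lattice, 0.01, 100.0, rng)
        for g in wt_locus.genes:
            if g.cluster_domain is not ClusterDomain.ANTERIOR:
                assert chrom.gene_states[g.name] == ACTIVE

    def test_enhancers_inactive_blocks_hazard(self, wt_locus, wt_lattice):
        chrom = self._chromatin(wt_locus, wt_lattice)
        params = TimerParams(k_act=math.inf)
        rng = np.random.default_rng(1)
        contact = {g.name: 1.0 for g in wt_locus.genes}
        activation_update(chrom, contact, wt_locus, params, wt_lattice, 0.01, 90.0, rng,
                          enhancers_active=False)
        assert all(s == SILENT for s in chrom.gene_states.values())

    def test_median_firing_time_matches_exponential(self):
        """Constant contact c: median onset = ln2 / (k_act c)."""
        locus = many_gene_locus(10_000)
        lmap = discretize(locus, 1_000)
        k_act, c, dt = 2.0, 5.0, 0.01
        params = TimerParams(k_act=k_act)
        chrom = init_chromatin(locus, lmap)
        rng = np.random.default_rng(7)
        contact = {g.name: c for g in locus.genes}
        t, fire_times = 0.0, {}
        while any(s == SILENT for s in chrom.gene_states.values()) and t < 3.0:
            _, events = activation_update(chrom, contact, locus, params, lmap, dt, t, rng)
            for name, when in events:
                fire_times[name] = when
            t += dt
        med = np.median(list(fire_times.values()))
        assert med == pytest.approx(math.log(2) / (k_act * c), rel=0.05)

    def test_threshold_rule(self, wt_locus, wt_lattice):
        chrom = self._chromatin(wt_locus, wt_lattice)
        params = TimerParams(activation_rule="threshold", activation_threshold=2.0)
        rng = np.random.default_rng(1)
        contact = {g.name: 1.0 for g in wt_locus.genes}
        activation_update(chrom, contact, wt_locus, params, wt_lattice, 0.01, 100.0, rng)
        assert chrom.gene_states["Hoxd9"] == SILENT
        contact["Hoxd9"] = 2.5
        activation_update(chrom, contact, wt_locus, params, wt_lattice, 0.01, 100.0, rng)
        assert chrom.gene_states["Hoxd9"] == ACTIVE


class TestRunTimer:
    def test_k_act_zero_only_anterior_activates(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        tp = dataclasses.replace(tp, k_act=0.0)
        res = run_timer(wt_locus, sp, tp, t_start=48, t_end=110, seed=3,
                        record_trajectory=False)
        for g in wt_locus.genes:
            onset = res.schedule.onsets[g.name]
            if g.cluster_domain is ClusterDomain.ANTERIOR:
                assert np.isfinite(onset)
            else:
                assert np.isinf(onset)

    def test_reproducible_from_seed(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        r1 = run_timer(wt_locus, sp, tp, t_start=48, t_end=100, seed=9)
        r2 = run_timer(wt_locus, sp, tp, t_start=48, t_end=100, seed=9)
        assert r1.schedule.onsets == r2.schedule.onsets
        for g in r1.contact_activation:
            assert np.array_equal(r1.contact_activation[g], r2.contact_activation[g])
        for a, b in zip(r1.trajectory.snapshot_left, r2.trajectory.snapshot_left):
            assert np.array_equal(a, b)

    def test_onsets_respect_pulse_and_enhancer_gates(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        res = run_timer(wt_locus, sp, tp, t_start=48, t_end=120, seed=12,
                        record_trajectory=False)
        for g in wt_locus.genes:
            onset = res.schedule.onsets[g.name]
            if not np.isfinite(onset):
                continue
            if g.cluster_domain is ClusterDomain.ANTERIOR:
                assert onset >= tp.t_wnt
            else:
                assert onset >= tp.t_enh

    def test_chromatin_mutual_exclusion_all_samples(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        res = run_timer(wt_locus, sp, tp, t_start=48, t_end=120, seed=5,
                        record_trajectory=False, chromatin_sample_every=6.0)
        for _, chrom in res.chromatin_timecourse:
            chrom.assert_mutual_exclusion()


class TestExpressionProxy:
    def test_silent_gene_zero_everywhere(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        tp = dataclasses.replace(tp, k_act=0.0)
        res = run_timer(wt_locus, sp, tp, t_start=48, t_end=100, seed=2,
                        record_trajectory=False)
        table = expression_proxy(res, [72, 96, 100], tp, wt_locus)
        assert np.all(table.loc["Hoxd13"].to_numpy() == 0.0)

    def test_dilution_monotone_in_rank(self, wt_locus, wt_lattice, shipped_params):
        sp, tp = shipped_params
        res = run_timer(wt_locus, sp, tp, t_start=48, t_end=100, seed=2,
                        record_trajectory=False)
        # force equal contact and onset bookkeeping for two ranks
        res.schedule.onsets["Hoxd1"] = 80.0
        res.schedule.onsets["Hoxd9"] = 80.0
        res.contact_anchor["Hoxd1"] = np.ones_like(res.contact_times)
        res.contact_anchor["Hoxd9"] = np.ones_like(res.contact_times)
        table = expression_proxy(res, [96.0], tp, wt_locus)
        assert table.loc["Hoxd9", 96.0] < table.loc["Hoxd1", 96.0]
        ratio = table.loc["Hoxd9", 96.0] / table.loc["Hoxd1", 96.0]
        rank_gap = wt_locus.gene_rank("Hoxd9") - wt_locus.gene_rank("Hoxd1")
        assert ratio == pytest.approx(2.0 ** (-rank_gap / tp.dilution_half_life))


class TestCalibration:
    def test_single_point_grid_returns_it(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        res = calibrate_defaults(
            {"k_act": [0.123]},
            {"Hoxd4": 84.0},
            wt_locus,
            sim_params=sp,
            timer_params=tp,
            n_replicates=2,
            t_end=90.0,
            seed=1,
        )
        assert res.timer_params.k_act == 0.123
        assert len(res.table) == 1

    def test_argmin_property(self, wt_locus, shipped_params):
        sp, tp = shipped_params
        res = calibrate_defaults(
            {"anterior_activation_rate": [math.log(2) / 6, math.log(2) / 30]},
            {"Hoxd4": 78.0},
            wt_locus,
            sim_params=sp,
            timer_params=tp,
            n_replicates=3,
            t_end=90.0,
            seed=1,
        )
        assert res.objective == res.table["objective"].min()
        assert res.timer_params.anterior_activation_rate == pytest.approx(math.log(2) / 6)

    def test_empty_grid_rejected(self, wt_locus):
        with pytest.raises(ValueError):
            calibrate_defaults({}, {"Hoxd4": 84.0}, wt_locus)
        with pytest.raises(ValueError):
            calibrate_defaults({"k_act": []}, {"Hoxd4": 84.0}, wt_locus)

    def test_unknown_parameter_rejected(self, wt_locus):
        with pytest.raises(KeyError):
            calibrate_defaults({"nope": [1]}, {"Hoxd4": 84.0}, wt_locus, n_replicates=1)
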