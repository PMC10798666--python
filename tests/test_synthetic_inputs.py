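"""Unit and property tests for PC input synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbnsim.synthetic_inputs import (
    CHLORIDE_DIVISOR,
    DEPRESSION_FACTOR,
    MAX_LOGNORMAL_RATE,
    InputPopulation,
    SizeDistributionModel,
    SpikeTrain,
    UnitaryInput,
    apply_pauses,
    apply_synchrony,
    correct_conductance,
    draw_input_population,
    isi_lognormal_model,
    isi_poisson_model,
    population_from_yaml,
    population_to_yaml,
    read_spike_trains,
    sample_spike_train,
    simplified_population,
    synchronize_largest,
    write_spike_trains,
)

HSETTINGS = dict(derandomize=True, max_examples=25, deadline=None)


class TestISIModels:
    @pytest.mark.parametrize(
        "rate, mean, sd",
        [(80.0, 0.0125, 0.0057475), (49.0, 1 / 49, -0.00154 + 0.583 / 49)],
    )
    def test_lognormal_linear_sd_relation(self, rate, mean, sd):
        m = isi_lognormal_model(rate)
        assert m.mean_isi == pytest.approx(mean, rel=1e-12)
        assert m.sd_isi == pytest.approx(sd, rel=1e-12)

    def test_lognormal_shape_parameters_at_80hz(self):
        m = isi_lognormal_model(80.0)
        assert m.sigma == pytest.approx(0.4380, abs=1e-4)
        assert m.mu == pytest.approx(-4.4779, abs=1e-4)

    @pytest.mark.parametrize("rate", [378.6, 0.0, -5.0, 500.0])
    def test_lognormal_rate_out_of_range(self, rate):
        with pytest.raises(ValueError, match="sd"):
            isi_lognormal_model(rate)

    def test_lognormal_valid_up_to_the_sd_root(self):
        # 378.5 spikes/s still yields a (tiny) positive sd.
        m = isi_lognormal_model(378.5)
        assert m.sd_isi > 0
        assert MAX_LOGNORMAL_RATE == pytest.approx(0.583 / 0.00154)

    def test_poisson_model(self):
        m = isi_poisson_model(80.0)
        assert m.mean_isi == pytest.approx(0.0125)
        assert m.kind == "exponential"
        assert isi_poisson_model(1.0).mean_isi == 1.0
        with pytest.raises(ValueError):
            isi_poisson_model(0.0)

    @given(rate=st.floats(1.0, 370.0))
    @settings(**HSETTINGS)
    def test_moment_matching_identity(self, rate):
        m = isi_lognormal_model(rate)
        assert math.exp(m.mu + m.sigma**2 / 2) == pytest.approx(m.mean_isi, rel=1e-9)
        implied_var = (math.exp(m.sigma**2) - 1) * m.mean_isi**2
        assert implied_var == pytest.approx(m.sd_isi**2, rel=1e-9)

    def test_poisson_isi_cv_is_one(self):
        rng = np.random.default_rng(0)
        isis = isi_poisson_model(80.0).sample_isis(80_000, rng)
        cv = isis.std() / isis.mean()
        assert abs(cv - 1.0) < 3 / math.sqrt(isis.size)

    @pytest.mark.parametrize("rate", [49.0, 83.0, 122.0])
    def test_moment_recovery(self, rate):
        m = isi_lognormal_model(rate)
        rng = np.random.default_rng(1)
        x = m.sample_isis(100_000, rng)
        n = x.size
        se_mean = x.std() / math.sqrt(n)
        kappa = np.mean((x - x.mean()) ** 4) / x.std() ** 4
        se_sd = x.std() * math.sqrt((kappa - 1) / (4 * n))
        assert abs(x.mean() - m.mean_isi) < 4 * se_mean
        assert abs(x.std() - m.sd_isi) < 4 * se_sd

    def test_negligible_mass_below_one_ms_at_83hz(self):
        # The lognormal itself produces the refractory structure: almost no
        # ISIs shorter than 1 ms at physiological rates.
        m = isi_lognormal_model(83.0)
        rng = np.random.default_rng(2)
        assert np.mean(m.sample_isis(100_000, rng) < 1e-3) < 0.01


class TestSpikeTrains:
    def test_zero_duration_is_empty(self):
        tr = sample_spike_train(isi_lognormal_model(80.0), 0.0, seed=0)
        assert len(tr) == 0

    def test_same_seed_is_identical(self):
        m = isi_lognormal_model(80.0)
        a = sample_spike_train(m, 50.0, seed=42)
        b = sample_spike_train(m, 50.0, seed=42)
        assert np.array_equal(a.times, b.times)
        c = sample_spike_train(m, 50.0, seed=43)
        assert not np.array_equal(a.times, c.times)

    def test_count_and_isi_statistics(self):
        m = isi_lognormal_model(80.0)
        tr = sample_spike_train(m, 100.0, seed=3)
        n = len(tr)
        assert abs(n - 8000) < 3 * math.sqrt(8000)
        isis = np.diff(tr.times)
        assert abs(isis.mean() - m.mean_isi) < 4 * isis.std() / math.sqrt(isis.size)
        assert tr.times[0] >= 0 and tr.times[-1] < tr.duration

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.5, 1.0]), 1.0)


class TestSizeModel:
    def test_analytic_calibration_is_exact(self):
        m = SizeDistributionModel.juvenile()
        assert m.raw_mean == 52.9
        assert m.raw_cv == 1.0
        assert m.corrected_mean == pytest.approx(52.9 * 0.4 / 2.3)

    def test_draws_recover_moments(self):
        m = SizeDistributionModel.juvenile()
        x = m.sample_raw(100_000, np.random.default_rng(4))
        n = x.size
        se_mean = x.std() / math.sqrt(n)
        kappa = np.mean((x - x.mean()) ** 4) / x.std() ** 4
        se_sd = x.std() * math.sqrt((kappa - 1) / (4 * n))
        assert abs(x.mean() - 52.9) < 4 * se_mean
        assert abs(x.std() - 52.9) < 4 * se_sd  # CV 1.0 => sd == mean

    def test_corrected_draws_apply_both_factors(self):
        m = SizeDistributionModel.juvenile()
        raw = m.sample_raw(1000, np.random.default_rng(5))
        corr = m.sample_corrected(1000, np.random.default_rng(5))
        assert np.allclose(corr, raw * DEPRESSION_FACTOR / CHLORIDE_DIVISOR)
        half = m.sample_corrected(1000, np.random.default_rng(5), scale=0.5)
        assert np.allclose(half, corr * 0.5)

    def test_empirical_model_from_csv(self, tmp_path):
        path = tmp_path / "sizes.csv"
        path.write_text("conductance_ns\n10.0\n20.0\n30.0\n")
        m = SizeDistributionModel.from_csv(path)
        assert m.raw_mean == pytest.approx(20.0)
        draws = m.sample_raw(500, np.random.default_rng(6))
        assert set(np.unique(draws)) <= {10.0, 20.0, 30.0}

    @pytest.mark.parametrize(
        "raw, expected", [(52.9, 9.2), (0.0, 0.0), (5.75, 1.0)]
    )
    def test_correct_conductance(self, raw, expected):
        assert correct_conductance(raw) == pytest.approx(expected)

    def test_correct_conductance_rejects_negative(self):
        with pytest.raises(ValueError):
            correct_conductance(-1.0)


class TestDrawPopulation:
    def test_degenerate_constant_model_gives_exact_count(self):
        m = SizeDistributionModel(
            family="empirical", values=np.array([5.0 * 2.3 / 0.4])
        )
        pop = draw_input_population(m, 200.0, 80.0, seed=0)
        assert len(pop) == 40
        assert pop.total_conductance == pytest.approx(200.0)

    @given(seed=st.integers(0, 10_000))
    @settings(**HSETTINGS)
    def test_stopping_rule(self, seed):
        m = SizeDistributionModel.juvenile()
        pop = draw_input_population(m, 200.0, 80.0, seed=seed)
        amps = pop.amplitudes
        assert amps.sum() >= 200.0
        assert amps.sum() - amps[-1] < 200.0

    def test_expected_count_wald_bracket(self):
        # E[N] * 9.2 = E[S_N] (Wald), with 200 <= E[S_N] <= 200 + size-biased
        # overshoot (~2x the 9.2 nS mean at CV = 1).
        m = SizeDistributionModel.juvenile()
        counts = [
            len(draw_input_population(m, 200.0, 80.0, seed=s)) for s in range(300)
        ]
        mean_n = np.mean(counts)
        assert 200.0 / 9.2 - 1.0 < mean_n < (200.0 + 2 * 9.2) / 9.2 + 1.0

    def test_scale_factor(self):
        m = SizeDistributionModel(
            family="empirical", values=np.array([5.0 * 2.3 / 0.4])
        )
        pop = draw_input_population(m, 200.0, 80.0, seed=0, scale=0.5)
        assert len(pop) == 80
        assert pop.amplitudes[0] == pytest.approx(2.5)

    def test_each_input_independent_model_and_group(self):
        pop = draw_input_population(
            SizeDistributionModel.juvenile(), 100.0, 83.0, seed=1
        )
        groups = {u.sync_group for u in pop.inputs}
        assert len(groups) == len(pop)
        assert all(u.rate_model.rate == pytest.approx(83.0) for u in pop.inputs)


class TestSimplifiedPopulations:
    def test_fig2_counts_and_total(self):
        pop = simplified_population("fig2")
        assert len(pop) == 28
        amps = sorted(pop.amplitudes)
        assert amps == [3.0] * 16 + [10.0] * 10 + [30.0] * 2
        assert pop.total_conductance == pytest.approx(208.0)

    def test_uniform40(self):
        pop = simplified_population("uniform40")
        assert len(pop) == 40
        assert np.all(pop.amplitudes == 5.0)
        assert pop.total_conductance == pytest.approx(200.0)

    def test_fig3_variants(self):
        pop = simplified_population("fig3-122")
        assert len(pop) == 6
        assert np.all(pop.amplitudes == 20.0)
        assert pop.inputs[0].rate_model.rate == pytest.approx(122.0)
        poisson = simplified_population("fig3-poisson")
        assert poisson.inputs[0].rate_model.kind == "exponential"

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            simplified_population("fig9")


class TestSynchrony:
    def test_grouping_preserves_amplitudes_and_total(self):
        pop = simplified_population("uniform40")
        grouped = apply_synchrony(pop, ["a"] * 10 + [f"g{i}" for i in range(30)])
        assert len(grouped) == len(pop)
        assert grouped.total_conductance == pop.total_conductance
        assert np.array_equal(grouped.amplitudes, pop.amplitudes)
        assert len(grouped.sync_groups()["a"]) == 10

    def test_singleton_groups_change_nothing(self):
        pop = simplified_population("fig2")
        same = apply_synchrony(pop, [u.sync_group for u in pop.inputs])
        assert same.sync_groups() == pop.sync_groups()

    def test_incomplete_assignment_rejected(self):
        pop = simplified_population("uniform40")
        with pytest.raises(ValueError):
            apply_synchrony(pop, {0: "a"})

    def test_synchronize_largest(self):
        pop = simplified_population("fig2")
        g = synchronize_largest(pop, 2)
        members = g.sync_groups()["sync"]
        assert sorted(g.inputs[i].amplitude for i in members) == [30.0, 30.0]


class TestPauses:
    def test_window_deletion_example(self):
        tr = SpikeTrain(np.array([1e-3, 3e-3, 5e-3, 7e-3]), 0.01)
        out = apply_pauses(tr, [2e-3], 2e-3)
        assert np.allclose(out.times, [1e-3, 5e-3, 7e-3])

    def test_empty_region_unchanged(self):
        tr = SpikeTrain(np.array([1e-3, 7e-3]), 0.01)
        out = apply_pauses(tr, [3e-3], 2e-3)
        assert np.array_equal(out.times, tr.times)

    def test_overlapping_windows_merged(self):
        tr = SpikeTrain(np.array([1e-3, 3e-3, 4.5e-3, 7e-3]), 0.01)
        out = apply_pauses(tr, [2e-3, 3.5e-3], 2e-3)
        assert np.allclose(out.times, [1e-3, 7e-3])

    def test_periodic_deletion_fraction(self):
        tr = sample_spike_train(isi_poisson_model(80.0), 100.0, seed=8)
        out = apply_pauses(tr, np.arange(0.0, 100.0 - 2e-3, 0.02), 2e-3)
        frac = 1 - len(out) / len(tr)
        se = math.sqrt(0.1 * 0.9 / len(tr))
        assert abs(frac - 0.1) < 3 * se

    @given(onset=st.floats(0.0, 0.99), width=st.floats(1e-4, 0.05))
    @settings(**HSETTINGS)
    def test_monotone_and_exact_when_untouched(self, onset, width):
        tr = sample_spike_train(isi_poisson_model(50.0), 1.0, seed=9)
        out = apply_pauses(tr, [onset], width)
        assert len(out) <= len(tr)
        hit = np.any((tr.times >= onset) & (tr.times < onset + width))
        assert (len(out) < len(tr)) == bool(hit)


class TestIO:
    def test_spike_train_csv_round_trip_microsecond(self, tmp_path):
        rng = np.random.default_rng(10)
        trains = [
            SpikeTrain(np.round(np.sort(rng.uniform(0, 9.9, 50)), 6), 10.0, "pc0"),
            SpikeTrain(np.round(np.sort(rng.uniform(0, 9.9, 30)), 6), 10.0, "pc1"),
        ]
        path = tmp_path / "trains.csv"
        write_spike_trains(path, trains)
        back = read_spike_trains(path)
        assert [t.source_id for t in back] == ["pc0", "pc1"]
        for a, b in zip(trains, back):
            assert b.duration == a.duration
            assert np.array_equal(a.times, b.times)

    def test_population_yaml_round_trip(self, tmp_path):
        pop = simplified_population("fig6")
        text = population_to_yaml(pop, tmp_path / "pop.yaml")
        back = population_from_yaml(text)
        assert len(back) == len(pop)
        assert np.array_equal(back.amplitudes, pop.amplitudes)
        assert [u.sync_group for u in back.inputs] == [
            u.sync_group for u in pop.inputs
        ]
        assert back.inputs[0].rate_model.rate == pytest.approx(
            pop.inputs[0].rate_model.rate
        )
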