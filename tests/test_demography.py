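import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demoscope.demography import (
    Epoch,
    PiecewiseDemography,
    SizeTrajectory,
    average_trajectories,
    emit_msmc_table,
    parse_msmc_output,
    parse_ms_command,
    rescale_mutation_rate,
    set_ancestral_size,
    to_ms_command,
    trajectory_to_stepwise,
    trim_model,
)
from demoscope.errors import (
    FormatError,
    InvalidInputError,
    UnsupportedFeatureError,
)


class TestEpochInvariants:
    def test_nonpositive_size_rejected(self):
        with pytest.raises(InvalidInputError):
            Epoch(0, 100, {"a": 0.0})

    def test_time_ordering(self):
        with pytest.raises(InvalidInputError):
            Epoch(100, 100, {"a": 10.0})

    def test_migration_range(self):
        with pytest.raises(InvalidInputError):
            Epoch(0, 100, {"a": 10, "b": 10}, migration={("a", "b"): 1.5})

    def test_exponential_size_interpolation(self):
        e = Epoch(0, 100, {"a": 100.0}, end_sizes={"a": 400.0})
        assert e.size("a", 0) == pytest.approx(100.0)
        assert e.size("a", 50) == pytest.approx(200.0)  # geometric midpoint

    def test_unbounded_cannot_be_exponential(self):
        with pytest.raises(InvalidInputError):
            Epoch(0, math.inf, {"a": 10.0}, end_sizes={"a": 20.0})


class TestPiecewiseDemography:
    def test_requires_contiguous_epochs(self):
        with pytest.raises(InvalidInputError):
            PiecewiseDemography(
                (Epoch(0, 100, {"a": 10}), Epoch(200, math.inf, {"a": 10}))
            )

    def test_requires_one_unbounded_epoch(self):
        with pytest.raises(InvalidInputError):
            PiecewiseDemography((Epoch(0, 100, {"a": 10}),))

    def test_partition_property(self, three_epoch_pop):
        # every t >= 0 lies in exactly one epoch; lookup is total
        for t in [0, 1, 499, 500, 2999.9, 3000, 1e7]:
            hits = [e for e in three_epoch_pop.epochs if e.contains(t)]
            assert len(hits) == 1
            assert three_epoch_pop.size("pop0", t) == next(iter(hits[0].sizes.values()))

    def test_yaml_round_trip(self, tmp_path, three_epoch_pop):
        p = tmp_path / "model.yaml"
        three_epoch_pop.to_yaml(p)
        back = PiecewiseDemography.from_yaml(p)
        assert back.equivalent(three_epoch_pop)

    def test_split_requires_extant_populations(self):
        from demoscope.demography import Split

        with pytest.raises(InvalidInputError):
            PiecewiseDemography(
                (Epoch(0, math.inf, {"a": 10}),),
                splits=(Split(5.0, "ghost", "a"),),
            )


class TestParseMsmc:
    def test_scaling_inversion(self):
        # lambda=1000 at mu=1.25e-8 -> N = 1/(2 mu lambda) = 40,000
        table = np.array([[0, 0.0, 1e-4, 1000.0], [1, 1e-4, 2e-4, 500.0]])
        traj = parse_msmc_output(table, mu=1.25e-8)
        assert traj.steps[0][2] == pytest.approx(40_000.0)
        assert traj.steps[1][2] == pytest.approx(80_000.0)
        assert traj.steps[0][1] == pytest.approx(1e-4 / 1.25e-8)

    def test_default_generation_time_is_30(self):
        import inspect

        sig = inspect.signature(parse_msmc_output)
        assert sig.parameters["generation_time"].default == 30.0

    def test_round_trip(self):
        steps = ((0.0, 800.0, 20_000.0), (800.0, 5_000.0, 5_000.0), (5_000.0, math.inf, 12_000.0))
        traj = SizeTrajectory(steps)
        back = parse_msmc_output(emit_msmc_table(traj, 1.25e-8), mu=1.25e-8)
        for (l0, r0, n0), (l1, r1, n1) in zip(traj.steps, back.steps):
            assert l0 == pytest.approx(l1)
            assert n0 == pytest.approx(n1)

    def test_nonpositive_lambda_rejected(self):
        table = np.array([[0, 0.0, 1e-4, -1.0]])
        with pytest.raises(InvalidInputError):
            parse_msmc_output(table, mu=1.25e-8)

    def test_nonpositive_mu_rejected(self):
        table = np.array([[0, 0.0, 1e-4, 100.0]])
        with pytest.raises(InvalidInputError):
            parse_msmc_output(table, mu=0.0)

    def test_unsorted_boundaries_rejected(self):
        table = np.array([[0, 1e-4, 2e-4, 100.0], [1, 0.5e-4, 1e-4, 100.0]])
        with pytest.raises(FormatError):
            parse_msmc_output(table, mu=1.25e-8)

    def test_file_input(self, tmp_path):
        p = tmp_path / "msmc.txt"
        df = pd.DataFrame(
            {
                "time_index": [0, 1],
                "left_time_boundary": [0.0, 1e-4],
                "right_time_boundary": [1e-4, 2e-4],
                "lambda": [1000.0, 400.0],
            }
        )
        df.to_csv(p, sep="\t", index=False)
        traj = parse_msmc_output(p, mu=1.25e-8)
        assert traj.steps[1][2] == pytest.approx(1 / (2 * 1.25e-8 * 400.0))


class TestTrajectoryToStepwise:
    def test_stepwise_passthrough_is_identity(self):
        traj = SizeTrajectory(((0.0, 100.0, 5000.0), (100.0, math.inf, 800.0)))
        d1 = trajectory_to_stepwise(traj, 5)
        d2 = trajectory_to_stepwise(traj, 500)
        assert d1.equivalent(d2)
        assert d1.size("pop0", 50) == 5000.0
        assert d1.size("pop0", 1e6) == 800.0

    def test_refinement_monotonicity(self):
        f = lambda t: 1000.0 * math.exp(-t / 5e4)  # noqa: E731
        ts = np.geomspace(10, 1e6, 400)

        def max_rel_err(n_steps):
            d = trajectory_to_stepwise(f, n_steps, t_min=10, t_max=1e6)
            vals = np.array([d.size("pop0", t) for t in ts])
            truth = np.array([f(t) for t in ts])
            return np.max(np.abs(vals - truth) / truth)

        errs = [max_rel_err(k) for k in (8, 16, 32, 64)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_n_steps_validation(self):
        with pytest.raises(InvalidInputError):
            trajectory_to_stepwise(lambda t: 100.0, 0)


class TestAverageTrajectories:
    def test_mean_of_identical_is_identity(self):
        traj = SizeTrajectory(((0.0, 50.0, 1000.0), (50.0, math.inf, 3000.0)))
        avg = average_trajectories([traj] * 50)
        assert avg.steps == traj.steps

    def test_arithmetic_mean_of_constants(self):
        t1 = SizeTrajectory(((0.0, math.inf, 1000.0),))
        t2 = SizeTrajectory(((0.0, math.inf, 3000.0),))
        avg = average_trajectories([t1, t2])
        assert avg.steps == ((0.0, math.inf, 2000.0),)

    def test_log_mode_geometric_mean(self):
        t1 = SizeTrajectory(((0.0, math.inf, 1000.0),))
        t2 = SizeTrajectory(((0.0, math.inf, 4000.0),))
        avg = average_trajectories([t1, t2], mode="log")
        assert avg.steps[0][2] == pytest.approx(2000.0)

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            average_trajectories([])

    def test_explicit_grid(self):
        traj = SizeTrajectory(((0.0, 75.0, 1000.0), (75.0, math.inf, 3000.0)))
        avg = average_trajectories([traj], grid=[50.0, 100.0])
        # left-hold sampling at grid points 0, 50, 100
        assert avg.size(60.0) == 1000.0
        assert avg.size(100.0) == 3000.0


class TestTrimModel:
    def test_noop_beyond_all_boundaries(self, three_epoch_pop):
        assert trim_model(three_epoch_pop, 1e9) is three_epoch_pop

    def test_trim_preserves_recent_sizes(self, three_epoch_pop):
        trimmed = trim_model(three_epoch_pop, 2_000.0)
        for t in (0, 499, 500, 1999):
            assert trimmed.size("pop0", t) == three_epoch_pop.size("pop0", t)
        # oldest retained epoch extends at its own size
        assert trimmed.size("pop0", 1e8) == 2_000.0
        assert math.isinf(trimmed.epochs[-1].t_end)

    def test_idempotent(self, three_epoch_pop):
        once = trim_model(three_epoch_pop, 2_000.0)
        twice = trim_model(once, 2_000.0)
        assert once.equivalent(twice)

    def test_years_units(self):
        d = PiecewiseDemography.single_population(
            [(0, 41_261 / 2), (5_000, 41_261), (9_020, 80_000)],
            generation_time=25.0,
        )
        trimmed = trim_model(d, 225.5e3, units="years")  # 225.5 KYA = 9020 gens
        assert trimmed.size("pop0", 1e7) == 41_261
        assert len(trimmed.epochs) == 2

    def test_invalid_t_max(self, three_epoch_pop):
        with pytest.raises(InvalidInputError):
            trim_model(three_epoch_pop, 0)


class TestSetAncestralSize:
    def test_identity_when_equal(self, three_epoch_pop):
        out = set_ancestral_size(three_epoch_pop, 8_000)
        assert out.equivalent(three_epoch_pop)

    def test_only_oldest_epoch_changes(self, three_epoch_pop):
        out = set_ancestral_size(three_epoch_pop, 12_300)
        assert out.size("pop0", 1e7) == 12_300
        assert out.size("pop0", 0) == three_epoch_pop.size("pop0", 0)
        assert out.size("pop0", 600) == three_epoch_pop.size("pop0", 600)

    def test_rejects_nonpositive(self, three_epoch_pop):
        with pytest.raises(InvalidInputError):
            set_ancestral_size(three_epoch_pop, -5)


class TestRescaleMutationRate:
    def test_identity(self, three_epoch_pop):
        out = rescale_mutation_rate(three_epoch_pop, three_epoch_pop.mutation_rate)
        assert out.equivalent(three_epoch_pop)

    def test_doubling_halves_everything(self, three_epoch_pop):
        out = rescale_mutation_rate(three_epoch_pop, 2.5e-8)
        for e_old, e_new in zip(three_epoch_pop.epochs, out.epochs):
            assert e_new.t_start == pytest.approx(e_old.t_start / 2)
            for pop in e_old.sizes:
                assert e_new.sizes[pop] == pytest.approx(e_old.sizes[pop] / 2)
                # per-epoch theta invariant
                assert 4 * e_new.sizes[pop] * out.mutation_rate == pytest.approx(
                    4 * e_old.sizes[pop] * three_epoch_pop.mutation_rate
                )

    def test_round_trip_identity(self, three_epoch_pop):
        there = rescale_mutation_rate(three_epoch_pop, 2.0e-8)
        back = rescale_mutation_rate(there, three_epoch_pop.mutation_rate)
        for e0, e1 in zip(three_epoch_pop.epochs, back.epochs):
            assert e1.t_start == pytest.approx(e0.t_start, rel=1e-12)
            assert e1.sizes["pop0"] == pytest.approx(e0.sizes["pop0"], rel=1e-12)

    def test_rejects_nonpositive(self, three_epoch_pop):
        with pytest.raises(InvalidInputError):
            rescale_mutation_rate(three_epoch_pop, 0.0)


class TestMsCommand:
    def test_constant_population_has_no_flags(self, const_pop):
        cmd = to_ms_command(const_pop, 10_000)
        assert cmd.strip() == ""

    def test_size_change_time_scaling(self):
        # a step at t = 2*N0 generations is at 0.5 in units of 4*N0
        n0 = 10_000
        d = PiecewiseDemography.single_population([(0, n0), (2 * n0, 5_000)])
        cmd = to_ms_command(d, n0)
        toks = cmd.split()
        assert toks[toks.index("-en") + 1] == "0.5"
        assert float(toks[toks.index("-en") + 3]) == pytest.approx(0.5)

    def test_two_epoch_round_trip(self, bottleneck_pop):
        cmd = to_ms_command(bottleneck_pop, 10_000)
        back = parse_ms_command(
            cmd, 10_000, mutation_rate=bottleneck_pop.mutation_rate
        )
        assert back.equivalent(bottleneck_pop)

    def test_multi_population_round_trip(self):
        from demoscope.demography import Split

        d = PiecewiseDemography(
            (
                Epoch(
                    0,
                    4_000,
                    {"pop0": 10_000, "pop1": 4_000},
                    migration={("pop0", "pop1"): 1e-4, ("pop1", "pop0"): 2.5e-5},
                ),
                Epoch(4_000, math.inf, {"pop0": 8_000}),
            ),
            splits=(Split(4_000, "pop1", "pop0"),),
        )
        cmd = to_ms_command(d, 10_000, samples_per_pop={"pop0": 10, "pop1": 10})
        back = parse_ms_command(cmd, 10_000)
        assert back.equivalent(d)

    def test_pulse_round_trip(self):
        from demoscope.models import archaic_pulse_model

        d = archaic_pulse_model()
        cmd = to_ms_command(d, 10_000, samples_per_pop={"modern": 10, "archaic": 2})
        assert "-es" in cmd
        back = parse_ms_command(cmd, 10_000, labels=["modern", "archaic"])
        assert back.equivalent(d)

    def test_exponential_unsupported(self):
        from demoscope.models import recent_growth

        with pytest.raises(UnsupportedFeatureError):
            to_ms_command(recent_growth(), 10_000)


@settings(max_examples=25, deadline=None)
@given(
    sizes=st.lists(st.floats(min_value=10, max_value=1e6), min_size=1, max_size=6),
    bounds=st.lists(
        st.floats(min_value=1, max_value=1e5), min_size=0, max_size=5, unique=True
    ),
)
def test_epoch_partition_is_total(sizes, bounds):
    bounds = sorted(bounds)[: len(sizes) - 1]
    sizes = sizes[: len(bounds) + 1]
    steps = [(0.0, sizes[0])] + [(t, n) for t, n in zip(bounds, sizes[1:])]
    d = PiecewiseDemography.single_population(steps)
    for t in [0.0, *(b * 0.999 for b in bounds), *(b for b in bounds), 1e9]:
        hits = sum(e.contains(t) for e in d.epochs)
        assert hits == 1
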