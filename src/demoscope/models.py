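"""Built-in demographic model families.

These cover the fixture families used by the pipeline (constant, two-epoch
bottleneck, growth, three-population-with-migration, archaic-pulse) plus the
published three-population out-of-Africa model of Gutenkunst et al. (2009,
PLoS Genet 5:e1000695, Table 1), encoded in physical units.
"""

from __future__ import annotations

import math

from .demography import Epoch, PiecewiseDemography, Pulse, Split
from .errors import InvalidInputError

__all__ = [
    "constant_size",
    "two_epoch_bottleneck",
    "recent_growth",
    "out_of_africa_gutenkunst",
    "three_population_migration",
    "archaic_pulse_model",
    "FIXTURE_FAMILIES",
    "make_family",
]


def constant_size(
    n: float = 10_000, *, mutation_rate: float = 1.25e-8, label: str = "pop0"
) -> PiecewiseDemography:
    """A single population of constant diploid size ``n``."""
    return PiecewiseDemography.single_population(
        [(0.0, n)], label=label, mutation_rate=mutation_rate, name="constant"
    )


def two_epoch_bottleneck(
    n_recent: float = 10_000,
    n_ancestral: float = 1_000,
    t_change: float = 1_000,
    *,
    mutation_rate: float = 1.25e-8,
    label: str = "pop0",
) -> PiecewiseDemography:
    """Recent size ``n_recent`` back to ``t_change`` generations, then
    ``n_ancestral`` (a bottleneck-release / expansion when recent > ancestral)."""
    return PiecewiseDemography.single_population(
        [(0.0, n_recent), (t_change, n_ancestral)],
        label=label,
        mutation_rate=mutation_rate,
        name="two_epoch",
    )


def recent_growth(
    n_current: float = 50_000,
    n_ancestral: float = 10_000,
    t_growth: float = 1_000,
    *,
    mutation_rate: float = 1.25e-8,
    label: str = "pop0",
) -> PiecewiseDemography:
    """Exponential growth from ``n_ancestral`` to ``n_current`` over the most
    recent ``t_growth`` generations."""
    epochs = (
        Epoch(
            0.0,
            t_growth,
            {label: n_current},
            end_sizes={label: n_ancestral},
        ),
        Epoch(t_growth, math.inf, {label: n_ancestral}),
    )
    return PiecewiseDemography(epochs, mutation_rate=mutation_rate, name="growth")


def out_of_africa_gutenkunst(
    *, mutation_rate: float = 2.35e-8, generation_time: float = 25.0
) -> PiecewiseDemography:
    """The Gutenkunst et al. (2009) three-population out-of-Africa model.

    Maximum-likelihood parameters from their Table 1, converted to physical
    units at 25 yr/generation: ancestral size 7300; African expansion to
    12300 at 220 kya; out-of-Africa bottleneck population of 2100 splitting
    at 140 kya with symmetric AF<->B migration 25e-5; European/Asian split
    21.2 kya with starting sizes 1000/510 growing at 0.4%/0.55% per
    generation, and migration AF<->EU 3e-5, AF<->AS 1.9e-5, EU<->AS 9.6e-5.
    """
    n_a = 7300.0
    n_af = 12300.0
    n_b = 2100.0
    n_eu0, r_eu = 1000.0, 0.004
    n_as0, r_as = 510.0, 0.0055
    t_af = 220e3 / generation_time
    t_b = 140e3 / generation_time
    t_eu_as = 21.2e3 / generation_time
    m_af_b = 25e-5
    m_af_eu = 3e-5
    m_af_as = 1.9e-5
    m_eu_as = 9.6e-5
    n_eu = n_eu0 * math.exp(r_eu * t_eu_as)
    n_as = n_as0 * math.exp(r_as * t_eu_as)

    recent_mig = {
        ("YRI", "CEU"): m_af_eu,
        ("CEU", "YRI"): m_af_eu,
        ("YRI", "CHB"): m_af_as,
        ("CHB", "YRI"): m_af_as,
        ("CEU", "CHB"): m_eu_as,
        ("CHB", "CEU"): m_eu_as,
    }
    epochs = (
        Epoch(
            0.0,
            t_eu_as,
            {"YRI": n_af, "CEU": n_eu, "CHB": n_as},
            end_sizes={"YRI": n_af, "CEU": n_eu0, "CHB": n_as0},
            migration=recent_mig,
        ),
        Epoch(
            t_eu_as,
            t_b,
            {"YRI": n_af, "B": n_b},
            migration={("YRI", "B"): m_af_b, ("B", "YRI"): m_af_b},
        ),
        Epoch(t_b, t_af, {"YRI": n_af}),
        Epoch(t_af, math.inf, {"YRI": n_a}),
    )
    splits = (
        Split(t_eu_as, "CEU", "B"),
        Split(t_eu_as, "CHB", "B"),
        Split(t_b, "B", "YRI"),
    )
    return PiecewiseDemography(
        epochs,
        splits=splits,
        mutation_rate=mutation_rate,
        generation_time=generation_time,
        name="gutenkunst_ooa",
    )


def three_population_migration(
    n_each: float = 10_000,
    t_split: float = 4_000,
    m: float = 1e-4,
    *,
    mutation_rate: float = 1.25e-8,
) -> PiecewiseDemography:
    """A symmetric three-population island-style toy: an ancestral population
    splits into A/B/C at ``t_split`` with symmetric migration ``m``."""
    pops = ("A", "B", "C")
    mig = {(a, b): m for a in pops for b in pops if a != b}
    epochs = (
        Epoch(0.0, t_split, {p: n_each for p in pops}, migration=mig),
        Epoch(t_split, math.inf, {"A": n_each}),
    )
    splits = (Split(t_split, "B", "A"), Split(t_split, "C", "A"))
    return PiecewiseDemography(
        epochs, splits=splits, mutation_rate=mutation_rate, name="three_pop_migration"
    )


def archaic_pulse_model(
    n_modern: float = 10_000,
    n_archaic: float = 2_000,
    t_divergence: float = 20_000,
    t_pulse: float = 1_500,
    fraction: float = 0.03,
    *,
    mutation_rate: float = 1.25e-8,
) -> PiecewiseDemography:
    """A modern population receiving a single archaic admixture pulse from a
    deeply diverged donor."""
    if not 0 < t_pulse < t_divergence:
        raise InvalidInputError("require 0 < t_pulse < t_divergence")
    epochs = (
        Epoch(0.0, t_divergence, {"modern": n_modern, "archaic": n_archaic}),
        Epoch(t_divergence, math.inf, {"modern": n_modern}),
    )
    return PiecewiseDemography(
        epochs,
        splits=(Split(t_divergence, "archaic", "modern"),),
        pulses=(Pulse(t_pulse, "archaic", "modern", fraction),),
        mutation_rate=mutation_rate,
        name="archaic_pulse",
    )


FIXTURE_FAMILIES = {
    "constant": constant_size,
    "two-epoch": two_epoch_bottleneck,
    "growth": recent_growth,
    "three-population-with-migration": three_population_migration,
    "archaic-pulse": archaic_pulse_model,
}


def make_family(family: str, **kwargs) -> PiecewiseDemography:
    """Instantiate a built-in fixture family by name."""
    try:
        builder = FIXTURE_FAMILIES[family]
    except KeyError:
        raise InvalidInputError(
            f"unknown model family {family!r}; choose from {sorted(FIXTURE_FAMILIES)}"
        ) from None
    return builder(**kwargs)
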