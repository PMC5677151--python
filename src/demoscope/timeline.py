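"""Compilation of demographies into piecewise-constant simulation timelines.

Both the analytic SFS engine and the coalescent simulators consume the same
compiled form: an ordered list of constant-size segments (exponential epochs
are subdivided geometrically) plus the discrete lineage-moving events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .demography import PiecewiseDemography, Pulse, Split
from .errors import InvalidInputError


@dataclass(frozen=True)
class Segment:
    """A time slice over which all coalescent rates are constant."""

    t0: float
    t1: float
    sizes: dict[str, float]
    migration: dict[tuple[str, str], float]


@dataclass(frozen=True)
class Timeline:
    segments: tuple[Segment, ...]
    splits: tuple[Split, ...]
    pulses: tuple[Pulse, ...]


def compile_timeline(demog: PiecewiseDemography, exp_substeps: int = 64) -> Timeline:
    """Flatten a demography into constant segments.

    Exponential epochs are cut into ``exp_substeps`` equal-width slices,
    each held at its midpoint size (the relative size step per slice is
    geometric, so refinement converges quickly).  Event times are inserted
    as segment boundaries so simulators only handle events between
    segments.
    """
    if exp_substeps < 1:
        raise InvalidInputError("exp_substeps must be >= 1")
    for e in demog.epochs:
        for pop, n in e.sizes.items():
            if not n > 0:
                raise InvalidInputError(f"zero-size epoch for population {pop!r}")
    event_times = sorted(
        {ev.time for ev in (*demog.splits, *demog.pulses)}
    )
    segments: list[Segment] = []
    for e in demog.epochs:
        cuts = [e.t_start]
        cuts += [t for t in event_times if e.t_start < t < e.t_end]
        cuts.append(e.t_end)
        for a, b in zip(cuts[:-1], cuts[1:]):
            if e.is_exponential:
                sub = _linspace(a, b, exp_substeps)
                for lo, hi in zip(sub[:-1], sub[1:]):
                    mid = 0.5 * (lo + hi)
                    segments.append(
                        Segment(
                            lo,
                            hi,
                            {p: e.size(p, mid) for p in e.sizes},
                            dict(e.migration),
                        )
                    )
            else:
                segments.append(Segment(a, b, dict(e.sizes), dict(e.migration)))
    return Timeline(tuple(segments), demog.splits, demog.pulses)


def _linspace(a: float, b: float, k: int) -> list[float]:
    if math.isinf(b):
        raise InvalidInputError("exponential epochs must be bounded")
    return [a + (b - a) * i / k for i in range(k + 1)]
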