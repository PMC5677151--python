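"""Piecewise demographic histories: representation, parsing, conversion, editing.

Time is measured in generations before present throughout; years appear only
at I/O boundaries, converted via each model's ``generation_time``.  Population
sizes count diploid individuals, so ``k`` lineages inside a population of size
``N`` coalesce at rate ``k*(k-1)/2 * 1/(2*N)`` per generation.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InvalidInputError, UnsupportedFeatureError

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "Split",
    "Pulse",
    "PiecewiseDemography",
    "SizeTrajectory",
    "parse_msmc_output",
    "emit_msmc_table",
    "trajectory_to_stepwise",
    "average_trajectories",
    "trim_model",
    "set_ancestral_size",
    "rescale_mutation_rate",
    "to_ms_command",
    "parse_ms_command",
]

_TOL = 1e-9


@dataclass(frozen=True)
class Epoch:
    """One contiguous time slice of a demography.

    ``sizes`` gives the diploid size of every population extant during the
    epoch, measured at ``t_start`` (the recent boundary).  If ``end_sizes``
    is given the size interpolates exponentially between the two endpoint
    values; otherwise it is constant.  ``migration[(a, b)]`` is the
    per-generation fraction of population ``a`` made up of migrants from
    ``b`` (equivalently, the backward-in-time hop rate of an ``a`` lineage
    into ``b``).
    """

    t_start: float
    t_end: float
    sizes: Mapping[str, float]
    end_sizes: Mapping[str, float] | None = None
    migration: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_start < 0:
            raise InvalidInputError(f"epoch t_start must be >= 0, got {self.t_start}")
        if not self.t_start < self.t_end:
            raise InvalidInputError(
                f"epoch requires t_start < t_end, got [{self.t_start}, {self.t_end}]"
            )
        if not self.sizes:
            raise InvalidInputError("epoch must list at least one population")
        for pop, n in self.sizes.items():
            if not n > 0:
                raise InvalidInputError(f"population {pop!r} size must be > 0, got {n}")
        if self.end_sizes is not None:
            if math.isinf(self.t_end):
                raise InvalidInputError("unbounded epoch cannot have end_sizes")
            if set(self.end_sizes) != set(self.sizes):
                raise InvalidInputError("end_sizes must cover the same populations as sizes")
            for pop, n in self.end_sizes.items():
                if not n > 0:
                    raise InvalidInputError(f"end size of {pop!r} must be > 0, got {n}")
        for (a, b), m in self.migration.items():
            if a == b:
                raise InvalidInputError("migration requires two distinct populations")
            if a not in self.sizes or b not in self.sizes:
                raise InvalidInputError(f"migration references unknown population ({a}, {b})")
            if not 0.0 <= m <= 1.0:
                raise InvalidInputError(f"migration fraction must lie in [0, 1], got {m}")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.sizes)

    @property
    def is_exponential(self) -> bool:
        return self.end_sizes is not None

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end

    def size(self, pop: str, t: float) -> float:
        """Diploid size of ``pop`` at time ``t`` (must lie inside the epoch)."""
        if pop not in self.sizes:
            raise InvalidInputError(f"population {pop!r} not extant in epoch")
        n0 = self.sizes[pop]
        if self.end_sizes is None:
            return n0
        n1 = self.end_sizes[pop]
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        return n0 * (n1 / n0) ** frac


@dataclass(frozen=True)
class Split:
    """Backward-in-time lineage move: at ``time``, ``derived`` merges into
    ``ancestral`` (a forward-time population split)."""

    time: float
    derived: str
    ancestral: str

    def __post_init__(self) -> None:
        if self.time <= 0 or math.isinf(self.time):
            raise InvalidInputError("split time must be positive and finite")
        if self.derived == self.ancestral:
            raise InvalidInputError("split requires distinct populations")


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture: forward in time, a fraction ``fraction`` of
    ``dest`` is replaced by migrants from ``source`` at ``time``."""

    time: float
    source: str
    dest: str
    fraction: float

    def __post_init__(self) -> None:
        if self.time <= 0 or math.isinf(self.time):
            raise InvalidInputError("pulse time must be positive and finite")
        if not 0.0 <= self.fraction <= 1.0:
            raise InvalidInputError(f"pulse fraction must lie in [0, 1], got {self.fraction}")
        if self.source == self.dest:
            raise InvalidInputError("pulse requires distinct populations")


@dataclass(frozen=True)
class PiecewiseDemography:
    """A multi-population piecewise demographic history.

    Epochs are ordered from the present backward and must tile ``[0, inf)``
    contiguously, with exactly one unbounded (oldest) epoch.  Splits and
    pulses are discrete events whose times fall on or inside epoch spans.
    """

    epochs: tuple[Epoch, ...]
    splits: tuple[Split, ...] = ()
    pulses: tuple[Pulse, ...] = ()
    mutation_rate: float = 1.25e-8
    generation_time: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise InvalidInputError("demography requires at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        object.__setattr__(self, "splits", tuple(sorted(self.splits, key=lambda s: s.time)))
        object.__setattr__(self, "pulses", tuple(sorted(self.pulses, key=lambda p: p.time)))
        if self.epochs[0].t_start != 0.0:
            raise InvalidInputError("first epoch must start at t=0")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not math.isclose(a.t_end, b.t_start, rel_tol=0, abs_tol=_TOL * max(1.0, a.t_end)):
                raise InvalidInputError(
                    f"epochs must be contiguous: gap between {a.t_end} and {b.t_start}"
                )
        n_unbounded = sum(math.isinf(e.t_end) for e in self.epochs)
        if n_unbounded != 1 or not math.isinf(self.epochs[-1].t_end):
            raise InvalidInputError("exactly one unbounded (oldest) epoch is required")
        if not self.mutation_rate > 0:
            raise InvalidInputError("mutation_rate must be > 0")
        if not self.generation_time > 0:
            raise InvalidInputError("generation_time must be > 0")
        for s in self.splits:
            before = self.epoch_at(s.time * (1 - 1e-12)) if s.time > 0 else self.epochs[0]
            after = self.epoch_at(s.time)
            if s.derived not in before.sizes:
                raise InvalidInputError(
                    f"split derived population {s.derived!r} not extant just before {s.time}"
                )
            if s.ancestral not in after.sizes:
                raise InvalidInputError(
                    f"split ancestral population {s.ancestral!r} not extant at {s.time}"
                )
        for p in self.pulses:
            epoch = self.epoch_at(p.time)
            for pop in (p.source, p.dest):
                if pop not in epoch.sizes:
                    raise InvalidInputError(
                        f"pulse population {pop!r} not extant at time {p.time}"
                    )

    # -- lookups ---------------------------------------------------------

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.epochs:
            for pop in e.sizes:
                seen.setdefault(pop)
        return tuple(seen)

    @property
    def sample_populations(self) -> tuple[str, ...]:
        """Populations extant at the present."""
        return self.epochs[0].populations

    @property
    def is_single_population(self) -> bool:
        return (
            len(self.populations) == 1
            and not self.splits
            and not self.pulses
        )

    def epoch_at(self, t: float) -> Epoch:
        """The unique epoch containing time ``t >= 0``."""
        if t < 0:
            raise InvalidInputError(f"time must be >= 0, got {t}")
        for e in self.epochs:
            if e.contains(t):
                return e
        return self.epochs[-1]  # t == inf guard; unreachable for finite t

    def size(self, pop: str, t: float) -> float:
        return self.epoch_at(t).size(pop, t)

    @property
    def ancestral_size(self) -> float:
        oldest = self.epochs[-1]
        if len(oldest.sizes) != 1:
            raise InvalidInputError("ancestral size is ambiguous: oldest epoch has >1 population")
        return next(iter(oldest.sizes.values()))

    # -- constructors ----------------------------------------------------

    @classmethod
    def single_population(
        cls,
        steps: Sequence[tuple[float, float]],
        *,
        label: str = "pop0",
        mutation_rate: float = 1.25e-8,
        generation_time: float = 1.0,
        name: str = "",
    ) -> "PiecewiseDemography":
        """Build a one-population stepwise history.

        ``steps`` is a sequence of ``(t_start, N)`` pairs ordered from the
        present backward; each step extends to the next start time and the
        final step extends to infinity.
        """
        if not steps:
            raise InvalidInputError("steps must be non-empty")
        starts = [s[0] for s in steps]
        if starts[0] != 0:
            raise InvalidInputError("first step must start at t=0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidInputError("step start times must be strictly increasing")
        epochs = []
        for i, (t0, n) in enumerate(steps):
            t1 = starts[i + 1] if i + 1 < len(steps) else math.inf
            epochs.append(Epoch(t0, t1, {label: n}))
        return cls(
            tuple(epochs),
            mutation_rate=mutation_rate,
            generation_time=generation_time,
            name=name,
        )

    # -- editing ---------------------------------------------------------

    def simplify(self) -> "PiecewiseDemography":
        """Merge adjacent constant epochs with identical sizes and migration."""
        merged: list[Epoch] = [self.epochs[0]]
        for e in self.epochs[1:]:
            prev = merged[-1]
            same = (
                not prev.is_exponential
                and not e.is_exponential
                and dict(prev.sizes) == dict(e.sizes)
                and dict(prev.migration) == dict(e.migration)
            )
            if same:
                merged[-1] = replace(prev, t_end=e.t_end)
            else:
                merged.append(e)
        return replace(self, epochs=tuple(merged))

    def equivalent(self, other: "PiecewiseDemography", rel_tol: float = 1e-9) -> bool:
        """Whether two demographies define the same size functions and events."""
        a, b = self.simplify(), other.simplify()
        if len(a.epochs) != len(b.epochs):
            return False
        for ea, eb in zip(a.epochs, b.epochs):
            if set(ea.sizes) != set(eb.sizes):
                return False
            if not math.isclose(ea.t_start, eb.t_start, rel_tol=rel_tol, abs_tol=1e-9):
                return False
            if ea.is_exponential != eb.is_exponential:
                return False
            for pop in ea.sizes:
                if not math.isclose(ea.sizes[pop], eb.sizes[pop], rel_tol=rel_tol):
                    return False
                if ea.is_exponential and not math.isclose(
                    ea.end_sizes[pop], eb.end_sizes[pop], rel_tol=rel_tol
                ):
                    return False
            keys = set(ea.migration) | set(eb.migration)
            for k in keys:
                if not math.isclose(
                    ea.migration.get(k, 0.0), eb.migration.get(k, 0.0), rel_tol=rel_tol, abs_tol=1e-15
                ):
                    return False
        if len(a.splits) != len(b.splits) or len(a.pulses) != len(b.pulses):
            return False
        for sa, sb in zip(a.splits, b.splits):
            if sa.derived != sb.derived or sa.ancestral != sb.ancestral:
                return False
            if not math.isclose(sa.time, sb.time, rel_tol=rel_tol):
                return False
        for pa, pb in zip(a.pulses, b.pulses):
            if (pa.source, pa.dest) != (pb.source, pb.dest):
                return False
            if not math.isclose(pa.time, pb.time, rel_tol=rel_tol):
                return False
            if not math.isclose(pa.fraction, pb.fraction, rel_tol=rel_tol, abs_tol=1e-15):
                return False
        return True

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        epochs = []
        for e in self.epochs:
            d = {
                "t_start": e.t_start,
                "t_end": None if math.isinf(e.t_end) else e.t_end,
                "sizes": dict(e.sizes),
            }
            if e.end_sizes is not None:
                d["end_sizes"] = dict(e.end_sizes)
            if e.migration:
                d["migration"] = [
                    {"from": a, "to": b, "rate": m} for (a, b), m in e.migration.items()
                ]
            epochs.append(d)
        return {
            "name": self.name,
            "mutation_rate": self.mutation_rate,
            "generation_time": self.generation_time,
            "epochs": epochs,
            "splits": [
                {"time": s.time, "derived": s.derived, "ancestral": s.ancestral}
                for s in self.splits
            ],
            "pulses": [
                {"time": p.time, "source": p.source, "dest": p.dest, "fraction": p.fraction}
                for p in self.pulses
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PiecewiseDemography":
        epochs = []
        for ed in d["epochs"]:
            t_end = ed.get("t_end")
            mig = {
                (m["from"], m["to"]): float(m["rate"]) for m in ed.get("migration", [])
            }
            epochs.append(
                Epoch(
                    float(ed["t_start"]),
                    math.inf if t_end is None else float(t_end),
                    {k: float(v) for k, v in ed["sizes"].items()},
                    end_sizes=(
                        {k: float(v) for k, v in ed["end_sizes"].items()}
                        if ed.get("end_sizes")
                        else None
                    ),
                    migration=mig,
                )
            )
        return cls(
            tuple(epochs),
            splits=tuple(
                Split(float(s["time"]), s["derived"], s["ancestral"])
                for s in d.get("splits", [])
            ),
            pulses=tuple(
                Pulse(float(p["time"]), p["source"], p["dest"], float(p["fraction"]))
                for p in d.get("pulses", [])
            ),
            mutation_rate=float(d.get("mutation_rate", 1.25e-8)),
            generation_time=float(d.get("generation_time", 1.0)),
            name=str(d.get("name", "")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PiecewiseDemography":
        logger.info("reading demography config from %s", path)
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class SizeTrajectory:
    """A raw single-population step function of diploid size over time.

    ``steps`` are contiguous ``(t_left, t_right, N)`` triples in generations,
    ordered from the present backward; the last step is unbounded.
    """

    steps: tuple[tuple[float, float, float], ...]
    provenance: str = "physical"

    def __post_init__(self) -> None:
        if not self.steps:
            raise InvalidInputError("trajectory requires at least one step")
        object.__setattr__(self, "steps", tuple(tuple(s) for s in self.steps))
        if self.steps[0][0] != 0:
            raise InvalidInputError("first step must start at t=0")
        for (l0, r0, n0), (l1, _r1, _n1) in zip(self.steps, self.steps[1:]):
            if not math.isclose(r0, l1, rel_tol=1e-12, abs_tol=1e-9):
                raise InvalidInputError("trajectory steps must be contiguous")
        for l, r, n in self.steps:
            if not n > 0:
                raise InvalidInputError(f"trajectory sizes must be > 0, got {n}")
            if not l < r:
                raise InvalidInputError("trajectory step bounds must satisfy t_left < t_right")
        if not math.isinf(self.steps[-1][1]):
            raise InvalidInputError("last trajectory step must be unbounded on the right")

    def size(self, t: float) -> float:
        """Left-hold step lookup of size at time ``t`` (generations)."""
        if t < 0:
            raise InvalidInputError("time must be >= 0")
        for l, r, n in self.steps:
            if l <= t < r:
                return n
        return self.steps[-1][2]

    @property
    def breakpoints(self) -> list[float]:
        return [s[0] for s in self.steps[1:]]

    def to_demography(
        self,
        *,
        label: str = "pop0",
        mutation_rate: float = 1.25e-8,
        generation_time: float = 1.0,
        name: str = "",
    ) -> PiecewiseDemography:
        return PiecewiseDemography.single_population(
            [(l, n) for l, _r, n in self.steps],
            label=label,
            mutation_rate=mutation_rate,
            generation_time=generation_time,
            name=name,
        )


# ---------------------------------------------------------------------------
# MSMC-style trajectory I/O
# ---------------------------------------------------------------------------

def parse_msmc_output(
    table: str | Path | pd.DataFrame | np.ndarray,
    mu: float,
    generation_time: float = 30.0,
) -> SizeTrajectory:
    """Convert MSMC-style scaled output into a physical-unit trajectory.

    The table carries columns ``time_index, left_time_boundary,
    right_time_boundary, lambda``; the standard scaling is
    ``t_generations = scaled_time / mu`` and ``N = 1 / (2 * mu * lambda)``.
    Years are available downstream as ``t * generation_time``.
    """
    if not mu > 0:
        raise InvalidInputError(f"mutation rate must be > 0, got {mu}")
    if not generation_time > 0:
        raise InvalidInputError("generation_time must be > 0")
    if isinstance(table, (str, Path)):
        logger.info("reading MSMC-style trajectory from %s", table)
        df = pd.read_csv(table, sep=r"\s+")
        if df.shape[1] != 4:
            raise FormatError(
                f"MSMC-style table must have 4 columns, found {df.shape[1]}"
            )
        arr = df.to_numpy(dtype=float)
    elif isinstance(table, pd.DataFrame):
        if table.shape[1] != 4:
            raise FormatError("MSMC-style table must have 4 columns")
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise FormatError("MSMC-style array must be 2-D with 4 columns")
    left, right, lam = arr[:, 1], arr[:, 2], arr[:, 3]
    if np.any(lam <= 0):
        raise InvalidInputError("lambda entries must be > 0")
    if np.any(np.diff(left) < 0) or np.any(right < left):
        raise FormatError("time boundaries must be nondecreasing")
    steps = []
    for i in range(len(arr)):
        t0 = left[i] / mu
        t1 = right[i] / mu if i < len(arr) - 1 else math.inf
        if i == len(arr) - 1 and not math.isinf(right[i] / mu):
            t1 = math.inf  # the oldest interval extends indefinitely
        n = 1.0 / (2.0 * mu * lam[i])
        steps.append((t0, t1, n))
    traj = SizeTrajectory(tuple(steps), provenance="physical")
    if traj.steps[-1][2] > 1e6:
        logger.warning(
            "parsed trajectory's oldest size %.3g exceeds 1e6 diploids; "
            "check the scaling mutation rate",
            traj.steps[-1][2],
        )
    return traj


def emit_msmc_table(trajectory: SizeTrajectory, mu: float) -> pd.DataFrame:
    """Inverse of :func:`parse_msmc_output`: emit a scaled 4-column table."""
    if not mu > 0:
        raise InvalidInputError("mutation rate must be > 0")
    rows = []
    for i, (l, r, n) in enumerate(trajectory.steps):
        right = r * mu if math.isfinite(r) else trajectory.steps[-1][0] * mu * 4 + 1.0
        rows.append((i, l * mu, right, 1.0 / (2.0 * mu * n)))
    return pd.DataFrame(
        rows, columns=["time_index", "left_time_boundary", "right_time_boundary", "lambda"]
    )


# ---------------------------------------------------------------------------
# Conversion and editing operations
# ---------------------------------------------------------------------------

def trajectory_to_stepwise(
    trajectory: SizeTrajectory | Callable[[float], float],
    n_steps: int,
    *,
    t_min: float = 10.0,
    t_max: float = 1e6,
    label: str = "pop0",
    mutation_rate: float = 1.25e-8,
    generation_time: float = 1.0,
) -> PiecewiseDemography:
    """Discretize a size history onto a geometric time grid.

    A :class:`SizeTrajectory` is already stepwise and passes through
    unchanged (``n_steps`` ignored).  A callable ``N(t)`` is sampled at the
    geometric midpoint of each of ``n_steps`` grid intervals between
    ``t_min`` and ``t_max``; before ``t_min`` the first value holds, after
    ``t_max`` the last.
    """
    if n_steps < 1:
        raise InvalidInputError(f"n_steps must be >= 1, got {n_steps}")
    if isinstance(trajectory, SizeTrajectory):
        return trajectory.to_demography(
            label=label, mutation_rate=mutation_rate, generation_time=generation_time
        )
    if not callable(trajectory):
        raise InvalidInputError("trajectory must be a SizeTrajectory or callable N(t)")
    if not (0 < t_min < t_max):
        raise InvalidInputError("require 0 < t_min < t_max")
    bounds = np.geomspace(t_min, t_max, n_steps + 1)
    # first interval [0, t_min): hold the value at t_min
    steps: list[tuple[float, float]] = [(0.0, float(trajectory(t_min)))]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = math.sqrt(lo * hi)
        steps.append((float(lo), float(trajectory(mid))))
    steps.append((float(t_max), float(trajectory(t_max))))
    # collapse equal adjacent values so stepwise inputs round-trip cleanly
    collapsed = [steps[0]]
    for t0, n in steps[1:]:
        if math.isclose(n, collapsed[-1][1], rel_tol=1e-12):
            continue
        collapsed.append((t0, n))
    return PiecewiseDemography.single_population(
        collapsed, label=label, mutation_rate=mutation_rate, generation_time=generation_time
    )


def average_trajectories(
    trajectories: Sequence[SizeTrajectory],
    grid: Sequence[float] | None = None,
    *,
    mode: str = "arithmetic",
) -> SizeTrajectory:
    """Pointwise mean of size trajectories, returned as a step function.

    By default the evaluation grid is the union of every input's
    breakpoints, which makes the mean exact for step inputs; pass an
    explicit (e.g. geometric) ``grid`` to control the output resolution.
    ``mode`` selects arithmetic (default) or log-scale averaging.
    """
    if not trajectories:
        raise InvalidInputError("at least one trajectory is required")
    if mode not in ("arithmetic", "log"):
        raise InvalidInputError(f"unknown averaging mode {mode!r}")
    if grid is None:
        pts: set[float] = {0.0}
        for tr in trajectories:
            pts.update(tr.breakpoints)
        grid_arr = np.array(sorted(pts), dtype=float)
    else:
        grid_arr = np.asarray(sorted(set([0.0, *map(float, grid)])), dtype=float)
        if np.any(grid_arr < 0):
            raise InvalidInputError("grid times must be >= 0")
    steps = []
    for i, t0 in enumerate(grid_arr):
        t1 = grid_arr[i + 1] if i + 1 < len(grid_arr) else math.inf
        vals = np.array([tr.size(t0) for tr in trajectories])
        n = float(np.exp(np.mean(np.log(vals)))) if mode == "log" else float(np.mean(vals))
        steps.append((float(t0), float(t1), n))
    # merge equal-value neighbours
    merged = [steps[0]]
    for t0, t1, n in steps[1:]:
        if math.isclose(n, merged[-1][2], rel_tol=1e-12):
            merged[-1] = (merged[-1][0], t1, merged[-1][2])
        else:
            merged.append((t0, t1, n))
    return SizeTrajectory(tuple(merged), provenance="averaged")


def geometric_grid(t_min: float, t_max: float, n_points: int = 64) -> np.ndarray:
    """A geometric time grid, the default resolution for trajectory work."""
    if not (0 < t_min < t_max) or n_points < 2:
        raise InvalidInputError("require 0 < t_min < t_max and n_points >= 2")
    return np.geomspace(t_min, t_max, n_points)


def trim_model(
    demog: PiecewiseDemography, t_max: float, *, units: str = "generations"
) -> PiecewiseDemography:
    """Remove events older than ``t_max`` from a single-population history.

    Epochs entirely older than ``t_max`` are dropped, a straddling epoch is
    truncated, and the oldest retained epoch is extended to infinity at its
    own size.  ``units`` may be ``"generations"`` or ``"years"`` (converted
    via the model's generation time).  A ``t_max`` beyond all finite
    boundaries returns the input unchanged.
    """
    if not t_max > 0:
        raise InvalidInputError("t_max must be > 0")
    if len(demog.populations) != 1:
        raise InvalidInputError("trim_model requires a single-population demography")
    if units == "years":
        t_max = t_max / demog.generation_time
    elif units != "generations":
        raise InvalidInputError(f"unknown units {units!r}")
    if demog.epochs[-1].t_start < t_max:
        return demog
    kept: list[Epoch] = []
    for e in demog.epochs:
        if e.t_start >= t_max:
            break
        kept.append(e)
    last = kept[-1]
    size_at_cut = {pop: last.size(pop, min(t_max, last.t_end) * (1 - 1e-15)) for pop in last.sizes}
    if last.is_exponential:
        # truncate the interpolation at the cut, then hold the cut value
        kept[-1] = replace(
            last,
            t_end=t_max,
            end_sizes={pop: last.size(pop, t_max) for pop in last.sizes},
        )
        kept.append(Epoch(t_max, math.inf, size_at_cut))
    else:
        kept[-1] = replace(last, t_end=math.inf)
    return replace(demog, epochs=tuple(kept))


def set_ancestral_size(demog: PiecewiseDemography, n_ancestral: float) -> PiecewiseDemography:
    """Replace the unbounded oldest epoch's size with ``n_ancestral``."""
    if not n_ancestral > 0:
        raise InvalidInputError(f"ancestral size must be > 0, got {n_ancestral}")
    oldest = demog.epochs[-1]
    new_oldest = replace(
        oldest, sizes={pop: n_ancestral for pop in oldest.sizes}
    )
    return replace(demog, epochs=(*demog.epochs[:-1], new_oldest))


def rescale_mutation_rate(demog: PiecewiseDemography, mu_new: float) -> PiecewiseDemography:
    """Rescale a model to an alternative mutation rate.

    All sizes and times are multiplied by ``mu_old / mu_new`` so that every
    epoch's per-site theta (and the expected proportional SFS) is invariant.
    """
    if not mu_new > 0:
        raise InvalidInputError(f"mutation rate must be > 0, got {mu_new}")
    c = demog.mutation_rate / mu_new
    epochs = []
    for e in demog.epochs:
        epochs.append(
            Epoch(
                e.t_start * c,
                e.t_end * c,
                {p: n * c for p, n in e.sizes.items()},
                end_sizes=(
                    {p: n * c for p, n in e.end_sizes.items()} if e.end_sizes else None
                ),
                migration={k: min(1.0, m / c) for k, m in e.migration.items()},
            )
        )
    return replace(
        demog,
        epochs=tuple(epochs),
        splits=tuple(replace(s, time=s.time * c) for s in demog.splits),
        pulses=tuple(replace(p, time=p.time * c) for p in demog.pulses),
        mutation_rate=mu_new,
    )


# ---------------------------------------------------------------------------
# ms-style command emission / parsing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.10g}"


def to_ms_command(
    demog: PiecewiseDemography,
    n0: float,
    samples_per_pop: Mapping[str, int] | None = None,
) -> str:
    """Emit the demographic flags of an ms command in 4*N0-scaled units.

    Times are in units of ``4*N0`` generations, sizes relative to ``N0``,
    and migration entries as ``4*N0*m``.  Only constant-size epochs,
    splits, and pulses are supported; exponential epochs raise
    :class:`UnsupportedFeatureError`.
    """
    if not n0 > 0:
        raise InvalidInputError("N0 must be > 0")
    if any(e.is_exponential for e in demog.epochs):
        raise UnsupportedFeatureError(
            "ms emission supports constant-size epochs only"
        )
    pops = list(demog.populations)
    idx = {p: i + 1 for i, p in enumerate(pops)}
    flags: list[str] = []
    scale_t = 1.0 / (4.0 * n0)

    if len(pops) > 1:
        counts = [
            str((samples_per_pop or {}).get(p, 0)) for p in pops
        ]
        flags += ["-I", str(len(pops)), *counts]

    first = demog.epochs[0]
    for p in first.populations:
        if not math.isclose(first.sizes[p], n0, rel_tol=1e-12):
            flags += ["-n", str(idx[p]), _fmt(first.sizes[p] / n0)]
    for (a, b), m in first.migration.items():
        flags += ["-em", _fmt(0.0), str(idx[a]), str(idx[b]), _fmt(4.0 * n0 * m)]

    events: list[tuple[float, int, list[str]]] = []
    for e_prev, e in zip(demog.epochs, demog.epochs[1:]):
        t = e.t_start * scale_t
        for p in e.populations:
            if p not in e_prev.sizes or not math.isclose(
                e.sizes[p], e_prev.sizes[p], rel_tol=1e-12
            ):
                events.append((t, 1, ["-en", _fmt(t), str(idx[p]), _fmt(e.sizes[p] / n0)]))
        keys = set(e.migration) | {
            k for k in e_prev.migration if k[0] in e.sizes and k[1] in e.sizes
        }
        for k in sorted(keys):
            m_new = e.migration.get(k, 0.0)
            m_old = e_prev.migration.get(k, 0.0)
            if not math.isclose(m_new, m_old, rel_tol=1e-12, abs_tol=1e-300):
                events.append(
                    (t, 1, ["-em", _fmt(t), str(idx[k[0]]), str(idx[k[1]]), _fmt(4.0 * n0 * m_new)])
                )
    for s in demog.splits:
        t = s.time * scale_t
        events.append((t, 2, ["-ej", _fmt(t), str(idx[s.derived]), str(idx[s.ancestral])]))
    for p in demog.pulses:
        # ms has no direct pulse flag: -es splits dest keeping each lineage
        # with prob (1-f), and the new deme (index npop+1 at that moment)
        # immediately joins the source.
        t = p.time * scale_t
        events.append(
            (t, 0, ["-es", _fmt(t), str(idx[p.dest]), _fmt(1.0 - p.fraction),
                    "-ej", _fmt(t), "NEW", str(idx[p.source])])
        )
    events.sort(key=lambda ev: (ev[0], ev[1]))
    n_pop = len(pops)
    for _t, _k, words in events:
        if "NEW" in words:
            n_pop += 1
            words[words.index("NEW")] = str(n_pop)
        flags += words
    return " ".join(flags)


def parse_ms_command(
    cmd: str,
    n0: float,
    labels: Sequence[str] | None = None,
    *,
    mutation_rate: float = 1.25e-8,
    generation_time: float = 1.0,
) -> PiecewiseDemography:
    """Parse ms-style demographic flags back into a demography.

    Supports the subset emitted by :func:`to_ms_command` (``-I -n -en -eN
    -em -ej -es``); other flags raise :class:`UnsupportedFeatureError`.
    """
    if not n0 > 0:
        raise InvalidInputError("N0 must be > 0")
    tokens = cmd.split()
    npop = 1
    sizes0: dict[int, float] = {}
    mig0: dict[tuple[int, int], float] = {}
    size_changes: list[tuple[float, int, float]] = []
    mig_changes: list[tuple[float, int, int, float]] = []
    joins: list[tuple[float, int, int]] = []
    es_events: list[tuple[float, int, float, int]] = []  # (t, dest, 1-f, new_index)
    t4 = 4.0 * n0
    i = 0
    pending_es: tuple[float, int, float] | None = None
    n_created = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok == "-I":
            npop = int(tokens[i + 1])
            i += 2 + npop
        elif tok == "-n":
            sizes0[int(tokens[i + 1])] = float(tokens[i + 2]) * n0
            i += 3
        elif tok == "-eN":
            t = float(tokens[i + 1]) * t4
            size_changes.append((t, 0, float(tokens[i + 2]) * n0))
            i += 3
        elif tok == "-en":
            t = float(tokens[i + 1]) * t4
            size_changes.append((t, int(tokens[i + 2]), float(tokens[i + 3]) * n0))
            i += 4
        elif tok == "-em":
            t = float(tokens[i + 1]) * t4
            mig_changes.append(
                (t, int(tokens[i + 2]), int(tokens[i + 3]), float(tokens[i + 4]) / t4)
            )
            i += 5
        elif tok == "-ej":
            t = float(tokens[i + 1]) * t4
            src, dst = int(tokens[i + 2]), int(tokens[i + 3])
            if pending_es is not None and src > npop + n_created - 1 and math.isclose(
                t, pending_es[0], rel_tol=1e-12
            ):
                es_events.append((pending_es[0], pending_es[1], pending_es[2], dst))
                pending_es = None
            else:
                joins.append((t, src, dst))
            i += 4
        elif tok == "-es":
            t = float(tokens[i + 1]) * t4
            n_created += 1
            pending_es = (t, int(tokens[i + 2]), float(tokens[i + 3]))
            i += 4
        else:
            raise UnsupportedFeatureError(f"unsupported ms flag {tok!r}")
    if pending_es is not None:
        raise FormatError("-es without a matching -ej for the created deme")

    if labels is None:
        labels = [f"pop{j}" for j in range(npop)] if npop > 1 else ["pop0"]
    if len(labels) != npop:
        raise InvalidInputError("labels length must match the number of populations")
    lab = {j + 1: labels[j] for j in range(npop)}

    times = sorted(
        {t for t, *_ in size_changes}
        | {t for t, *_ in mig_changes}
        | {t for t, *_ in joins}
        | {t for t, *_ in es_events}
    )
    cur_sizes = {lab[j]: sizes0.get(j, n0) for j in range(1, npop + 1)}
    cur_mig = {
        (lab[a], lab[b]): m for _t, a, b, m in mig_changes if _t == 0.0 and m > 0
    }
    for (a, b), m in list(mig0.items()):
        cur_mig[(lab[a], lab[b])] = m
    times = [t for t in times if t > 0]
    epochs = []
    splits: list[Split] = []
    pulses: list[Pulse] = []
    bounds = [0.0, *times, math.inf]
    alive = set(cur_sizes)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        epochs.append(
            Epoch(
                t0,
                t1,
                {p: n for p, n in cur_sizes.items() if p in alive},
                migration={
                    k: m for k, m in cur_mig.items()
                    if m > 0 and k[0] in alive and k[1] in alive
                },
            )
        )
        if math.isinf(t1):
            break
        for t, j, n in size_changes:
            if math.isclose(t, t1, rel_tol=1e-12) and t > 0:
                if j == 0:
                    for p in alive:
                        cur_sizes[p] = n
                else:
                    cur_sizes[lab[j]] = n
        for t, a, b, m in mig_changes:
            if math.isclose(t, t1, rel_tol=1e-12) and t > 0:
                cur_mig[(lab[a], lab[b])] = m
        for t, a, b in joins:
            if math.isclose(t, t1, rel_tol=1e-12):
                splits.append(Split(t, lab[a], lab[b]))
                alive.discard(lab[a])
        for t, dest, keep, src in es_events:
            if math.isclose(t, t1, rel_tol=1e-12):
                pulses.append(Pulse(t, lab[src], lab[dest], 1.0 - keep))
    return PiecewiseDemography(
        tuple(epochs),
        splits=tuple(splits),
        pulses=tuple(pulses),
        mutation_rate=mutation_rate,
        generation_time=generation_time,
    ).simplify()
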