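"""Monte-Carlo expected SFS via structured-coalescent genealogy simulation.

Genealogies are simulated backward in time under a compiled piecewise
timeline (splits, migration, pulses, constant and exponential epochs).  For
every focal population the simulator accumulates, per derived-allele count
class, the total branch length subtending that many of the population's
samples; the mean over replicates times the mutation rate is the expected
per-site SNP density.

Seeding contract: replicate ``i`` draws from ``default_rng((seed, i))`` so
results are independent of batching or execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .demography import PiecewiseDemography
from .errors import InvalidInputError
from .sfs import SFSSpectrum
from .timeline import Timeline, compile_timeline

logger = logging.getLogger(__name__)

__all__ = ["BranchLengthStats", "simulate_genealogies", "expected_sfs_montecarlo"]


@dataclass(frozen=True)
class BranchLengthStats:
    """Per-population mean subtending branch lengths by frequency class."""

    samples_per_pop: dict[str, int]
    mean: dict[str, np.ndarray]  # generations, classes 1..n_p-1
    se: dict[str, np.ndarray]
    n_reps: int


class _ExpBuffer:
    """Buffered draws so tight loops avoid per-call Generator overhead."""

    __slots__ = ("rng", "_exp", "_uni", "_ei", "_ui")

    def __init__(self, rng: np.random.Generator, size: int = 128):
        self.rng = rng
        self._exp = rng.standard_exponential(size)
        self._uni = rng.random(size)
        self._ei = 0
        self._ui = 0

    def exponential(self) -> float:
        if self._ei >= len(self._exp):
            self._exp = self.rng.standard_exponential(len(self._exp))
            self._ei = 0
        v = self._exp[self._ei]
        self._ei += 1
        return v

    def uniform(self) -> float:
        if self._ui >= len(self._uni):
            self._uni = self.rng.random(len(self._uni))
            self._ui = 0
        v = self._uni[self._ui]
        self._ui += 1
        return v


def _simulate_one(
    timeline: Timeline,
    pop_index: dict[str, int],
    n_samples: list[int],
    focal: list[int],
    buf: _ExpBuffer,
) -> list[np.ndarray]:
    """One genealogy; returns per-focal-pop subtending-length accumulators."""
    n_pops = len(pop_index)
    # lineage state: parallel lists
    pop_of: list[int] = []
    desc: list[list[int]] = []
    members: list[list[int]] = [[] for _ in range(n_pops)]
    for p in range(n_pops):
        for _ in range(n_samples[p]):
            lid = len(pop_of)
            pop_of.append(p)
            d = [0] * n_pops
            d[p] = 1
            desc.append(d)
            members[p].append(lid)
    total = len(pop_of)
    # cnt[f][c-1]: lineages whose descendant count in focal pop f equals c
    cnt = [np.zeros(max(n_samples[f] - 1, 0)) for f in focal]
    acc = [np.zeros(max(n_samples[f] - 1, 0)) for f in focal]
    for fi, f in enumerate(focal):
        if n_samples[f] >= 2:
            cnt[fi][0] = n_samples[f]
    t_flush = 0.0

    def flush(now: float) -> None:
        nonlocal t_flush
        dt = now - t_flush
        if dt > 0.0:
            for fi in range(len(focal)):
                acc[fi] += dt * cnt[fi]
        t_flush = now

    events: list[tuple[float, int, object]] = []
    for s in timeline.splits:
        events.append((s.time, 0, s))
    for p in timeline.pulses:
        events.append((p.time, 1, p))
    events.sort(key=lambda e: (e[0], e[1]))
    ev_i = 0

    for seg in timeline.segments:
        if total <= 1:
            break
        t = seg.t0
        inv2n = [0.0] * n_pops
        mig_tot = [0.0] * n_pops
        mig_to: list[list[tuple[int, float]]] = [[] for _ in range(n_pops)]
        for pop, sz in seg.sizes.items():
            inv2n[pop_index[pop]] = 1.0 / (2.0 * sz)
        for (a, b), m in seg.migration.items():
            if m > 0:
                ai, bi = pop_index[a], pop_index[b]
                mig_tot[ai] += m
                mig_to[ai].append((bi, m))
        while total > 1:
            rate = 0.0
            for p in range(n_pops):
                k = len(members[p])
                if k:
                    rate += k * (k - 1) * 0.5 * inv2n[p] + k * mig_tot[p]
            if rate <= 0.0:
                break
            dt = buf.exponential() / rate
            if t + dt >= seg.t1:
                break
            t += dt
            u = buf.uniform() * rate
            chosen_pop = -1
            is_mig = False
            for p in range(n_pops):
                k = len(members[p])
                if not k:
                    continue
                r_coal = k * (k - 1) * 0.5 * inv2n[p]
                if u < r_coal:
                    chosen_pop = p
                    break
                u -= r_coal
                r_mig = k * mig_tot[p]
                if u < r_mig:
                    chosen_pop = p
                    is_mig = True
                    break
                u -= r_mig
            if chosen_pop < 0:  # numerical edge: retry
                continue
            mem = members[chosen_pop]
            if is_mig:
                li = mem[int(buf.uniform() * len(mem))]
                w = buf.uniform() * mig_tot[chosen_pop]
                dest = mig_to[chosen_pop][-1][0]
                for q, m in mig_to[chosen_pop]:
                    if w < m:
                        dest = q
                        break
                    w -= m
                mem.remove(li)
                members[dest].append(li)
                pop_of[li] = dest
            else:
                flush(t)
                i1 = int(buf.uniform() * len(mem))
                i2 = int(buf.uniform() * (len(mem) - 1))
                if i2 >= i1:
                    i2 += 1
                a, b = mem[i1], mem[i2]
                da, db = desc[a], desc[b]
                for fi, f in enumerate(focal):
                    ns = n_samples[f]
                    ca, cb = da[f], db[f]
                    if 1 <= ca <= ns - 1:
                        cnt[fi][ca - 1] -= 1
                    if 1 <= cb <= ns - 1:
                        cnt[fi][cb - 1] -= 1
                    cm = ca + cb
                    if 1 <= cm <= ns - 1:
                        cnt[fi][cm - 1] += 1
                for p in range(n_pops):
                    da[p] += db[p]
                # keep lineage a, retire b
                mem.pop(i2)
                total -= 1
        # advance to segment end and apply boundary events
        if total <= 1:
            break
        t1 = seg.t1
        if math.isinf(t1):
            # no events possible but lineages remain isolated: done if no
            # class can accrue further mass
            if all(c.sum() == 0 for c in cnt):
                break
            raise InvalidInputError(
                "demography leaves uncoalesced lineages with unresolved "
                "frequency classes at infinite time"
            )
        while ev_i < len(events) and events[ev_i][0] <= t1 * (1 + 1e-12):
            _t, tag, ev = events[ev_i]
            ev_i += 1
            flush(_t)
            if tag == 0:  # split: derived lineages join ancestral
                src = pop_index[ev.derived]
                dst = pop_index[ev.ancestral]
                for li in members[src]:
                    pop_of[li] = dst
                    members[dst].append(li)
                members[src] = []
            else:  # pulse: dest lineages hop to source with prob fraction
                src = pop_index[ev.source]
                dst = pop_index[ev.dest]
                moved = []
                for li in members[dst]:
                    if buf.uniform() < ev.fraction:
                        moved.append(li)
                for li in moved:
                    members[dst].remove(li)
                    members[src].append(li)
                    pop_of[li] = src
    return acc


def simulate_genealogies(
    demog: PiecewiseDemography,
    samples_per_pop: Mapping[str, int],
    n_reps: int,
    seed: int,
    *,
    exp_substeps: int = 64,
) -> BranchLengthStats:
    """Simulate unlinked genealogies and accumulate subtending branch lengths.

    Deterministic given ``seed``.  Supports splits, migration, pulses, and
    constant/exponential epochs (the latter via fine sub-discretization of
    the timeline).
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    for pop in samples_per_pop:
        if pop not in demog.sample_populations:
            raise InvalidInputError(
                f"population {pop!r} is not extant at the present "
                f"(have {demog.sample_populations})"
            )
    if not samples_per_pop or all(v == 0 for v in samples_per_pop.values()):
        raise InvalidInputError("at least one sampled lineage is required")
    timeline = compile_timeline(demog, exp_substeps)
    pops = list(demog.populations)
    pop_index = {p: i for i, p in enumerate(pops)}
    n_samples = [int(samples_per_pop.get(p, 0)) for p in pops]
    if any(v < 0 for v in n_samples):
        raise InvalidInputError("sample sizes must be >= 0")
    focal = [pop_index[p] for p in samples_per_pop if samples_per_pop[p] >= 2]

    sums = [np.zeros(max(n_samples[f] - 1, 0)) for f in focal]
    sumsq = [np.zeros(max(n_samples[f] - 1, 0)) for f in focal]
    for rep in range(n_reps):
        rng = np.random.default_rng((seed, rep))
        buf = _ExpBuffer(rng)
        acc = _simulate_one(timeline, pop_index, n_samples, focal, buf)
        for fi in range(len(focal)):
            sums[fi] += acc[fi]
            sumsq[fi] += acc[fi] ** 2
    mean: dict[str, np.ndarray] = {}
    se: dict[str, np.ndarray] = {}
    for fi, f in enumerate(focal):
        pop = pops[f]
        mu_hat = sums[fi] / n_reps
        var = np.maximum(sumsq[fi] / n_reps - mu_hat**2, 0.0)
        mean[pop] = mu_hat
        se[pop] = np.sqrt(var / max(n_reps - 1, 1))
    return BranchLengthStats(
        samples_per_pop={pops[f]: n_samples[f] for f in focal},
        mean=mean,
        se=se,
        n_reps=n_reps,
    )


def expected_sfs_montecarlo(
    demog: PiecewiseDemography,
    samples_per_pop: Mapping[str, int],
    n_reps: int = 200_000,
    seed: int = 0,
    *,
    exp_substeps: int = 64,
) -> dict[str, SFSSpectrum]:
    """Per-population marginal expected SFS with per-bin standard errors.

    Returns per-site SNP density spectra (``kind='density'``): mean
    subtending branch length per class times the mutation rate.  Identical
    seeds give identical output.
    """
    stats = simulate_genealogies(
        demog, samples_per_pop, n_reps, seed, exp_substeps=exp_substeps
    )
    out: dict[str, SFSSpectrum] = {}
    for pop, m in stats.mean.items():
        out[pop] = SFSSpectrum(
            m * demog.mutation_rate,
            n=stats.samples_per_pop[pop],
            folded=False,
            kind="density",
            se=stats.se[pop] * demog.mutation_rate,
        )
    return out
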