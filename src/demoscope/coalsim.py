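"""Synthetic-data coalescent simulator.

Two backends share this module: unlinked genealogies (re-exported from
:mod:`demoscope.montecarlo`) feeding the Monte-Carlo SFS engine, and a
sequential SMC' simulator producing recombining sequence blocks for
heterozygosity and LD summaries.

The SMC' transition samples the left-end genealogy from the standard
coalescent, then walks along the sequence: the distance to the next
recombination breakpoint is exponential with rate ``r`` times the total tree
branch length, a detachment point is chosen uniformly on the tree, and the
detached lineage re-coalesces backward in time into the standing tree —
including, possibly, its own original lineage (which leaves the tree
unchanged; this is what distinguishes SMC' from SMC).  Mutations are laid
down as a Poisson process on branches under infinite sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .demography import PiecewiseDemography, Pulse
from .errors import InvalidInputError, UnsupportedFeatureError
from .montecarlo import simulate_genealogies  # noqa: F401  (re-export)
from .timeline import compile_timeline

logger = logging.getLogger(__name__)

__all__ = [
    "SimBlock",
    "RateSamplerConfig",
    "simulate_genealogies",
    "simulate_window",
    "simulate_blocks",
    "add_pulse_admixture",
    "write_vcf",
]


@dataclass(frozen=True)
class SimBlock:
    """An independent simulated sequence block.

    ``haplotypes`` is a (sites x 2*diploids) 0/1 incidence matrix over the
    segregating sites at the 1-based, strictly increasing ``positions``.
    """

    block_id: str
    length: int
    rate: float
    positions: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        hap = np.asarray(self.haplotypes, dtype=np.uint8)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "haplotypes", hap)
        if pos.ndim != 1 or hap.ndim != 2 or hap.shape[0] != pos.shape[0]:
            raise InvalidInputError("positions and haplotypes must align on sites")
        if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 1 or pos[-1] > self.length):
            raise InvalidInputError("positions must be strictly increasing within [1, length]")
        if len(hap):
            rowsum = hap.sum(axis=1)
            if np.any(rowsum == 0) or np.any(rowsum == hap.shape[1]):
                raise InvalidInputError("sites must be polymorphic (infinite sites)")

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[1])

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])


@dataclass(frozen=True)
class RateSamplerConfig:
    """Per-block recombination-rate sampler.

    The default lognormal (median 1.1e-8 /bp/generation, log-SD 0.7) is a
    configurable stand-in for an empirical pedigree-map rate distribution,
    not a reproduction of one.
    """

    family: str = "lognormal"
    median: float = 1.1e-8
    log_sd: float = 0.7
    fixed_rate: float = 1.1e-8
    truncate_low: float = 0.0
    truncate_high: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "fixed"):
            raise InvalidInputError(f"unknown rate family {self.family!r}")
        if self.family == "lognormal" and not self.median > 0:
            raise InvalidInputError("lognormal median must be > 0")
        if self.truncate_low < 0 or self.truncate_high <= self.truncate_low:
            raise InvalidInputError("invalid truncation bounds")
        if self.family == "fixed" and not (
            math.isfinite(self.fixed_rate) and self.fixed_rate >= 0
        ):
            raise InvalidInputError("fixed rate must be finite and >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return float(self.fixed_rate)
        for _ in range(1000):
            r = float(self.median * math.exp(self.log_sd * rng.standard_normal()))
            if self.truncate_low <= r <= self.truncate_high and math.isfinite(r):
                return r
        raise InvalidInputError("rate sampler truncation bounds reject all draws")


# ---------------------------------------------------------------------------
# marginal tree machinery
# ---------------------------------------------------------------------------

class _Tree:
    """A mutable rooted genealogy over ``n`` leaves (node-array layout)."""

    __slots__ = ("n", "time", "parent", "children", "root", "_leafsets")

    def __init__(self, n: int):
        self.n = n
        m = 2 * n - 1
        self.time = np.zeros(m)
        self.parent = np.full(m, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in range(m)]
        self.root = -1
        self._leafsets: dict[int, np.ndarray] | None = None

    def invalidate(self) -> None:
        self._leafsets = None

    def parent_time(self, v: int) -> float:
        p = self.parent[v]
        return math.inf if p < 0 else float(self.time[p])

    def total_length(self) -> float:
        tot = 0.0
        for v in range(2 * self.n - 1):
            p = self.parent[v]
            if p >= 0:
                tot += self.time[p] - self.time[v]
        return tot

    def edges(self) -> list[int]:
        return [v for v in range(2 * self.n - 1) if self.parent[v] >= 0]

    def alive_at(self, t: float) -> list[int]:
        """Lineages spanning time ``t`` (the root lineage extends to inf)."""
        out = []
        for v in range(2 * self.n - 1):
            if self.time[v] <= t < self.parent_time(v):
                out.append(v)
        return out

    def leafset(self, v: int) -> np.ndarray:
        if self._leafsets is None:
            self._leafsets = {}
        cached = self._leafsets.get(v)
        if cached is not None:
            return cached
        if v < self.n:
            s = np.zeros(self.n, dtype=bool)
            s[v] = True
        else:
            s = np.zeros(self.n, dtype=bool)
            for c in self.children[v]:
                s |= self.leafset(c)
        self._leafsets[v] = s
        return s

    def check(self) -> None:
        """Internal-consistency assertions (used by tests)."""
        seen = 0
        for v in range(2 * self.n - 1):
            p = self.parent[v]
            if p >= 0:
                assert self.time[p] > self.time[v]
                assert v in self.children[p]
            else:
                seen += 1
        assert seen == 1
        assert self.leafset(self.root).all()


def _sample_marginal_tree(segments, n: int, rng: np.random.Generator) -> _Tree:
    """Left-end genealogy from the (non-sequential) coalescent."""
    tree = _Tree(n)
    active = list(range(n))
    next_node = n
    t = 0.0
    seg_i = 0
    while len(active) > 1:
        seg = segments[seg_i]
        n_dip = next(iter(seg.sizes.values()))
        k = len(active)
        rate = k * (k - 1) / 2.0 / (2.0 * n_dip)
        wait = rng.standard_exponential() / rate
        if t + wait >= seg.t1:
            t = seg.t1
            seg_i += 1
            continue
        t += wait
        i = int(rng.random() * k)
        j = int(rng.random() * (k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        q = next_node
        next_node += 1
        tree.time[q] = t
        tree.children[q] = [a, b]
        tree.parent[a] = q
        tree.parent[b] = q
        active = [v for v in active if v not in (a, b)]
        active.append(q)
    tree.root = active[0]
    return tree


def _size_at(segments, t: float) -> float:
    for seg in segments:
        if seg.t0 <= t < seg.t1:
            return next(iter(seg.sizes.values()))
    return next(iter(segments[-1].sizes.values()))


def _sample_recoalescence(
    tree: _Tree, segments, t_start: float, rng: np.random.Generator
) -> tuple[float, int]:
    """Time and target lineage at which a detached lineage re-coalesces."""
    cuts = sorted(
        {float(tt) for tt in tree.time[tree.n:] if tt > t_start}
        | {seg.t1 for seg in segments if t_start < seg.t1 < math.inf}
    )
    cuts.append(math.inf)
    e_draw = rng.standard_exponential()
    t = t_start
    for b in cuts:
        k = len(tree.alive_at(t))
        n_dip = _size_at(segments, t)
        rate = k / (2.0 * n_dip)
        if math.isinf(b):
            t_star = t + e_draw / rate
            break
        cap = (b - t) * rate
        if e_draw <= cap:
            t_star = t + e_draw / rate
            break
        e_draw -= cap
        t = b
    alive = tree.alive_at(t_star)
    target = alive[int(rng.random() * len(alive))]
    return t_star, target


def _apply_recoalescence(tree: _Tree, e: int, t_star: float, target: int) -> None:
    """Rebuild the tree after lineage ``e`` re-coalesces onto ``target``."""
    p = int(tree.parent[e])
    sib = [c for c in tree.children[p] if c != e][0]
    g = int(tree.parent[p])
    # splice out p: sibling inherits p's edge
    tree.children[p] = []
    tree.parent[sib] = g
    if g >= 0:
        tree.children[g] = [sib if c == p else c for c in tree.children[g]]
    else:
        tree.root = sib
    if target == p:  # the old edge above p now belongs to the sibling
        target = sib
    # insert new node (reuse p's slot) on target's edge at t_star
    r = int(tree.parent[target])
    tree.time[p] = t_star
    tree.children[p] = [e, target]
    tree.parent[e] = p
    tree.parent[target] = p
    tree.parent[p] = r
    if r >= 0:
        tree.children[r] = [p if c == target else c for c in tree.children[r]]
    else:
        tree.root = p
    tree.invalidate()


def simulate_window(
    demog: PiecewiseDemography,
    n_haplotypes: int,
    length: int,
    r: float,
    mu: float | None = None,
    seed: int = 0,
    *,
    block_id: str = "block_0",
    exp_substeps: int = 64,
) -> SimBlock:
    """Simulate one recombining sequence window under the SMC' transition.

    Single-population histories only (constant or exponential epochs); the
    genealogy at any single position is marginally distributed as the
    standard coalescent.  ``r`` and ``mu`` are per-bp per-generation rates
    (``mu`` defaults to the demography's mutation rate).  Deterministic
    given ``seed``.
    """
    if n_haplotypes < 2:
        raise InvalidInputError(f"n_haplotypes must be >= 2, got {n_haplotypes}")
    if length < 1:
        raise InvalidInputError("length must be >= 1")
    if r < 0 or (mu is not None and mu < 0):
        raise InvalidInputError("rates must be >= 0")
    if not demog.is_single_population:
        raise UnsupportedFeatureError(
            "the SMC' window simulator supports single-population histories; "
            "use simulate_genealogies for structured models"
        )
    mu = demog.mutation_rate if mu is None else mu
    segments = compile_timeline(demog, exp_substeps).segments
    rng = np.random.default_rng((seed, _stable_hash(block_id)))
    tree = _sample_marginal_tree(segments, n_haplotypes, rng)

    raw_sites: list[tuple[float, np.ndarray]] = []  # (continuous position, incidence)

    def drop_mutations(x0: float, x1: float) -> None:
        span = x1 - x0
        if span <= 0 or mu == 0:
            return
        lam = mu * span * tree.total_length()
        n_mut = rng.poisson(lam)
        if n_mut == 0:
            return
        edges = tree.edges()
        lens = np.array([tree.parent_time(v) - tree.time[v] for v in edges])
        probs = lens / lens.sum()
        choices = rng.choice(len(edges), size=n_mut, p=probs)
        xs = x0 + span * rng.random(n_mut)
        for x, ci in zip(xs, choices):
            raw_sites.append((float(x), tree.leafset(edges[ci]).copy()))

    x = 0.0
    while x < length:
        lam_tree = tree.total_length()
        if r > 0 and lam_tree > 0:
            gap = rng.standard_exponential() / (r * lam_tree)
        else:
            gap = math.inf
        x_next = min(x + gap, float(length))
        drop_mutations(x, x_next)
        if x_next >= length:
            break
        x = x_next
        # choose detachment point uniformly on the tree
        edges = tree.edges()
        lens = np.array([tree.parent_time(v) - tree.time[v] for v in edges])
        ci = int(rng.choice(len(edges), p=lens / lens.sum()))
        e = edges[ci]
        t_d = tree.time[e] + lens[ci] * rng.random()
        t_star, target = _sample_recoalescence(tree, segments, t_d, rng)
        if target != e:
            _apply_recoalescence(tree, e, t_star, target)

    raw_sites.sort(key=lambda s: s[0])
    positions: list[int] = []
    haps: list[np.ndarray] = []
    used: set[int] = set()
    for xf, inc in raw_sites:
        pos = min(int(xf) + 1, length)
        while pos in used and pos < length:
            pos += 1
        if pos in used:  # saturated at the right edge; walk left
            pos = min(int(xf) + 1, length)
            while pos in used and pos > 1:
                pos -= 1
            if pos in used:
                continue  # more mutations than base pairs: drop (infinite sites)
        used.add(pos)
        positions.append(pos)
        haps.append(inc.astype(np.uint8))
    order = np.argsort(positions)
    pos_arr = np.array(positions, dtype=np.int64)[order] if positions else np.empty(0, dtype=np.int64)
    hap_arr = (
        np.array(haps, dtype=np.uint8)[order]
        if haps
        else np.empty((0, n_haplotypes), dtype=np.uint8)
    )
    return SimBlock(block_id=block_id, length=length, rate=r, positions=pos_arr, haplotypes=hap_arr)


def _stable_hash(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (1 << 32)
    return h


def simulate_blocks(
    demog: PiecewiseDemography,
    n_diploids: int,
    n_blocks: int,
    length: int,
    rate_sampler: RateSamplerConfig,
    mu: float | None = None,
    seed: int = 0,
) -> list[SimBlock]:
    """Simulate independent recombining blocks for ``n_diploids`` samples.

    Each block draws its own recombination rate from ``rate_sampler`` and
    its own RNG stream keyed by ``(seed, block index)``, so results do not
    depend on execution order.
    """
    if n_blocks < 1:
        raise InvalidInputError("n_blocks must be >= 1")
    if n_diploids < 1:
        raise InvalidInputError("n_diploids must be >= 1")
    blocks = []
    for i in range(n_blocks):
        rate_rng = np.random.default_rng((seed, i, 1))
        r = rate_sampler.sample(rate_rng)
        if r < 0:
            raise InvalidInputError("rate sampler produced a negative rate")
        blocks.append(
            simulate_window(
                demog,
                2 * n_diploids,
                length,
                r,
                mu,
                seed=seed,
                block_id=f"block_{i}",
            )
        )
    return blocks


def add_pulse_admixture(
    demog: PiecewiseDemography,
    t: float,
    source_pop: str,
    dest_pop: str,
    fraction: float,
) -> PiecewiseDemography:
    """Return a copy of ``demog`` with one pulse admixture event appended."""
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError(f"pulse fraction must lie in [0, 1], got {fraction}")
    if fraction == 0.0:
        return demog
    pulse = Pulse(t, source_pop, dest_pop, fraction)
    from dataclasses import replace

    return replace(demog, pulses=(*demog.pulses, pulse))


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(
    blocks: Sequence[SimBlock],
    path: str | Path,
    *,
    sample_prefix: str = "ind",
) -> None:
    """Write blocks as a minimal VCF 4.2 with phased GT, one contig each.

    Haplotypes are paired consecutively into diploid individuals
    (haplotypes ``2j`` and ``2j+1`` form sample ``j``); reading the file
    back reproduces the dosage matrix exactly.
    """
    blocks = list(blocks)
    if not blocks:
        raise InvalidInputError("no blocks to write")
    n_hap = blocks[0].n_haplotypes
    if n_hap % 2 != 0:
        raise InvalidInputError("VCF output requires an even haplotype count")
    if any(b.n_haplotypes != n_hap for b in blocks):
        raise InvalidInputError("all blocks must share a haplotype count")
    n_ind = n_hap // 2
    samples = [f"{sample_prefix}{j}" for j in range(n_ind)]
    lines = ["##fileformat=VCFv4.2", "##source=demoscope.coalsim"]
    for b in blocks:
        lines.append(f"##contig=<ID={b.block_id},length={b.length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for b in blocks:
        if len(b.positions) and np.any(np.diff(b.positions) <= 0):
            raise InvalidInputError(f"unsorted positions in block {b.block_id}")
        for s in range(b.n_sites):
            gts = "\t".join(
                f"{b.haplotypes[s, 2 * j]}|{b.haplotypes[s, 2 * j + 1]}"
                for j in range(n_ind)
            )
            lines.append(
                f"{b.block_id}\t{b.positions[s]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
    logger.info("wrote VCF with %d contigs to %s", len(blocks), path)
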