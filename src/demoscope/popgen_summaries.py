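"""Windowed heterozygosity, LD decay, and empirical SFS from genotype data.

Input is either simulated blocks or VCF(+BED callability mask).  All three
summaries run on a :class:`GenotypeMatrix` of diploid dosages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coalsim import SimBlock
from .errors import InsufficientDataError, InvalidInputError
from .sfs import SFSSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "WindowStat",
    "LDBins",
    "window_pi",
    "pi_summary",
    "ld_decay",
    "empirical_sfs",
    "read_vcf",
    "read_bed_mask",
    "genotypes_from_blocks",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Biallelic dosages (0/1/2) per site x diploid individual.

    ``positions`` are 1-based bp, strictly increasing within each contig;
    ``contigs`` labels each site's contig and ``contig_lengths`` gives the
    physical span available per contig.
    """

    dosages: np.ndarray
    positions: np.ndarray
    contigs: np.ndarray
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=np.int8)
        pos = np.asarray(self.positions, dtype=np.int64)
        ctg = np.asarray(self.contigs)
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "contigs", ctg)
        if d.ndim != 2 or len(pos) != d.shape[0] or len(ctg) != d.shape[0]:
            raise InvalidInputError("dosages, positions, contigs must align on sites")
        if d.size and (d.min() < 0 or d.max() > 2):
            raise InvalidInputError("dosages must lie in {0, 1, 2}")
        for c in dict.fromkeys(ctg.tolist()):
            p = pos[ctg == c]
            if np.any(np.diff(p) <= 0):
                raise InvalidInputError(f"positions not strictly increasing on contig {c}")

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[1])

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals

    @property
    def n_sites(self) -> int:
        return int(self.dosages.shape[0])

    def contig_names(self) -> list[str]:
        return list(self.contig_lengths)


@dataclass(frozen=True)
class WindowStat:
    """Per-window nucleotide diversity (1-based inclusive bounds)."""

    contig: str
    start: int
    end: int
    callable_length: int
    pi: float


@dataclass(frozen=True)
class LDBins:
    """Mean genotype r^2 in fixed-width distance bins."""

    bin_width: int
    means: np.ndarray  # NaN where a bin has no pairs
    pair_counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.means)

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "midpoint_bp": self.midpoints,
                "mean_r2": self.means,
                "n_pairs": self.pair_counts,
            }
        )


def genotypes_from_blocks(blocks: Sequence[SimBlock]) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploid dosages, one contig per block."""
    blocks = list(blocks)
    if not blocks:
        raise InvalidInputError("no blocks given")
    n_hap = blocks[0].n_haplotypes
    if n_hap % 2:
        raise InvalidInputError("odd haplotype count cannot form diploids")
    dos, pos, ctg = [], [], []
    lengths: dict[str, int] = {}
    for b in blocks:
        lengths[b.block_id] = int(b.length)
        if b.n_sites == 0:
            continue
        h = b.haplotypes.astype(np.int8)
        dos.append(h[:, 0::2] + h[:, 1::2])
        pos.append(b.positions)
        ctg.extend([b.block_id] * b.n_sites)
    if dos:
        d = np.vstack(dos)
        p = np.concatenate(pos)
    else:
        d = np.empty((0, n_hap // 2), dtype=np.int8)
        p = np.empty(0, dtype=np.int64)
    return GenotypeMatrix(d, p, np.array(ctg, dtype=object), lengths)


# ---------------------------------------------------------------------------
# windowed heterozygosity
# ---------------------------------------------------------------------------

def _window_callable(
    start: int, end: int, mask: "np.ndarray | None"
) -> int:
    """Callable bp of a 1-based inclusive window given a mask interval array."""
    if mask is None:
        return end - start + 1
    if len(mask) == 0:
        return 0
    lo = np.maximum(mask[:, 0], start)
    hi = np.minimum(mask[:, 1], end)
    return int(np.maximum(hi - lo + 1, 0).sum())


def window_pi(
    genotypes: GenotypeMatrix,
    window_size: int,
    mask: "dict[str, np.ndarray] | None" = None,
    *,
    min_callable_fraction: float = 0.0,
) -> list[WindowStat]:
    """Expected heterozygosity per site in non-overlapping windows.

    ``pi = n/(n-1) * sum_i 2 p_i (1 - p_i) / L`` over the sites in each
    window, where ``n`` is the number of sampled chromosomes and ``L`` the
    callable length (window size when no mask is given, truncated at the
    contig end).  Windows with zero callable length are excluded (counted
    in a log message, not an error); ``min_callable_fraction`` optionally
    drops low-coverage windows.
    """
    if window_size < 1:
        raise InvalidInputError("window_size must be >= 1")
    n = genotypes.n_chromosomes
    if n < 2:
        raise InvalidInputError("need at least one diploid individual")
    corr = n / (n - 1.0)
    out: list[WindowStat] = []
    n_dropped = 0
    for contig, clen in genotypes.contig_lengths.items():
        sel = genotypes.contigs == contig
        pos = genotypes.positions[sel]
        dos = genotypes.dosages[sel]
        cmask = None if mask is None else mask.get(contig, np.empty((0, 2), dtype=np.int64))
        for w0 in range(1, clen + 1, window_size):
            w1 = min(w0 + window_size - 1, clen)
            L = _window_callable(w0, w1, cmask)
            if L <= 0 or L < min_callable_fraction * (w1 - w0 + 1):
                n_dropped += 1
                continue
            in_w = (pos >= w0) & (pos <= w1)
            if in_w.any():
                p = dos[in_w].sum(axis=1) / n
                het = float(np.sum(2.0 * p * (1.0 - p)))
            else:
                het = 0.0
            out.append(WindowStat(contig, w0, w1, L, corr * het / L))
    if n_dropped:
        logger.info("window_pi: excluded %d windows with no callable sites", n_dropped)
    return out


def pi_summary(stats: Sequence[WindowStat]) -> dict:
    """Mean, sample SD, and mean +/- 2 SD of per-window pi."""
    if len(stats) < 2:
        raise InsufficientDataError("pi_summary requires at least 2 windows")
    vals = np.array([s.pi for s in stats])
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return {
        "mean": mean,
        "sd": sd,
        "low2sd": mean - 2 * sd,
        "high2sd": mean + 2 * sd,
        "n_windows": len(vals),
        "values": vals,
    }


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    genotypes: GenotypeMatrix,
    max_dist: int = 51_000,
    bin_width: int = 1_000,
) -> LDBins:
    """Mean genotype r^2 by pairwise distance.

    Filters first: singleton sites (minor allele count 1 among 2n alleles)
    and invariant sites are removed.  Every remaining within-contig pair at
    distance < ``max_dist`` contributes its squared Pearson correlation of
    dosage vectors to the half-open bin ``[k*bin_width, (k+1)*bin_width)``;
    pairs where either site has zero dosage variance are skipped.
    """
    if max_dist < bin_width or bin_width < 1:
        raise InvalidInputError("require bin_width >= 1 and max_dist >= bin_width")
    n_bins = max_dist // bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    two_n = genotypes.n_chromosomes
    for contig in genotypes.contig_lengths:
        sel = genotypes.contigs == contig
        pos = genotypes.positions[sel]
        dos = genotypes.dosages[sel].astype(float)
        if len(pos) < 2:
            continue
        ac = dos.sum(axis=1)
        mac = np.minimum(ac, two_n - ac)
        keep = (mac >= 2) & (np.var(dos, axis=1) > 0)
        pos = pos[keep]
        dos = dos[keep]
        if len(pos) < 2:
            continue
        c = np.corrcoef(dos)
        r2 = c * c
        d = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(pos), k=1)
        dist = d[iu]
        vals = r2[iu]
        ok = (dist < max_dist) & np.isfinite(vals)
        idx = dist[ok] // bin_width
        np.add.at(sums, idx, vals[ok])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDBins(bin_width=bin_width, means=means, pair_counts=counts)


# ---------------------------------------------------------------------------
# empirical SFS
# ---------------------------------------------------------------------------

def empirical_sfs(genotypes: GenotypeMatrix, folded: bool = False) -> SFSSpectrum:
    """Tabulate the SFS of a genotype matrix.

    Unfolded uses the dosage-coded allele as derived; folded uses minor
    allele counts.  Monomorphic sites are ignored.
    """
    n = genotypes.n_chromosomes
    ac = genotypes.dosages.sum(axis=1).astype(np.int64)
    ac = ac[(ac > 0) & (ac < n)]
    if folded:
        mac = np.minimum(ac, n - ac)
        vals = np.bincount(mac, minlength=n // 2 + 1)[1 : n // 2 + 1]
        return SFSSpectrum(vals.astype(float), n=n, folded=True, kind="counts")
    vals = np.bincount(ac, minlength=n)[1:n]
    return SFSSpectrum(vals.astype(float), n=n, folded=False, kind="counts")


# ---------------------------------------------------------------------------
# VCF / BED input
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic sites from a VCF into a dosage matrix (via cyvcf2)."""
    from cyvcf2 import VCF  # deferred: optional heavyweight dependency

    logger.info("reading VCF from %s", path)
    vcf = VCF(str(path))
    lengths: dict[str, int] = {}
    for ctg, ln in zip(vcf.seqnames, vcf.seqlens or []):
        lengths[ctg] = int(ln)
    dos, pos, ctg_l = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        g = np.asarray(var.genotype.array())[:, :2]
        dos.append((g > 0).sum(axis=1).astype(np.int8))
        pos.append(var.POS)
        ctg_l.append(var.CHROM)
    vcf.close()
    for c in ctg_l:
        lengths.setdefault(c, int(max(p for p, cc in zip(pos, ctg_l) if cc == c)))
    d = np.array(dos, dtype=np.int8) if dos else np.empty((0, 0), dtype=np.int8)
    return GenotypeMatrix(
        d,
        np.array(pos, dtype=np.int64),
        np.array(ctg_l, dtype=object),
        lengths,
    )


def read_bed_mask(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED callability mask into per-contig 1-based inclusive intervals.

    BED is 0-based half-open on disk; intervals are converted on read.
    """
    logger.info("reading BED mask from %s", path)
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["contig", "start", "end"],
        comment="#",
    )
    out: dict[str, np.ndarray] = {}
    for contig, grp in df.groupby("contig", sort=False):
        iv = np.stack([grp["start"].to_numpy() + 1, grp["end"].to_numpy()], axis=1)
        out[str(contig)] = iv[np.argsort(iv[:, 0])]
    return out
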