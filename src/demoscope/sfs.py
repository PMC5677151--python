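"""Site frequency spectra and their transforms.

An unfolded spectrum indexes derived-allele counts ``1..n-1``; a folded one
indexes minor-allele counts ``1..n//2``.  Fixed classes are excluded
everywhere.  ``kind`` distinguishes SNP counts, proportions, and per-site
expectations (expected SNP density per bp, i.e. mutation rate times expected
subtending branch length).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import (
    DegenerateSpectrumError,
    FormatError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

KINDS = ("counts", "proportions", "density")


@dataclass(frozen=True)
class ScalingParams:
    """Absolute-SFS scaling: ancestral size, mutation rate, sequence length.

    ``theta = 4 * n_ancestral * mu * length`` is derived, never stored.
    """

    n_ancestral: float
    mu: float
    length: float

    def __post_init__(self) -> None:
        if not (self.n_ancestral > 0 and self.mu > 0 and self.length >= 0):
            raise InvalidInputError("scaling parameters must be positive (length >= 0)")

    @property
    def theta(self) -> float:
        return 4.0 * self.n_ancestral * self.mu * self.length


@dataclass(frozen=True)
class SFSSpectrum:
    """A 1-D site frequency spectrum.

    ``values[i]`` is the mass at allele count ``i + 1``.  ``se`` carries
    optional per-bin Monte-Carlo standard errors.
    """

    values: np.ndarray
    n: int
    folded: bool = False
    kind: str = "counts"
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.n < 2:
            raise InvalidInputError(f"sample size must be >= 2, got {self.n}")
        if self.kind not in KINDS:
            raise InvalidInputError(f"kind must be one of {KINDS}, got {self.kind!r}")
        expected = self.n // 2 if self.folded else self.n - 1
        if v.shape != (expected,):
            raise InvalidInputError(
                f"{'folded' if self.folded else 'unfolded'} spectrum at n={self.n} "
                f"must have {expected} bins, got {v.shape}"
            )
        if np.any(v < 0):
            raise InvalidInputError("spectrum values must be >= 0")
        if self.kind == "proportions" and abs(v.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                f"proportions must sum to 1 within 1e-9, got {v.sum()!r}"
            )
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != v.shape:
                raise InvalidInputError("se must match values in shape")
            object.__setattr__(self, "se", se)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def allele_counts(self) -> np.ndarray:
        """The allele count each bin indexes (1-based)."""
        return np.arange(1, len(self.values) + 1)

    def to_proportions(self) -> "SFSSpectrum":
        tot = self.total
        if tot <= 0:
            raise DegenerateSpectrumError("cannot normalize an all-zero spectrum")
        return replace(
            self,
            values=self.values / tot,
            kind="proportions",
            se=None if self.se is None else self.se / tot,
        )


def fold(sfs: SFSSpectrum) -> SFSSpectrum:
    """Fold an unfolded spectrum onto minor-allele counts.

    ``F_j = xi_j + xi_{n-j}`` for ``j < n/2`` and ``F_{n/2} = xi_{n/2}``;
    total mass is conserved.
    """
    if sfs.folded:
        raise InvalidInputError("spectrum is already folded")
    n = sfs.n
    out = np.zeros(n // 2)
    se2 = np.zeros(n // 2) if sfs.se is not None else None
    for i in range(1, n):
        j = min(i, n - i)  # i == n - i lands in the middle bin exactly once
        out[j - 1] += sfs.values[i - 1]
        if se2 is not None:
            se2[j - 1] += sfs.se[i - 1] ** 2
    return SFSSpectrum(
        out,
        n=n,
        folded=True,
        kind=sfs.kind,
        se=None if se2 is None else np.sqrt(se2),
    )


def project(sfs: SFSSpectrum, m: int) -> SFSSpectrum:
    """Expected hypergeometric down-sampling from ``n`` to ``m`` chromosomes.

    Mass reaching the monomorphic classes of the subsample is dropped;
    ``m == n`` is the identity.  A proportions input is renormalized after
    projection (i.e. conditioned on remaining polymorphic) so the output
    still sums to 1.
    """
    if sfs.folded:
        raise InvalidInputError("project requires an unfolded spectrum")
    n = sfs.n
    if m > n:
        raise InvalidInputError(f"cannot project up: m={m} > n={n}")
    if m < 2:
        raise InvalidInputError("target sample size must be >= 2")
    if m == n:
        return sfs
    # weight[i-1, j-1] = P(j derived of m | i derived of n)
    i = np.arange(1, n)
    out = np.zeros(m - 1)
    for j in range(1, m):
        out[j - 1] = float(np.dot(sfs.values, hypergeom.pmf(j, n, i, m)))
    if sfs.kind == "proportions":
        tot = out.sum()
        if tot <= 0:
            raise DegenerateSpectrumError("projection left no polymorphic mass")
        out = out / tot
    return SFSSpectrum(out, n=m, folded=False, kind=sfs.kind)


def marginalize_joint(
    joint: np.ndarray, pop_label: str, labels: Sequence[str]
) -> SFSSpectrum:
    """Marginalize a joint SFS array onto one population's axis.

    ``joint`` has one axis per population with shape ``n_p + 1`` (allele
    counts ``0..n_p`` including the monomorphic corners); all other axes are
    summed and the focal ``0`` and ``n`` entries dropped.
    """
    joint = np.asarray(joint, dtype=float)
    if len(labels) != joint.ndim:
        raise InvalidInputError("labels must name every axis of the joint array")
    if pop_label not in labels:
        raise InvalidInputError(f"population {pop_label!r} is not an axis label")
    axis = list(labels).index(pop_label)
    others = tuple(a for a in range(joint.ndim) if a != axis)
    marg = joint.sum(axis=others) if others else joint
    n = marg.shape[0] - 1
    return SFSSpectrum(marg[1:-1], n=n, folded=False, kind="counts")


def scale_to_counts(sfs: SFSSpectrum, scaling: ScalingParams) -> SFSSpectrum:
    """Convert a per-site density spectrum to absolute expected SNP counts
    for a region of ``scaling.length`` bp."""
    if sfs.kind != "density":
        raise InvalidInputError(
            f"scale_to_counts requires a per-site density spectrum, got kind={sfs.kind!r}"
        )
    return replace(
        sfs,
        values=sfs.values * scaling.length,
        kind="counts",
        se=None if sfs.se is None else sfs.se * scaling.length,
    )


def drop_singletons_renormalize(
    sfs: SFSSpectrum, *, drop_polarized_high: bool = False
) -> SFSSpectrum:
    """Zero the singleton bin and rescale the remainder to sum to 1.

    For unfolded spectra, ``drop_polarized_high`` additionally zeroes the
    ``n-1`` bin (derived-allele near-fixation singleton of the other
    allele).
    """
    if sfs.kind != "proportions":
        raise InvalidInputError("drop_singletons_renormalize requires proportions")
    v = sfs.values.copy()
    v[0] = 0.0
    if drop_polarized_high and not sfs.folded:
        v[-1] = 0.0
    tot = v.sum()
    if tot <= 0:
        raise DegenerateSpectrumError("all probability mass was in the singleton class")
    return replace(sfs, values=v / tot, se=None)


# ---------------------------------------------------------------------------
# Text I/O: one header line (n, folded, kind), then index<TAB>value rows.
# ---------------------------------------------------------------------------

def write_sfs(sfs: SFSSpectrum, path: str | Path) -> None:
    lines = [f"# n={sfs.n} folded={int(sfs.folded)} kind={sfs.kind}"]
    for i, v in zip(sfs.allele_counts, sfs.values):
        lines.append(f"{i}\t{v:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfs(
    path: str | Path,
    *,
    n: int | None = None,
    folded: bool = False,
    kind: str = "counts",
) -> SFSSpectrum:
    """Read the SFS text format; also accepts a bare whitespace-separated
    vector (then ``n``/``folded``/``kind`` must describe it)."""
    logger.info("reading SFS from %s", path)
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"empty SFS file: {path}")
    lines = text.splitlines()
    if lines[0].startswith("#"):
        # provenance comments may precede the structural header line
        header: dict[str, str] = {}
        body_start = 0
        for i, ln in enumerate(lines):
            if not ln.startswith("#"):
                body_start = i
                break
            fields = dict(
                item.split("=", 1) for item in ln.lstrip("# ").split() if "=" in item
            )
            if {"n", "folded", "kind"} <= set(fields):
                header = fields
            body_start = i + 1
        try:
            n = int(header["n"])
            folded = bool(int(header["folded"]))
            kind = header["kind"]
        except (KeyError, ValueError) as exc:
            raise FormatError(f"no valid SFS header line found in {path}") from exc
        vals: dict[int, float] = {}
        for ln in lines[body_start:]:
            if not ln.strip() or ln.startswith("#"):
                continue
            idx_s, val_s = ln.split()
            vals[int(idx_s)] = float(val_s)
        size = n // 2 if folded else n - 1
        arr = np.zeros(size)
        for i, v in vals.items():
            if not 1 <= i <= size:
                raise FormatError(f"allele count {i} out of range for n={n}")
            arr[i - 1] = v
        return SFSSpectrum(arr, n=n, folded=folded, kind=kind)
    flat = np.array([float(x) for ln in lines for x in ln.split()])
    if n is None:
        n = len(flat) + 1 if not folded else len(flat) * 2
    return SFSSpectrum(flat, n=n, folded=folded, kind=kind)
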