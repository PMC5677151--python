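"""Deterministic expected SFS for single-population piecewise histories.

The expected spectrum follows from the coalescent identity

    E[xi_i] = mu * sum_k  k * E[T_k] * P(branch subtends i | k lineages),

with ``P(i | k) = C(n-i-1, k-2) / C(n-1, k-1)`` and ``E[T_k]`` the expected
time during which exactly ``k`` ancestral lineages survive.  Under a
piecewise-constant history the lineage-count chain is time-homogeneous
within each epoch, so the expected state occupancies are computed exactly
from the matrix exponential of the (triangular) death-chain generator in
coalescent-scaled time; exponential-growth epochs are handled by geometric
sub-discretization with adaptive refinement.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm, solve_triangular
from scipy.special import comb

from .demography import PiecewiseDemography
from .errors import InvalidInputError, UnsupportedFeatureError
from .sfs import SFSSpectrum
from .timeline import compile_timeline

__all__ = ["expected_branch_times", "expected_sfs_analytic", "subtend_probability_matrix"]


def _occupancies_from_segments(segments, n: int) -> np.ndarray:
    """E[T_k] (generations), k = 2..n, given constant-size segments."""
    m = n - 1  # transient states k = n..2, index i <-> k = n - i
    ks = np.arange(n, 1, -1, dtype=float)
    lam = ks * (ks - 1.0) / 2.0
    T = np.zeros((m, m))
    T[np.arange(m), np.arange(m)] = -lam
    T[np.arange(1, m), np.arange(m - 1)] = lam[:-1]
    v = np.zeros(m)
    v[0] = 1.0
    occ = np.zeros(m)
    for seg in segments:
        n_dip = next(iter(seg.sizes.values()))
        if math.isinf(seg.t1):
            # integrate to absorption: occ += -T^{-1} v, in scaled time
            o = -solve_triangular(T, v, lower=True)
            occ += 2.0 * n_dip * o
            v = np.zeros(m)
            break
        dtau = (seg.t1 - seg.t0) / (2.0 * n_dip)
        E = expm(T * dtau)
        w = E @ v
        o = solve_triangular(T, w - v, lower=True)
        occ += 2.0 * n_dip * o
        v = w
        if v.sum() < 1e-16:
            break
    return occ[::-1]  # reorder to k = 2..n


def expected_branch_times(
    demog: PiecewiseDemography, n: int, *, rtol: float = 1e-8
) -> np.ndarray:
    """Expected time (generations) with exactly ``k`` lineages, k = 2..n.

    Exact for piecewise-constant histories; exponential epochs are refined
    geometrically until successive estimates agree to ``rtol``.
    """
    if n < 2:
        raise InvalidInputError(f"sample size must be >= 2, got {n}")
    if not demog.is_single_population:
        raise UnsupportedFeatureError(
            "analytic engine handles single-population histories only; "
            "use expected_sfs_montecarlo for multi-population models"
        )
    has_exp = any(e.is_exponential for e in demog.epochs)
    if not has_exp:
        return _occupancies_from_segments(compile_timeline(demog, 1).segments, n)
    substeps = 64
    prev = _occupancies_from_segments(compile_timeline(demog, substeps).segments, n)
    while substeps < 4096:
        substeps *= 2
        cur = _occupancies_from_segments(compile_timeline(demog, substeps).segments, n)
        if np.max(np.abs(cur - prev) / np.maximum(np.abs(cur), 1e-300)) < rtol:
            return cur
        prev = cur
    return prev


def subtend_probability_matrix(n: int) -> np.ndarray:
    """``P[i-1, k-2] = P(a random branch among k subtends i of n samples)``.

    Rows index derived counts ``1..n-1``, columns lineage counts ``2..n``.
    """
    i = np.arange(1, n)[:, None]
    k = np.arange(2, n + 1)[None, :]
    return comb(n - i - 1, k - 2) / comb(n - 1, k - 1)


def expected_sfs_analytic(demog: PiecewiseDemography, n: int) -> SFSSpectrum:
    """Expected per-site SNP density per derived-allele count, ``1..n-1``.

    Deterministic; relative accuracy is limited only by the matrix
    exponential (constant epochs) or the refinement tolerance (exponential
    epochs).  Multiply by sequence length for absolute expected counts, or
    normalize for the proportional spectrum.
    """
    t_k = expected_branch_times(demog, n)  # k = 2..n
    k = np.arange(2, n + 1, dtype=float)
    p = subtend_probability_matrix(n)
    density = demog.mutation_rate * (p @ (k * t_k))
    return SFSSpectrum(density, n=n, folded=False, kind="density")
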