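"""Multinomial and Poisson log-likelihood scoring of predicted spectra.

Conventions: the multinomial log-likelihood is ``sum_i x_i ln p_i`` without
the multinomial coefficient (a model-independent constant, so delta-LLs are
unaffected either way); the Poisson log-likelihood keeps the
``-ln Gamma(x+1)`` term so absolute values match likelihood-theory
references.  "Data to data" denotes the best achievable log-likelihood,
obtained by scoring the observed spectrum against its own proportions (or,
for Poisson, its own counts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import InvalidInputError
from .sfs import SFSSpectrum, fold as fold_sfs, project as project_sfs
from .sfs import drop_singletons_renormalize

logger = logging.getLogger(__name__)

__all__ = [
    "multinomial_ll",
    "poisson_ll",
    "data_to_data_ll",
    "FitTable",
    "fit_table",
]

_P_FLOOR = 1e-300
DATA_TO_DATA = "Data to data"


def _check_compatible(observed: SFSSpectrum, model: SFSSpectrum) -> None:
    if observed.n != model.n or observed.folded != model.folded:
        raise InvalidInputError(
            f"binning mismatch: observed (n={observed.n}, folded={observed.folded}) "
            f"vs model (n={model.n}, folded={model.folded})"
        )
    if len(observed) != len(model):
        raise InvalidInputError("spectra differ in bin count")


def multinomial_ll(observed: SFSSpectrum, model: SFSSpectrum) -> float:
    """``sum_i x_i ln p_i`` of observed counts under model proportions.

    Zero-probability bins carrying observations are floored at 1e-300 with
    a prominent warning so pathological models still rank (very badly).
    """
    _check_compatible(observed, model)
    if model.kind != "proportions":
        raise InvalidInputError("model spectrum must be proportions")
    x = observed.values
    p = model.values.copy()
    bad = (p <= 0) & (x > 0)
    if bad.any():
        warnings.warn(
            f"model assigns zero probability to {int(bad.sum())} observed bin(s); "
            f"flooring at {_P_FLOOR:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.maximum(p, _P_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.maximum(p, _P_FLOOR)), 0.0)
    return float(terms.sum())


def poisson_ll(observed: SFSSpectrum, model: SFSSpectrum) -> float:
    """``sum_i [x_i ln m_i - m_i - ln Gamma(x_i + 1)]`` for expected counts m."""
    _check_compatible(observed, model)
    m = model.values
    x = observed.values
    if np.any(m < 0):
        raise InvalidInputError("expected counts must be >= 0")
    if np.any((m == 0) & (x > 0)):
        raise InvalidInputError(
            "model expected count is 0 where observations exist; Poisson LL undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.maximum(m, _P_FLOOR)), 0.0)
    return float((terms - m - gammaln(x + 1.0)).sum())


def data_to_data_ll(observed: SFSSpectrum, family: str = "multinomial") -> float:
    """Best achievable LL: the observed spectrum scored against itself.

    Multinomial: ``sum_i x_i ln(x_i / X)`` with ``0 ln 0 = 0``.  Poisson:
    ``poisson_ll(x, x)``.
    """
    x = observed.values
    total = x.sum()
    if total <= 0:
        raise InvalidInputError("observed spectrum is empty")
    if family == "multinomial":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(x > 0, x * np.log(x / total), 0.0)
        return float(terms.sum())
    if family == "poisson":
        return poisson_ll(observed, observed)
    raise InvalidInputError(f"unknown likelihood family {family!r}")


@dataclass(frozen=True)
class FitTable:
    """Ranked per-model log-likelihoods relative to the data-to-data maximum."""

    table: pd.DataFrame  # columns: model, ll, delta_ll, rank, [poisson_ll, poisson_delta_ll], failed
    family: str = "multinomial"

    def __post_init__(self) -> None:
        ok = self.table[~self.table["failed"]]
        d2d = ok[ok["model"] == DATA_TO_DATA]
        if len(d2d) != 1 or abs(float(d2d["delta_ll"].iloc[0])) > 1e-9:
            raise InvalidInputError("fit table must contain the data-to-data row at delta 0")

    def delta_ll(self, model: str) -> float:
        row = self.table[self.table["model"] == model]
        if row.empty:
            raise InvalidInputError(f"no model named {model!r} in table")
        return float(row["delta_ll"].iloc[0])

    def best_model(self) -> str:
        ok = self.table[~self.table["failed"] & (self.table["model"] != DATA_TO_DATA)]
        return str(ok.sort_values("rank").iloc[0]["model"])

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for ln in header_lines or []:
                fh.write(f"# {ln}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _prepare(
    sfs: SFSSpectrum,
    *,
    fold: bool,
    project_to: int | None,
    drop_singletons: bool,
) -> SFSSpectrum:
    out = sfs
    if project_to is not None and not out.folded:
        out = project_sfs(out, project_to)
    if fold and not out.folded:
        out = fold_sfs(out)
    if drop_singletons:
        out = drop_singletons_renormalize(out.to_proportions())
    return out


def fit_table(
    models: Mapping[str, SFSSpectrum],
    observed: SFSSpectrum,
    *,
    drop_singletons: bool = False,
    fold: bool = False,
    project_to: int | None = None,
    poisson: bool = False,
) -> FitTable:
    """Score every model against an observed count spectrum and rank by delta-LL.

    Identical transforms (projection, folding, singleton handling) are
    applied to the observed spectrum and every model before scoring.  A
    model that cannot be reconciled with the observed binning is flagged
    ``failed`` and the rest are still reported.  For the multinomial score
    the observed spectrum keeps its counts (with the singleton bin zeroed
    when ``drop_singletons``), while models are reduced to proportions; the
    Poisson score additionally requires models carrying expected counts.
    """
    if observed.kind != "counts":
        raise InvalidInputError("observed spectrum must carry counts")
    obs = observed
    if project_to is not None and not obs.folded:
        obs = project_sfs(obs, project_to)
    if fold and not obs.folded:
        obs = fold_sfs(obs)
    obs_counts = obs
    if drop_singletons:
        v = obs_counts.values.copy()
        v[0] = 0.0
        obs_counts = SFSSpectrum(v, n=obs.n, folded=obs.folded, kind="counts")

    d2d_mult = data_to_data_ll(obs_counts, "multinomial")
    d2d_pois = data_to_data_ll(obs_counts, "poisson") if poisson else np.nan

    rows = [
        {
            "model": DATA_TO_DATA,
            "ll": d2d_mult,
            "delta_ll": 0.0,
            "poisson_ll": d2d_pois,
            "poisson_delta_ll": 0.0 if poisson else np.nan,
            "failed": False,
        }
    ]
    for name, spec in models.items():
        try:
            prepared = _prepare(
                spec, fold=fold, project_to=project_to, drop_singletons=drop_singletons
            )
            props = prepared if prepared.kind == "proportions" else prepared.to_proportions()
            ll = multinomial_ll(obs_counts, props)
            if poisson:
                if prepared.kind == "density":
                    raise InvalidInputError(
                        "Poisson scoring needs absolute expected counts; "
                        "scale density spectra with scale_to_counts first"
                    )
                counts_model = prepared
                if drop_singletons:
                    v = counts_model.values.copy()
                    v[0] = 0.0
                    counts_model = SFSSpectrum(
                        v, n=counts_model.n, folded=counts_model.folded, kind=counts_model.kind
                    )
                p_ll = poisson_ll(obs_counts, counts_model)
            else:
                p_ll = np.nan
            rows.append(
                {
                    "model": name,
                    "ll": ll,
                    "delta_ll": ll - d2d_mult,
                    "poisson_ll": p_ll,
                    "poisson_delta_ll": (p_ll - d2d_pois) if poisson else np.nan,
                    "failed": False,
                }
            )
        except Exception as exc:  # isolate per-model failures
            logger.warning("model %r failed to score: %s", name, exc)
            rows.append(
                {
                    "model": name,
                    "ll": np.nan,
                    "delta_ll": np.nan,
                    "poisson_ll": np.nan,
                    "poisson_delta_ll": np.nan,
                    "failed": True,
                }
            )
    df = pd.DataFrame(rows)
    order = df["delta_ll"].where(~df["failed"], -np.inf)
    df = df.iloc[np.argsort(-order.to_numpy(), kind="stable")].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if not poisson:
        df = df.drop(columns=["poisson_ll", "poisson_delta_ll"])
    return FitTable(df)
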