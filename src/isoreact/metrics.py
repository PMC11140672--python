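"""Sample-level chemodiversity and formula-composition summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (
    IsotopeTable,
    aromaticity_index,
    double_bond_equivalent,
    monoisotopic_mass,
    mz_deprotonated,
)

__all__ = ["SampleSummary", "shannon_index", "summarize", "rank_correlation",
           "summary_frame"]

_ELEMENTS = ("C", "H", "O", "N", "F", "Cl")


def shannon_index(intensities: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity of an intensity distribution.

    H = -Σ pᵢ log pᵢ with pᵢ = Iᵢ/ΣI, in nats unless *base* is given.
    0 for a single species, at most log(n); invariant to rescaling the
    intensities, so raw or normalized spectra give the same value.
    """
    arr = np.asarray(list(intensities), dtype=float)
    if arr.size == 0:
        raise ValueError("empty intensity list")
    if np.any(arr <= 0):
        raise ValueError("intensities must be strictly positive")
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(0.0, h)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample composition summary over a consensus formula set."""

    n_formulas: int
    shannon: float
    mean_mz: float
    mean_dbe: float
    mean_ai: float
    mean_h_to_c: float
    mean_o_to_c: float
    mean_counts: dict
    weighted: bool

    def to_dict(self) -> dict:
        d = {
            "n_formulas": self.n_formulas,
            "shannon": self.shannon,
            "mean_mz": self.mean_mz,
            "mean_dbe": self.mean_dbe,
            "mean_ai": self.mean_ai,
            "mean_h_to_c": self.mean_h_to_c,
            "mean_o_to_c": self.mean_o_to_c,
            "weighted": self.weighted,
        }
        for el, v in self.mean_counts.items():
            d[f"mean_{el}"] = v
        return d


def summarize(consensus, weighted: bool = False,
              table: IsotopeTable | None = None) -> SampleSummary:
    """Composition summary of a consensus formula set.

    Means are unweighted by default (each formula counts once); with
    ``weighted=True`` they are intensity-weighted.  m/z is the theoretical
    deprotonated m/z of each formula.  The Shannon index always uses the
    consensus intensities and ignores the weighting flag.
    """
    if not consensus.formulas:
        raise ValueError("empty consensus set")
    formulas = list(consensus.formulas)
    intens = np.array([consensus.formulas[f] for f in formulas], dtype=float)
    w = intens / intens.sum() if weighted else np.full(len(formulas), 1.0 / len(formulas))

    mzs = np.array([mz_deprotonated(monoisotopic_mass(f, table)) for f in formulas])
    dbe = np.array([double_bond_equivalent(f) for f in formulas])
    ai = np.array([aromaticity_index(f) for f in formulas])
    counts = {el: np.array([float(f[el]) for f in formulas]) for el in _ELEMENTS}
    with np.errstate(divide="ignore", invalid="ignore"):
        h_to_c = np.where(counts["C"] > 0, counts["H"] / counts["C"], np.nan)
        o_to_c = np.where(counts["C"] > 0, counts["O"] / counts["C"], np.nan)

    def wmean(x):
        m = ~np.isnan(x)
        return float((x[m] * w[m]).sum() / w[m].sum()) if m.any() else float("nan")

    return SampleSummary(
        n_formulas=len(formulas),
        shannon=shannon_index(intens[intens > 0]),
        mean_mz=wmean(mzs),
        mean_dbe=wmean(dbe),
        mean_ai=wmean(ai),
        mean_h_to_c=wmean(h_to_c),
        mean_o_to_c=wmean(o_to_c),
        mean_counts={el: wmean(counts[el]) for el in _ELEMENTS},
        weighted=weighted,
    )


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's ρ with average ranks for ties."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def summary_frame(summaries: dict) -> pd.DataFrame:
    """Tidy long-format table (sample, metric, weighting, value) for export."""
    rows = []
    for sample, summary in summaries.items():
        weighting = "weighted" if summary.weighted else "unweighted"
        for metric, value in summary.to_dict().items():
            if metric == "weighted":
                continue
            rows.append({"sample": sample, "metric": metric,
                         "weighting": weighting, "value": value})
    return pd.DataFrame(rows)
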