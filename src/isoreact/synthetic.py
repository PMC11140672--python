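"""Ground-truth product ensembles and noisy replicate peak lists.

Emulates the data structure of a ¹⁵N-labeled chloramination experiment
measured by negative-mode FT-ICR MS: a product ensemble grown by applying
catalog transformations to a starting material with planted relative
weights, rendered as singly charged deprotonated peak lists with ppm-scale
mass jitter, log-normal intensities, minor-isotopologue peaks, contaminant
peaks with random mass defects, and technical replicates with dropout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem import (
    IsotopeTable,
    MolecularFormula,
    Transformation,
    TransformationNotApplicable,
    apply_transformation,
    format_formula,
    monoisotopic_mass,
    mz_deprotonated,
    nitrogen15_table,
    parse_formula,
)
from .assign import DEFAULT_LIMITS, predict_isotopologues
from .network import default_catalog
from .peaklist import Peak, PeakList

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "simulate_products", "simulate_peaklists",
           "amino_acid_fixture", "AMINO_ACIDS"]

#: The 20 canonical proteinogenic amino acids (neutral formulas).  Note that
#: leucine and isoleucine are constitutional isomers and share a formula.
AMINO_ACIDS: dict[str, str] = {
    "glycine": "C2H5NO2",
    "alanine": "C3H7NO2",
    "serine": "C3H7NO3",
    "proline": "C5H9NO2",
    "valine": "C5H11NO2",
    "threonine": "C4H9NO3",
    "cysteine": "C3H7NO2S",
    "leucine": "C6H13NO2",
    "isoleucine": "C6H13NO2",
    "asparagine": "C4H8N2O3",
    "aspartate": "C4H7NO4",
    "glutamine": "C5H10N2O3",
    "lysine": "C6H14N2O2",
    "glutamate": "C5H9NO4",
    "methionine": "C5H11NO2S",
    "histidine": "C6H9N3O2",
    "phenylalanine": "C9H11NO2",
    "arginine": "C6H14N4O2",
    "tyrosine": "C9H11NO3",
    "tryptophan": "C11H12N2O2",
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the chloramination study: 4-hydroxybenzoic acid as the
    starting material, the eight-reaction catalog, 98.2% ¹⁵N enrichment,
    three technical replicates, sub-ppm mass jitter and the study's element
    limits (products outside them would be unassignable, as in the real
    acquisition where such peaks stay unexplained).
    """

    seed_formula: MolecularFormula = field(
        default_factory=lambda: parse_formula("C7H6O3"))
    catalog: Sequence[Transformation] | None = None
    weights: Mapping[str, float] | None = None  # transformation -> relative weight
    steps: int = 60
    seed: int = 0
    ppm_sigma: float = 0.2
    log_intensity_mean: float = float(np.log(1e8))
    log_intensity_sigma: float = 1.0
    replicate_sigma: float = 0.1  # multiplicative per-replicate scatter
    emit_isotopologues: bool = True
    min_isotopologue_rel: float = 1e-3
    n_replicates: int = 3
    dropout: float = 0.1
    contaminant_rate: float = 0.05  # expected contaminants per true formula
    contaminant_mz_range: tuple[float, float] = (100.0, 600.0)
    noise_floor: float = 2e5  # s2n = intensity / noise_floor
    limits: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LIMITS))
    table: IsotopeTable | None = None

    def __post_init__(self):
        if self.catalog is None:
            self.catalog = default_catalog(self.seed_formula)
        if self.weights is None:
            self.weights = {t.name: 1.0 for t in self.catalog}
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be in [0, 1]")
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.table is None:
            self.table = nitrogen15_table()


def _within_limits(f: MolecularFormula, limits: Mapping[str, int]) -> bool:
    return all(el in limits and n <= limits[el] for el, n in f.items())


def simulate_products(
    cfg: SyntheticConfig,
) -> tuple[set[MolecularFormula], nx.MultiDiGraph, dict[str, float]]:
    """Grow a product ensemble by a weighted random walk over the catalog.

    Each step picks a random realized formula and a transformation with
    probability proportional to the planted weights, applies it if the
    result stays within the element limits, and records the realized edge;
    a step completes when a *new* formula appears.  Returns the formula set,
    the true reaction network (with node intensities unset), and the planted
    weights.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = list(cfg.catalog)
    names = [t.name for t in catalog]
    w = np.array([max(0.0, float(cfg.weights.get(t, 0.0))) for t in names])
    if w.sum() <= 0:
        raise ValueError("all transformation weights are zero")
    p = w / w.sum()

    if not any(_applicable(cfg.seed_formula, t, cfg.limits) for t in catalog
               if cfg.weights.get(t.name, 0.0) > 0):
        raise ValueError("no weighted transformation applies to the seed formula")

    realized: list[MolecularFormula] = [cfg.seed_formula]
    formula_set = {cfg.seed_formula}
    net = nx.MultiDiGraph()
    net.add_node(format_formula(cfg.seed_formula),
                 formula=format_formula(cfg.seed_formula))
    max_attempts = 200 * cfg.steps
    new_count = 0
    attempts = 0
    while new_count < cfg.steps and attempts < max_attempts:
        attempts += 1
        src = realized[rng.integers(len(realized))]
        t = catalog[rng.choice(len(catalog), p=p)]
        try:
            product = apply_transformation(src, t)
        except TransformationNotApplicable:
            continue
        if not _within_limits(product, cfg.limits):
            continue
        su, sv = format_formula(src), format_formula(product)
        if product not in formula_set:
            formula_set.add(product)
            realized.append(product)
            net.add_node(sv, formula=sv)
            new_count += 1
        if not net.has_edge(su, sv, key=t.name):
            net.add_edge(su, sv, key=t.name, transformation=t.name)
    if new_count < cfg.steps:
        logger.info("product walk saturated after %d new formulas "
                    "(%d attempts)", new_count, attempts)
    return formula_set, net, {n: float(v) for n, v in zip(names, w)}


def _applicable(f, t, limits) -> bool:
    try:
        return _within_limits(apply_transformation(f, t), limits)
    except TransformationNotApplicable:
        return False


def simulate_peaklists(
    formulas: Mapping[MolecularFormula, float] | Sequence[MolecularFormula],
    cfg: SyntheticConfig,
) -> tuple[list[PeakList], pd.DataFrame]:
    """Render formulas as noisy replicate peak lists plus a truth table.

    Per formula: a deprotonated monoisotopic peak with Gaussian ppm jitter
    and log-normal intensity (shared across replicates up to multiplicative
    replicate scatter), minor-isotopologue peaks at their predicted shifts
    and ratios, per-replicate dropout, and uniform-mass-defect contaminant
    peaks.  The truth table maps every emitted peak to (replicate, m/z,
    formula, role).
    """
    if isinstance(formulas, Mapping):
        base_formulas = list(formulas)
        base_intens = {f: float(v) for f, v in formulas.items()}
    else:
        base_formulas = list(formulas)
        base_intens = {}
    if not base_formulas:
        raise ValueError("no formulas to simulate")
    base_formulas = sorted(base_formulas, key=format_formula)
    rng = np.random.default_rng(cfg.seed + 1)

    theo_mz = {f: mz_deprotonated(monoisotopic_mass(f, cfg.table))
               for f in base_formulas}
    for f in base_formulas:
        if f not in base_intens:
            base_intens[f] = float(rng.lognormal(
                cfg.log_intensity_mean, cfg.log_intensity_sigma))

    peaklists: list[PeakList] = []
    truth_rows: list[dict] = []
    for rep in range(cfg.n_replicates):
        peaks: list[Peak] = []
        for f in base_formulas:
            if rng.random() < cfg.dropout:
                continue
            inten = base_intens[f] * float(
                rng.lognormal(0.0, cfg.replicate_sigma))
            mz = theo_mz[f] * (1.0 + rng.normal(0.0, cfg.ppm_sigma) * 1e-6)
            peaks.append(Peak(mz, inten, inten / cfg.noise_floor))
            truth_rows.append({"replicate": rep, "mz": mz,
                               "formula": format_formula(f),
                               "role": "monoisotopic"})
            if cfg.emit_isotopologues:
                for entry in predict_isotopologues(f, cfg.table):
                    if entry.rel_intensity < cfg.min_isotopologue_rel:
                        continue
                    iso_mz = (theo_mz[f] + entry.mass_shift) * (
                        1.0 + rng.normal(0.0, cfg.ppm_sigma) * 1e-6)
                    iso_i = inten * entry.rel_intensity
                    peaks.append(Peak(iso_mz, iso_i, iso_i / cfg.noise_floor))
                    truth_rows.append({"replicate": rep, "mz": iso_mz,
                                       "formula": format_formula(f),
                                       "role": f"isotopologue:{entry.label}"})
        n_contam = rng.poisson(cfg.contaminant_rate * len(base_formulas))
        lo, hi = cfg.contaminant_mz_range
        for _ in range(n_contam):
            mz = float(rng.uniform(lo, hi))
            inten = float(rng.lognormal(np.log(5e6), 1.0))
            peaks.append(Peak(mz, inten, inten / cfg.noise_floor))
            truth_rows.append({"replicate": rep, "mz": mz,
                               "formula": "", "role": "contaminant"})
        peaklists.append(PeakList(tuple(peaks), sample_id="synthetic",
                                  replicate=rep))
    truth = pd.DataFrame(truth_rows,
                         columns=["replicate", "mz", "formula", "role"])
    return peaklists, truth


def amino_acid_fixture(
    enrichment: float = 0.982,
    intensity: float = 1e8,
    s2n: float = 1000.0,
) -> tuple[PeakList, pd.DataFrame, IsotopeTable]:
    """Noiseless [M-H]⁻ peak list of the 20 fully-¹⁵N proteinogenic amino acids.

    Every nitrogen carries the label at the stated enrichment; each amino
    acid contributes its monoisotopic peak (equal intensities) plus a ¹⁴N
    single-substitution isotopologue peak at relative intensity
    n(N) × (1 - e)/e.  Leucine and isoleucine share C6H13NO2, so their
    peaks coincide and merge.  Returns (peak list, truth table, table) where
    the isotope table is the ¹⁵N-relabeled one the fixture was built with.
    """
    table = nitrogen15_table(enrichment)
    peaks: list[Peak] = []
    rows: list[dict] = []
    for name, text in AMINO_ACIDS.items():
        f = parse_formula(text)
        mz = mz_deprotonated(monoisotopic_mass(f, table))
        peaks.append(Peak(mz, intensity, s2n))
        rows.append({"amino_acid": name, "formula": format_formula(f),
                     "theoretical_mz": mz, "n_nitrogen": f["N"]})
        for entry in predict_isotopologues(f, table):
            if entry.label != "14N":
                continue
            iso_i = intensity * entry.rel_intensity
            peaks.append(Peak(mz + entry.mass_shift, iso_i,
                              s2n * entry.rel_intensity))
    truth = pd.DataFrame(rows).sort_values("theoretical_mz",
                                           kind="mergesort").reset_index(drop=True)
    return PeakList(tuple(peaks), sample_id="15N-amino-acids"), truth, table
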