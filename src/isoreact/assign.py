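"""Molecular formula assignment with isotopologue verification.

Candidate formulas are enumerated exhaustively within element limits and a
ppm mass tolerance by a branch-and-bound search, scored on mass error and on
the agreement between predicted and observed minor-isotopologue peaks, and
resolved one formula per peak.  Formulas present in control samples are
excluded as contaminants, and replicate consensus keeps only formulas found
in every technical replicate.

Nitrogen semantics follow the active isotope table: with a ¹⁵N-relabeled
table (see :func:`isoreact.chem.nitrogen15_table`) every "N" is ¹⁵N and ¹⁴N
appears only as the minor isotopologue at 1 - enrichment.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem import (
    PROTON_MASS,
    IsotopeTable,
    MolecularFormula,
    default_isotope_table,
    double_bond_equivalent,
    format_formula,
    monoisotopic_mass,
    mz_deprotonated,
    ppm_error,
)
from .peaklist import Peak, PeakList

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentConfig",
    "Candidate",
    "IsotopologueEntry",
    "Assignment",
    "ConsensusFormulaSet",
    "enumerate_candidates",
    "predict_isotopologues",
    "isotopologue_similarity",
    "assign_peaklist",
    "assigned_formulas",
    "exclude_controls",
    "replicate_consensus",
    "assignments_to_frame",
]

#: Default element limits of the chloramination study (compound 1).
DEFAULT_LIMITS = {"C": 29, "H": 72, "O": 18, "N": 10, "Cl": 8}

#: Element limits with the conservative F limit of 3 (compound 2).
FLUORINE_LIMITS = {"C": 29, "H": 72, "O": 18, "N": 10, "F": 3, "Cl": 8}


@dataclass(frozen=True)
class AssignmentConfig:
    """Parameters of the assignment engine.

    limits
        Element → maximum count; the candidate search space.
    table
        Active isotope table (relabel for enriched experiments).
    tol_ppm
        Maximum |mass error| for a candidate, in ppm (default 1.0).
    sigma_ppm
        Width of the Gaussian mass score exp(-ppm²/2σ²); default tol_ppm/2.
    w_mass, w_iso
        Confidence weights for the mass and isotope-pattern scores.
    detectability_factor
        An expected isotopologue is *detectable* (its absence penalized) when
        its predicted intensity exceeds ``detectability_factor`` times the
        monoisotopic peak's implied noise floor (intensity / s2n), i.e. when
        relative intensity ≥ factor / s2n.
    require_integer_dbe
        Keep only candidates with integer, non-negative DBE (even-electron
        neutral molecules).
    """

    limits: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LIMITS))
    table: IsotopeTable | None = None
    tol_ppm: float = 1.0
    sigma_ppm: float | None = None
    w_mass: float = 0.5
    w_iso: float = 0.5
    detectability_factor: float = 0.2
    require_integer_dbe: bool = True

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        if self.table is None:
            object.__setattr__(self, "table", default_isotope_table())
        if self.sigma_ppm is None:
            object.__setattr__(self, "sigma_ppm", self.tol_ppm / 2.0)

    def mass_score(self, ppm: float) -> float:
        return math.exp(-(ppm * ppm) / (2.0 * self.sigma_ppm * self.sigma_ppm))


@dataclass(frozen=True)
class Candidate:
    """A candidate formula for one peak."""

    formula: MolecularFormula
    theoretical_mz: float
    ppm: float
    mass_score: float
    isotope_score: float | None = None
    confidence: float = 0.0


@dataclass(frozen=True)
class IsotopologueEntry:
    """A predicted single-substitution minor isotopologue."""

    element: str
    label: str
    mass_shift: float  # Da, minor - principal (may be negative)
    rel_intensity: float  # relative to the monoisotopic peak


@dataclass(frozen=True)
class Assignment:
    """Final status of one peak after assignment."""

    peak: Peak
    status: str  # "assigned" | "isotopologue" | "unassigned" | "contaminant"
    candidate: Candidate | None = None
    parent_formula: MolecularFormula | None = None
    isotope_label: str | None = None
    isotopologue_links: tuple[tuple[Peak, str], ...] = ()

    @property
    def formula(self) -> MolecularFormula | None:
        return self.candidate.formula if self.candidate is not None else None


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _dbe_ok(f: MolecularFormula) -> bool:
    dbe = double_bond_equivalent(f)
    return dbe >= 0 and abs(dbe - round(dbe)) < 1e-9


def enumerate_candidates(mz: float, cfg: AssignmentConfig) -> list[Candidate]:
    """All formulas within the element limits whose deprotonated m/z lies
    within ``cfg.tol_ppm`` of *mz*, sorted by |ppm| then formula.

    The search is a branch-and-bound over elements in descending mass with
    interval pruning on the residual mass; it is exhaustive over the limit
    box.  Candidates failing the integer-DBE / DBE ≥ 0 filter are dropped
    when ``cfg.require_integer_dbe`` is set.
    """
    if mz <= 0:
        raise ValueError(f"non-positive m/z {mz}")
    table = cfg.table
    t = cfg.tol_ppm * 1e-6
    # |mz - mzt| <= t * mzt  =>  mzt in [mz/(1+t), mz/(1-t)]
    lo = mz / (1.0 + t) + PROTON_MASS
    hi = mz / (1.0 - t) + PROTON_MASS

    elements = sorted(cfg.limits, key=lambda el: -table.principal_mass(el))
    masses = [table.principal_mass(el) for el in elements]
    limits = [int(cfg.limits[el]) for el in elements]
    n_el = len(elements)
    # suffix_max[i]: largest mass attainable from elements i..end
    suffix_max = [0.0] * (n_el + 1)
    for i in range(n_el - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * limits[i]

    found: list[tuple[int, ...]] = []
    counts = [0] * n_el

    def rec(i: int, acc: float) -> None:
        if i == n_el - 1:
            m = masses[i]
            n_lo = max(0, math.ceil((lo - acc) / m - 1e-12))
            n_hi = min(limits[i], math.floor((hi - acc) / m + 1e-12))
            for n in range(n_lo, n_hi + 1):
                total = acc + n * m
                if lo <= total <= hi:
                    counts[i] = n
                    found.append(tuple(counts))
            counts[i] = 0
            return
        m = masses[i]
        max_n = min(limits[i], int((hi - acc) / m + 1e-12))
        for n in range(0, max_n + 1):
            new_acc = acc + n * m
            if new_acc > hi:
                break
            if new_acc + suffix_max[i + 1] < lo:
                continue
            counts[i] = n
            rec(i + 1, new_acc)
        counts[i] = 0

    if n_el == 1:
        rec(0, 0.0)
    elif n_el > 1:
        rec(0, 0.0)

    out: list[Candidate] = []
    for tup in found:
        f = MolecularFormula({el: n for el, n in zip(elements, tup) if n})
        if not f:
            continue
        if cfg.require_integer_dbe and not _dbe_ok(f):
            continue
        mass = monoisotopic_mass(f, table)
        mzt = mz_deprotonated(mass)
        ppm = ppm_error(mz, mzt)
        if abs(ppm) > cfg.tol_ppm:
            continue
        out.append(Candidate(f, mzt, ppm, cfg.mass_score(ppm)))
    out.sort(key=lambda c: (abs(c.ppm), format_formula(c.formula)))
    return out


# ---------------------------------------------------------------------------
# Isotopologue prediction and scoring
# ---------------------------------------------------------------------------

def predict_isotopologues(
    f: MolecularFormula, table: IsotopeTable | None = None,
    min_atom_ratio: float = 1e-3,
) -> list[IsotopologueEntry]:
    """Single-substitution minor isotopologues of *f*.

    One entry per element carrying a minor isotope (its most abundant
    non-principal isotope): mass shift = m(minor) - m(principal) and
    relative intensity = count × a(minor)/a(principal).  Elements whose
    per-atom abundance ratio falls below *min_atom_ratio* are skipped (this
    drops ²H, leaving ¹³C, ¹⁸O, ³⁷Cl, ³⁴S and the off-label nitrogen — at
    natural abundance ¹⁵N, or ¹⁴N at a *negative* shift with a
    ¹⁵N-relabeled table).
    """
    if not f:
        raise ValueError("empty formula")
    if table is None:
        table = default_isotope_table()
    entries: list[IsotopologueEntry] = []
    for el, n in f.items():
        minor = table.minor(el)
        if minor is None or minor.abundance <= 0:
            continue
        principal = table.principal(el)
        ratio = minor.abundance / principal.abundance
        if ratio < min_atom_ratio:
            continue
        shift = minor.mass - principal.mass
        entries.append(IsotopologueEntry(el, minor.label, shift, n * ratio))
    entries.sort(key=lambda e: e.mass_shift)
    return entries


def isotopologue_similarity(
    expected: Sequence[IsotopologueEntry],
    mono_mz: float,
    mono_intensity: float,
    peak_mzs: Sequence[float],
    peak_intensities: Sequence[float],
    tol_ppm: float,
    rel_threshold: float,
    available=None,
) -> tuple[float | None, list[tuple[int, str]]]:
    """Score agreement between predicted and observed isotopologue peaks.

    For each expected entry with relative intensity ≥ *rel_threshold*
    (detectable), the nearest available peak within *tol_ppm* of the expected
    position is matched; its deviation is |obs - exp| / max(obs, exp) on
    relative intensities, and an unmatched detectable entry contributes
    deviation 1.  Score = 1 - mean deviation.  Returns ``(score, matches)``
    where matches are (peak index, isotope label) pairs; the score is None
    (no isotope evidence either way) when no entry is detectable.
    """
    deviations: list[float] = []
    matches: list[tuple[int, str]] = []
    for entry in expected:
        if entry.rel_intensity < rel_threshold:
            continue
        target = mono_mz + entry.mass_shift
        tol_abs = tol_ppm * 1e-6 * target
        i_lo = bisect_left(peak_mzs, target - tol_abs)
        i_hi = bisect_right(peak_mzs, target + tol_abs)
        best_j, best_d = -1, float("inf")
        for j in range(i_lo, i_hi):
            if available is not None and not available(j):
                continue
            d = abs(peak_mzs[j] - target)
            if d < best_d:
                best_j, best_d = j, d
        if best_j < 0:
            deviations.append(1.0)
            continue
        obs_rel = peak_intensities[best_j] / mono_intensity if mono_intensity > 0 else 0.0
        denom = max(obs_rel, entry.rel_intensity)
        deviations.append(min(1.0, abs(obs_rel - entry.rel_intensity) / denom)
                          if denom > 0 else 1.0)
        matches.append((best_j, entry.label))
    if not deviations:
        return None, []
    return 1.0 - sum(deviations) / len(deviations), matches


# ---------------------------------------------------------------------------
# Peak-list assignment
# ---------------------------------------------------------------------------

def assign_peaklist(pl: PeakList, cfg: AssignmentConfig) -> list[Assignment]:
    """Assign at most one formula per peak, with isotopologue verification.

    Peaks are visited in ascending m/z.  For each unclaimed peak, candidates
    are enumerated and scored; confidence = w_m·mass_score + w_i·isotope_score
    (falling back to the mass score when no isotopologue is detectable).
    Ties break on smaller |ppm| then on the Hill formula string, so the
    result is deterministic.  Peaks matched as isotopologues of an accepted
    assignment are linked to it and removed from the monoisotopic pool.
    """
    peaks = pl.peaks
    n = len(peaks)
    mzs = [p.mz for p in peaks]
    intens = [p.intensity for p in peaks]
    status: list[str | None] = [None] * n
    chosen: list[Candidate | None] = [None] * n
    links: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    claimed_by: dict[int, tuple[int, str]] = {}  # iso peak -> (mono index, label)

    w_sum = cfg.w_mass + cfg.w_iso

    for i, p in enumerate(peaks):
        if i in claimed_by:
            continue
        cands = enumerate_candidates(p.mz, cfg)
        if not cands:
            status[i] = "unassigned"
            continue
        rel_thr = (cfg.detectability_factor / p.s2n) if p.s2n > 0 else float("inf")

        def avail(j: int, i=i) -> bool:
            return j != i and j not in claimed_by and status[j] in (None, "unassigned")

        best: tuple | None = None
        for cand in cands:
            entries = predict_isotopologues(cand.formula, cfg.table)
            iso_score, matches = isotopologue_similarity(
                entries, p.mz, p.intensity, mzs, intens,
                cfg.tol_ppm, rel_thr, available=avail,
            )
            if iso_score is None:
                conf = cand.mass_score
            else:
                conf = (cfg.w_mass * cand.mass_score + cfg.w_iso * iso_score) / w_sum
            scored = Candidate(cand.formula, cand.theoretical_mz, cand.ppm,
                               cand.mass_score, iso_score, conf)
            key = (-conf, abs(cand.ppm), format_formula(cand.formula))
            if best is None or key < best[0]:
                best = (key, scored, matches)
        _, winner, matches = best
        status[i] = "assigned"
        chosen[i] = winner
        for j, label in matches:
            claimed_by[j] = (i, label)
            links[i].append((j, label))
            status[j] = "isotopologue"

    out: list[Assignment] = []
    for i, p in enumerate(peaks):
        if i in claimed_by:
            mono_i, label = claimed_by[i]
            out.append(Assignment(
                peak=p, status="isotopologue",
                parent_formula=chosen[mono_i].formula, isotope_label=label,
            ))
        elif status[i] == "assigned":
            out.append(Assignment(
                peak=p, status="assigned", candidate=chosen[i],
                isotopologue_links=tuple((peaks[j], lab) for j, lab in links[i]),
            ))
        else:
            out.append(Assignment(peak=p, status="unassigned"))
    n_assigned = sum(1 for a in out if a.status == "assigned")
    logger.info("assigned %d/%d peaks (%d isotopologue links)",
                n_assigned, n, len(claimed_by))
    return out


def assigned_formulas(assignments: Iterable[Assignment]) -> dict[MolecularFormula, float]:
    """Formula → monoisotopic peak intensity for assigned peaks.

    If the same formula was assigned to several peaks (should not happen on
    clean data), the most intense peak wins.
    """
    out: dict[MolecularFormula, float] = {}
    for a in assignments:
        if a.status == "assigned":
            f = a.formula
            out[f] = max(out.get(f, 0.0), a.peak.intensity)
    return out


# ---------------------------------------------------------------------------
# Control exclusion and replicate consensus
# ---------------------------------------------------------------------------

def exclude_controls(
    assignments: Sequence[Assignment],
    control_assignments: Sequence[Sequence[Assignment]],
) -> tuple[list[Assignment], set[MolecularFormula]]:
    """Mark formulas found in any control replicate as contaminants.

    Returns the updated assignment list (contaminant peaks get status
    "contaminant") and the set of contaminant formulas removed.
    """
    control_formulas: set[MolecularFormula] = set()
    for rep in control_assignments:
        control_formulas |= set(assigned_formulas(rep))
    removed: set[MolecularFormula] = set()
    out: list[Assignment] = []
    for a in assignments:
        if a.status == "assigned" and a.formula in control_formulas:
            removed.add(a.formula)
            out.append(Assignment(
                peak=a.peak, status="contaminant", candidate=a.candidate,
                isotopologue_links=a.isotopologue_links,
            ))
        else:
            out.append(a)
    n_left = sum(1 for a in out if a.status == "assigned")
    if removed and n_left == 0:
        logger.warning("all assigned formulas were found in controls")
    logger.info("control exclusion removed %d formula(s)", len(removed))
    return out, removed


@dataclass(frozen=True)
class ConsensusFormulaSet:
    """Formulas retained across technical replicates, with mean intensities."""

    formulas: Mapping[MolecularFormula, float]
    n_replicates: int
    min_replicates: int
    replicate_overlap: float  # |intersection| / |union| over all replicates

    def __len__(self) -> int:
        return len(self.formulas)

    def __contains__(self, f) -> bool:
        return f in self.formulas

    def items(self):
        return self.formulas.items()


def replicate_consensus(
    per_replicate: Sequence,
    min_replicates: int | None = None,
) -> ConsensusFormulaSet:
    """Intersect formula sets across technical replicates.

    *per_replicate* holds either assignment lists or formula → intensity
    mappings, one per replicate.  By default a formula must be present in
    **all** replicates to be retained; its consensus intensity is the
    arithmetic mean of its per-replicate monoisotopic intensities.  The
    reported ``replicate_overlap`` is |formulas in all replicates| /
    |formulas in any replicate| — the replicate-reproducibility diagnostic.
    """
    if not per_replicate:
        raise ValueError("no replicates given")
    rep_maps: list[dict[MolecularFormula, float]] = []
    for rep in per_replicate:
        if isinstance(rep, Mapping):
            rep_maps.append(dict(rep))
        else:
            rep_maps.append(assigned_formulas(rep))
    n_rep = len(rep_maps)
    need = n_rep if min_replicates is None else min(min_replicates, n_rep)
    counts: dict[MolecularFormula, int] = {}
    sums: dict[MolecularFormula, float] = {}
    for rep in rep_maps:
        for f, inten in rep.items():
            counts[f] = counts.get(f, 0) + 1
            sums[f] = sums.get(f, 0.0) + inten
    union = len(counts)
    inter = sum(1 for c in counts.values() if c == n_rep)
    kept = {f: sums[f] / counts[f] for f, c in counts.items() if c >= need}
    kept = dict(sorted(kept.items(), key=lambda kv: format_formula(kv[0])))
    return ConsensusFormulaSet(
        formulas=kept, n_replicates=n_rep, min_replicates=need,
        replicate_overlap=(inter / union) if union else 0.0,
    )


def assignments_to_frame(assignments: Sequence[Assignment]):
    """Tabulate assignments for CSV export (sorted by m/z)."""
    import pandas as pd

    rows = []
    for a in assignments:
        c = a.candidate
        rows.append({
            "mz": a.peak.mz,
            "intensity": a.peak.intensity,
            "s2n": a.peak.s2n,
            "status": a.status,
            "formula": format_formula(c.formula) if c else
                       (format_formula(a.parent_formula) if a.parent_formula else ""),
            "theoretical_mz": c.theoretical_mz if c else float("nan"),
            "ppm": c.ppm if c else float("nan"),
            "mass_score": c.mass_score if c else float("nan"),
            "isotope_score": (c.isotope_score if c and c.isotope_score is not None
                              else float("nan")),
            "confidence": c.confidence if c else float("nan"),
            "isotope_label": a.isotope_label or "",
            "isotopologue_links": ";".join(
                f"{pk.mz:.6f}:{lab}" for pk, lab in a.isotopologue_links),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("mz", kind="mergesort").reset_index(drop=True)
    return df
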