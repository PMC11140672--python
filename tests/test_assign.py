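"""Candidate enumeration, isotopologue verification, and consensus building."""

import numpy as np
import pytest

from isoreact.assign import (
    AssignmentConfig,
    assign_peaklist,
    assigned_formulas,
    enumerate_candidates,
    exclude_controls,
    isotopologue_similarity,
    predict_isotopologues,
    replicate_consensus,
)
from isoreact.chem import (
    PROTON_MASS,
    MolecularFormula,
    default_isotope_table,
    double_bond_equivalent,
    format_formula,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
)
from isoreact.peaklist import Peak, PeakList


def brute_force_candidates(mz, cfg):
    """Exhaustive nested-loop enumeration over the element-limit box."""
    els = sorted(cfg.limits)
    out = set()

    def rec(i, counts):
        if i == len(els):
            f = MolecularFormula(dict(zip(els, counts)))
            if not f:
                return
            dbe = double_bond_equivalent(f)
            if cfg.require_integer_dbe and (dbe < 0 or abs(dbe - round(dbe)) > 1e-9):
                return
            mzt = mz_deprotonated(monoisotopic_mass(f, cfg.table))
            if abs((mz - mzt) / mzt * 1e6) <= cfg.tol_ppm:
                out.add(f)
            return
        for n in range(cfg.limits[els[i]] + 1):
            rec(i + 1, counts + [n])

    rec(0, [])
    return out


class TestEnumeration:
    def test_salicylate_rank_one(self, study_config):
        cands = enumerate_candidates(137.024418, study_config)
        assert cands
        assert format_formula(cands[0].formula) == "C7H6O3"

    def test_zero_tolerance_is_exact_match(self, n15_table):
        cfg = AssignmentConfig(table=n15_table, tol_ppm=1e-9)
        mz = mz_deprotonated(monoisotopic_mass(parse_formula("C7H6O3")))
        cands = enumerate_candidates(mz, cfg)
        assert [format_formula(c.formula) for c in cands] == ["C7H6O3"]

    def test_no_candidate_below_formula_space(self, study_config):
        assert enumerate_candidates(50.0, study_config) == []

    def test_all_candidates_respect_contract(self, study_config):
        rng = np.random.default_rng(5)
        for mz in rng.uniform(100, 600, 25):
            for c in enumerate_candidates(float(mz), study_config):
                assert abs(c.ppm) <= study_config.tol_ppm
                for el, n in c.formula.items():
                    assert n <= study_config.limits[el]
                dbe = double_bond_equivalent(c.formula)
                assert dbe >= 0 and abs(dbe - round(dbe)) < 1e-9

    def test_matches_brute_force_small_limits(self, n15_table):
        cfg = AssignmentConfig(
            limits={"C": 10, "H": 16, "O": 6, "N": 3, "Cl": 3},
            table=n15_table,
        )
        rng = np.random.default_rng(11)
        for mz in rng.uniform(100, 300, 15):
            got = {c.formula for c in enumerate_candidates(float(mz), cfg)}
            assert got == brute_force_candidates(float(mz), cfg)

    def test_sorted_by_abs_ppm(self, study_config):
        cands = enumerate_candidates(437.5, study_config)
        ppms = [abs(c.ppm) for c in cands]
        assert ppms == sorted(ppms)


class TestIsotopologues:
    def test_trichloro_pattern(self):
        entries = predict_isotopologues(parse_formula("C6H4Cl3NO4"))
        cl = next(e for e in entries if e.label == "37Cl")
        assert cl.mass_shift == pytest.approx(1.99705, abs=1e-5)
        assert cl.rel_intensity == pytest.approx(0.960, abs=1e-3)

    def test_c13_ratio(self):
        entries = predict_isotopologues(parse_formula("C7H6O3"))
        c13 = next(e for e in entries if e.label == "13C")
        assert c13.rel_intensity == pytest.approx(0.0757, abs=1e-4)

    def test_n14_under_enrichment(self, n15_table):
        entries = predict_isotopologues(parse_formula("C2H5NO2"), n15_table)
        n14 = next(e for e in entries if e.label == "14N")
        assert n14.mass_shift == pytest.approx(-0.99703, abs=1e-5)
        assert n14.rel_intensity == pytest.approx(0.018 / 0.982, abs=1e-4)

    def test_deuterium_excluded(self):
        entries = predict_isotopologues(parse_formula("C7H6O3"))
        assert all(e.element != "H" for e in entries)

    def test_perfect_match_scores_one(self, n15_table):
        f = parse_formula("C7H5ClO3")
        entries = predict_isotopologues(f, n15_table)
        mono_mz = mz_deprotonated(monoisotopic_mass(f, n15_table))
        mzs = sorted([mono_mz + e.mass_shift for e in entries])
        intens = []
        rel = {round(mono_mz + e.mass_shift, 6): e.rel_intensity for e in entries}
        intens = [1e8 * rel[round(m, 6)] for m in mzs]
        score, matches = isotopologue_similarity(
            entries, mono_mz, 1e8, mzs, intens, tol_ppm=1.0, rel_threshold=1e-3)
        assert score == pytest.approx(1.0)
        assert len(matches) == len(entries)

    def test_missing_detectable_peak_penalized(self, n15_table):
        f = parse_formula("C7H5ClO3")
        entries = [e for e in predict_isotopologues(f, n15_table)
                   if e.label in ("13C", "37Cl")]
        mono_mz = mz_deprotonated(monoisotopic_mass(f, n15_table))
        c13 = next(e for e in entries if e.label == "13C")
        mzs = [mono_mz + c13.mass_shift]
        intens = [1e8 * c13.rel_intensity]
        score, _ = isotopologue_similarity(
            entries, mono_mz, 1e8, mzs, intens, tol_ppm=1.0, rel_threshold=1e-3)
        assert score is not None and score <= 0.5

    def test_no_detectable_expectation_gives_none(self, n15_table):
        entries = predict_isotopologues(parse_formula("C7H6O3"), n15_table)
        score, matches = isotopologue_similarity(
            entries, 137.0244, 1e8, [], [], tol_ppm=1.0, rel_threshold=10.0)
        assert score is None and matches == []


class TestAssignPeaklist:
    def test_mono_plus_isotopologue(self, study_config):
        f = parse_formula("C7H6O3")
        mono = mz_deprotonated(monoisotopic_mass(f, study_config.table))
        c13 = next(e for e in predict_isotopologues(f, study_config.table)
                   if e.label == "13C")
        pl = PeakList((
            Peak(mono, 1e8, 500.0),
            Peak(mono + c13.mass_shift, 1e8 * c13.rel_intensity, 40.0),
        ))
        asg = assign_peaklist(pl, study_config)
        statuses = [a.status for a in asg]
        assert statuses == ["assigned", "isotopologue"]
        assert format_formula(asg[0].formula) == "C7H6O3"
        assert asg[0].isotopologue_links[0][1] == "13C"
        assert asg[1].parent_formula == f

    def test_unassignable_peak_reported(self, study_config):
        pl = PeakList((Peak(50.0, 1e8, 100.0),))
        asg = assign_peaklist(pl, study_config)
        assert asg[0].status == "unassigned"

    def test_deterministic(self, study_config, small_synthetic):
        _, _, _, _, peaklists, _ = small_synthetic
        a1 = assign_peaklist(peaklists[0], study_config)
        a2 = assign_peaklist(peaklists[0], study_config)
        assert [(a.status, format_formula(a.formula) if a.formula else "")
                for a in a1] == \
               [(a.status, format_formula(a.formula) if a.formula else "")
                for a in a2]


class TestControlsAndConsensus:
    def _sets(self, *maps):
        return [{parse_formula(k): v for k, v in m.items()} for m in maps]

    def test_exclude_controls_set_difference(self, study_config):
        f = parse_formula("C7H6O3")
        g = parse_formula("C7H5ClO3")
        table = study_config.table
        peaks = [Peak(mz_deprotonated(monoisotopic_mass(x, table)), 1e8, 500.0)
                 for x in (f, g)]
        asg = assign_peaklist(PeakList(tuple(peaks)), study_config)
        ctrl = assign_peaklist(PeakList((peaks[1],)), study_config)
        kept, removed = exclude_controls(asg, [ctrl])
        assert removed == {g}
        assert set(assigned_formulas(kept)) == {f}
        statuses = {format_formula(a.formula): a.status
                    for a in kept if a.formula}
        assert statuses[format_formula(g)] == "contaminant"

    def test_exclude_controls_empty_identity(self, study_config):
        f = parse_formula("C7H6O3")
        table = study_config.table
        asg = assign_peaklist(PeakList(
            (Peak(mz_deprotonated(monoisotopic_mass(f, table)), 1e8, 500.0),)),
            study_config)
        kept, removed = exclude_controls(asg, [])
        assert removed == set() and [a.status for a in kept] == ["assigned"]

    def test_consensus_intersection(self):
        reps = self._sets({"C7H6O3": 1.0, "C7H5ClO3": 2.0},
                          {"C7H6O3": 3.0, "C6H6O": 1.0},
                          {"C7H6O3": 5.0})
        cons = replicate_consensus(reps)
        assert set(map(format_formula, cons.formulas)) == {"C7H6O3"}
        assert cons.formulas[parse_formula("C7H6O3")] == pytest.approx(3.0)
        assert cons.replicate_overlap == pytest.approx(1 / 3)

    def test_consensus_identity_on_identical_replicates(self):
        reps = self._sets({"C7H6O3": 2.0}, {"C7H6O3": 2.0}, {"C7H6O3": 2.0})
        cons = replicate_consensus(reps)
        assert cons.formulas[parse_formula("C7H6O3")] == pytest.approx(2.0)
        assert cons.replicate_overlap == 1.0

    def test_consensus_order_independent(self):
        reps = self._sets({"C7H6O3": 1.0, "C6H6O": 2.0},
                          {"C7H6O3": 3.0},
                          {"C7H6O3": 5.0, "C7H5ClO3": 1.0})
        a = replicate_consensus(reps)
        b = replicate_consensus(list(reversed(reps)))
        assert dict(a.formulas) == dict(b.formulas)

    def test_min_replicates_relaxation(self):
        reps = self._sets({"C7H6O3": 1.0, "C6H6O": 2.0}, {"C7H6O3": 3.0})
        cons = replicate_consensus(reps, min_replicates=1)
        assert len(cons) == 2

    def test_empty_replicates_error(self):
        with pytest.raises(ValueError):
            replicate_consensus([])

    def test_consensus_matches_truth_intersection(self, study_config,
                                                  small_synthetic):
        cfg, formulas, _, _, peaklists, truth = small_synthetic
        per_rep = [assign_peaklist(pl, study_config) for pl in peaklists]
        cons = replicate_consensus(per_rep)
        mono = truth[truth.role == "monoisotopic"]
        surviving = None
        for rep in range(cfg.n_replicates):
            present = set(mono[mono.replicate == rep].formula)
            surviving = present if surviving is None else surviving & present
        got = {format_formula(f) for f in cons.formulas}
        # every truth-intersection formula must be recovered; spurious
        # consensus formulas would need the same contaminant in all replicates
        assert surviving <= got
        assert len(got - surviving) <= 1
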