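"""Coverage reports, enzyme comparisons, type calls, boundary histograms."""

import numpy as np
import pytest

from splicepep import (
    JunctionIndex,
    boundary_distance_histogram,
    classify_kr_junctions,
    classify_peptides,
    collapse_unique,
    compare_enzymes,
    coverage_report,
    digest,
    digest_transcripts,
    get_enzyme,
    project_to_genome,
    type_ratio_summary,
)
from splicepep.detectability import CoverageReport, annotation_fingerprint
from splicepep.digestion import PeptideRecord, unique_representatives
from splicepep.simulate import SyntheticConfig, simulate_observed_peptides

from conftest import make_pipeline


@pytest.fixture(scope="module")
def toy():
    return make_pipeline(SyntheticConfig(n_genes=12, p_boundary_kr=0.5, seed=31))


def brute_force_coverage(peps, jcts, cts, min_acceptor=3, min_donor=1):
    """Exhaustive recount over genomic positions and junctions."""
    reps = unique_representatives(peps)
    cds = set()
    for ct in cts:
        for s, e in ct.model.coding_segments():
            cds.update(range(s, e))
    covered = set()
    for r in reps:
        for s, e in r.blocks:
            covered.update(range(s, e))
    detectable = set()
    for j in jcts:
        for r in reps:
            cov = r.junction_coverage.get(j.key)
            if cov and cov[1] >= min_acceptor and cov[0] >= min_donor:
                detectable.add(j.key)
                break
    return len(covered & cds) / len(cds), detectable


class TestCoverageReport:
    def test_matches_exhaustive_recount(self, toy):
        _, cts, jcts = toy
        peps = collapse_unique(digest_transcripts(cts, get_enzyme("trypsin")))
        rep = coverage_report(peps, jcts, cts, enzyme_name="trypsin")
        cds_cov, detectable = brute_force_coverage(peps, jcts, cts)
        assert rep.cds_coverage == pytest.approx(cds_cov)
        assert rep.detectable_keys == detectable
        kr_keys = {j.key for j in classify_kr_junctions(jcts).kr}
        assert rep.detectable_kr_keys == detectable & kr_keys

    def test_single_nt_acceptor_not_detectable(self, twoexon_plus):
        """A junction whose only spanning peptide covers 1 acceptor nt
        (type-4 geometry) is excluded."""
        from splicepep import build_coding_transcript, enumerate_junctions

        genome, model = twoexon_plus
        ct = build_coding_transcript(model, genome)
        jcts = enumerate_junctions([ct])
        pep = project_to_genome(
            PeptideRecord(sequence="MK", start_res=0, end_res=2), ct)
        pep.unique_genomic = True
        rep = coverage_report([pep], jcts, [ct])
        assert rep.n_detectable_junctions == 0
        rep2 = coverage_report([pep], jcts, [ct], min_acceptor_nt=1)
        assert rep2.n_detectable_junctions == 1

    def test_wide_coverage_detectable(self, toy):
        _, cts, jcts = toy
        ct = next(c for c in cts if len(c.segments()) >= 2)
        cum = ct.junction_offsets()[0]
        # peptide with 4 residues on each side of the first junction
        s = cum // 3 - 4 if cum % 3 == 0 else (cum - cum % 3) // 3 - 3
        e = s + 8
        pep = project_to_genome(
            PeptideRecord(sequence=ct.protein[s:e], start_res=s, end_res=e), ct)
        pep.unique_genomic = True
        rep = coverage_report([pep], jcts, cts)
        assert rep.n_detectable_junctions == 1

    def test_empty_peptides_zero_coverage(self, toy):
        _, cts, jcts = toy
        rep = coverage_report([], jcts, cts)
        assert rep.cds_coverage == 0.0 and rep.n_detectable_junctions == 0

    def test_detectable_sets_monotone_in_filters(self, toy):
        """Relaxing the length window or missed-cleavage budget never
        shrinks the detectable set."""
        _, cts, jcts = toy
        tr = get_enzyme("trypsin")
        base = coverage_report(
            collapse_unique(digest_transcripts(cts, tr, 8, 25, 0)),
            jcts, cts)
        longer = coverage_report(
            collapse_unique(digest_transcripts(cts, tr, 8, 40, 0)),
            jcts, cts)
        missed = coverage_report(
            collapse_unique(digest_transcripts(cts, tr, 8, 25, 2)),
            jcts, cts)
        assert base.detectable_keys <= longer.detectable_keys
        assert base.detectable_keys <= missed.detectable_keys


class TestCompareEnzymes:
    def _rep(self, name, keys, fp="f"):
        return CoverageReport(enzyme=name, cds_coverage=0, n_junctions=10,
                              n_detectable_junctions=len(keys),
                              n_kr_junctions=0, n_detectable_kr=0,
                              detectable_keys=set(keys), fingerprint=fp)

    def test_identical_sets(self):
        out = compare_enzymes([self._rep("a", {1, 2}), self._rep("b", {1, 2})])
        assert out["union"] == out["intersection"] == 2

    def test_disjoint_sets(self):
        out = compare_enzymes([self._rep("a", {1, 2, 3}),
                               self._rep("b", {4, 5, 6, 7})])
        assert out["union"] == 7 and out["intersection"] == 0
        assert out["exclusive_regions"] == {"a": 3, "b": 4, "a&b": 0}

    def test_three_way_regions_match_enumeration(self):
        sets = {"a": set(range(0, 10)), "b": set(range(5, 15)),
                "c": set(range(8, 12))}
        out = compare_enzymes([self._rep(n, s) for n, s in sets.items()])
        regions = out["exclusive_regions"]
        # brute-force region counts
        from itertools import product

        expect = {}
        universe = set().union(*sets.values())
        for x in universe:
            member = tuple(n for n in "abc" if x in sets[n])
            expect["&".join(member)] = expect.get("&".join(member), 0) + 1
        for k, v in expect.items():
            assert regions[k] == v
        assert out["union"] == len(universe)

    def test_fingerprint_mismatch_error(self):
        with pytest.raises(ValueError, match="fingerprint"):
            compare_enzymes([self._rep("a", {1}, "x"), self._rep("b", {1}, "y")])

    def test_single_run_error(self):
        with pytest.raises(ValueError):
            compare_enzymes([self._rep("a", {1})])


@pytest.fixture(scope="module")
def scenario1():
    """Every junction phase 0 with a K boundary: trypsin cleaves at
    the splice site, yielding type-3 / type-1 product pairs."""
    return make_pipeline(
        SyntheticConfig(n_genes=25, p_boundary_kr=1.0,
                        phase_weights=(1.0, 0.0, 0.0),
                        kr_codons=("AAA", "AAG"), seed=41))


class TestClassifyTypes:

    def test_junction_adjacent_products_typed_3_then_1(self, scenario1):
        syn, cts, jcts = scenario1
        index = JunctionIndex(jcts)
        tr = get_enzyme("trypsin")
        by_id = {ct.transcript_id: ct for ct in cts}
        checked = 0
        for ct in cts:
            peps = [project_to_genome(r, ct)
                    for r in digest(ct.protein, tr, 0)]
            for p in peps:
                p.unique_genomic = True
            for cum in ct.junction_offsets():
                b = (cum - 1) // 3
                if b + 1 < len(ct.protein) and ct.protein[b + 1] == "P":
                    continue  # proline suppression: no cut at this junction
                left = [p for p in peps if p.end_res == b + 1]
                right = [p for p in peps if p.start_res == b + 1]
                assert left and right
                lcall = classify_peptides(left, index)
                rcall = classify_peptides(right, index)
                assert any(c.type == 3 for c in lcall)
                assert any(c.type == 1 for c in rcall)
                checked += 1
        assert checked > 30

    def test_type4_single_acceptor_nt(self, twoexon_plus):
        from splicepep import build_coding_transcript, enumerate_junctions

        genome, model = twoexon_plus
        ct = build_coding_transcript(model, genome)
        index = JunctionIndex(enumerate_junctions([ct]))
        pep = project_to_genome(
            PeptideRecord(sequence="MK", start_res=0, end_res=2), ct)
        pep.unique_genomic = True
        calls = classify_peptides([pep], index)
        assert any(c.type == 4 for c in calls)

    def test_ambiguous_peptides_skipped(self, toy, caplog):
        _, cts, jcts = toy
        index = JunctionIndex(jcts)
        bad = PeptideRecord(sequence="AAAA", unique_genomic=False)
        with caplog.at_level("WARNING"):
            assert classify_peptides([bad], index) == []

    def test_type_counts_equal_histogram_cells(self, syn_mid):
        """Types 1-4 and the boundary histograms agree cell by cell."""
        syn, cts, jcts = syn_mid
        index = JunctionIndex(jcts)
        obs = simulate_observed_peptides(
            cts, get_enzyme("trypsin"),
            lambda n: 1.0 if 8 <= n <= 25 else 0.0, seed=1)
        calls = classify_peptides(obs, index)
        summary = type_ratio_summary(calls)
        h = boundary_distance_histogram(obs, index)
        assert summary["counts"][1] == int(h["starts_vs_acceptor"].counts[0])
        assert summary["counts"][2] == int(h["starts_vs_acceptor"].counts[1])
        assert summary["counts"][3] == int(h["ends_vs_donor"].counts[0])
        assert summary["counts"][4] == int(
            h["junction_ends_vs_acceptor_start"].counts[0])
        assert summary["counts"][1] > 0 and summary["counts"][3] > 0


class TestTypeRatioSummary:
    def test_zero_calls(self):
        s = type_ratio_summary([])
        assert s["summed_ratio"] == 0.0

    def test_fraction_arithmetic(self):
        from splicepep.detectability import PeptideTypeCall

        calls = [PeptideTypeCall(f"p{i}", 0, -1) for i in range(18)]
        calls += [PeptideTypeCall("q1", 1, 0), PeptideTypeCall("q2", 1, 0)]
        s = type_ratio_summary(calls)
        assert s["n_peptides"] == 20
        assert s["fractions"][1] == pytest.approx(0.10)


class TestBoundaryHistogram:
    def test_all_starts_at_offset_zero(self, syn_mid):
        """Tryptic peptides of a K/R-boundary-rich genome pile up at
        offset 0; the z-test flags it."""
        _, cts, jcts = syn_mid
        index = JunctionIndex(jcts)
        obs = simulate_observed_peptides(
            cts, get_enzyme("trypsin"),
            lambda n: 1.0 if 8 <= n <= 25 else 0.0, seed=2)
        h = boundary_distance_histogram(obs, index)["starts_vs_acceptor"]
        assert h.counts[0] == h.counts.max()
        assert h.p[0] < 1e-6

    def test_enrichment_enzyme_dependent(self, syn_mid):
        """Trypsin enriches boundary offsets on a K/R-biased genome;
        chymotrypsin does not."""
        _, cts, jcts = syn_mid
        index = JunctionIndex(jcts)
        model = lambda n: 1.0 if 8 <= n <= 25 else 0.0
        tryp = boundary_distance_histogram(
            simulate_observed_peptides(cts, get_enzyme("trypsin"), model, 3),
            index)
        chym = boundary_distance_histogram(
            simulate_observed_peptides(cts, get_enzyme("chymotrypsin"), model, 3),
            index)
        assert tryp["starts_vs_acceptor"].p[0] < 0.05
        assert tryp["ends_vs_donor"].p[0] < 0.05
        assert tryp["junction_ends_vs_acceptor_start"].p[0] < 0.05
        assert chym["starts_vs_acceptor"].p[0] > 0.05

    def test_structural_rule_trypsin_proline(self, syn_mid):
        """With the default trypsin preset at zero missed cleavages, every
        detectable K/R junction's boundary residue is followed by
        proline (the suppressed site that lets a peptide span)."""
        _, cts, jcts = syn_mid
        peps = collapse_unique(digest_transcripts(cts, get_enzyme("trypsin")))
        rep = coverage_report(peps, jcts, cts)
        by_key = {}
        from splicepep import iter_junction_occurrences

        by_id = {ct.transcript_id: ct for ct in cts}
        for j in iter_junction_occurrences(cts):
            by_key.setdefault(j.key, j)
        assert rep.detectable_kr_keys  # the rule must actually be exercised
        for key in rep.detectable_kr_keys:
            j = by_key[key]
            ct = by_id[j.transcript_id]
            cum = dict(zip([jj.key for jj in iter_junction_occurrences([ct])],
                           ct.junction_offsets()))[key]
            b = (cum - 1) // 3
            assert ct.protein[b] in "KR"
            assert ct.protein[b + 1] == "P"
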