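"""Redundancy clustering, full-length calls, polymorphism filter, motif
scan, naming and the funnel report."""

import re

import networkx as nx
import pytest

from aphidmine.align import align_strings, translated_search
from aphidmine.records import ESTRecord, ProteinRecord
from aphidmine.selection import (
    CandidateEffector,
    PipelineConfig,
    assess_full_length,
    build_funnel_report,
    cluster_redundant,
    flag_gut_matches,
    name_candidates,
    polymorphism_filter,
    redundancy_edge,
    scan_csp_motif,
)
from aphidmine.simulate import back_translate

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, pid, length=120):
    return ProteinRecord(id=pid, seq="M" + "".join(rng.choice(AA20, size=length - 1)))


def mutated(protein, pid, positions, to="W"):
    seq = list(protein.seq)
    for pos in positions:
        seq[pos] = to if seq[pos] != to else "Y"
    return ProteinRecord(id=pid, seq="".join(seq))


class TestClusterRedundant:
    def test_identical_pair_is_one_cluster(self, rng):
        a = random_protein(rng, "a", 100)
        b = ProteinRecord(id="b", seq=a.seq)
        (cluster,) = cluster_redundant([a, b])
        assert {m.id for m in cluster.members} == {"a", "b"}
        # equal lengths: lexicographically smaller id is representative
        assert cluster.representative.id == "a"

    def test_unrelated_pair_stays_apart(self, rng):
        a, b = random_protein(rng, "a"), random_protein(rng, "b")
        clusters = cluster_redundant([a, b])
        assert len(clusters) == 2

    def test_single_linkage_chain_matches_graph_oracle(self, rng):
        # a~b and b~c but a!~c: single linkage joins all three
        a = random_protein(rng, "a", 150)
        # interior substitutions spread out so trimming cannot hide them
        b = mutated(a, "b", [20, 45, 70, 95, 120])    # ~96.7% identity to a
        c = mutated(b, "c", [30, 55, 80, 105, 130])   # ~96.7% to b, ~93% to a
        proteins = [a, b, c]
        clusters = cluster_redundant(proteins)
        # independent oracle: explicit connected components on the pair graph
        g = nx.Graph()
        g.add_nodes_from(p.id for p in proteins)
        for i, p in enumerate(proteins):
            for q in proteins[i + 1:]:
                res = align_strings(p.id, p.seq, q.id, q.seq)
                if redundancy_edge(res, len(p), len(q)):
                    g.add_edge(p.id, q.id)
        assert not g.has_edge("a", "c") and g.has_edge("a", "b")
        expected = {frozenset(comp) for comp in nx.connected_components(g)}
        got = {frozenset(m.id for m in cl.members) for cl in clusters}
        assert got == expected == {frozenset({"a", "b", "c"})}

    def test_clusters_partition_input(self, rng):
        proteins = [random_protein(rng, f"p{i}", int(rng.integers(80, 140)))
                    for i in range(8)]
        proteins += [mutated(proteins[0], "p0b", [5]),
                     mutated(proteins[3], "p3b", [9])]
        clusters = cluster_redundant(proteins)
        ids = [m.id for cl in clusters for m in cl.members]
        assert sorted(ids) == sorted(p.id for p in proteins)
        for cl in clusters:
            assert cl.representative.id in {m.id for m in cl.members}

    def test_representatives_are_mutually_nonredundant(self, rng):
        proteins = [random_protein(rng, f"p{i}") for i in range(6)]
        proteins.append(mutated(proteins[0], "p0b", [3]))
        reps = [cl.representative for cl in cluster_redundant(proteins)]
        for i, p in enumerate(reps):
            for q in reps[i + 1:]:
                res = align_strings(p.id, p.seq, q.id, q.seq)
                assert not redundancy_edge(res, len(p), len(q))

    def test_longest_member_is_representative(self, rng):
        a = random_protein(rng, "long", 130)
        short = ProteinRecord(id="short", seq=a.seq[:100])
        (cluster,) = cluster_redundant([short, a])
        assert cluster.representative.id == "long"


class TestCspMotif:
    def test_constructed_motif_at_offset(self):
        motif = "C" + "A" * 6 + "C" + "A" * 18 + "C" + "A" * 2 + "C"
        seq = "D" * 10 + motif + "D" * 5
        assert scan_csp_motif(seq) == 11
        assert scan_csp_motif(seq, all_occurrences=True) == (11,)

    def test_three_cysteines_do_not_match(self):
        assert scan_csp_motif("C" + "A" * 6 + "C" + "A" * 18 + "C" + "A" * 10) is None

    def test_matches_regex_oracle(self, rng):
        pattern = re.compile(r"(?=(C.{6}C.{18}C.{2}C))", re.S)
        pool = list("CADEG")  # cysteine-rich so matches actually occur
        n_matched = 0
        for _ in range(1000):
            seq = "".join(rng.choice(pool, size=int(rng.integers(30, 90))))
            expected = tuple(m.start() + 1 for m in pattern.finditer(seq))
            assert scan_csp_motif(seq, all_occurrences=True) == expected
            assert scan_csp_motif(seq) == (expected[0] if expected else None)
            n_matched += bool(expected)
        assert n_matched > 10  # the oracle comparison was not vacuous


def _make_candidate(protein, species="mp"):
    from aphidmine.secretion import MatureProtein, SignalPeptideCall, TopologyCall
    call = SignalPeptideCall(protein_id=protein.id, score=0.95, cleavage_site=1,
                             source="parsed_report")
    return CandidateEffector(
        protein=protein,
        mature=MatureProtein(protein_id=protein.id, full_seq=protein.seq,
                             cleavage_site=1, mature_seq=protein.seq[1:]),
        sp_call=call,
        topology=TopologyCall(protein_id=protein.id, tm_segments=(),
                              has_tm_in_mature=False),
        species=species)


class TestFullLength:
    def _est_for(self, aa, utr5=30, utr3=45, rng=None, prefix_aa=""):
        # in-frame stop right before the start keeps criterion 2 honest
        import numpy as np
        r = rng or np.random.default_rng(7)
        utr = "".join(r.choice(list("ACGT"), size=utr5)) + "TAA"
        return (utr + back_translate(prefix_aa + aa) + "TAA"
                + "".join(r.choice(list("ACGT"), size=utr3)))

    def test_start_stop_conserved_by_redundant_ests(self, rng):
        protein = random_protein(rng, "cand", 90)
        ests = [ESTRecord(id=f"e{i}", seq=self._est_for(protein.seq, rng=rng))
                for i in range(3)]
        hits = [translated_search(protein, e) for e in ests]
        call = assess_full_length(protein, hits, [])
        assert call.criterion1_start_stop
        assert call.criterion2_no_upstream_met
        assert call.is_full_length

    def test_upstream_met_breaks_criterion2(self, rng):
        protein = random_protein(rng, "cand", 90)
        # supporting read encodes Met five codons upstream, in frame
        est = ESTRecord(id="up", seq=self._est_for(
            protein.seq, rng=rng, prefix_aa="MDDDD"))
        hits = [translated_search(protein, est)]
        call = assess_full_length(protein, hits, [])
        assert not call.criterion2_no_upstream_met

    def test_truncated_support_fails_criterion1(self, rng):
        protein = random_protein(rng, "cand", 90)
        full = self._est_for(protein.seq, rng=rng)
        ests = [ESTRecord(id=f"t{i}", seq=full[60:]) for i in range(3)]
        hits = [translated_search(protein, e) for e in ests]
        call = assess_full_length(protein, hits, [])
        assert not call.criterion1_start_stop

    def test_no_hits_means_not_full_length(self, rng):
        protein = random_protein(rng, "cand", 90)
        call = assess_full_length(protein, [], [])
        assert call == call.__class__(protein_id="cand",
                                      criterion1_start_stop=False,
                                      criterion2_no_upstream_met=True,
                                      criterion3_ortholog_support=False,
                                      is_full_length=False) or not call.is_full_length

    def test_ortholog_support_route(self, rng):
        config = PipelineConfig(fulllength_rule="c1_or_c2c3")
        protein = random_protein(rng, "cand", 90)
        ortholog = mutated(protein, "orth", range(10, 22))
        orth_hits = [align_strings(protein.id, protein.seq, "orth", ortholog.seq)]
        call = assess_full_length(protein, [], orth_hits, config)
        assert call.criterion3_ortholog_support
        assert call.is_full_length  # c2 (vacuous) and c3


class TestPolymorphismFilter:
    def _hits(self, protein, variants, rng):
        ests = [ESTRecord(id=f"v{i}", seq=back_translate(v.seq) + "TAA")
                for i, v in enumerate(variants)]
        return [translated_search(protein, e) for e in ests]

    def test_monomorphic_with_conserved_ortholog_is_dropped(self, rng):
        protein = random_protein(rng, "cand", 100)
        cand = _make_candidate(protein)
        hits = self._hits(protein, [protein, protein], rng)
        orth = mutated(protein, "ap", [50])  # exactly one mature difference
        ap_best = align_strings("m", cand.mature.mature_seq, "ap", orth.seq[1:])
        keep, reason = polymorphism_filter(cand, hits, ap_best)
        assert not keep and reason == "monomorphic_conserved_ortholog"

    def test_two_ortholog_differences_keep(self, rng):
        protein = random_protein(rng, "cand", 100)
        cand = _make_candidate(protein)
        hits = self._hits(protein, [protein, protein], rng)
        orth = mutated(protein, "ap", [50, 60])
        ap_best = align_strings("m", cand.mature.mature_seq, "ap", orth.seq[1:])
        keep, reason = polymorphism_filter(cand, hits, ap_best)
        assert keep and reason == "ortholog_diverged"

    def test_same_species_variation_keeps(self, rng):
        protein = random_protein(rng, "cand", 100)
        cand = _make_candidate(protein)
        variant = mutated(protein, "var", [40, 70])
        hits = self._hits(protein, [protein, variant], rng)
        keep, reason = polymorphism_filter(cand, hits, None)
        assert keep and reason == "same_species_variation"

    def test_monomorphic_without_ortholog_is_dropped(self, rng):
        protein = random_protein(rng, "cand", 100)
        cand = _make_candidate(protein)
        hits = self._hits(protein, [protein], rng)
        keep, reason = polymorphism_filter(cand, hits, None)
        assert not keep and reason == "monomorphic_no_ortholog"


class TestGutFlags:
    def test_implanted_candidate_is_flagged_and_order_invariant(self, rng):
        protein = random_protein(rng, "cand", 90)
        cand = _make_candidate(protein)
        gut_hit = ESTRecord(id="g1", seq=back_translate(protein.seq) + "TAA",
                            species="mp", tissue="gut")
        noise = [ESTRecord(id=f"n{i}",
                           seq="".join(rng.choice(list("ACGT"), size=300)),
                           species="mp", tissue="gut") for i in range(4)]
        flags_fwd = flag_gut_matches([cand], [gut_hit] + noise)
        flags_rev = flag_gut_matches([cand], noise + [gut_hit])
        assert flags_fwd == flags_rev == [True]

    def test_absent_candidate_not_flagged(self, rng):
        cand = _make_candidate(random_protein(rng, "cand", 90))
        noise = [ESTRecord(id=f"n{i}",
                           seq="".join(rng.choice(list("ACGT"), size=300)))
                 for i in range(4)]
        assert flag_gut_matches([cand], noise) == [False]


class TestNamingAndFunnel:
    def test_serial_names_per_species(self, rng):
        cands = [_make_candidate(random_protein(rng, f"p{i}"), "mp")
                 for i in range(3)]
        cands.append(_make_candidate(random_protein(rng, "q0"), "ap"))
        names = name_candidates(cands)
        assert names == ["Mp1", "Mp2", "Mp3", "Ap1"]

    def test_legacy_names_are_honoured(self, rng):
        cands = [_make_candidate(random_protein(rng, f"p{i}"), "mp")
                 for i in range(3)]
        names = name_candidates(cands, legacy_names={"p1": "MpC002"})
        assert names == ["Mp1", "MpC002", "Mp2"]

    def test_funnel_report_roundtrip_and_validation(self):
        counts = dict(ests_in=100, orfs_called=150,
                      with_signal_peptide_nonredundant=20, with_tm_removed=17,
                      predicted_secreted=17, full_length=9,
                      after_polymorphism_filter=8, added_cross_species=10,
                      final_candidates=10)
        report = build_funnel_report(counts)
        assert report.as_dict() == counts
        assert "ests_in" in report.to_text()
        with pytest.raises(ValueError, match="missing funnel stages"):
            build_funnel_report({"ests_in": 1})
        bad = dict(counts, predicted_secreted=25)  # filter stage increased
        with pytest.raises(ValueError, match="increased"):
            build_funnel_report(bad)
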