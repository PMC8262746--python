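import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protfun.errors import CycleError, FormatError, UnknownClassError
from protfun.ontology import (AnnotationCorpus, EvidenceRecord,
                              EXPERIMENTAL_EVIDENCE_CODES, OntologyGraph,
                              closure, filter_experimental,
                              information_content, parse_obo,
                              propagate_annotations, read_annotations,
                              select_terms, write_obo)

from _oracles import random_parent_map, reachable_up

FOUR_TERM_OBO = """\
format-version: 1.2

[Term]
id: R
name: root
namespace: molecular_function

[Term]
id: A
name: a
namespace: molecular_function
is_a: R

[Term]
id: B
name: b
namespace: molecular_function
is_a: A

[Term]
id: C
name: c
namespace: molecular_function
is_a: A
"""


def _graph(parents):
    return OntologyGraph({c: {(p, "is_a") for p in ps}
                          for c, ps in parents.items()})


class TestParseObo:
    def test_four_term_fixture(self):
        g = parse_obo(io.StringIO(FOUR_TERM_OBO))
        assert g.classes == {"R", "A", "B", "C"}
        assert g.parents_of("B") == {"A"}
        assert g.roots == {"molecular_function": "R"}
        assert g.name_of("A") == "a"

    def test_obsolete_term_excluded(self):
        obo = FOUR_TERM_OBO + "\n[Term]\nid: X\nname: gone\nis_obsolete: true\n"
        g = parse_obo(io.StringIO(obo))
        assert "X" in g.obsolete and "X" not in g.classes

    def test_cycle_rejected_naming_members(self):
        obo = ("format-version: 1.2\n\n[Term]\nid: A\nname: a\nis_a: B\n\n"
               "[Term]\nid: B\nname: b\nis_a: A\n")
        with pytest.raises(CycleError) as exc:
            parse_obo(io.StringIO(obo))
        assert {"A", "B"} <= set(exc.value.cycle)

    def test_dangling_parent_rejected(self):
        obo = "format-version: 1.2\n\n[Term]\nid: A\nname: a\nis_a: ZZZ\n"
        with pytest.raises(FormatError, match="ZZZ"):
            parse_obo(io.StringIO(obo))

    def test_part_of_relationship_and_alt_id(self):
        obo = (FOUR_TERM_OBO
               + "\n[Term]\nid: P\nname: p\nnamespace: molecular_function\n"
                 "alt_id: P_OLD\nrelationship: part_of A\n")
        g = parse_obo(io.StringIO(obo))
        assert g.parents["P"] == {("A", "part_of")}
        assert g.resolve("P_OLD") == "P"

    def test_write_read_round_trip(self):
        g = parse_obo(io.StringIO(FOUR_TERM_OBO))
        buf = io.StringIO()
        write_obo(g, buf)
        buf.seek(0)
        g2 = parse_obo(buf)
        assert g2.classes == g.classes
        assert g2.parents == g.parents
        assert g2.namespace == g.namespace


class TestClosure:
    def test_chain_ancestors(self, chain_graph):
        assert closure(chain_graph, "C", "up") == {"A", "R"}

    def test_root_has_no_ancestors(self, chain_graph):
        assert closure(chain_graph, "R", "up") == set()

    def test_down_direction(self, chain_graph):
        assert closure(chain_graph, "R", "down") == {"A", "C"}

    def test_unknown_class_named(self, chain_graph):
        with pytest.raises(UnknownClassError, match="NOPE"):
            closure(chain_graph, "NOPE", "up")

    def test_diamond_matches_path_enumeration(self, diamond_graph):
        assert closure(diamond_graph, "D", "up") == {"B", "C", "A"}

    def test_matches_bruteforce_on_random_dags(self, rng):
        """Closure equals explicit path enumeration on all small DAGs."""
        for _ in range(50):
            parents = random_parent_map(rng, int(rng.integers(2, 9)))
            g = _graph(parents)
            for node in parents:
                assert g.ancestors(node) == reachable_up(parents, node)


class TestEvidenceFilter:
    def test_experimental_codes_kept_iea_dropped(self):
        recs = [EvidenceRecord("p", "A", c) for c in ("IDA", "IEA", "TAS")]
        kept = filter_experimental(recs)
        assert [r.evidence for r in kept] == ["IDA", "TAS"]

    def test_empty_input(self):
        assert filter_experimental([]) == []

    def test_all_rejected(self):
        recs = [EvidenceRecord("p", "A", "IEA")] * 3
        assert filter_experimental(recs) == []

    def test_thirteen_default_codes(self):
        assert len(EXPERIMENTAL_EVIDENCE_CODES) == 13
        assert "IEA" not in EXPERIMENTAL_EVIDENCE_CODES


class TestPropagation:
    def test_chain_closure(self, chain_graph):
        corpus = propagate_annotations(chain_graph, {"p1": {"C"}})
        assert corpus.annotations["p1"] == {"C", "A", "R"}

    def test_diamond_matches_bruteforce(self, diamond_graph):
        corpus = propagate_annotations(diamond_graph, {"p": {"D"}})
        assert corpus.annotations["p"] == {"D", "B", "C", "A"}

    def test_unresolvable_names_protein_and_class(self, chain_graph):
        with pytest.raises(UnknownClassError, match="p1"):
            propagate_annotations(chain_graph, {"p1": {"MISSING"}})

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_idempotent_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        parents = random_parent_map(rng, int(rng.integers(2, 30)))
        g = _graph(parents)
        nodes = sorted(parents)
        raw = {f"p{i}": {nodes[j] for j in
                         rng.choice(len(nodes),
                                    size=int(rng.integers(1, 4)),
                                    replace=False)}
               for i in range(5)}
        once = propagate_annotations(g, raw)
        twice = propagate_annotations(g, once.annotations)
        assert once.annotations == twice.annotations

    def test_parent_counts_monotone(self, rng):
        """Propagated count of a parent >= that of each child, every edge."""
        parents = random_parent_map(rng, 20)
        g = _graph(parents)
        nodes = sorted(parents)
        raw = {f"p{i}": {nodes[int(rng.integers(len(nodes)))]}
               for i in range(30)}
        counts = propagate_annotations(g, raw).counts()
        for child, ps in parents.items():
            for parent in ps:
                assert counts.get(parent, 0) >= counts.get(child, 0)


class TestSelectTerms:
    def test_min_count_boundary(self):
        annotations = {f"p{i}": frozenset({"A"} | ({"B"} if i else set()))
                       for i in range(50)}
        corpus = AnnotationCorpus(annotations)
        assert select_terms(corpus, 50) == ["A"]  # B has only 49

    def test_min_count_one_keeps_everything(self):
        corpus = AnnotationCorpus({"p": frozenset({"A", "B"})})
        assert select_terms(corpus, 1) == ["A", "B"]

    def test_matches_direct_counting(self, rng):
        classes = [f"c{i}" for i in range(6)]
        annotations = {
            f"p{i}": frozenset(
                classes[j] for j in rng.choice(6, size=3, replace=False))
            for i in range(10)
        }
        corpus = AnnotationCorpus(annotations)
        expected = sorted(
            c for c in classes
            if sum(c in s for s in annotations.values()) >= 3)
        assert select_terms(corpus, 3) == expected


class TestInformationContent:
    def test_root_ic_zero(self, chain_graph):
        corpus = propagate_annotations(chain_graph,
                                       {"p1": {"C"}, "p2": {"A"}})
        ic = information_content(chain_graph, corpus)
        assert ic["R"] == 0.0

    def test_conditional_probability_hand_value(self, chain_graph):
        # parent A in 4 proteins, child C in 1 of them -> IC = -log2(1/4) = 2
        raw = {"p1": {"C"}, "p2": {"A"}, "p3": {"A"}, "p4": {"A"}}
        corpus = propagate_annotations(chain_graph, raw)
        ic = information_content(chain_graph, corpus, log_base=2)
        assert ic["C"] == pytest.approx(2.0)

    def test_nonnegative_everywhere(self, rng):
        parents = random_parent_map(rng, 12)
        g = _graph(parents)
        nodes = sorted(parents)
        raw = {f"p{i}": {nodes[int(rng.integers(len(nodes)))]}
               for i in range(15)}
        ic = information_content(g, propagate_annotations(g, raw))
        assert all(v >= 0 for v in ic.ic.values())

    def test_natural_log_base(self, chain_graph):
        raw = {"p1": {"C"}, "p2": {"A"}}
        corpus = propagate_annotations(chain_graph, raw)
        ic = information_content(chain_graph, corpus, log_base=math.e)
        assert ic["C"] == pytest.approx(math.log(2))

    def test_empty_corpus_rejected(self, chain_graph):
        from protfun.errors import ProtfunError
        with pytest.raises(ProtfunError):
            information_content(chain_graph, AnnotationCorpus({}))


class TestAnnotationReaders:
    def test_tsv_dialect(self):
        text = "p1\tA\tIDA\np2\tB\tIEA\n"
        recs = read_annotations(io.StringIO(text))
        assert recs == [EvidenceRecord("p1", "A", "IDA"),
                        EvidenceRecord("p2", "B", "IEA")]

    def test_gaf_dialect(self):
        cols = [""] * 17
        cols[1], cols[4], cols[6] = "P12345", "GO:0000001", "IDA"
        text = "!gaf-version: 2.1\n" + "\t".join(cols) + "\n"
        recs = read_annotations(io.StringIO(text))
        assert recs == [EvidenceRecord("P12345", "GO:0000001", "IDA")]

    def test_malformed_tsv_reports_line(self):
        with pytest.raises(FormatError, match="line 2"):
            read_annotations(io.StringIO("p1\tA\tIDA\np2\tB\n"))
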