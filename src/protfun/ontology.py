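"""Gene Ontology–style DAGs, annotation propagation and information content.

The ontology is a directed acyclic graph over class identifiers, split into
namespaces (GO's three sub-hierarchies, or a single synthetic one).  The true
path rule says that a protein annotated with a class is implicitly annotated
with every ancestor of that class, so annotation sets are always propagated
upward before anything else consumes them.

Information content of a class ``c`` is ``IC(c) = -log Pr(c | P(c))`` where
``P(c)`` is the set of parents of ``c``; the conditional probability is
estimated from a propagated annotation corpus as the fraction of proteins
carrying all parents of ``c`` that also carry ``c``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

from .errors import CycleError, FormatError, ProtfunError, UnknownClassError

logger = logging.getLogger(__name__)

#: GAF evidence codes marking experimentally supported annotations.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC", "HTP", "HDA",
     "HMP", "HGI", "HEP"}
)

#: Relations traversed for propagation and consistency by default.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

GO_NAMESPACES = ("molecular_function", "biological_process",
                 "cellular_component")


@dataclass
class EvidenceRecord:
    """One protein → class annotation with its GAF evidence code."""

    protein: str
    term: str
    evidence: str


class OntologyGraph:
    """A validated ontology DAG.

    Parameters
    ----------
    parents
        class → set of ``(parent, relation)`` pairs.  Every class, including
        parentless roots, must appear as a key.
    namespace
        class → namespace label.  Classes missing from the mapping are
        assigned ``default_namespace``.
    names, alt_ids, obsolete
        Optional human-readable names, alias → canonical identifiers, and
        obsolete identifiers (kept out of ``classes``).

    Raises
    ------
    CycleError
        if the parent relation (restricted to ``relations``) has a cycle.
    FormatError
        if an edge references an identifier with no class definition.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[tuple[str, str]]],
        namespace: Mapping[str, str] | None = None,
        names: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
        obsolete: Iterable[str] | None = None,
        default_namespace: str = "molecular_function",
        relations: frozenset[str] = DEFAULT_RELATIONS,
    ):
        self.classes: set[str] = set(parents)
        self.parents: dict[str, set[tuple[str, str]]] = {
            c: set(ps) for c, ps in parents.items()
        }
        self.obsolete: set[str] = set(obsolete or ())
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.names: dict[str, str] = dict(names or {})
        namespace = namespace or {}
        self.namespace: dict[str, str] = {
            c: namespace.get(c, default_namespace) for c in self.classes
        }
        self._relations = relations
        self._validate()
        self.roots: dict[str, str] = self._find_roots()
        self._children: dict[str, set[tuple[str, str]]] | None = None

    # -- construction-time checks -------------------------------------------

    def _validate(self) -> None:
        for child, ps in self.parents.items():
            for parent, _rel in ps:
                if parent not in self.classes:
                    raise FormatError(
                        f"class {child!r} references undefined parent "
                        f"{parent!r}"
                    )
        for alias, canonical in self.alt_ids.items():
            if canonical not in self.classes:
                raise FormatError(
                    f"alt_id {alias!r} maps to undefined class {canonical!r}"
                )
        g = self._digraph(self._relations)
        if not nx.is_directed_acyclic_graph(g):
            cycle_edges = nx.find_cycle(g)
            cycle = [e[0] for e in cycle_edges] + [cycle_edges[-1][1]]
            raise CycleError(cycle)

    def _digraph(self, relations: frozenset[str]) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for child, ps in self.parents.items():
            for parent, rel in ps:
                if rel in relations:
                    g.add_edge(child, parent)
        return g

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for c in self.classes:
            same_ns = [p for p, r in self.parents[c]
                       if r in self._relations
                       and self.namespace[p] == self.namespace[c]]
            if not same_ns:
                ns = self.namespace[c]
                if ns in roots:
                    # multiple parentless classes in one namespace: keep the
                    # lexicographically smallest as the designated root
                    roots[ns] = min(roots[ns], c)
                else:
                    roots[ns] = c
        return roots

    # -- basic queries ------------------------------------------------------

    def resolve(self, identifier: str) -> str:
        """Map an identifier (possibly an alt_id) to its canonical class."""
        if identifier in self.classes:
            return identifier
        if identifier in self.alt_ids:
            canonical = self.alt_ids[identifier]
            logger.debug("alt_id %s resolved to %s", identifier, canonical)
            return canonical
        raise UnknownClassError(identifier)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.classes or identifier in self.alt_ids

    def parents_of(self, term: str,
                   relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        term = self.resolve(term)
        return {p for p, r in self.parents[term] if r in relations}

    def children_of(self, term: str,
                    relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        term = self.resolve(term)
        if self._children is None:
            self._children = {c: set() for c in self.classes}
            for child, ps in self.parents.items():
                for parent, rel in ps:
                    self._children[parent].add((child, rel))
        return {c for c, r in self._children[term] if r in relations}

    def ancestors(self, term: str,
                  relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        """All classes reachable upward from ``term`` (``term`` excluded)."""
        return self._reach(term, relations, up=True)

    def descendants(self, term: str,
                    relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
        """All classes reachable downward from ``term`` (``term`` excluded)."""
        return self._reach(term, relations, up=False)

    def _reach(self, term: str, relations: frozenset[str], up: bool) -> set[str]:
        seed = self.resolve(term)
        step = self.parents_of if up else self.children_of
        seen: set[str] = set()
        stack = [seed]
        while stack:
            for nxt in step(stack.pop(), relations):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def topological_order(
        self, relations: frozenset[str] = DEFAULT_RELATIONS
    ) -> list[str]:
        """Classes ordered parents-before-children (deterministic)."""
        g = self._digraph(relations).reverse()
        return list(nx.lexicographical_topological_sort(g))

    def name_of(self, term: str) -> str:
        return self.names.get(self.resolve(term), "")


def closure(graph: OntologyGraph, seed: str, direction: str = "up",
            relations: frozenset[str] = DEFAULT_RELATIONS) -> set[str]:
    """Transitive ancestor (``up``) or descendant (``down``) set of ``seed``.

    The seed itself is excluded; for a root, ``closure(root, "up")`` is empty.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if direction == "up":
        return graph.ancestors(seed, relations)
    return graph.descendants(seed, relations)


# ---------------------------------------------------------------------------
# OBO reading / writing


def parse_obo(source: IO[str] | str,
              default_namespace: str = "molecular_function") -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    ``is_a`` lines and ``relationship: part_of`` lines populate the parent
    relation; other relationship types are ignored.  Obsolete terms are
    recorded in ``obsolete`` and excluded from ``classes``.

    Raises :class:`FormatError` for terms referencing undefined parents and
    :class:`CycleError` if the parent relation is cyclic.
    """
    net = obonet.read_obo(source, ignore_obsolete=False)

    obsolete = {n for n, d in net.nodes(data=True)
                if str(d.get("is_obsolete", "")).lower() == "true"}
    defined = {n for n, d in net.nodes(data=True) if "name" in d or d}
    parents: dict[str, set[tuple[str, str]]] = {
        n: set() for n in net.nodes if n not in obsolete
    }
    for child, parent, rel in net.edges(keys=True):
        if rel not in DEFAULT_RELATIONS or child in obsolete:
            continue
        if parent in obsolete or parent not in defined:
            raise FormatError(
                f"term {child!r} references undefined or obsolete parent "
                f"{parent!r}"
            )
        parents[child].add((parent, rel))

    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, data in net.nodes(data=True):
        if node in obsolete:
            continue
        if "namespace" in data:
            namespace[node] = data["namespace"]
        if "name" in data:
            names[node] = data["name"]
        for alias in data.get("alt_id", []):
            alt_ids[alias] = node

    return OntologyGraph(parents, namespace=namespace, names=names,
                         alt_ids=alt_ids, obsolete=obsolete,
                         default_namespace=default_namespace)


def write_obo(graph: OntologyGraph, stream: IO[str]) -> None:
    """Write the graph as an OBO 1.2 flat file (round-trips with parse_obo)."""
    stream.write("format-version: 1.2\nontology: synthetic\n")
    alt_by_class: dict[str, list[str]] = {}
    for alias, canonical in graph.alt_ids.items():
        alt_by_class.setdefault(canonical, []).append(alias)
    for term in sorted(graph.classes):
        stream.write("\n[Term]\n")
        stream.write(f"id: {term}\n")
        stream.write(f"name: {graph.names.get(term, term)}\n")
        stream.write(f"namespace: {graph.namespace[term]}\n")
        for alias in sorted(alt_by_class.get(term, [])):
            stream.write(f"alt_id: {alias}\n")
        for parent, rel in sorted(graph.parents[term]):
            if rel == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {rel} {parent}\n")
    for term in sorted(graph.obsolete):
        stream.write(f"\n[Term]\nid: {term}\nname: obsolete {term}\n"
                     "is_obsolete: true\n")


# ---------------------------------------------------------------------------
# Annotations


@dataclass
class AnnotationCorpus:
    """Protein → propagated class sets, closed under the true path rule."""

    annotations: dict[str, frozenset[str]]
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.proteins:
            self.proteins = list(self.annotations)

    def __len__(self) -> int:
        return len(self.proteins)

    def counts(self) -> Counter[str]:
        """Number of proteins annotated with each class."""
        c: Counter[str] = Counter()
        for p in self.proteins:
            c.update(self.annotations[p])
        return c


def filter_experimental(
    records: Iterable[EvidenceRecord],
    accepted: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> list[EvidenceRecord]:
    """Keep only records with an accepted evidence code (order preserved)."""
    return [r for r in records if r.evidence in accepted]


def propagate_annotations(
    graph: OntologyGraph,
    raw: Mapping[str, Iterable[str]],
    relations: frozenset[str] = DEFAULT_RELATIONS,
) -> AnnotationCorpus:
    """Close each protein's annotation set upward (true path rule).

    alt_ids are resolved to canonical classes; obsolete classes are dropped
    with a warning; unknown classes raise naming the protein and class.
    Idempotent: propagating an already-closed corpus leaves it unchanged.
    """
    annotations: dict[str, frozenset[str]] = {}
    for protein, terms in raw.items():
        closed: set[str] = set()
        for term in terms:
            if term in graph.obsolete:
                logger.warning("dropping obsolete class %s from %s",
                               term, protein)
                continue
            try:
                canonical = graph.resolve(term)
            except UnknownClassError:
                raise UnknownClassError(
                    term, context=f"annotation of protein {protein!r}"
                ) from None
            closed.add(canonical)
            closed |= graph.ancestors(canonical, relations)
        annotations[protein] = frozenset(closed)
    return AnnotationCorpus(annotations, proteins=list(raw))


def select_terms(corpus: AnnotationCorpus, min_count: int,
                 exclude: Iterable[str] = ()) -> list[str]:
    """Prediction vocabulary: classes annotated to ≥ ``min_count`` proteins.

    Returned in lexicographic order for stable column alignment.  Namespace
    roots can be excluded by passing them via ``exclude``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    excluded = set(exclude)
    counts = corpus.counts()
    return sorted(c for c, n in counts.items()
                  if n >= min_count and c not in excluded)


# ---------------------------------------------------------------------------
# Information content


@dataclass
class ICTable:
    """Per-class information content estimated from an annotation corpus."""

    ic: dict[str, float]
    log_base: float
    counts: dict[str, int]

    @property
    def max_ic(self) -> float:
        return max(self.ic.values(), default=0.0)

    def value(self, term: str) -> float:
        """IC of ``term``; unseen classes fall back to the maximum IC."""
        return self.ic.get(term, self.max_ic)

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


def information_content(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    log_base: float = 2.0,
    relations: frozenset[str] = DEFAULT_RELATIONS,
) -> ICTable:
    """Estimate ``IC(c) = -log Pr(c | P(c))`` for every class in the graph.

    ``Pr(c | P(c))`` is the maximum-likelihood estimate ``N(c) / N(P(c))``:
    ``N(c)`` counts proteins annotated with ``c`` and ``N(P(c))`` counts
    proteins annotated with *every* parent of ``c``; for parentless roots
    ``N(P(c))`` is the corpus size.  Classes with ``N(c) = 0`` or
    ``N(P(c)) = 0`` get the maximum observed IC as a fallback.
    """
    if not corpus.proteins:
        raise ProtfunError("cannot estimate information content from an "
                           "empty corpus")
    n_total = len(corpus.proteins)
    counts = corpus.counts()
    sets = [corpus.annotations[p] for p in corpus.proteins]

    log = (lambda x: math.log2(x)) if log_base == 2 else \
        (lambda x: math.log(x) / math.log(log_base))

    ic: dict[str, float] = {}
    fallback: list[str] = []
    for c in sorted(graph.classes):
        n_c = counts.get(c, 0)
        parents = graph.parents_of(c, relations)
        if parents:
            n_parents = sum(1 for s in sets if parents <= s)
        else:
            n_parents = n_total
        if n_c == 0 or n_parents == 0:
            fallback.append(c)
            continue
        ic[c] = max(0.0, -log(n_c / n_parents))

    if fallback:
        top = max(ic.values(), default=0.0)
        logger.info("assigning fallback IC=%.4g to %d unannotated classes",
                    top, len(fallback))
        for c in fallback:
            ic[c] = top
    return ICTable(ic=ic, log_base=log_base, counts=dict(counts))


# ---------------------------------------------------------------------------
# Annotation file readers / writers (GAF 2.x and 3-column TSV)


def read_annotations(stream: IO[str]) -> list[EvidenceRecord]:
    """Read annotations from GAF 2.x or a 3-column TSV, auto-detected.

    GAF lines start with a ``!`` header or carry ≥ 15 tab-separated columns
    (column 2 = protein, 5 = class, 7 = evidence code); the TSV dialect is
    ``protein<TAB>class<TAB>evidence``.
    """
    records: list[EvidenceRecord] = []
    dialect: str | None = None
    for lineno, raw_line in enumerate(stream, start=1):
        line = raw_line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("!"):
            dialect = "gaf"
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if dialect is None:
            dialect = "gaf" if len(fields) >= 15 else "tsv"
        if dialect == "gaf":
            if len(fields) < 15:
                raise FormatError(
                    f"expected >= 15 GAF columns, found {len(fields)}",
                    line=lineno,
                )
            records.append(EvidenceRecord(fields[1], fields[4], fields[6]))
        else:
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 TSV columns, found {len(fields)}",
                    line=lineno,
                )
            records.append(EvidenceRecord(*fields))
    for rec in records:
        if not rec.evidence:
            raise FormatError(
                f"empty evidence code for {rec.protein} / {rec.term}"
            )
    return records


def write_annotations(records: Iterable[EvidenceRecord],
                      stream: IO[str]) -> None:
    """Write records in the 3-column TSV dialect."""
    for rec in records:
        stream.write(f"{rec.protein}\t{rec.term}\t{rec.evidence}\n")


def records_to_raw(records: Iterable[EvidenceRecord]) -> dict[str, set[str]]:
    """Group evidence records into the raw protein → class-set mapping."""
    raw: dict[str, set[str]] = {}
    for rec in records:
        raw.setdefault(rec.protein, set()).add(rec.term)
    return raw
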