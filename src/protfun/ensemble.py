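"""Score combination, hierarchy-consistency post-processing and output.

The final prediction score is the weighted sum

    S = α · S_similarity + (1 − α) · S_cnn,        0 ≤ α ≤ 1,

where α weighs the similarity-transfer component against the CNN.  Because
the two components support different class sets, the sum runs over the
union, with a missing component contributing 0.

The raw scores need not respect the ontology, so a post-processing step
replaces each class's score with the maximum over itself and all its
descendants.  After that, scores decrease monotonically from a class to its
subclasses and each namespace root carries the maximum score of its branch.

A score of 0 means "not predicted": thresholding keeps classes with
``score ≥ t`` (strict ``>`` selectable) among those with positive score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from .errors import ProtfunError
from .ontology import DEFAULT_RELATIONS, OntologyGraph

DEFAULT_ALPHA = 0.5
DEFAULT_THRESHOLD = 0.3


@dataclass
class PredictionMatrix:
    """Per-protein class scores in [0, 1].

    ``provenance`` optionally carries, per protein, the (subject, bitscore)
    hit list behind the similarity component, sorted by decreasing bitscore.
    """

    proteins: list[str]
    scores: dict[str, dict[str, float]]
    provenance: dict[str, list[tuple[str, float]]] = field(
        default_factory=dict)

    @classmethod
    def from_array(cls, proteins: list[str], classes: list[str], array
                   ) -> "PredictionMatrix":
        """Build from a dense (n_proteins × n_classes) score array."""
        scores = {
            p: {c: float(array[i, j]) for j, c in enumerate(classes)}
            for i, p in enumerate(proteins)
        }
        return cls(proteins=list(proteins), scores=scores)

    def classes_of(self, protein: str) -> dict[str, float]:
        return self.scores.get(protein, {})


def combine_scores(cnn: PredictionMatrix, similarity: PredictionMatrix,
                   alpha: float = DEFAULT_ALPHA) -> PredictionMatrix:
    """Weighted sum of the two components over the union of their supports.

    ``alpha`` multiplies the similarity (DIAMOND) term; ``alpha = 1``
    reproduces the similarity scores exactly and ``alpha = 0`` the CNN
    scores.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ProtfunError(f"alpha must be in [0, 1], got {alpha}")
    proteins = list(dict.fromkeys(cnn.proteins + similarity.proteins))
    combined: dict[str, dict[str, float]] = {}
    for p in proteins:
        c_scores = cnn.classes_of(p)
        d_scores = similarity.classes_of(p)
        merged: dict[str, float] = {}
        for term in c_scores.keys() | d_scores.keys():
            merged[term] = (alpha * d_scores.get(term, 0.0)
                            + (1.0 - alpha) * c_scores.get(term, 0.0))
        combined[p] = merged
    provenance = dict(similarity.provenance)
    provenance.update({p: v for p, v in cnn.provenance.items()
                       if p not in provenance})
    return PredictionMatrix(proteins=proteins, scores=combined,
                            provenance=provenance)


def enforce_consistency(graph: OntologyGraph, preds: PredictionMatrix,
                        relations: frozenset[str] = DEFAULT_RELATIONS
                        ) -> PredictionMatrix:
    """Make scores monotone along the hierarchy.

    For every class ``D``, the returned score is the maximum of ``D``'s own
    score and the scores of all subclasses of ``D``; ancestors of scored
    classes that were not scored themselves are filled in.  Computed in one
    reverse-topological pass per protein; idempotent, and never decreases a
    score.
    """
    order = graph.topological_order(relations)  # parents before children
    out: dict[str, dict[str, float]] = {}
    for protein in preds.proteins:
        raw = preds.classes_of(protein)
        for term in raw:
            graph.resolve(term)  # raises UnknownClassError if unresolvable
        val: dict[str, float] = {}
        for term in reversed(order):  # children before parents
            best = raw.get(term, 0.0)
            for child in graph.children_of(term, relations):
                best = max(best, val.get(child, 0.0))
            if best > 0.0:
                val[term] = best
        out[protein] = val
    return PredictionMatrix(proteins=list(preds.proteins), scores=out,
                            provenance=dict(preds.provenance))


def threshold_predictions(preds: PredictionMatrix,
                          t: float = DEFAULT_THRESHOLD,
                          strict: bool = False) -> dict[str, set[str]]:
    """Predicted class sets P_i(t); ``score ≥ t`` by default, ``>`` if strict.

    Zero-score classes are never predicted (0 encodes "absent").
    """
    if not 0.0 <= t <= 1.0:
        raise ProtfunError(f"threshold must be in [0, 1], got {t}")
    keep = (lambda s: s > t) if strict else (lambda s: s >= t)
    return {
        p: {c for c, s in preds.classes_of(p).items() if s > 0.0 and keep(s)}
        for p in preds.proteins
    }


def format_predictions(preds: PredictionMatrix, graph: OntologyGraph,
                       t: float = DEFAULT_THRESHOLD,
                       strict: bool = False) -> list[dict]:
    """Structured report: per protein, per namespace, sorted predictions.

    Within a namespace block, classes are sorted by decreasing score with
    ties broken lexicographically by identifier.  Every namespace present in
    the graph appears, even when empty.  Assumes consistency was enforced.
    """
    kept = threshold_predictions(preds, t, strict=strict)
    namespaces = sorted(set(graph.namespace.values()))
    report = []
    for protein in preds.proteins:
        blocks: dict[str, list[dict]] = {ns: [] for ns in namespaces}
        entries = [(c, preds.scores[protein][c]) for c in kept[protein]]
        for term, score in sorted(entries, key=lambda e: (-e[1], e[0])):
            ns = graph.namespace[graph.resolve(term)]
            blocks[ns].append({
                "go_id": term,
                "name": graph.name_of(term),
                "score": round(score, 6),
            })
        report.append({
            "protein_id": protein,
            "predictions": blocks,
            "similar_proteins": [
                {"id": s, "bitscore": b}
                for s, b in preds.provenance.get(protein, [])
            ],
        })
    return report


def write_predictions_tsv(preds: PredictionMatrix, graph: OntologyGraph,
                          stream: IO[str], t: float = DEFAULT_THRESHOLD,
                          strict: bool = False) -> None:
    """Flat TSV alternative: protein, go_id, namespace, score."""
    for block in format_predictions(preds, graph, t, strict=strict):
        for ns, entries in block["predictions"].items():
            for e in entries:
                stream.write(f"{block['protein_id']}\t{e['go_id']}\t{ns}\t"
                             f"{e['score']:g}\n")


def read_predictions_tsv(stream: IO[str]) -> PredictionMatrix:
    """Read the flat TSV format back into a :class:`PredictionMatrix`."""
    proteins: list[str] = []
    scores: dict[str, dict[str, float]] = {}
    for line in stream:
        if not line.strip() or line.startswith("#"):
            continue
        protein, term, _ns, score = line.rstrip("\n").split("\t")
        if protein not in scores:
            proteins.append(protein)
            scores[protein] = {}
        scores[protein][term] = float(score)
    return PredictionMatrix(proteins=proteins, scores=scores)
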