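"""Sequence-similarity annotation transfer.

Given BLAST/DIAMOND tabular hits for a query protein against an annotated
training set, each annotated class of a hit subject receives a vote weighted
by the alignment bitscore.  The transfer score for class ``f`` of query
``q`` with hit set ``E`` is

    S(q, f) = Σ_{s ∈ E} 1[f ∈ T_s] · bitscore(q, s)  /  Σ_{s ∈ E} bitscore(q, s)

where ``T_s`` is the propagated annotation set of subject ``s``.  Scores lie
in (0, 1]; a class carried by every subject scores exactly 1, and because
``T_s`` is propagated the scores are automatically consistent along the
ontology (parent ≥ child).
"""

from __future__ import annotations

import logging
from typing import IO, Iterable

import pandas as pd

from .errors import FormatError
from .ontology import AnnotationCorpus

logger = logging.getLogger(__name__)

#: BLAST/DIAMOND "outfmt 6" column order.
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DEFAULT_EVALUE_MAX = 0.001


class HitTable:
    """Filtered similarity hits, one row per (query, subject) pair."""

    def __init__(self, frame: pd.DataFrame, evalue_max: float):
        self.frame = frame.reset_index(drop=True)
        self.evalue_max = evalue_max
        self._groups: dict[str, pd.DataFrame] | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def hits_for(self, query: str) -> pd.DataFrame:
        """Rows for ``query`` (empty frame when the query has no hits)."""
        if self._groups is None:
            self._groups = {q: g for q, g in self.frame.groupby("qseqid")}
        empty = self.frame.iloc[0:0]
        return self._groups.get(query, empty)

    @property
    def queries(self) -> list[str]:
        return list(dict.fromkeys(self.frame["qseqid"]))


def parse_hits(stream: IO[str], evalue_max: float = DEFAULT_EVALUE_MAX
               ) -> HitTable:
    """Parse BLAST/DIAMOND tabular output ("outfmt 6").

    Rows with e-value above ``evalue_max`` are dropped; duplicate
    (query, subject) pairs — e.g. multiple HSPs — are collapsed keeping the
    maximum bitscore.  Malformed rows raise with their line number.
    """
    rows = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(OUTFMT6_COLUMNS):
            raise FormatError(
                f"expected {len(OUTFMT6_COLUMNS)} tab-separated columns, "
                f"found {len(fields)}", line=lineno)
        try:
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError:
            raise FormatError(
                f"non-numeric evalue/bitscore {fields[10]!r}/{fields[11]!r}",
                line=lineno) from None
        if bitscore <= 0:
            raise FormatError(f"non-positive bitscore {bitscore}",
                              line=lineno)
        if evalue > evalue_max:
            continue
        rows.append((fields[0], fields[1], bitscore, evalue))

    frame = pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore",
                                        "evalue"])
    frame = (frame.sort_values(["qseqid", "sseqid", "bitscore"])
             .drop_duplicates(["qseqid", "sseqid"], keep="last")
             .sort_index())
    return HitTable(frame, evalue_max=evalue_max)


def write_hits(frame_or_table: HitTable | pd.DataFrame,
               stream: IO[str]) -> None:
    """Write hits back out in the 12-column tabular dialect.

    Alignment-coordinate columns not tracked by :class:`HitTable` are filled
    with placeholder values; query/subject/e-value/bitscore round-trip.
    """
    frame = (frame_or_table.frame
             if isinstance(frame_or_table, HitTable) else frame_or_table)
    for row in frame.itertuples(index=False):
        stream.write(
            f"{row.qseqid}\t{row.sseqid}\t100.0\t0\t0\t0\t0\t0\t0\t0\t"
            f"{row.evalue:g}\t{row.bitscore:g}\n")


def transfer_score(hits: HitTable, corpus: AnnotationCorpus, query: str,
                   exclude_self: bool = True) -> dict[str, float]:
    """Bitscore-weighted annotation transfer for one query protein.

    Subjects missing from the corpus are skipped (logged).  A query with no
    usable hits yields an empty map, not an error.  With ``exclude_self``
    the query's own row (subject == query) is ignored, which prevents label
    leakage when the query is part of the annotated corpus.
    """
    rows = hits.hits_for(query)
    scores: dict[str, float] = {}
    total = 0.0
    for row in rows.itertuples(index=False):
        subject = row.sseqid
        if exclude_self and subject == query:
            continue
        if subject not in corpus.annotations:
            logger.debug("hit subject %s absent from corpus; skipped",
                         subject)
            continue
        total += row.bitscore
        for term in corpus.annotations[subject]:
            scores[term] = scores.get(term, 0.0) + row.bitscore
    if total <= 0:
        if len(rows):
            logger.warning("query %s: no usable hits after filtering", query)
        return {}
    return {term: s / total for term, s in scores.items()}


def transfer_provenance(hits: HitTable, corpus: AnnotationCorpus, query: str,
                        exclude_self: bool = True) -> list[tuple[str, float]]:
    """(subject, bitscore) pairs that contributed votes, best first."""
    rows = hits.hits_for(query)
    pairs = [(r.sseqid, r.bitscore) for r in rows.itertuples(index=False)
             if r.sseqid in corpus.annotations
             and not (exclude_self and r.sseqid == query)]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def transfer_all(hits: HitTable, corpus: AnnotationCorpus,
                 queries: Iterable[str], exclude_self: bool = True):
    """Transfer scores for many queries as a :class:`PredictionMatrix`."""
    from .ensemble import PredictionMatrix

    queries = list(queries)
    scores = {q: transfer_score(hits, corpus, q, exclude_self=exclude_self)
              for q in queries}
    provenance = {
        q: transfer_provenance(hits, corpus, q, exclude_self=exclude_self)
        for q in queries
    }
    return PredictionMatrix(proteins=queries, scores=scores,
                            provenance=provenance)
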