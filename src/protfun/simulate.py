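"""Synthetic benchmark data: toy ontologies, motif-implanted sequences,
annotations and simulated similarity hits.

The generator builds a rooted class tree (optionally with extra "diamond"
edges), attaches a unique amino-acid motif to each leaf class, and samples
proteins that draw one or more leaf functions: a background sequence is
drawn from configurable residue frequencies and each owned leaf's motif is
implanted at a random non-overlapping position with probability
``implant_prob``.  Function is therefore learnable from sequence, and
internal classes gain signal only through upward propagation — mirroring
how specific functions drive sequence signal in real annotation corpora.

Similarity hits are simulated by counting shared motif-length k-mers
between two sequences (a stand-in for alignment: two proteins sharing a
leaf function share its implanted motif), scaled into a pseudo-bitscore
with seeded noise; e-values decrease monotonically with bitscore so the
standard e-value cutoff is exercised downstream.

Every output is a pure function of :class:`SynthConfig`, including the
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ProtfunError
from .ontology import (AnnotationCorpus, EvidenceRecord, GO_NAMESPACES,
                       OntologyGraph, write_annotations, write_obo)
from .sequences import SequenceRecord, write_fasta
from .similarity import HitTable, write_hits

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 0
    n_namespaces: int = 1
    depth: int = 2
    branching: int = 3
    n_extra_edges: int = 0          # optional diamond edges
    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 200)
    motif_len: int = 8
    implant_prob: float = 0.9
    classes_per_protein: tuple[int, int] = (1, 2)
    background_freqs: tuple[float, ...] | None = None  # uniform if None
    hit_score_scale: float = 60.0
    hit_noise_scale: float = 3.0
    min_bitscore: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.implant_prob <= 1.0:
            raise ProtfunError("implant_prob must be in [0, 1]")
        for name in ("n_namespaces", "depth", "branching", "n_proteins",
                     "motif_len"):
            if getattr(self, name) < 1:
                raise ProtfunError(f"{name} must be >= 1")
        if self.motif_len > self.length_range[0]:
            raise ProtfunError("motif_len exceeds the minimum sequence "
                               "length")
        if self.background_freqs is not None:
            freqs = np.asarray(self.background_freqs, dtype=float)
            if len(freqs) != len(AA20) or not np.isclose(freqs.sum(), 1.0):
                raise ProtfunError("background_freqs must be 20 "
                                   "probabilities summing to 1")


def _namespace_label(i: int) -> str:
    return GO_NAMESPACES[i] if i < len(GO_NAMESPACES) else f"namespace_{i}"


def make_ontology(config: SynthConfig
                  ) -> tuple[OntologyGraph, dict[str, str]]:
    """Build the toy DAG and assign a unique motif to every leaf class.

    Each namespace is a complete tree of the configured depth and branching
    factor (depth 2, branching 3 → 1 + 3 + 9 = 13 classes); extra diamond
    edges, when requested, link a class to a second, strictly shallower
    parent.  Returns the graph and a leaf → motif map.
    """
    rng = np.random.default_rng(config.seed)
    parents: dict[str, set[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    depth_of: dict[str, int] = {}
    leaves: list[str] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    for ns_index in range(config.n_namespaces):
        ns = _namespace_label(ns_index)
        root = new_id()
        parents[root] = set()
        namespace[root] = ns
        names[root] = f"{ns} root"
        depth_of[root] = 0
        level = [root]
        for d in range(1, config.depth + 1):
            nxt = []
            for parent in level:
                for _ in range(config.branching):
                    child = new_id()
                    parents[child] = {(parent, "is_a")}
                    namespace[child] = ns
                    names[child] = f"synthetic class {child[3:]}"
                    depth_of[child] = d
                    nxt.append(child)
            level = nxt
        leaves.extend(level)

        # optional diamond edges: a second parent at a shallower depth
        candidates = [c for c in parents
                      if namespace[c] == ns and depth_of[c] >= 2]
        for _ in range(config.n_extra_edges):
            if not candidates:
                break
            child = candidates[rng.integers(len(candidates))]
            shallower = [c for c in parents
                         if namespace[c] == ns
                         and depth_of[c] < depth_of[child]
                         and c not in {p for p, _ in parents[child]}]
            if shallower:
                extra = shallower[rng.integers(len(shallower))]
                parents[child].add((extra, "is_a"))

    motifs: dict[str, str] = {}
    used: set[str] = set()
    for leaf in leaves:
        while True:
            motif = "".join(
                AA20[i] for i in rng.integers(0, len(AA20), config.motif_len))
            if motif not in used:
                used.add(motif)
                motifs[leaf] = motif
                break

    graph = OntologyGraph(parents, namespace=namespace, names=names)
    return graph, motifs


def _implant(background: list[str], motifs: list[str],
             rng: np.random.Generator) -> str:
    """Place motifs at uniform random non-overlapping positions."""
    length = len(background)
    placed: list[tuple[int, int]] = []
    for motif in motifs:
        for _ in range(200):
            start = int(rng.integers(0, length - len(motif) + 1))
            span = (start, start + len(motif))
            if all(span[1] <= s or span[0] >= e for s, e in placed):
                placed.append(span)
                background[span[0]:span[1]] = list(motif)
                break
        else:  # pragma: no cover - essentially unreachable at defaults
            raise ProtfunError("could not place motif without overlap")
    return "".join(background)


def sample_proteins(graph: OntologyGraph, motifs: dict[str, str],
                    config: SynthConfig
                    ) -> tuple[list[SequenceRecord], dict[str, set[str]]]:
    """Sample proteins with leaf-class annotations and implanted motifs.

    Raw annotations are the drawn leaves; upward propagation is left to
    :func:`protfun.ontology.propagate_annotations`.  If a drawn sequence is
    too short to host all its motifs, its length is resampled upward
    (logged).
    """
    rng = np.random.default_rng(config.seed + 1)
    leaf_ids = sorted(motifs)
    lo, hi = config.classes_per_protein
    freqs = (np.asarray(config.background_freqs, dtype=float)
             if config.background_freqs is not None else None)
    records: list[SequenceRecord] = []
    raw: dict[str, set[str]] = {}
    for i in range(config.n_proteins):
        name = f"P{i:05d}"
        n_classes = int(rng.integers(lo, hi + 1))
        n_classes = min(n_classes, len(leaf_ids))
        drawn = [leaf_ids[j]
                 for j in rng.choice(len(leaf_ids), size=n_classes,
                                     replace=False)]
        implanted = [motifs[leaf] for leaf in drawn
                     if rng.random() < config.implant_prob]
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        needed = sum(len(m) for m in implanted)
        if needed > length:
            logger.info("resampling length for %s to host %d motifs",
                        name, len(implanted))
            length = needed + int(rng.integers(config.motif_len,
                                               2 * config.motif_len))
        background = list(rng.choice(list(AA20), size=length, p=freqs))
        sequence = _implant(background, implanted, rng)
        records.append(SequenceRecord(name, sequence))
        raw[name] = set(drawn)
    return records, raw


def _kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i:i + k] for i in range(len(sequence) - k + 1)}


def simulate_hits(queries: list[SequenceRecord],
                  subjects: list[SequenceRecord],
                  config: SynthConfig) -> HitTable:
    """Pseudo-alignment hit table from shared k-mer counts.

    bitscore = scale × (number of distinct shared motif-length k-mers)
    plus seeded noise; pairs sharing no k-mer, or falling below the bitscore
    floor, are omitted.  E-values are a decreasing function of bitscore
    (``10^(-bitscore/10)``), so a bitscore at the floor of 30 sits exactly
    at e-value 1e-3.
    """
    rng = np.random.default_rng(config.seed + 2)
    k = config.motif_len
    subject_kmers = [(s, _kmers(s.sequence, k)) for s in subjects]
    rows = []
    for q in queries:
        q_kmers = _kmers(q.sequence, k)
        for s, s_kmers in subject_kmers:
            shared = len(q_kmers & s_kmers)
            if shared == 0:
                continue
            bitscore = round(
                config.hit_score_scale * shared
                + float(rng.uniform(0, config.hit_noise_scale)), 1)
            if bitscore < config.min_bitscore:
                continue
            evalue = 10.0 ** max(-180.0, -bitscore / 10.0)
            rows.append((q.identifier, s.identifier, bitscore, evalue))
    frame = pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore",
                                        "evalue"])
    return HitTable(frame, evalue_max=float("inf"))


@dataclass
class SyntheticDataset:
    """One generated benchmark: ontology, motifs, proteins, annotations."""

    config: SynthConfig
    graph: OntologyGraph
    motifs: dict[str, str]
    records: list[SequenceRecord]
    raw: dict[str, set[str]]
    corpus: AnnotationCorpus = field(init=False)

    def __post_init__(self) -> None:
        from .ontology import propagate_annotations

        self.corpus = propagate_annotations(self.graph, self.raw)


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    graph, motifs = make_ontology(config)
    records, raw = sample_proteins(graph, motifs, config)
    return SyntheticDataset(config=config, graph=graph, motifs=motifs,
                            records=records, raw=raw)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  with_hits: bool = True) -> dict[str, Path]:
    """Write the dataset in the dialects the readers consume.

    Produces ``ontology.obo``, ``proteins.fasta``, ``annotations.tsv``
    (evidence code IDA) and, optionally, all-vs-all ``hits.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "fasta": outdir / "proteins.fasta",
        "annotations": outdir / "annotations.tsv",
    }
    with open(paths["obo"], "w") as fh:
        write_obo(dataset.graph, fh)
    with open(paths["fasta"], "w") as fh:
        write_fasta(dataset.records, fh)
    with open(paths["annotations"], "w") as fh:
        write_annotations(
            [EvidenceRecord(p, t, "IDA")
             for p in sorted(dataset.raw)
             for t in sorted(dataset.raw[p])], fh)
    if with_hits:
        paths["hits"] = outdir / "hits.tsv"
        hits = simulate_hits(dataset.records, dataset.records,
                             dataset.config)
        with open(paths["hits"], "w") as fh:
            write_hits(hits, fh)
    return paths
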