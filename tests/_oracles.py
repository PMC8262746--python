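"""Independent brute-force re-implementations used as test oracles.

Everything here is written directly from the defining formulas with naive
loops and explicit path enumeration, deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


# -- random instance generators ---------------------------------------------


def random_parent_map(rng: np.random.Generator, n_nodes: int
                      ) -> dict[str, set[str]]:
    """Rooted random DAG: node i > 0 draws >= 1 parents among 0..i-1."""
    nodes = [f"T{i:03d}" for i in range(n_nodes)]
    parents: dict[str, set[str]] = {nodes[0]: set()}
    for i in range(1, n_nodes):
        k = int(rng.integers(1, min(i, 3) + 1))
        parents[nodes[i]] = {nodes[j]
                             for j in rng.choice(i, size=k, replace=False)}
    return parents


def random_scores(rng: np.random.Generator, classes: list[str],
                  p_scored: float = 0.7, decimals: int | None = 2
                  ) -> dict[str, float]:
    out = {}
    for c in classes:
        if rng.random() < p_scored:
            s = float(rng.uniform(0.01, 1.0))
            out[c] = round(s, decimals) if decimals else s
    return {c: s for c, s in out.items() if s > 0}


# -- reachability by explicit path enumeration ------------------------------


def reachable_up(parents: dict[str, set[str]], seed: str) -> set[str]:
    """All ancestors of ``seed`` found by enumerating every simple path."""
    found: set[str] = set()

    def walk(node: str, path: tuple[str, ...]) -> None:
        for p in parents.get(node, ()):  # noqa: B023 - simple recursion
            if p not in path:
                found.add(p)
                walk(p, path + (p,))

    walk(seed, (seed,))
    return found


def reachable_down(parents: dict[str, set[str]], seed: str) -> set[str]:
    children: dict[str, set[str]] = {c: set() for c in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)
    return reachable_up(children, seed)


# -- similarity transfer -----------------------------------------------------


def transfer_bruteforce(hit_rows: list[tuple[str, str, float]],
                        annotations: dict[str, set[str] | frozenset[str]],
                        query: str, exclude_self: bool = True
                        ) -> dict[str, float]:
    """Enumerate every (class, subject) indicator term of the weighted vote."""
    rows = [(s, b) for q, s, b in hit_rows
            if q == query and s in annotations
            and not (exclude_self and s == query)]
    total = sum(b for _, b in rows)
    if total <= 0:
        return {}
    classes: set[str] = set()
    for s, _ in rows:
        classes |= set(annotations[s])
    return {
        f: sum(b for s, b in rows if f in annotations[s]) / total
        for f in classes
    }


# -- consistency -------------------------------------------------------------


def consistency_bruteforce(parents: dict[str, set[str]],
                           scores: dict[str, float]) -> dict[str, float]:
    """max over {c} ∪ descendants(c) for every class, dropping zeros."""
    out = {}
    for c in parents:
        pool = [scores.get(c, 0.0)]
        pool += [scores.get(d, 0.0) for d in reachable_down(parents, c)]
        best = max(pool)
        if best > 0:
            out[c] = best
    return out


# -- evaluation --------------------------------------------------------------


def fmax_bruteforce(pred_scores: dict[str, dict[str, float]],
                    truth: dict[str, set[str]]) -> tuple[float, float]:
    """Naive loop transcription of the protein-centric F-measure sweep."""
    proteins = [p for p in truth if truth[p]]
    n = len(proteins)
    best, best_t = 0.0, 0.0
    any_valid = False
    for i in range(101):
        t = i / 100.0
        m, pr_sum, rc_sum = 0, 0.0, 0.0
        for p in proteins:
            pset = {c for c, s in pred_scores.get(p, {}).items()
                    if s > 0 and s >= t}
            tset = truth[p]
            tp = len(pset & tset)
            rc_sum += tp / len(tset)
            if pset:
                m += 1
                pr_sum += tp / len(pset)
        if m == 0:
            continue
        avg_pr = pr_sum / m
        avg_rc = rc_sum / n
        f = (2 * avg_pr * avg_rc / (avg_pr + avg_rc)
             if avg_pr + avg_rc > 0 else 0.0)
        if not any_valid or f > best:
            best, best_t = f, t
        any_valid = True
    return best, best_t


def smin_bruteforce(pred_scores: dict[str, dict[str, float]],
                    truth: dict[str, set[str]],
                    ic: dict[str, float]) -> tuple[float, float]:
    proteins = [p for p in truth if truth[p]]
    n = len(proteins)
    best, best_t = math.inf, 0.0
    for i in range(101):
        t = i / 100.0
        ru, mi = 0.0, 0.0
        for p in proteins:
            pset = {c for c, s in pred_scores.get(p, {}).items()
                    if s > 0 and s >= t}
            tset = truth[p]
            ru += sum(ic[c] for c in tset - pset)
            mi += sum(ic[c] for c in pset - tset)
        s = math.sqrt((ru / n) ** 2 + (mi / n) ** 2)
        if s < best - 1e-15:
            best, best_t = s, t
    return best, best_t
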