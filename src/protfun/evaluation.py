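"""Protein-centric evaluation: Fmax, Smin and AUPR over a threshold sweep.

For each threshold t on the grid 0.00, 0.01, …, 1.00 the predicted set of
protein i is P_i(t); with truth set T_i,

    pr_i(t) = |P_i(t) ∩ T_i| / |P_i(t)|
    rc_i(t) = |P_i(t) ∩ T_i| / |T_i|
    AvgPr(t) = mean of pr_i over the m(t) proteins with P_i(t) ≠ ∅
    AvgRc(t) = mean of rc_i over all n proteins
    Fmax = max_t 2·AvgPr·AvgRc / (AvgPr + AvgRc)      (m(t) = 0 skipped)

    ru(t) = mean over n of Σ_{c ∈ T_i − P_i(t)} IC(c)   (remaining uncertainty)
    mi(t) = mean over n of Σ_{c ∈ P_i(t) − T_i} IC(c)   (misinformation)
    Smin = min_t sqrt(ru(t)² + mi(t)²)

AUPR is the trapezoidal area under the protein-centric (AvgRc, AvgPr) curve
(a micro-averaged variant over (protein, class) pairs is selectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ensemble import PredictionMatrix, threshold_predictions
from .errors import ProtfunError
from .ontology import AnnotationCorpus, ICTable, OntologyGraph

THRESHOLD_GRID = np.arange(101) / 100.0  # 0.00, 0.01, ..., 1.00


@dataclass
class EvalResult:
    """Threshold-swept evaluation curves and their summary statistics."""

    thresholds: np.ndarray
    avg_pr: np.ndarray          # NaN where m(t) = 0
    avg_rc: np.ndarray
    f: np.ndarray               # NaN where m(t) = 0
    m: np.ndarray               # proteins with >= 1 prediction
    ru: np.ndarray | None
    mi: np.ndarray | None
    s: np.ndarray | None
    n: int
    fmax: float
    fmax_threshold: float
    smin: float | None
    smin_threshold: float | None
    aupr: float

    def summary(self) -> str:
        lines = [
            f"proteins evaluated : {self.n}",
            f"Fmax               : {self.fmax:.4f} (t = "
            f"{self.fmax_threshold:.2f})",
        ]
        if self.smin is not None:
            lines.append(f"Smin               : {self.smin:.4f} (t = "
                         f"{self.smin_threshold:.2f})")
        lines.append(f"AUPR               : {self.aupr:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "aupr": self.aupr,
            "thresholds": self.thresholds.tolist(),
            "avg_pr": [None if math.isnan(v) else v for v in self.avg_pr],
            "avg_rc": self.avg_rc.tolist(),
            "m": self.m.tolist(),
        }
        if self.smin is not None:
            d["smin"] = self.smin
            d["smin_threshold"] = self.smin_threshold
            d["ru"] = self.ru.tolist()
            d["mi"] = self.mi.tolist()
        return d


def _restrict(classes: set[str], graph: OntologyGraph | None,
              namespace: str | None, exclude_roots: bool) -> set[str]:
    if graph is None:
        return classes
    out = set()
    roots = set(graph.roots.values())
    for c in classes:
        if c not in graph.classes:
            continue
        if namespace is not None and graph.namespace[c] != namespace:
            continue
        if exclude_roots and c in roots:
            continue
        out.add(c)
    return out


def sweep(preds: PredictionMatrix, truth: AnnotationCorpus,
          ic: ICTable | None = None, graph: OntologyGraph | None = None,
          namespace: str | None = None, exclude_roots: bool = True,
          strict: bool = False, curve: str = "protein") -> EvalResult:
    """Full threshold sweep of the protein-centric measures.

    Evaluation covers the proteins of ``truth`` whose (restricted) truth set
    is nonempty; every protein appearing in ``preds`` must be in ``truth``.
    When ``graph`` is given, truth and predictions are restricted to
    ``namespace`` (if set) and namespace roots are dropped unless
    ``exclude_roots`` is False.  ``ic`` enables the ru/mi/Smin track; classes
    missing from the table fall back to its maximum IC.
    """
    if not truth.proteins:
        raise ProtfunError("evaluation requires a nonempty truth corpus")
    for p in preds.proteins:
        if p not in truth.annotations:
            raise ProtfunError(
                f"protein {p!r} has predictions but no truth annotations")
    if curve not in ("protein", "micro"):
        raise ProtfunError(f"unknown curve type {curve!r}")

    truth_sets: dict[str, set[str]] = {}
    for p in truth.proteins:
        t_set = _restrict(set(truth.annotations[p]), graph, namespace,
                          exclude_roots)
        if t_set:
            truth_sets[p] = t_set
    if not truth_sets:
        raise ProtfunError("no protein has truth annotations after "
                           "namespace/root restriction")
    proteins = list(truth_sets)
    n = len(proteins)

    pred_sets_by_t = []
    for t in THRESHOLD_GRID:
        kept = threshold_predictions(preds, float(t), strict=strict)
        pred_sets_by_t.append({
            p: _restrict(kept.get(p, set()), graph, namespace, exclude_roots)
            for p in proteins
        })

    avg_pr = np.full(101, np.nan)
    avg_rc = np.zeros(101)
    f = np.full(101, np.nan)
    m = np.zeros(101, dtype=int)
    micro_pr = np.full(101, np.nan)
    micro_rc = np.zeros(101)
    want_s = ic is not None
    ru = np.zeros(101) if want_s else None
    mi = np.zeros(101) if want_s else None

    for k, t in enumerate(THRESHOLD_GRID):
        pred_sets = pred_sets_by_t[k]
        pr_sum, rc_sum, m_t = 0.0, 0.0, 0
        tp_tot, pred_tot, true_tot = 0, 0, 0
        ru_sum, mi_sum = 0.0, 0.0
        for p in proteins:
            t_set = truth_sets[p]
            p_set = pred_sets[p]
            tp = len(p_set & t_set)
            rc_sum += tp / len(t_set)
            tp_tot += tp
            pred_tot += len(p_set)
            true_tot += len(t_set)
            if p_set:
                m_t += 1
                pr_sum += tp / len(p_set)
            if want_s:
                ru_sum += sum(ic.value(c) for c in t_set - p_set)
                mi_sum += sum(ic.value(c) for c in p_set - t_set)
        avg_rc[k] = rc_sum / n
        m[k] = m_t
        micro_rc[k] = tp_tot / true_tot
        if pred_tot:
            micro_pr[k] = tp_tot / pred_tot
        if m_t:
            avg_pr[k] = pr_sum / m_t
            if avg_pr[k] + avg_rc[k] > 0:
                f[k] = 2 * avg_pr[k] * avg_rc[k] / (avg_pr[k] + avg_rc[k])
            else:
                f[k] = 0.0
        if want_s:
            ru[k] = ru_sum / n
            mi[k] = mi_sum / n

    valid = ~np.isnan(f)
    if valid.any():
        fmax = float(np.nanmax(f))
        fmax_threshold = float(THRESHOLD_GRID[valid][
            np.argmax(f[valid] >= fmax - 1e-15)])
    else:
        fmax, fmax_threshold = 0.0, 0.0

    if want_s:
        s = np.sqrt(ru ** 2 + mi ** 2)
        smin = float(np.min(s))
        smin_threshold = float(THRESHOLD_GRID[np.argmax(s <= smin + 1e-15)])
    else:
        s = smin = smin_threshold = None

    if curve == "protein":
        pr_pts, rc_pts = avg_pr[valid], avg_rc[valid]
    else:
        mv = ~np.isnan(micro_pr)
        pr_pts, rc_pts = micro_pr[mv], micro_rc[mv]
    if len(rc_pts) >= 2:
        order = np.argsort(rc_pts, kind="stable")
        aupr = float(np.trapezoid(pr_pts[order], rc_pts[order]))
    else:
        aupr = 0.0

    return EvalResult(thresholds=THRESHOLD_GRID.copy(), avg_pr=avg_pr,
                      avg_rc=avg_rc, f=f, m=m, ru=ru, mi=mi, s=s, n=n,
                      fmax=fmax, fmax_threshold=fmax_threshold, smin=smin,
                      smin_threshold=smin_threshold, aupr=aupr)


def fmax_only(preds: PredictionMatrix, truth: AnnotationCorpus,
              **kwargs) -> tuple[float, float]:
    """(Fmax, maximizing threshold); smallest maximizer under ties."""
    res = sweep(preds, truth, ic=None, **kwargs)
    return res.fmax, res.fmax_threshold


def smin_only(preds: PredictionMatrix, truth: AnnotationCorpus, ic: ICTable,
              **kwargs) -> tuple[float, float]:
    """(Smin, minimizing threshold); smallest minimizer under ties."""
    res = sweep(preds, truth, ic=ic, **kwargs)
    return res.smin, res.smin_threshold
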