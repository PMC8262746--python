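import math

import numpy as np
import pytest

from protfun.ensemble import PredictionMatrix
from protfun.errors import ProtfunError
from protfun.evaluation import THRESHOLD_GRID, fmax_only, smin_only, sweep
from protfun.ontology import AnnotationCorpus, ICTable

from _oracles import fmax_bruteforce, smin_bruteforce


def _pm(**scores):
    return PredictionMatrix(proteins=list(scores),
                            scores={p: dict(v) for p, v in scores.items()})


def _truth(**sets):
    return AnnotationCorpus({p: frozenset(v) for p, v in sets.items()})


def _ic(values):
    return ICTable(ic=dict(values), log_base=2, counts={})


def _random_instance(rng, n_proteins=5, n_classes=10):
    classes = [f"c{i}" for i in range(n_classes)]
    truth = {}
    preds = {}
    for i in range(int(rng.integers(1, n_proteins + 1))):
        p = f"p{i}"
        truth[p] = {classes[j] for j in rng.choice(
            n_classes, size=int(rng.integers(1, 4)), replace=False)}
        preds[p] = {c: round(float(rng.uniform(0.01, 1.0)), 2)
                    for c in classes if rng.random() < 0.5}
    return preds, truth, {c: float(rng.uniform(0.1, 3.0)) for c in classes}


class TestGrid:
    def test_grid_is_101_points_step_001(self):
        assert len(THRESHOLD_GRID) == 101
        assert THRESHOLD_GRID[0] == 0.0 and THRESHOLD_GRID[-1] == 1.0
        assert np.allclose(np.diff(THRESHOLD_GRID), 0.01)

    def test_recall_and_m_nonincreasing(self, rng):
        preds, truth, _ = _random_instance(rng, n_proteins=5)
        res = sweep(_pm(**preds), _truth(**truth))
        assert np.all(np.diff(res.avg_rc) <= 1e-15)
        assert np.all(np.diff(res.m) <= 0)


class TestSweep:
    def test_perfect_predictor(self):
        truth = _truth(p1={"a", "b"}, p2={"c"})
        preds = _pm(p1={"a": 1.0, "b": 1.0}, p2={"c": 1.0})
        ic = _ic({"a": 1.0, "b": 2.0, "c": 0.5})
        res = sweep(preds, truth, ic=ic)
        assert res.fmax == 1.0
        assert res.smin == 0.0

    def test_hand_sweep_half_precision_recall(self):
        # T = {a, b}, predicted {a: 0.9, c: 0.9} -> pr = rc = 1/2 up to 0.9
        res = sweep(_pm(p={"a": 0.9, "c": 0.9}), _truth(p={"a", "b"}))
        assert res.fmax == pytest.approx(0.5)
        k = 50  # t = 0.50, well inside the predicted range
        assert res.avg_pr[k] == pytest.approx(0.5)
        assert res.avg_rc[k] == pytest.approx(0.5)

    def test_avgpr_over_m_avgrc_over_n(self):
        # only p1 has predictions at t = 0.5
        truth = _truth(p1={"a"}, p2={"b"})
        preds = _pm(p1={"a": 0.9}, p2={"b": 0.1})
        res = sweep(preds, truth)
        k = 50
        assert res.m[k] == 1
        assert res.avg_pr[k] == pytest.approx(1.0)   # mean over m(t) = 1
        assert res.avg_rc[k] == pytest.approx(0.5)   # mean over n = 2
        assert res.n == 2

    def test_protein_without_truth_rejected(self):
        with pytest.raises(ProtfunError, match="ghost"):
            sweep(_pm(ghost={"a": 0.5}), _truth(p={"a"}))

    def test_empty_truth_rejected(self):
        with pytest.raises(ProtfunError):
            sweep(_pm(), AnnotationCorpus({}))

    def test_namespace_split_equals_separate_runs(self):
        from protfun.ontology import OntologyGraph

        parents, namespace = {}, {}
        for i, ns in enumerate(["molecular_function", "biological_process",
                                "cellular_component"]):
            parents[f"R{i}"] = set()
            parents[f"L{i}"] = {(f"R{i}", "is_a")}
            namespace[f"R{i}"] = namespace[f"L{i}"] = ns
        g = OntologyGraph(parents, namespace=namespace)
        truth = _truth(p={"L0", "L1", "R0", "R1", "R2", "L2"})
        preds = _pm(p={"L0": 0.8, "L1": 0.4, "L2": 0.9})
        for i, ns in enumerate(["molecular_function", "biological_process",
                                "cellular_component"]):
            joint = sweep(preds, truth, graph=g, namespace=ns)
            alone = sweep(_pm(p={f"L{i}": preds.scores["p"][f"L{i}"]}),
                          _truth(p={f"L{i}"}))
            assert joint.fmax == pytest.approx(alone.fmax)


class TestFmaxOnly:
    def test_perfect_gives_smallest_threshold(self):
        fmax, t = fmax_only(_pm(p={"a": 1.0}), _truth(p={"a"}))
        assert fmax == 1.0
        assert t == 0.0  # smallest maximizer under ties

    def test_all_zero_scores_give_zero(self):
        fmax, _ = fmax_only(_pm(p={"a": 0.0}), _truth(p={"a"}))
        assert fmax == 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            preds, truth, _ = _random_instance(rng)
            got = fmax_only(_pm(**preds), _truth(**truth))
            ref = fmax_bruteforce(preds, truth)
            assert got[0] == pytest.approx(ref[0], abs=1e-12)
            assert got[1] == pytest.approx(ref[1], abs=1e-12)


class TestSminOnly:
    def test_perfect_is_zero(self):
        smin, _ = smin_only(_pm(p={"a": 1.0}), _truth(p={"a"}),
                            _ic({"a": 1.0}))
        assert smin == 0.0

    def test_hand_sweep_with_empty_prediction_optimum(self):
        # truth {A, IC 1}, predicted {B, IC 2} at 0.5: at low t
        # s = sqrt(1 + 4); above 0.5 predictions vanish and ru = 1
        smin, t = smin_only(_pm(p={"B": 0.5}), _truth(p={"A"}),
                            _ic({"A": 1.0, "B": 2.0}))
        assert smin == pytest.approx(1.0)
        assert t == pytest.approx(0.51)

    def test_homogeneity_doubling_ic_doubles_smin(self, rng):
        preds, truth, ic = _random_instance(rng)
        s1, _ = smin_only(_pm(**preds), _truth(**truth), _ic(ic))
        s2, _ = smin_only(_pm(**preds), _truth(**truth),
                          _ic({c: 2 * v for c, v in ic.items()}))
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            preds, truth, ic = _random_instance(rng)
            got = smin_only(_pm(**preds), _truth(**truth), _ic(ic))
            ref = smin_bruteforce(preds, truth, ic)
            assert got[0] == pytest.approx(ref[0], abs=1e-12)


class TestAupr:
    def test_trapezoid_hand_value(self):
        # pr = 1 throughout; recall drops from 1 to 0.5 past t = 0.5,
        # so the area over the observed recall range [0.5, 1] is 0.5
        res = sweep(_pm(p={"a": 1.0, "b": 0.5}), _truth(p={"a", "b"}))
        assert res.aupr == pytest.approx(0.5)

    def test_micro_curve_variant_runs(self, rng):
        preds, truth, _ = _random_instance(rng)
        res = sweep(_pm(**preds), _truth(**truth), curve="micro")
        assert 0.0 <= res.aupr <= 1.0
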