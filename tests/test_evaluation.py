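"""Prediction mocking, confidence screening, partitioned metrics, ranking."""

import numpy as np
import pytest

from segremodel.backbone import synthetic_inpaint
from segremodel.core import SegmentSpec
from segremodel.evaluation import (EvaluationError, EvaluationRecord,
                                   MockPredictionBackend, PredictionRecord,
                                   composite_rank, evaluate_variants,
                                   mock_predictor, partitioned_metrics,
                                   predict_structures, screen_predictions)
from segremodel.geometry import kabsch_superpose, rmsd_over, tm_score_over
from segremodel.seqdesign import MockSequenceBackend, design_sequences


@pytest.fixture(scope="module")
def backbone(scaffold, scaffold_spec_h):
    return synthetic_inpaint(scaffold, scaffold_spec_h, "H", 5.0, seed=2)


@pytest.fixture(scope="module")
def variants(backbone):
    kept, _ = design_sequences(MockSequenceBackend(), backbone, 10, seed=5)
    return kept


def make_eval(vid="v", **overrides):
    base = dict(variant_id=vid, backbone_id="bb", compliance_pred=0.5,
                segment_ss3="H" * 12, fixed_rmsd=1.0, fixed_tm=0.9,
                segment_rmsd=3.0, segment_tm=0.3, global_score=1.0,
                segment_mean_plddt=70.0, global_mean_plddt=80.0)
    base.update(overrides)
    return EvaluationRecord(**base)


class TestMockPredictor:
    def test_deterministic_under_seed(self, variants, scaffold, backbone):
        a = mock_predictor(variants[0], scaffold, backbone, seed=3)
        b = mock_predictor(variants[0], scaffold, backbone, seed=3)
        assert a.global_mean_plddt == b.global_mean_plddt
        for r1, r2 in zip(a.structure.residues(), b.structure.residues()):
            assert r1.plddt == r2.plddt
            for atom in r1.atoms:
                assert np.array_equal(r1.atoms[atom], r2.atoms[atom])

    def test_regular_helix_segment_confident(self, scaffold, scaffold_spec_h,
                                             variants):
        """An unjittered ideal-helix segment scores high confidence; the
        direct formula on regular geometry gives >= 80."""
        clean = synthetic_inpaint(scaffold, scaffold_spec_h, "H", 0.0, seed=1,
                                  target_block=(0, 12))
        rec = mock_predictor(variants[0], scaffold, clean, seed=2,
                             jitter=0.0)
        assert rec.segment_mean_plddt >= 80.0 or not clean.closure_converged

    def test_jittered_twin_scores_lower(self, scaffold, scaffold_spec_h,
                                        variants):
        clean = synthetic_inpaint(scaffold, scaffold_spec_h, "H", 0.0, seed=1)
        noisy = synthetic_inpaint(scaffold, scaffold_spec_h, "H", 45.0, seed=1)
        rec_clean = mock_predictor(variants[0], scaffold, clean, seed=2,
                                   jitter=0.0)
        rec_noisy = mock_predictor(variants[0], scaffold, noisy, seed=2,
                                   jitter=0.0)
        assert rec_noisy.segment_mean_plddt < rec_clean.segment_mean_plddt

    def test_plddt_bounds_and_means_consistent(self, variants, scaffold,
                                               backbone):
        rec = mock_predictor(variants[0], scaffold, backbone, seed=0)
        vals = [r.plddt for r in rec.structure.residues()]
        assert all(30.0 <= v <= 95.0 for v in vals)
        assert rec.global_mean_plddt == pytest.approx(np.mean(vals), abs=1e-6)


class TestPredictStructures:
    def test_one_record_per_variant(self, scaffold, backbone, variants):
        backend = MockPredictionBackend(scaffold,
                                        {backbone.candidate_id: backbone})
        records, rejections = predict_structures(backend, variants, seed=1)
        assert len(records) == len(variants) and not rejections

    def test_missing_confidence_rejected(self, scaffold, backbone, variants):
        class NoConfidence(MockPredictionBackend):
            def predict(self, vs, seed):
                out = super().predict(vs, seed)
                for _, rec, _ in out[:1]:
                    for res in rec.structure.residues():
                        res.plddt = None
                return out

        backend = NoConfidence(scaffold, {backbone.candidate_id: backbone})
        records, rejections = predict_structures(backend, variants, seed=1)
        assert len(rejections) == 1
        assert "confidence" in rejections[0].reason

    def test_empty_variant_list_ok(self, scaffold, backbone):
        backend = MockPredictionBackend(scaffold, {})
        records, rejections = predict_structures(backend, [], seed=1)
        assert records == [] and rejections == []


class TestScreening:
    def test_exact_coverage_threshold_retained(self):
        ev = make_eval(compliance_pred=0.40)
        kept, _ = screen_predictions([ev])
        assert kept == [ev]  # >= semantics at the screening stage

    def test_low_global_confidence_dropped_and_counted(self):
        ev = make_eval(global_mean_plddt=60.0)
        kept, counts = screen_predictions([ev])
        assert kept == [] and counts["global_plddt"] == 1

    def test_survivors_monotone_in_each_threshold(self, rng):
        evals = [make_eval(f"v{i}",
                           compliance_pred=float(rng.uniform(0, 1)),
                           segment_mean_plddt=float(rng.uniform(30, 95)),
                           global_mean_plddt=float(rng.uniform(50, 95)))
                 for i in range(60)]
        for key, grid in [("ss_coverage_min", (0.2, 0.4, 0.6, 0.8)),
                          ("segment_plddt_min", (40, 50, 60, 70)),
                          ("global_plddt_min", (60, 70, 80, 90))]:
            sizes = [len(screen_predictions(evals, {key: t})[0])
                     for t in grid]
            assert sizes == sorted(sizes, reverse=True)


class TestPartitionedMetrics:
    def test_identity_prediction(self, scaffold, scaffold_spec_h):
        rec = PredictionRecord("v", scaffold.copy(), scaffold_spec_h,
                               90.0, 90.0)
        out = partitioned_metrics(scaffold, rec, scaffold_spec_h, fit="all")
        assert out["fixed_rmsd"] < 1e-9
        assert out["segment_rmsd"] < 1e-9
        assert out["fixed_tm"] == pytest.approx(1.0)
        assert out["segment_tm"] == pytest.approx(1.0)

    def test_displaced_segment_fixed_fit(self, scaffold, scaffold_spec_h):
        moved = scaffold.copy()
        chain = moved.chain("A")
        for num in scaffold_spec_h.res_nums():
            res = chain[num]
            for a in res.atoms:
                res.atoms[a] = res.atoms[a] + np.array([10.0, 0, 0])
        rec = PredictionRecord("v", moved, scaffold_spec_h, 90.0, 90.0)
        out = partitioned_metrics(scaffold, rec, scaffold_spec_h, fit="fixed")
        assert out["fixed_rmsd"] < 1e-9
        assert out["segment_rmsd"] == pytest.approx(10.0, abs=1e-6)

    def test_matches_naive_two_step_recomputation(self, scaffold,
                                                  scaffold_spec_h, rng):
        jittered = scaffold.copy()
        for res in jittered.residues():
            for a in res.atoms:
                res.atoms[a] = res.atoms[a] + rng.normal(0, 0.4, 3)
        rec = PredictionRecord("v", jittered, scaffold_spec_h, 90.0, 90.0)
        out = partitioned_metrics(scaffold, rec, scaffold_spec_h, fit="all")

        chain = scaffold.chain("A")
        nums = chain.res_nums
        wild = np.array([chain[n].ca() for n in nums])
        pred = np.array([jittered.chain("A")[n].ca() for n in nums])
        tr, _ = kabsch_superpose(pred, wild)
        moved = tr.apply(pred)
        seg = np.array([n in set(scaffold_spec_h.res_nums()) for n in nums])
        assert out["fixed_rmsd"] == pytest.approx(
            rmsd_over(moved[~seg], wild[~seg]), abs=1e-9)
        assert out["segment_tm"] == pytest.approx(
            tm_score_over(moved[seg], wild[seg], int(seg.sum())), abs=1e-9)

    def test_numbering_mismatch_rejected(self, scaffold, scaffold_spec_h):
        from segremodel.core import Chain, Structure

        chain = scaffold.chain("A")
        shifted = Structure("shifted", [Chain("A", [
            type(r)(r.chain_id, r.res_num + 100, r.res_name,
                    {k: v.copy() for k, v in r.atoms.items()}, 90.0)
            for r in chain.residues])])
        rec = PredictionRecord("v", shifted, scaffold_spec_h, 90.0, 90.0)
        with pytest.raises(EvaluationError, match="cover"):
            partitioned_metrics(scaffold, rec, scaffold_spec_h)


class TestCompositeRank:
    def test_single_metric_dominance(self):
        evals = [make_eval("a", compliance_pred=0.8),
                 make_eval("b", compliance_pred=0.2)]
        ranked = composite_rank(evals)
        assert [e.variant_id for e in ranked] == ["a", "b"]

    def test_identical_vectors_tie_broken_by_id(self):
        ranked = composite_rank([make_eval("b"), make_eval("a")])
        assert [e.variant_id for e in ranked] == ["a", "b"]
        assert ranked[0].composite == ranked[1].composite

    def test_single_variant_composite_zero(self):
        ranked = composite_rank([make_eval("only")])
        assert ranked[0].composite == 0.0 and ranked[0].rank == 1

    def test_matches_brute_force_scorer(self, rng):
        evals = [make_eval(f"v{i:02d}",
                           compliance_pred=float(rng.uniform(0, 1)),
                           segment_mean_plddt=float(rng.uniform(30, 95)),
                           global_mean_plddt=float(rng.uniform(50, 95)),
                           global_score=float(rng.normal()),
                           fixed_rmsd=float(rng.uniform(0, 5)))
                 for i in range(20)]
        ranked = composite_rank([e for e in evals])

        def robust_z(vals):
            med = np.median(vals)
            mad = max(np.median(np.abs(vals - med)), 1e-9)
            return (vals - med) / mad

        cols = {
            "compliance_pred": +1, "segment_mean_plddt": +1,
            "global_mean_plddt": +1, "global_score": -1, "fixed_rmsd": -1,
        }
        total = np.zeros(20)
        for metric, direction in cols.items():
            total += direction * robust_z(
                np.array([getattr(e, metric) for e in evals]))
        order = sorted(range(20), key=lambda i: (-total[i],
                                                 evals[i].variant_id))
        assert [e.variant_id for e in ranked] == \
               [evals[i].variant_id for i in order]
        for e, i in zip(ranked, order):
            assert e.composite == pytest.approx(total[i])

    def test_invariant_to_metric_rescaling_and_order(self, rng):
        evals = [make_eval(f"v{i}", global_score=float(rng.normal()),
                           compliance_pred=float(rng.uniform(0, 1)))
                 for i in range(10)]
        baseline = [e.variant_id for e in composite_rank(
            [make_eval(e.variant_id, global_score=e.global_score,
                       compliance_pred=e.compliance_pred) for e in evals])]
        scaled = [e.variant_id for e in composite_rank(
            [make_eval(e.variant_id, global_score=e.global_score * 100,
                       compliance_pred=e.compliance_pred) for e in evals])]
        permuted = [e.variant_id for e in composite_rank(
            [make_eval(e.variant_id, global_score=e.global_score,
                       compliance_pred=e.compliance_pred)
             for e in reversed(evals)])]
        assert baseline == scaled == permuted


class TestEvaluateVariants:
    def test_full_records_assembled(self, scaffold, scaffold_spec_h,
                                    backbone, variants):
        backend = MockPredictionBackend(scaffold,
                                        {backbone.candidate_id: backbone})
        predictions, _ = predict_structures(backend, variants, seed=1)
        evals = evaluate_variants(scaffold, scaffold_spec_h, variants,
                                  predictions)
        assert len(evals) == len(variants)
        for ev in evals:
            assert 0.0 <= ev.compliance_pred <= 1.0
            assert ev.fixed_rmsd >= 0.0
            assert 0.0 < ev.fixed_tm <= 1.0
            assert len(ev.segment_ss3) == scaffold_spec_h.length
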