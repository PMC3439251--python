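import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from stabnet import bn, pipeline, simulate
from stabnet.pwm import background_from_sequences, scan_sequence
from stabnet.simulate import FixtureConfig


class TestPurity:
    def test_gpsp_deterministic_in_seed(self):
        cfg = FixtureConfig(gpsp_counts=(5, 5, 5))
        r1, l1 = simulate.simulate_gpsp(cfg, seed=3)
        r2, l2 = simulate.simulate_gpsp(cfg, seed=3)
        assert l1 == l2
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.bins, b.bins)

    def test_records_and_sequences_deterministic(self):
        cfg = FixtureConfig(n_stable=20, n_unstable=20)
        v1, t1 = simulate.simulate_bn_records(cfg, seed=5)
        v2, t2 = simulate.simulate_bn_records(cfg, seed=5)
        assert [v.protein_id for v in v1] == [v.protein_id for v in v2]
        np.testing.assert_array_equal(t1[bn.STABILITY], t2[bn.STABILITY])
        motifs = simulate.simulate_motif_windows(cfg, seed=6)
        s1, c1, _ = simulate.simulate_sequences(cfg, v1, motifs, seed=7)
        s2, c2, _ = simulate.simulate_sequences(cfg, v2, motifs, seed=7)
        assert s1 == s2 and c1 == c2


class TestGpsp:
    def test_empty_group_absent(self):
        cfg = FixtureConfig(gpsp_counts=(5, 0, 5))
        _, labels = simulate.simulate_gpsp(cfg, seed=0)
        assert "non_assigned" not in labels
        assert labels.count("stable") == 5 and labels.count("unstable") == 5

    def test_nonpositive_concentration_rejected(self):
        cfg = FixtureConfig(gpsp_concentration=0.0)
        with pytest.raises(ValueError):
            simulate.simulate_gpsp(cfg, seed=0)

    def test_corner_limit_still_separates(self):
        # very small concentration pushes draws to simplex corners, but the
        # three prototypes have distinct corner supports
        from sklearn.metrics import adjusted_rand_score
        from stabnet.stability_classes import assign_classes, cluster_distributions

        cfg = FixtureConfig(gpsp_counts=(25, 25, 25), gpsp_concentration=40.0)
        records, truth = simulate.simulate_gpsp(cfg, seed=2)
        pred = [a.label for a in assign_classes(cluster_distributions(records), records)]
        assert adjusted_rand_score(truth, pred) > 0.8


class TestBnRecords:
    def test_class_counts_respected(self, small_dataset):
        labels = [v.label for v in small_dataset.vectors]
        assert labels.count("stable") == small_dataset.config.n_stable
        assert labels.count("unstable") == small_dataset.config.n_unstable

    def test_deterministic_cpts_impose_logic(self):
        # AND-like network with hard 0/1 tables: b = a, stability = b
        nodes = (
            bn.Node("a", "cpt"),
            bn.Node("b", "cpt", ("a",)),
            bn.Node("stability", "cpt", ("b",)),
        )
        spec = bn.NetworkSpec(nodes, variant="bn")
        params = {
            "a": bn.CptParams(np.array([0.5, 0.5])),
            "b": bn.CptParams(np.array([[1.0, 0.0], [0.0, 1.0]])),
            "stability": bn.CptParams(np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        data = bn.sample_records(spec, params, 500, np.random.default_rng(0))
        np.testing.assert_array_equal(data["b"], data["a"])
        np.testing.assert_array_equal(data["stability"], data["a"])

    def test_empirical_marginal_matches_exact_inference(self, ground_truth):
        spec, params = ground_truth
        data = bn.sample_records(spec, params, 10000, np.random.default_rng(1))
        exact = bn.infer_stability(spec, params, {})
        assert abs(data[bn.STABILITY].mean() - exact) < 0.02

    def test_ancestral_records_untilted(self, ground_truth):
        spec, params = ground_truth
        cfg = FixtureConfig()
        vecs, truth = simulate.simulate_ancestral_records(cfg, 8000, 3)
        exact = bn.infer_stability(spec, params, {})
        frac = np.mean([v.label == "stable" for v in vecs])
        assert abs(frac - exact) < 0.02


class TestSequences:
    def test_pure_profile_fills_body(self):
        class PureE(FixtureConfig):
            def class_composition(self, label):
                p = np.zeros(20)
                p[simulate.AA_INDEX["E"]] = 1.0
                return p

        cfg = PureE(n_stable=3, n_unstable=3, motif_plant_prob={})
        vecs, _ = simulate.simulate_bn_records(cfg, seed=0)
        motifs = simulate.simulate_motif_windows(cfg, seed=1)
        seqs, _, _ = simulate.simulate_sequences(cfg, vecs, motifs, seed=2)
        for v in vecs:
            body = seqs[v.protein_id][2:]
            cleave = 31  # beyond any planted signal-peptide region
            assert set(body[cleave:]) <= {"E"}

    def test_n_terminus_honours_flag(self, small_dataset):
        from stabnet.features import n_term_stabilizing

        anns = {a.protein_id: a for a in small_dataset.annotations}
        for v in small_dataset.vectors:
            seq = small_dataset.sequences[v.protein_id]
            derived = n_term_stabilizing(seq, anns[v.protein_id].signal_cleavage_pos)
            assert derived == v.n_term_stabilizing

    def test_planted_motif_present_at_offset(self, small_dataset):
        found = 0
        for pid, offsets in small_dataset.planted_offsets.items():
            seq = small_dataset.sequences[pid]
            for kind, pos in offsets.items():
                width = small_dataset.config.motif_width
                window = seq[pos : pos + width]
                all_windows = [
                    w
                    for motif in small_dataset.motif_windows[kind].values()
                    for w in motif
                ]
                # the planted window may be partially overwritten by a later
                # plant of the other kind; require most to survive intact
                if window in all_windows:
                    found += 1
        assert found > 0.8 * sum(len(o) for o in small_dataset.planted_offsets.values())

    def test_motif_scores_separate_planted_from_unplanted(self):
        cfg = FixtureConfig(
            n_stable=100,
            n_unstable=100,
            motif_plant_prob={"stable": 1.0, "unstable": 0.0},
        )
        ds = simulate.simulate_dataset(cfg, seed=1)
        background = background_from_sequences(list(ds.sequences.values()))
        sets = pipeline.build_pwm_sets(ds.motif_windows, background)
        planted, unplanted = [], []
        for v in ds.vectors:
            score = scan_sequence(ds.sequences[v.protein_id], sets["tyrosine"])
            (planted if v.label == "stable" else unplanted).append(score)
        stat = mannwhitneyu(planted, unplanted, alternative="greater")
        assert stat.pvalue < 0.01


class TestEnrichmentDirections:
    def test_planted_signs_recovered(self, small_dataset):
        from stabnet.features import enrichment_analysis

        class_of = dict(small_dataset.labels)
        results_stable = {
            r.feature_name: r
            for r in enrichment_analysis(
                small_dataset.annotations,
                small_dataset.sequences,
                class_of,
                "stable",
            )
        }
        assert results_stable["tyr_phos"].direction == "over"
        assert results_stable["acetylation"].direction == "over"
        assert results_stable["transmembrane"].direction == "under"
        assert results_stable["n_degron"].direction == "under"
        results_unstable = {
            r.feature_name: r
            for r in enrichment_analysis(
                small_dataset.annotations,
                small_dataset.sequences,
                class_of,
                "unstable",
            )
        }
        assert results_unstable["transmembrane"].direction == "over"
        assert results_unstable["signal_peptide"].direction == "over"
        assert results_unstable["n_degron"].direction == "over"


class TestPipelineSmoke:
    def test_small_cv_closes_the_loop(self, small_stability_data):
        from stabnet import evaluation

        data = small_stability_data
        ids = data.training_ids()
        labels = [data.labels[i] for i in ids]
        builder = pipeline.make_model_builder(
            data, "bn_svm", bn.EmOptions(max_iter=40, tol=1e-4)
        )
        report = evaluation.cross_validate(builder, ids, labels, folds=5, repeats=1, seed=0)
        assert report.aggregate()["auc"]["mean"] > 0.8

    def test_nn_baseline_beats_chance(self, small_dataset):
        # nearest-neighbour margin over the full encoded feature vectors
        from stabnet import evaluation

        vectors = small_dataset.vectors
        labels = [v.label for v in vectors]

        def builder(train_vecs, train_labels, seed):
            X = pipeline.encode_vectors(train_vecs)
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            baseline = evaluation.NnBaseline(
                X=(X - mu) / sd + 1e-9,
                labels=np.array([l == "stable" for l in train_labels]),
            )
            return lambda test: np.array(
                [
                    evaluation.nn_score(baseline, q)
                    for q in (pipeline.encode_vectors(test) - mu) / sd + 1e-9
                ]
            )

        report = evaluation.cross_validate(builder, vectors, labels, folds=5, repeats=1, seed=0)
        assert report.aggregate()["auc"]["mean"] > 0.7
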