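import json

import numpy as np
import pytest

from nirsnet import (
    CohortSpec,
    GroundTruthSpec,
    NuisanceSpec,
    build_modular_covariance,
    generate_cohort,
    ground_truth_matrix,
    ground_truth_network,
    simulate_subject,
    toy_graph,
)
from nirsnet.preprocess import run_preprocess, screen_artifacts
from nirsnet.netbuild import correlation_matrix, group_mean


class TestGroundTruthSpec:
    def test_partition_must_cover_all_channels(self):
        with pytest.raises(ValueError, match="partition"):
            GroundTruthSpec(n_channels=46, partition=(1, 2, 3))

    def test_between_must_be_below_within(self):
        with pytest.raises(ValueError):
            GroundTruthSpec(r_within=0.4, r_between=0.4)

    def test_default_partition_has_five_modules_of_46(self):
        t = GroundTruthSpec()
        labels, counts = np.unique(t.partition, return_counts=True)
        assert len(labels) == 5
        assert sorted(counts.tolist(), reverse=True) == [13, 12, 8, 8, 5]


class TestModularCovariance:
    def test_two_block_construction_is_exact(self):
        t = GroundTruthSpec(
            n_channels=4, partition=(1, 1, 2, 2), r_within=0.6, r_between=0.0,
            hub_channels=(),
        )
        cov = build_modular_covariance(t)
        expect = np.array(
            [
                [1.0, 0.6, 0.0, 0.0],
                [0.6, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.6],
                [0.0, 0.0, 0.6, 1.0],
            ]
        )
        assert np.allclose(cov, expect)

    def test_hub_row_raised_to_within_level(self):
        t = GroundTruthSpec(
            n_channels=6, partition=(1, 1, 1, 2, 2, 2), r_within=0.5,
            r_between=0.1, hub_channels=(0,),
        )
        cov = build_modular_covariance(t)
        assert np.allclose(cov[0, 1:], 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_valid_specs_are_psd(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        part = tuple(int(x) for x in rng.integers(1, 4, size=n))
        rb = float(rng.uniform(0.0, 0.3))
        rw = float(rng.uniform(rb + 0.1, 0.7))
        t = GroundTruthSpec(
            n_channels=n, partition=part, r_within=rw, r_between=rb, hub_channels=()
        )
        assert np.linalg.eigvalsh(build_modular_covariance(t))[0] >= -1e-10

    def test_nonpsd_target_reports_smallest_eigenvalue(self):
        # a full-raise hub row against a weak background is geometrically
        # infeasible as a correlation matrix
        t = GroundTruthSpec.__new__(GroundTruthSpec)
        object.__setattr__(t, "n_channels", 46)
        object.__setattr__(t, "partition", GroundTruthSpec().partition)
        object.__setattr__(t, "r_within", 0.6)
        object.__setattr__(t, "r_between", 0.05)
        object.__setattr__(t, "hub_channels", (0,))
        with pytest.raises(ValueError, match="eigenvalue"):
            build_modular_covariance(t)


class TestBlueprint:
    def test_edge_count_matches_blueprint_sparsity(self):
        t = GroundTruthSpec()
        bp = ground_truth_network(t)
        assert bp.K == round(0.1 * 46 * 45 / 2)

    def test_hub_is_highest_degree_node(self):
        t = GroundTruthSpec()
        deg = ground_truth_network(t).degree()
        assert deg[0] == deg.max()
        assert deg[0] >= t.hub_degree

    def test_every_node_keeps_two_within_module_edges(self):
        t = GroundTruthSpec(seed=3)
        bp = ground_truth_network(t)
        part = np.asarray(t.partition)
        a = bp.adjacency
        for i in range(1, 46):
            same = part == part[i]
            assert a[i][same].sum() >= 2

    def test_deterministic_under_seed(self):
        a = ground_truth_network(GroundTruthSpec(seed=5)).adjacency
        b = ground_truth_network(GroundTruthSpec(seed=5)).adjacency
        assert np.array_equal(a, b)

    def test_target_matrix_is_psd_correlation(self):
        m = ground_truth_matrix(GroundTruthSpec(seed=1))
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m)[0] >= -1e-8


class TestSimulateSubject:
    def test_zero_amplitude_gives_flat_zero_od(self):
        spec = CohortSpec(
            n_subjects=2, duration=60.0, hemo_amp=0.0,
            noise=NuisanceSpec(drift_amp=0, nuisance_amp=0, spike_rate=0),
            truth=GroundTruthSpec(seed=1),
        )
        rec = simulate_subject(spec, 42)
        assert np.allclose(rec.od, 0.0)

    def test_same_seed_bitwise_identical(self, small_spec):
        a = simulate_subject(small_spec, 99).od
        b = simulate_subject(small_spec, 99).od
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self, small_spec):
        a = simulate_subject(small_spec, 1).od
        b = simulate_subject(small_spec, 2).od
        assert not np.allclose(a, b)

    def test_oxy_deoxy_anticorrelation_recovered(self):
        spec = CohortSpec(
            n_subjects=2, duration=600.0, kappa=0.5,
            noise=NuisanceSpec(drift_amp=0, nuisance_amp=0, spike_rate=0),
            truth=GroundTruthSpec(seed=2), jitter_sd=0.0,
        )
        rec = simulate_subject(spec, 5)
        ts, _ = run_preprocess(rec.od, rec.fs, channel_ids=rec.channel_ids)
        rs = [
            np.corrcoef(ts.oxy[c], ts.deoxy[c])[0, 1] for c in range(ts.n_channels)
        ]
        assert abs(np.mean(rs) - (-0.5)) < 0.1


class TestGenerateCohort:
    def test_subject_count_and_distinctness(self):
        spec = CohortSpec(n_subjects=2, duration=60.0, truth=GroundTruthSpec(seed=3))
        cohort = generate_cohort(spec)
        assert len(cohort.recordings) == 2
        assert not np.allclose(cohort.recordings[0].od, cohort.recordings[1].od)

    def test_cohort_mean_correlation_converges_with_duration(self):
        # estimation error of the cohort-mean matrix decreases with duration;
        # band-limited signals carry ~2·B·T effective samples, so the
        # deviation floor scales like 1/sqrt(duration)
        target = ground_truth_matrix(GroundTruthSpec(seed=4))
        devs = []
        for duration in (150.0, 600.0, 2400.0):
            spec = CohortSpec(
                n_subjects=4, duration=duration, jitter_sd=0.0,
                noise=NuisanceSpec(drift_amp=0, nuisance_amp=0, spike_rate=0),
                truth=GroundTruthSpec(seed=4),
            )
            cohort = generate_cohort(spec)
            mats = []
            for rec in cohort.recordings:
                ts, _ = run_preprocess(rec.od, rec.fs, channel_ids=rec.channel_ids, discard_s=30.0)
                mats.append(correlation_matrix(ts))
            mean = group_mean(mats).values
            iu = np.triu_indices(46, 1)
            devs.append(np.abs(mean[iu] - target[iu]).mean())
        assert devs[0] > devs[1] > devs[2]
        assert devs[1] < 0.05  # mean absolute deviation at the study duration

    def test_injected_spikes_are_detected_by_screen(self):
        spec = CohortSpec(
            n_subjects=3, duration=120.0,
            noise=NuisanceSpec(spike_rate=6.0, spike_amp=25.0),
            truth=GroundTruthSpec(seed=5),
        )
        cohort = generate_cohort(spec)
        hits = 0
        for rec in cohort.recordings:
            qc = screen_artifacts(rec.od.mean(axis=0), rec.fs)
            hits += int(qc.motion_flags.any())
        assert hits == 3  # every spiked subject is caught

    def test_ground_truth_sidecar_roundtrip(self, tmp_path):
        spec = CohortSpec(n_subjects=2, duration=60.0, truth=GroundTruthSpec(seed=6))
        cohort = generate_cohort(spec)
        cohort.write(tmp_path)
        gt = json.loads((tmp_path / "ground_truth.json").read_text())
        assert gt["partition"] == list(spec.truth.partition)
        assert gt["hub_channels"] == [0]
        assert len(gt["subject_seeds"]) == 2


class TestToyGraphs:
    def test_complete_graph_edge_count(self):
        assert toy_graph("complete", 4).K == 6

    def test_star_degrees(self):
        g = toy_graph("star", 5)
        deg = g.degree()
        assert deg[0] == 4 and (deg[1:] == 1).all()

    def test_erdos_renyi_deterministic(self):
        a = toy_graph("erdos_renyi", 12, p=0.3, seed=4).adjacency
        b = toy_graph("erdos_renyi", 12, p=0.3, seed=4).adjacency
        assert np.array_equal(a, b)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            toy_graph("smallworldish", 10)
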