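"""Properties of the synthetic study generator."""

import numpy as np
import pytest

from mvcs.exceptions import ConfigError
from mvcs.preprocess import compute_fd
from mvcs.similarity import compute_mvcs, similarity_index
from mvcs.synthetic import (
    CONDITIONS,
    BehaviorParams,
    GeneratorConfig,
    SiEffects,
    generate_behavior,
    generate_experiment,
    generate_motion,
    generate_roi_run,
    mix_loadings,
    random_loadings,
)
from mvcs.behavior import block_performance, fit_learning_curve


def _study_arrays(study):
    """Flatten a study into a deterministic list of arrays for comparison."""
    out = []
    for key in sorted(study.data):
        cd = study.data[key]
        for bundle in (cd.pre, cd.task, cd.post):
            if bundle is None:
                continue
            out.extend(bundle.roi_ts[r].data for r in sorted(bundle.roi_ts))
            out.append(bundle.motion.values)
            out.append(bundle.wm_pool)
            out.append(bundle.csf_pool)
    return out


class TestGenerateExperiment:
    def test_same_seed_bitwise_identical(self, small_config):
        a = generate_experiment(small_config)
        b = generate_experiment(small_config)
        for x, y in zip(_study_arrays(a), _study_arrays(b)):
            assert np.array_equal(x, y)
        assert a.design.equals(b.design)
        assert a.ground_truth.table.equals(b.ground_truth.table)

    def test_latin_square_counterbalancing(self, small_config):
        study = generate_experiment(small_config, runs=(),
                                    include_behavior=False)
        design = study.design
        for visit in range(1, 5):
            conds = design[design["visit"] == visit]["condition"]
            assert sorted(conds.tolist()) == sorted(CONDITIONS)

    def test_design_one_row_per_subject_condition(self, small_config):
        study = generate_experiment(small_config, runs=(),
                                    include_behavior=False)
        assert not study.design.duplicated(["subject", "condition"]).any()
        assert len(study.design) == small_config.n_subjects * 4

    def test_structure_realism_default_geometry(self):
        # default config: 300-volume rest runs at TR 1 s, task >= 300
        # volumes at TR 2 s
        config = GeneratorConfig(n_subjects=1, rois={"roi": 10})
        study = generate_experiment(config, include_behavior=False)
        cd = study.data[("sub-01", "cSEQ")]
        assert cd.pre.roi_ts["roi"].n_volumes == 300
        assert cd.pre.roi_ts["roi"].tr == 1.0
        assert cd.task.roi_ts["roi"].n_volumes >= 300
        assert cd.task.roi_ts["roi"].tr == 2.0

    def test_full_persistence_no_noise_gives_near_perfect_si(self):
        # identical loadings; long, lightly smoothed runs so the sample
        # factor covariance converges and the matrix correlation -> 1
        config = GeneratorConfig(
            n_subjects=1, rois={"roi": 30}, rest_volumes=800,
            persistence_rho={"early_late": 0.5, "rs_pre_post": 1.0,
                             "task_rs_post": 0.0},
            factor_smooth_s=2.0,
            noise_sd=0.0, drift_amplitude=0.0, nuisance_gamma_sd=0.0,
            seed=3,
        )
        study = generate_experiment(config, runs=("pre", "post"),
                                    include_behavior=False)
        cd = study.data[("sub-01", "cSEQ")]
        si = similarity_index(
            compute_mvcs(cd.pre.roi_ts["roi"]),
            compute_mvcs(cd.post.roi_ts["roi"]),
        )
        assert np.tanh(si) > 0.95

    def test_named_field_validation(self):
        with pytest.raises(ConfigError, match="n_subjects"):
            GeneratorConfig(n_subjects=0).validate()
        with pytest.raises(ConfigError, match="persistence_rho"):
            GeneratorConfig(
                persistence_rho={"early_late": 1.5, "rs_pre_post": 0.3,
                                 "task_rs_post": 0.3}
            ).validate()
        with pytest.raises(ConfigError, match="spike_prob"):
            GeneratorConfig(spike_prob=-0.1).validate()

    def test_ground_truth_covers_every_pair(self, small_config):
        study = generate_experiment(small_config, runs=(),
                                    include_behavior=False)
        gt = study.ground_truth.table
        assert len(gt) == small_config.n_subjects * 4 * 2 * 3
        assert set(gt["pairing"]) == {"early_late", "rs_pre_post",
                                      "task_rs_post"}

    def test_si_effects_shift_persistence(self):
        config = GeneratorConfig(
            n_subjects=1, rois={"roi": 8},
            si_effects=SiEffects(task=0.2),
        )
        study = generate_experiment(config, runs=(), include_behavior=False)
        gt = study.ground_truth.table
        gt_el = gt[gt["pairing"] == "early_late"].set_index("condition")
        assert gt_el.loc["cSEQ", "rho"] == pytest.approx(0.6)
        assert gt_el.loc["cRND", "rho"] == pytest.approx(0.4)


class TestGenerateRoiRun:
    def test_rank_one_loadings_give_unit_correlations(self):
        run = generate_roi_run(
            6, 100, 1.0, np.ones((6, 1)), noise_sd=0.0, drift_amplitude=0.0,
            seed=1,
        )
        r = np.corrcoef(run.data, rowvar=False)
        assert np.allclose(r, 1.0, atol=1e-10)

    def test_shared_loadings_raise_mvcs_correlation(self):
        rng = np.random.default_rng(9)
        shared, independent = [], []
        for _ in range(25):
            w = random_loadings(30, 4, rng)
            a = generate_roi_run(30, 120, 1.0, w, rng=rng)
            b = generate_roi_run(30, 120, 1.0, w, rng=rng)
            c = generate_roi_run(30, 120, 1.0, random_loadings(30, 4, rng),
                                 rng=rng)
            ma = compute_mvcs(a)
            shared.append(similarity_index(ma, compute_mvcs(b)))
            independent.append(similarity_index(ma, compute_mvcs(c)))
        assert np.mean(shared) > np.mean(independent) + 0.3

    def test_orthogonal_groups_uncorrelated(self):
        w = np.zeros((8, 2))
        w[:4, 0] = 1.0
        w[4:, 1] = 1.0
        run = generate_roi_run(8, 5000, 1.0, w, noise_sd=0.0,
                               drift_amplitude=0.0, seed=12)
        r = np.corrcoef(run.data, rowvar=False)
        assert np.max(np.abs(r[:4, 4:])) < 0.2  # Monte-Carlo tolerance

    def test_mixing_endpoints(self, rng):
        w = random_loadings(20, 3, rng)
        assert np.allclose(mix_loadings(w, 1.0, rng), w)
        w0 = mix_loadings(w, 0.0, rng)
        # independent draw: column correlations small on average
        cross = np.abs(np.sum(w0 * w, axis=0) / np.sum(w * w, axis=0))
        assert np.mean(cross) < 0.5

    def test_too_short_run_rejected(self):
        with pytest.raises(ConfigError):
            generate_roi_run(4, 1, 1.0, np.ones((4, 1)), seed=0)

    def test_loading_shape_checked(self):
        with pytest.raises(ConfigError):
            generate_roi_run(4, 10, 1.0, np.ones((3, 1)), seed=0)


class TestGenerateMotion:
    def test_no_spikes_no_walk_gives_zero_fd(self):
        motion = generate_motion(50, 0.0, 1.0, walk_sd_mm=0.0,
                                 walk_sd_rad=0.0, seed=4)
        assert np.all(compute_fd(motion).fd == 0)

    def test_exceedance_fraction_tracks_spike_prob(self):
        fracs = [
            np.mean(compute_fd(generate_motion(300, 0.05, 1.0, seed=s)).fd
                    > 0.5)
            for s in range(100)
        ]
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_determinism(self):
        a = generate_motion(100, 0.05, 1.0, seed=77)
        b = generate_motion(100, 0.05, 1.0, seed=77)
        assert np.array_equal(a.values, b.values)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            generate_motion(10, 1.5, 1.0, seed=0)


class TestGenerateBehavior:
    def test_no_learning_amplitude_equalizes_tasks(self):
        params = BehaviorParams(rt_learning_ms=0.0)
        seq = generate_behavior("SEQ", 16, 48, params, seed=5)
        rnd = generate_behavior("RND", 16, 48, params, seed=5)
        m_seq = block_performance(seq)["mean_rt_correct"]
        m_rnd = block_performance(rnd)["mean_rt_correct"]
        assert abs(m_seq.mean() - m_rnd.mean()) < 15.0

    def test_fast_learning_reaches_baseline(self):
        params = BehaviorParams(learning_rate=5.0, rt_sigma=0.01)
        seq = generate_behavior("SEQ", 16, 48, params, seed=6)
        perf = block_performance(seq)
        last = perf.loc[perf["block"] == 16, "mean_rt_correct"].iloc[0]
        assert last == pytest.approx(params.rt_baseline_ms, rel=0.02)

    def test_learning_rate_recovered_by_curve_fit(self):
        params = BehaviorParams()
        errs = []
        for s in range(30):
            seq = generate_behavior("SEQ", 16, 48, params, seed=s)
            _, _, lam = fit_learning_curve(block_performance(seq))
            errs.append(abs(lam - params.learning_rate) / params.learning_rate)
        assert np.median(errs) < 0.2

    def test_rnd_keys_cover_all_eight_per_window(self):
        log = generate_behavior("RND", 2, 48, seed=8)
        first = log[log["block"] == 1]["target_key"].to_numpy()
        for w in range(6):
            assert sorted(first[8 * w: 8 * w + 8].tolist()) == list(range(1, 9))

    def test_structure(self):
        log = generate_behavior("SEQ", 16, 48, seed=9)
        assert len(log) == 16 * 48
        assert (log.groupby("block").size() == 48).all()
        assert (log["rt_ms"] > 0).all()
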