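"""Synthetic-study generators: contracts, reproducibility, planted structure."""

import numpy as np
import pytest

from rankwarn import (SimulationConfig, compute_baseline, score_series,
                      simulate_cohort, simulate_factor_study,
                      simulate_network_study, simulate_null_study)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 1},
        {"dnb_size": 200},                      # must be < n_genes
        {"transition_index": 0},
        {"transition_index": 16},
        {"n_normal_samples": 0},
        {"noise_sd": -1.0},
        {"mode": "banana"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestFactorStudy:
    def test_shape_and_ground_truth_contract(self):
        cfg = SimulationConfig(n_genes=200, dnb_size=20, n_timepoints=16,
                               transition_index=10, seed=1)
        st = simulate_factor_study(cfg)
        assert st.normal_matrix.n_genes == 200
        assert st.normal_matrix.n_samples == cfg.n_normal_samples
        assert st.course.n_samples == 16
        assert st.truth_transition_index == 10
        assert len(st.dnb_gene_ids) == 20
        assert st.dnb_gene_ids <= set(st.course.gene_ids)

    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(seed=7)
        a, b = simulate_factor_study(cfg), simulate_factor_study(cfg)
        np.testing.assert_array_equal(a.course.values, b.course.values)
        np.testing.assert_array_equal(a.normal_matrix.values,
                                      b.normal_matrix.values)
        assert a.dnb_gene_ids == b.dnb_gene_ids

    def test_zero_ramp_equals_null_course(self):
        cfg = SimulationConfig(seed=3, dnb_variance_ramp=0.0)
        st = simulate_factor_study(cfg)
        null = simulate_null_study(SimulationConfig(seed=3))
        np.testing.assert_array_equal(st.course.values, null.course.values)

    def test_intra_dnb_correlation_rises_after_transition(self):
        """Planted DNB module: post-transition intra-module |PCC| exceeds
        the pre-transition level in nearly every seeded run."""
        wins = 0
        runs = 100
        for seed in range(runs):
            st = simulate_factor_study(SimulationConfig(seed=seed))
            idx = [st.course.gene_ids.index(g) for g in sorted(st.dnb_gene_ids)]
            vals = st.course.values[idx]
            t = st.truth_transition_index
            pre = np.corrcoef(vals[:, :t])
            post = np.corrcoef(vals[:, t:])
            tri = np.triu_indices(len(idx), 1)
            if np.abs(post[tri]).mean() > np.abs(pre[tri]).mean():
                wins += 1
        assert wins >= 95

    def test_dnb_sd_rises_after_transition(self):
        st = simulate_factor_study(SimulationConfig(seed=11))
        idx = [st.course.gene_ids.index(g) for g in sorted(st.dnb_gene_ids)]
        other = [i for i in range(st.course.n_genes) if i not in idx]
        t = st.truth_transition_index
        vals = st.course.values
        dnb_post_sd = vals[idx][:, t:].std(axis=1).mean()
        dnb_pre_sd = vals[idx][:, :t].std(axis=1).mean()
        rest_post_sd = vals[other][:, t:].std(axis=1).mean()
        assert dnb_post_sd > 2 * dnb_pre_sd
        assert dnb_post_sd > 2 * rest_post_sd


class TestNullStudy:
    def test_no_planted_structure(self):
        st = simulate_null_study(SimulationConfig(seed=5))
        assert st.truth_transition_index is None
        assert st.dnb_gene_ids == frozenset()

    def test_byte_identical_across_runs(self):
        cfg = SimulationConfig(seed=9)
        a, b = simulate_null_study(cfg), simulate_null_study(cfg)
        assert a.course.frame.equals(b.course.frame)


class TestNetworkStudy:
    CFG = dict(n_genes=8, dnb_size=3, n_timepoints=12, transition_index=8,
               n_normal_samples=4, mode="network_sde")

    def test_truth_index_is_where_q_crosses_zero(self):
        cfg = SimulationConfig(noise_sd=0.05, seed=2, **self.CFG)
        st = simulate_network_study(cfg, burn_in=300, dt=0.02)
        assert st.truth_transition_index == 8
        assert st.q_values[8] == 0.0
        assert all(q < 0 for q in st.q_values[:8])

    def test_zero_noise_is_deterministic_across_seeds(self):
        a = simulate_network_study(
            SimulationConfig(noise_sd=0.0, seed=1, **self.CFG),
            burn_in=300, dt=0.02)
        b = simulate_network_study(
            SimulationConfig(noise_sd=0.0, seed=99, **self.CFG),
            burn_in=300, dt=0.02)
        np.testing.assert_allclose(a.course.values, b.course.values)

    def test_core_node_jumps_after_fold(self):
        cfg = SimulationConfig(noise_sd=0.02, seed=4, **self.CFG)
        st = simulate_network_study(cfg, burn_in=400, dt=0.02)
        core = st.course.values[0]
        t = st.truth_transition_index
        assert core[t + 2:].mean() > 2 * core[:t].mean()

    def test_critical_slowing_down_variance(self):
        """Across seeds, the core node's spread at q just below 0 exceeds
        its spread far from the fold (variance inflation near the
        saddle-node)."""
        far, near = [], []
        for seed in range(30):
            cfg = SimulationConfig(noise_sd=0.03, seed=seed, **self.CFG)
            st = simulate_network_study(cfg, burn_in=250, dt=0.02)
            far.append(st.course.values[0, 1])
            near.append(st.course.values[0, st.truth_transition_index - 1])
        assert np.var(near) > np.var(far)

    def test_unstable_step_reports_advice(self):
        cfg = SimulationConfig(noise_sd=0.05, seed=2, **self.CFG)
        with pytest.raises(ValueError, match="reduce dt"):
            simulate_network_study(cfg, dt=5.0, burn_in=200)

    def test_scoring_detects_the_fold(self):
        cfg = SimulationConfig(noise_sd=0.05, seed=6, **self.CFG)
        st = simulate_network_study(cfg, burn_in=400, dt=0.02)
        baseline = compute_baseline(st.normal_matrix)
        s = score_series(st.course, baseline, m=4)
        jump = int(np.argmax(np.diff(s.ranking_scores)) + 1)
        assert abs(jump - st.truth_transition_index) <= 2


class TestCohort:
    def test_layout_and_truth(self):
        cfg = SimulationConfig(n_genes=60, dnb_size=8, n_timepoints=6,
                               transition_index=3, n_normal_samples=2, seed=0)
        matrix, meta, truth = simulate_cohort(cfg, n_case_subjects=2,
                                              n_null_subjects=3)
        assert matrix.n_samples == 5 * (2 + 6)
        assert set(meta["group"]) == {"baseline", "case", "normal"}
        assert truth["transition_index"] == 3
        assert len(truth["dnb_gene_ids"]) == 8
        assert truth["case_subjects"] == ["case00", "case01"]
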