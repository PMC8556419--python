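import numpy as np
import pytest

from conftest import make_panel
from introseek import iohub, seeker, simulate
from introseek.iohub import (ROLE_AFRICAN, ROLE_ARCHAIC_PREFIX, ROLE_OUTGROUP,
                             ROLE_TEST)
from introseek.seeker import HMMParams

ARCH = ROLE_ARCHAIC_PREFIX + "NEA"


class TestClassification:
    # columns: test, archaic, african, outgroup
    ROLES = [ROLE_TEST, ARCH, ROLE_AFRICAN, ROLE_OUTGROUP]

    @pytest.mark.parametrize("row,expected", [
        ([1, 1, 0, 0], 2),   # archaic marker
        ([1, 0, 1, 0], 3),   # AMH marker
        ([1, 0, 0, 0], 1),   # test-specific
        ([1, 1, 1, 0], 4),   # shared by both reference panels
        ([0, 1, 0, 0], 4),   # test ancestral
        ([0, 0, 1, 0], 4),
    ])
    def test_four_state_rules(self, row, expected):
        panel = make_panel([row], self.ROLES)
        obs = seeker.classify_observations(panel, "h0")
        assert obs[0] == expected

    def test_non_test_haplotype_rejected(self):
        panel = make_panel([[1, 1, 0, 0]], self.ROLES)
        with pytest.raises(ValueError, match="test"):
            seeker.classify_observations(panel, "h1")

    def test_missing_reference_genotypes_uninformative(self):
        # archaic missing, African ancestral: derived allele cannot be
        # attributed to the archaic panel -> test-specific
        panel = make_panel([[1, -1, 0, 0]], self.ROLES)
        assert seeker.classify_observations(panel, "h0")[0] == 1


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        P = seeker.transition_matrix(0.0, HMMParams(alpha=0.02, T=2000))
        np.testing.assert_allclose(P, np.eye(2))

    def test_large_distance_reaches_stationary(self):
        P = seeker.transition_matrix(1e3, HMMParams(alpha=0.02, T=2000))
        np.testing.assert_allclose(P, [[0.98, 0.02], [0.98, 0.02]], atol=1e-12)

    def test_direct_evaluation(self):
        P = seeker.transition_matrix(1e-4, HMMParams(alpha=0.02, T=2000))
        assert P[0, 1] == pytest.approx(0.02 * (1 - np.exp(-0.2)))
        assert P[1, 0] == pytest.approx(0.98 * (1 - np.exp(-0.2)))

    def test_rows_stochastic_for_grid(self):
        params = HMMParams(alpha=0.1, T=500)
        for d in [0.0, 1e-8, 1e-4, 1e-2, 1.0]:
            P = seeker.transition_matrix(d, params)
            np.testing.assert_allclose(P.sum(axis=1), [1.0, 1.0])
            assert np.all(P >= 0)


class TestEMFit:
    def test_loglik_monotone_and_alpha_recovered(self, small_pipeline):
        cfg, pp, truth, segments, params = small_pipeline
        trace = np.asarray(params.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))
        assert 0.01 <= params.alpha <= 0.04  # truth 0.02

    def test_posteriors_sum_to_one(self, small_pipeline):
        cfg, pp, truth, segments, params = small_pipeline
        obs, haps = seeker.classify_all(pp)
        post = seeker.posterior_matrix(obs, pp, params)
        assert np.all(post >= -1e-10) and np.all(post <= 1 + 1e-10)

    def test_no_informative_sites_errors(self):
        roles = [ROLE_TEST, ARCH, ROLE_AFRICAN, ROLE_OUTGROUP]
        panel = make_panel([[0, 1, 0, 0], [0, 0, 1, 0]], roles)
        obs, _ = seeker.classify_all(panel)
        with pytest.raises(ValueError, match="no markers"):
            seeker.em_fit(obs, panel)

    def test_panel_without_archaic_signal_fits_low_alpha(self):
        rng = np.random.default_rng(3)
        n = 4000
        roles = ([ROLE_TEST] * 4 + [ARCH] * 2 + [ROLE_AFRICAN] * 10
                 + [ROLE_OUTGROUP])
        A = np.zeros((n, len(roles)), dtype=np.int8)
        # only AMH markers and common sites: no state 1 or 2 at all
        shared = rng.random(n) < 0.5
        A[shared, 0:4] = 1
        A[shared, 6:16] = 1
        common = ~shared
        A[common] = 1
        A[common, -1] = 0
        panel = make_panel(A, roles, positions=np.arange(1, n + 1) * 500)
        obs, haps = seeker.classify_all(panel)
        assert not np.any((obs == 1) | (obs == 2))
        params = seeker.em_fit(obs, panel)
        assert params.alpha <= 0.02
        segs = seeker.decode_segments(obs, panel, params, haps)
        frac = seeker.archaic_fraction(segs, 4, panel.length)
        assert frac < 0.01


class TestDecode:
    def test_all_amh_markers_give_no_segments(self):
        roles = [ROLE_TEST, ARCH, ROLE_AFRICAN, ROLE_OUTGROUP]
        n = 500
        A = np.zeros((n, 4), dtype=np.int8)
        A[:, 0] = 1
        A[:, 2] = 1  # every site an AMH marker
        panel = make_panel(A, roles, positions=np.arange(1, n + 1) * 1000)
        obs, haps = seeker.classify_all(panel)
        params = HMMParams()
        params.emission = seeker.initial_emission(
            np.bincount(obs.ravel(), minlength=5)[1:] / obs.size)
        segs = seeker.decode_segments(obs, panel, params, haps)
        assert segs == []

    def test_single_tract_boundaries_within_25kb(self):
        cfg = simulate.ScenarioConfig(
            seed=11, length_bp=8_000_000, n_test=6,
            waves=[("NEA", 800.0, 0.02)])
        from introseek import pipeline
        pp, truth = pipeline.prepare_panel(cfg)
        segments, params = pipeline.seek_segments(pp)
        tr = truth.table
        big = tr[(tr.end - tr.start) > 80_000]
        assert len(big) > 0
        found = 0
        for _, t in big.iterrows():
            near = [s for s in segments if s.haplotype == t.haplotype
                 and s.start < t.end and s.end > t.start]
            if near and (abs(near[0].start - t.start) < 25_000
                       and abs(near[-1].end - t.end) < 25_000):
                found += 1
        assert found / len(big) >= 0.7

    def test_segments_sorted_disjoint_per_haplotype(self, small_pipeline):
        cfg, pp, truth, segments, params = small_pipeline
        by_hap = {}
        for s in segments:
            by_hap.setdefault(s.haplotype, []).append(s)
        for segs in by_hap.values():
            for a, b in zip(segs, segs[1:]):
                assert a.end <= b.start

    def test_pure_archaic_input_decoded_archaic(self, small_scenario):
        """Archaic references duplicated as test haplotypes are called
        archaic nearly everywhere; African-as-test almost nowhere."""
        cfg, panel, truth = small_scenario
        pp = iohub.polarize(panel, "outgroup")
        pp = iohub.attach_genetic_map(pp, simulate.scenario_map(cfg))
        arch_idx = pp.archaic_indices("NEA")
        afr_idx = pp.hap_indices(ROLE_AFRICAN)
        test_idx = pp.hap_indices(ROLE_TEST)

        def swap_roles(source_cols):
            A = pp.alleles.copy()
            A[:, test_idx[:len(source_cols)]] = pp.alleles[:, source_cols]
            import dataclasses
            return dataclasses.replace(pp, alleles=A)

        arch_panel = swap_roles(arch_idx)
        obs, haps = seeker.classify_all(arch_panel)
        obs = obs[:len(arch_idx)]
        haps = haps[:len(arch_idx)]
        params = seeker.em_fit(obs, arch_panel,
                               init=HMMParams(alpha=0.3, T=2000))
        segs = seeker.decode_segments(obs, arch_panel, params, haps)
        frac = seeker.archaic_fraction(segs, len(haps), arch_panel.length)
        assert frac > 0.95

        afr_panel = swap_roles(afr_idx[:4])
        obs, haps = seeker.classify_all(afr_panel)
        obs = obs[:4]
        haps = haps[:4]
        params = seeker.em_fit(obs, afr_panel)
        segs = seeker.decode_segments(obs, afr_panel, params, haps)
        frac = seeker.archaic_fraction(segs, 4, afr_panel.length)
        assert frac < 0.01
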