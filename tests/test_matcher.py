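import numpy as np
import pytest

from introseek import iohub, matcher, simulate
from introseek.iohub import Segment
from introseek.matcher import (AncestryTree, LABEL_AMH, LABEL_ANCESTOR,
                               LABEL_UNKNOWN)


@pytest.fixture(scope="module")
def calibrated():
    cfg = simulate.two_lineage_scenario(seed=5, length_bp=8_000_000, n_test=8)
    panel, truth = simulate.simulate_panel(cfg)
    pp = iohub.polarize(panel, "outgroup")
    pp = iohub.attach_genetic_map(pp, simulate.scenario_map(cfg))
    tree = matcher.calibrate_tree(pp)
    return cfg, pp, truth, tree


class TestCalibration:
    def test_outgroup_required(self, small_scenario):
        cfg, panel, _ = small_scenario
        pp = iohub.polarize(panel, "outgroup")
        import dataclasses
        roles = {h: (iohub.ROLE_AFRICAN if r == iohub.ROLE_OUTGROUP else r)
                 for h, r in pp.roles.items()}
        no_out = dataclasses.replace(pp, roles=roles)
        with pytest.raises(ValueError, match="outgroup"):
            matcher.calibrate_tree(no_out)

    def test_node_depths_recovered_within_10pct(self, calibrated):
        """Clock depths from a clean painted panel (diversity layers off)
        match the configured split times."""
        cfg0 = simulate.ScenarioConfig(
            seed=9, length_bp=8_000_000, n_test=4, waves=[("NEA", 1500.0, 0.02)],
            d_amh_poly=0.0, d_afr_priv=0.0, d_test_priv=0.0, d_ils=0.0,
            d_ref_het=0.0)
        panel, _ = simulate.simulate_panel(cfg0)
        pp = iohub.polarize(panel, "outgroup")
        tree = matcher.calibrate_tree(pp)
        mu = cfg0.mu
        assert tree.h_nd == pytest.approx(mu * cfg0.gens(cfg0.t_nd_kya), rel=0.1)
        assert tree.h_arch == pytest.approx(mu * cfg0.gens(cfg0.t_arch_kya),
                                            rel=0.1)
        assert tree.h_root == pytest.approx(mu * cfg0.gens(cfg0.t_out_kya),
                                            rel=0.1)

    def test_depths_are_nested(self, calibrated):
        *_, tree = calibrated
        assert 0 < tree.h_nd <= tree.h_arch <= tree.h_root

    def test_negative_or_inverted_depths_clamped(self):
        t = AncestryTree(("NEA", "DEN"), 2e-4, 3e-4, 3e-3)
        t.validate()
        with pytest.raises(ValueError):
            AncestryTree(("NEA", "DEN"), 4e-4, 3e-4, 3e-3).validate()

    def test_newick_round_trip(self):
        t = AncestryTree(("NEA", "DEN"), 2e-4, 3e-4, 3e-3)
        back = AncestryTree.from_newick(t.to_newick())
        assert back.archaic_names == ("DEN", "NEA") or \
            back.archaic_names == ("NEA", "DEN")
        assert back.h_nd == pytest.approx(t.h_nd)
        assert back.h_root == pytest.approx(t.h_root)


class TestDifferenceProfile:
    def test_identical_to_reference_gives_zero_density(self, calibrated):
        cfg, pp, truth, tree = calibrated
        test_idx = pp.hap_indices(iohub.ROLE_TEST)
        nea_idx = pp.archaic_indices("NEA")
        import dataclasses
        A = pp.alleles.copy()
        A[:, test_idx[0]] = pp.alleles[:, nea_idx[0]]
        clone = dataclasses.replace(pp, alleles=A)
        seg = Segment(pp.chrom, 0, 1_000_000,
                      pp.haplotypes[test_idx[0]])
        prof = matcher.segment_difference_profile(seg, clone)
        assert prof["NEA"][0] == 0

    def test_density_arithmetic(self):
        """10 differing variant sites over 10 kb -> 10 per 10,000 bp."""
        from conftest import make_panel
        roles = [iohub.ROLE_TEST, iohub.ROLE_ARCHAIC_PREFIX + "NEA",
                 iohub.ROLE_ARCHAIC_PREFIX + "DEN", iohub.ROLE_AFRICAN,
                 iohub.ROLE_OUTGROUP]
        A = np.zeros((10, 5), dtype=np.int8)
        A[:, 0] = 1  # test derived everywhere, references ancestral
        panel = make_panel(A, roles, positions=np.arange(10) * 1000 + 500,
                           chrom_length=10_000)
        seg = Segment("1", 0, 10_000, "h0")
        prof = matcher.segment_difference_profile(seg, panel)
        k, L = prof["NEA"]
        assert k == 10 and L == pytest.approx(10_000)

    def test_missing_data_halves_callable_bp(self):
        from conftest import make_panel
        roles = [iohub.ROLE_TEST, iohub.ROLE_ARCHAIC_PREFIX + "NEA",
                 iohub.ROLE_ARCHAIC_PREFIX + "DEN", iohub.ROLE_AFRICAN,
                 iohub.ROLE_OUTGROUP]
        A = np.zeros((10, 5), dtype=np.int8)
        A[:, 0] = 1
        A[5:, 1] = -1  # NEA missing at half the sites
        panel = make_panel(A, roles, positions=np.arange(10) * 1000 + 500,
                           chrom_length=10_000)
        prof = matcher.segment_difference_profile(
            Segment("1", 0, 10_000, "h0"), panel)
        assert prof["NEA"][1] == pytest.approx(5_000)

    def test_empty_segment_errors(self, calibrated):
        cfg, pp, truth, tree = calibrated
        hap = pp.haplotypes[pp.hap_indices(iohub.ROLE_TEST)[0]]
        gaps = np.diff(pp.positions)
        i = int(np.argmax(gaps))
        start = int(pp.positions[i]) + 1
        end = int(pp.positions[i + 1])  # window containing no site
        with pytest.raises(ValueError, match="uninformative"):
            matcher.segment_difference_profile(
                Segment(pp.chrom, start, end, hap), pp)


def _profile(tree, dN, dD, dA, dO, L=50_000):
    return {"NEA": (int(dN * L), L), "DEN": (int(dD * L), L),
            "AMH": (int(dA * L), L), "outgroup": (int(dO * L), L)}


class TestMatchSegment:
    TREE = AncestryTree(("NEA", "DEN"), 1.875e-4, 2.9e-4, 2.7e-3)

    def test_lineage_profiles_assigned_to_terminal_edges(self):
        t = self.TREE
        prof = _profile(t, dN=1.5e-4, dD=2 * t.h_nd, dA=2 * t.h_arch,
                        dO=2 * t.h_root)
        lls, label, depth = matcher.match_segment(prof, t)
        assert label == "NEA"
        assert depth == pytest.approx(0.75e-4, rel=0.15)

    def test_amh_profile_is_false_positive(self):
        t = self.TREE
        prof = _profile(t, dN=2 * t.h_arch, dD=2 * t.h_arch, dA=1e-4,
                        dO=2 * t.h_root)
        _, label, _ = matcher.match_segment(prof, t)
        assert label == LABEL_AMH

    def test_deep_symmetric_profile_is_unknown(self):
        t = self.TREE
        mid = t.h_nd + 0.6 * (t.h_arch - t.h_nd)
        prof = _profile(t, dN=2 * mid, dD=2 * mid, dA=2 * t.h_arch,
                        dO=2 * t.h_root)
        _, label, depth = matcher.match_segment(prof, t)
        assert label in (LABEL_UNKNOWN, LABEL_ANCESTOR)
        assert depth == pytest.approx(mid, rel=0.15)

    def test_tie_prefers_rootward_label(self):
        t = self.TREE
        lls = {"NEA": 1.0, LABEL_UNKNOWN: 1.0}
        assert matcher._rank(LABEL_UNKNOWN) < matcher._rank("NEA")

    def test_every_result_has_exactly_seven_logliks(self):
        t = self.TREE
        prof = _profile(t, 1e-4, 3e-4, 6e-4, 5e-3)
        lls, label, _ = matcher.match_segment(prof, t)
        assert len(lls) == 7
        assert label in lls
        assert all(np.isfinite(v) for v in lls.values())
        assert label == max(lls, key=lambda k: (lls[k], -matcher._rank(k)))


class TestSplitTime:
    def test_zero_density_clamps_to_edge_floor(self):
        t = TestMatchSegment.TREE
        prof = _profile(t, dN=0.0, dD=2 * t.h_nd, dA=2 * t.h_arch,
                        dO=2 * t.h_root)
        _, label, depth = matcher.match_segment(prof, t)
        assert label == "NEA"
        assert depth == 0.0

    def test_unit_conversion_2000_generations_is_60kya(self):
        t = TestMatchSegment.TREE
        depth = matcher.DEFAULT_MU * 2000
        kya = matcher.estimate_split_time(depth, t, "NEA", gen_years=30.0)
        assert kya == pytest.approx(60.0)

    def test_synthetic_density_recovers_time_within_20pct(self):
        """A noise-free profile with density 2*mu*t dates the split at t."""
        t = TestMatchSegment.TREE
        mu = matcher.DEFAULT_MU
        for gens in (4000.0, 8000.0):
            prof = _profile(t, dN=2 * mu * gens, dD=2 * t.h_nd,
                            dA=2 * t.h_arch, dO=2 * t.h_root)
            _, label, depth = matcher.match_segment(prof, t)
            est = depth / mu
            assert label == "NEA"
            assert est == pytest.approx(gens, rel=0.2)


class TestEndToEndMatching:
    def test_truth_tract_lineage_accuracy(self, calibrated):
        cfg, pp, truth, tree = calibrated
        t = truth.table
        t = t[(t.end - t.start) >= 15_000]
        segs = [Segment(pp.chrom, int(r.start), int(r.end), r.haplotype)
                for _, r in t.iterrows()]
        res = matcher.match_segments(segs, pp, tree)
        acc = np.mean([r.label == lin for r, lin in zip(res, t.lineage)])
        assert acc > 0.8

    def test_accuracy_increases_with_length(self, calibrated):
        from scipy.stats import spearmanr
        cfg, pp, truth, tree = calibrated
        t = truth.table
        t = t[(t.end - t.start) >= 10_000]
        segs = [Segment(pp.chrom, int(r.start), int(r.end), r.haplotype)
                for _, r in t.iterrows()]
        res = matcher.match_segments(segs, pp, tree)
        lens = np.array([s.length for s in segs])
        ok = np.array([r.label == lin for r, lin in zip(res, t.lineage)])
        edges = np.quantile(lens, [0, 0.33, 0.66, 1.0])
        accs = [ok[(lens >= lo) & (lens <= hi)].mean()
                for lo, hi in zip(edges[:-1], edges[1:])]
        rho, _ = spearmanr(range(len(accs)), accs)
        assert rho > 0
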