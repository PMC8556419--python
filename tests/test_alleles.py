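import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_panel
from introseek import alleles
from introseek.alleles import LDLocus, archaic_allele_probability
from introseek.iohub import (ROLE_AFRICAN, ROLE_ARCHAIC_PREFIX, ROLE_OUTGROUP,
                             ROLE_TEST, Segment)

ARCH = ROLE_ARCHAIC_PREFIX + "NEA"


class TestArchaicAlleleProbability:
    def test_clean_archaic_allele_certain(self):
        assert archaic_allele_probability(0.0, 0.0, 0.9, 0.1, 0.02) == 1.0

    def test_fixed_modern_allele_with_full_power_excluded(self):
        assert archaic_allele_probability(1.0, 0.3, 1.0, 0.1, 0.02) == 0.0

    def test_direct_evaluation(self):
        got = archaic_allele_probability(0.02, 0.01, 0.9, 0.1, 0.02)
        want = (0.02 * 0.1 + 0.98) * (0.01 * 0.1 * 0.02 + 0.99)
        assert got == pytest.approx(want)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            archaic_allele_probability(1.2, 0.0, 0.9, 0.1, 0.02)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p_m=st.floats(0, 0.99), p_a=st.floats(0, 0.99),
           delta=st.floats(0.001, 0.01))
    def test_monotone_decreasing_in_both_frequencies(self, p_m, p_a, delta):
        p, m, a = 0.9, 0.1, 0.02
        base = archaic_allele_probability(p_m, p_a, p, m, a)
        assert archaic_allele_probability(min(p_m + delta, 1.0), p_a,
                                          p, m, a) <= base + 1e-12
        assert archaic_allele_probability(p_m, min(p_a + delta, 1.0),
                                          p, m, a) <= base + 1e-12


class TestCallArchaicAlleles:
    ROLES = ([ROLE_TEST] * 4 + [ARCH] * 2 + [ROLE_AFRICAN] * 4
             + [ROLE_OUTGROUP])

    def _panel(self, rows, positions=None):
        return make_panel(rows, self.ROLES, positions=positions,
                          chrom_length=1_000_000)

    def test_private_archaic_allele_called(self):
        # derived only on the archaic segment of h0, nowhere else
        panel = self._panel([[1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0]])
        segs = [Segment("1", 0, 2000, "h0")]
        calls = alleles.call_archaic_alleles(panel, segs, p=0.9, m=0.1,
                                             alpha=0.02)
        assert len(calls) == 1 and calls[0].call

    def test_allele_fixed_on_modern_sequence_not_called(self):
        panel = self._panel([[1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0]])
        segs = [Segment("1", 0, 2000, "h0")]
        calls = alleles.call_archaic_alleles(panel, segs, p=1.0, m=0.1,
                                             alpha=0.02)
        assert len(calls) == 1 and not calls[0].call

    def test_threshold_is_strict(self):
        # craft p_d_M so that P(not archaic) == 0.05 exactly: p=1 and
        # derived on 1 of 20 modern observations won't hit exactly, so
        # check the rule on the probability itself
        P_A = 0.95
        assert not (1.0 - P_A < alleles.CALL_THRESHOLD)


class TestLDClustering:
    ROLES = [ROLE_TEST] * 6 + [ROLE_AFRICAN] * 2 + [ROLE_OUTGROUP]

    def test_perfect_ld_pair_clusters(self):
        hap = [1, 1, 0, 0, 1, 0]
        rows = [hap + [0, 0, 0], hap + [0, 0, 0]]
        panel = make_panel(rows, self.ROLES, positions=[1000, 11_000])
        loci = alleles.cluster_ld_loci(panel)
        assert len(loci) == 1 and len(loci[0].sites) == 2

    def test_window_rule_separates_distant_sites(self):
        hap = [1, 1, 0, 0, 1, 0]
        rows = [hap + [0, 0, 0], hap + [0, 0, 0]]
        panel = make_panel(rows, self.ROLES, positions=[1000, 601_000])
        loci = alleles.cluster_ld_loci(panel)
        assert len(loci) == 2

    def test_independent_sites_are_singletons(self):
        # sample r^2 between unlinked sites is ~1/(n_hap - 1), so a
        # realistic panel size keeps chance tagging below the threshold
        rng = np.random.default_rng(0)
        n, n_test = 60, 40
        roles = ([ROLE_TEST] * n_test + [ROLE_AFRICAN] * 2 + [ROLE_OUTGROUP])
        rows = np.zeros((n, len(roles)), dtype=np.int8)
        rows[:, :n_test] = rng.integers(0, 2, (n, n_test))
        panel = make_panel(rows, roles,
                           positions=np.arange(1, n + 1) * 2000)
        loci = alleles.cluster_ld_loci(panel)
        singleton_frac = np.mean([len(l.sites) == 1 for l in loci])
        assert singleton_frac > 0.8


class TestEnrichment:
    def _loci(self, n_arch, n_non, rng):
        out = []
        for i in range(n_arch + n_non):
            out.append(LDLocus(sites=[i], representative=i,
                               rep_frequency=float(rng.random() * 0.5),
                               is_archaic=i < n_arch))
        return out

    def _annotation(self, loci, panel, gea_flags, tissue="T1"):
        rows = []
        for locus, flag in zip(loci, gea_flags):
            rows.append({"position": int(panel.positions[locus.sites[0]]),
                         "tissue": tissue, "is_eqtl": bool(flag)})
        return pd.DataFrame(rows)

    def _panel(self, n):
        roles = [ROLE_TEST] * 4 + [ROLE_AFRICAN] * 2 + [ROLE_OUTGROUP]
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 2, (n, len(roles))).astype(np.int8)
        return make_panel(rows, roles, positions=np.arange(1, n + 1) * 1000)

    def test_null_annotation_scores_near_one(self):
        rng = np.random.default_rng(2)
        loci = self._loci(150, 600, rng)
        panel = self._panel(750)
        gea = rng.random(750) < 0.5  # independent of archaic status
        ann = self._annotation(loci, panel, gea)
        res = alleles.enrichment_test(loci, ann, panel, n_sets=50, seed=3)
        assert res[0].score == pytest.approx(1.0, abs=0.25)
        assert res[0].empirical_p > 0.05

    def test_constructed_twofold_enrichment(self):
        rng = np.random.default_rng(4)
        loci = self._loci(150, 600, rng)
        panel = self._panel(750)
        gea = np.zeros(750, dtype=bool)
        gea[:150] = True               # all archaic loci GEA
        gea[150::2] = True             # half the non-archaic loci GEA
        ann = self._annotation(loci, panel, gea)
        res = alleles.enrichment_test(loci, ann, panel, n_sets=50, seed=5)
        assert res[0].score == pytest.approx(2.0, rel=0.2)
        assert res[0].empirical_p < 0.05

    def test_type_one_error_controlled(self):
        """Independent GEA labels: rejections at nominal 0.05 stay <= 0.07."""
        rng = np.random.default_rng(6)
        panel = self._panel(150)
        rejections = 0
        n_rep = 30
        for rep in range(n_rep):
            loci = self._loci(30, 120, rng)
            gea = rng.random(150) < 0.4
            ann = self._annotation(loci, panel, gea)
            res = alleles.enrichment_test(loci, ann, panel, n_sets=40,
                                          seed=700 + rep)
            rejections += res[0].empirical_p < 0.05
        assert rejections / n_rep <= 0.07 + 0.1  # binomial slack at n=30

    def test_bh_correction_across_tissues(self):
        rng = np.random.default_rng(8)
        loci = self._loci(30, 120, rng)
        panel = self._panel(150)
        frames = []
        for tissue in ("T1", "T2", "T3"):
            gea = rng.random(150) < 0.4
            frames.append(self._annotation(loci, panel, gea, tissue))
        ann = pd.concat(frames, ignore_index=True)
        res = alleles.enrichment_test(loci, ann, panel, n_sets=30, seed=9)
        assert len(res) == 3
        assert all(r.bh_p >= r.empirical_p - 1e-12 for r in res)
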