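"""Generators: determinism, planted structure, error-rate calibration."""

import numpy as np
import pytest

from oxvar.ld_analysis import ld_matrix, pairwise_ld
from oxvar.site_profiles import AH, MH
from oxvar.synthetic_data import (BlockSpec, PanelConfig, simulate_archaic_calls,
                                  simulate_association_table, simulate_haplotypes,
                                  simulate_site_panel)


class TestSitePanel:
    def test_single_mhu_site_pattern(self):
        cfg = PanelConfig(n_sites_per_category={"MHU": 1}, allele_alphabet="AT", seed=2)
        panel, truth = simulate_site_panel(cfg)
        (prof,) = panel
        anc = truth.ancestral[prof.site_id]
        der = next(iter(prof.alleles[MH] - {anc}))
        assert prof.alleles[MH] == {anc, der}
        assert prof.alleles[AH] == {anc}
        for sp in cfg.nhp_taxa:
            assert prof.alleles[sp] == {anc}

    def test_all_counts_zero_empty_panel(self):
        cfg = PanelConfig(n_sites_per_category={}, seed=0)
        panel, truth = simulate_site_panel(cfg)
        assert panel == [] and truth.site_class == {}

    def test_fixed_seed_bit_identical(self):
        a, ta = simulate_site_panel(PanelConfig(seed=9))
        b, tb = simulate_site_panel(PanelConfig(seed=9))
        assert a == b and ta.ancestral == tb.ancestral and ta.site_class == tb.site_class

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            PanelConfig(allele_alphabet="")
        with pytest.raises(ValueError, match="MH"):
            PanelConfig(taxa=("AH", "chimpanzee"))
        with pytest.raises(ValueError, match="negative"):
            PanelConfig(n_sites_per_category={"MHU": -1})


class TestArchaicCalls:
    def test_no_noise_equals_planted_alleles(self):
        panel, _ = simulate_site_panel(PanelConfig(seed=4))
        sim = simulate_archaic_calls(panel, error_rate=0.0, mq_mean=37, seed=1)
        for g, sites in sim.calls.calls.items():
            for sid, entries in sites.items():
                assert entries[0][0] == sim.truth[g][sid]

    def test_error_rate_one_forces_flip(self):
        cfg = PanelConfig(n_sites_per_category={"MHU": 3}, allele_alphabet="AT", seed=0)
        panel, truth = simulate_site_panel(cfg)
        sim = simulate_archaic_calls(panel, error_rate=1.0, mq_mean=37, seed=1,
                                     alphabet="AT")
        for g, sites in sim.calls.calls.items():
            for sid, entries in sites.items():
                assert entries[0][0] != sim.truth[g][sid]

    def test_flip_fraction_within_binomial_envelope(self):
        """Observed flip fraction within 3 binomial SD of the planted 0.05."""
        cfg = PanelConfig(n_sites_per_category={"MHU": 1000}, seed=0)
        panel, _ = simulate_site_panel(cfg)
        sim = simulate_archaic_calls(panel, error_rate=0.05, mq_mean=37, seed=12)
        n = flips = 0
        for g, sites in sim.calls.calls.items():
            for sid, entries in sites.items():
                n += 1
                flips += entries[0][0] != sim.truth[g][sid]
        p = flips / n
        sd = (0.05 * 0.95 / n) ** 0.5
        assert abs(p - 0.05) < 3 * sd

    def test_mq_spread_crosses_threshold(self):
        panel, _ = simulate_site_panel(PanelConfig(seed=4))
        sim = simulate_archaic_calls(panel, error_rate=0.0, mq_mean=25, seed=3)
        mqs = [mq for sites in sim.calls.calls.values()
               for entries in sites.values() for _, mq in entries]
        assert min(mqs) >= 0
        assert any(m < 25 for m in mqs) and any(m >= 25 for m in mqs)

    def test_negative_mq_mean_rejected(self):
        panel, _ = simulate_site_panel(PanelConfig(seed=4))
        with pytest.raises(ValueError, match="mq_mean"):
            simulate_archaic_calls(panel, 0.0, -1.0, 0)


class TestHaplotypes:
    def test_within_r2_one_duplicates_columns(self):
        hap = simulate_haplotypes(BlockSpec([["a", "b"]], 1.0, 0.2, 50), seed=0)
        pair = pairwise_ld(hap, 0, 1)
        assert pair.r2 == pytest.approx(1.0)

    def test_independent_singletons_near_zero_r2(self):
        hap = simulate_haplotypes(BlockSpec([["a"], ["b"]], 1.0, 0.2, 2000), seed=1)
        assert pairwise_ld(hap, 0, 1).r2 < 0.01

    def test_planted_groups_meet_targets(self):
        spec = BlockSpec([["a", "b", "c"], ["d", "e"]], 0.9, 0.2, 500)
        hap = simulate_haplotypes(spec, seed=2, site_ids=list("abcdefg"))
        ld = ld_matrix(hap)
        idx = {s: i for i, s in enumerate(hap.site_ids)}
        for grp in spec.groups:
            for i, a in enumerate(grp):
                for b in grp[i + 1:]:
                    assert ld.r2[idx[a], idx[b]] >= 0.9
        for a in "abc":
            for b in "de":
                assert ld.r2[idx[a], idx[b]] <= 0.2

    def test_empirical_r2_converges_to_target(self):
        """At n=2000 the realized within-pair r2 sits near the tuned expectation."""
        spec = BlockSpec([["a", "b"]], 0.8, 0.2, 2000)
        hap = simulate_haplotypes(spec, seed=3)
        assert 0.8 <= pairwise_ld(hap, 0, 1).r2 <= 1.0

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="multiple groups"):
            BlockSpec([["a", "b"], ["b", "c"]], 0.9, 0.2, 100)

    def test_bad_targets_rejected(self):
        with pytest.raises(ValueError, match="r2 targets"):
            BlockSpec([["a"]], 1.5, 0.2, 100)

    def test_deterministic_given_seed(self):
        spec = BlockSpec([["a", "b"]], 0.9, 0.2, 100)
        h1 = simulate_haplotypes(spec, seed=7)
        h2 = simulate_haplotypes(spec, seed=7)
        assert (h1.data == h2.data).all()


class TestAssociationTable:
    def test_degenerate_mixture_all_strong(self):
        df = simulate_association_table({"G": (1.0, 0.0, 0.0)}, 5, 4, seed=0)
        assert set(df["category"]) == {"strong"}

    def test_zero_snps_empty_table(self):
        df = simulate_association_table({"G": (0.5, 0.25, 0.25)}, 0, 10, seed=0)
        assert df.empty

    def test_category_shares_within_multinomial_envelope(self):
        """1000 studies/SNP: per-category shares within 3 SD of (0.5, 0.25, 0.25)."""
        df = simulate_association_table({"G": (0.5, 0.25, 0.25)}, 1, 1000, seed=5)
        n = len(df)
        for cat, p in zip(("strong", "possible", "unrelated"), (0.5, 0.25, 0.25)):
            share = (df["category"] == cat).mean()
            sd = (p * (1 - p) / n) ** 0.5
            assert abs(share - p) < 3 * sd

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_association_table({"G": (0.5, 0.2, 0.2)}, 1, 10, seed=0)
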