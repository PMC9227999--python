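"""Mapping-quality, concordance and outlier-genome filters."""

import pytest

from oxvar.archaic_filter import (ArchaicCallSet, archaic_calls_frame,
                                  archaic_calls_from_frame, concordance_filter,
                                  filter_by_mq, flag_outlier_genomes)
from oxvar.site_profiles import AH
from oxvar.synthetic_data import PanelConfig, simulate_archaic_calls, simulate_site_panel


def make_calls(site_alleles: dict[str, list[tuple[str, float]]]) -> ArchaicCallSet:
    """One site, one call per genome: {genome: (allele, mq)} shorthand."""
    return ArchaicCallSet({g: {"s1": [entry]} for g, entry in site_alleles.items()})


class TestMQFilter:
    def test_threshold_is_inclusive(self):
        calls = make_calls({"g1": ("A", 20), "g2": ("A", 25), "g3": ("A", 30)})
        kept = filter_by_mq(calls, 25)
        assert set(kept.alleles_at("s1")) == {"g2", "g3"}

    def test_threshold_zero_is_identity(self):
        calls = make_calls({"g1": ("A", 20), "g2": ("T", 0)})
        assert filter_by_mq(calls, 0).calls == calls.calls

    def test_threshold_above_max_empties_everything(self):
        calls = make_calls({"g1": ("A", 20), "g2": ("A", 30)})
        assert filter_by_mq(calls, 99).alleles_at("s1") == {}

    def test_negative_mq_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            make_calls({"g1": ("A", -1)})


class TestConcordanceFilter:
    def test_singleton_variant_excluded(self):
        alleles = {f"g{i}": ("A", 30) for i in range(7)}
        alleles["g7"] = ("T", 30)
        assert concordance_filter(make_calls(alleles))["s1"] == {"A"}

    def test_two_genome_variant_kept_at_boundary(self):
        alleles = {f"g{i}": ("A", 30) for i in range(6)}
        alleles["g6"] = ("T", 30)
        alleles["g7"] = ("T", 30)
        assert concordance_filter(make_calls(alleles))["s1"] == {"A", "T"}

    def test_majority_always_enters(self):
        assert concordance_filter(make_calls({"g1": ("A", 30)}), min_genomes=2)["s1"] == {"A"}

    def test_min_genomes_below_one_rejected(self):
        with pytest.raises(ValueError, match="min_genomes"):
            concordance_filter(make_calls({"g1": ("A", 30)}), min_genomes=0)

    def test_anti_monotone_in_min_genomes(self):
        """Raising min_genomes never adds an allele."""
        panel, _ = simulate_site_panel(PanelConfig(seed=21))
        sim = simulate_archaic_calls(panel, error_rate=0.1, mq_mean=37, seed=2)
        calls = filter_by_mq(sim.calls)
        prev = concordance_filter(calls, 1)
        for mg in (2, 3, 4):
            cur = concordance_filter(calls, mg)
            for sid in cur:
                assert cur[sid] <= prev[sid]
            prev = cur

    def test_majority_tie_breaks_toward_ancestral(self):
        calls = make_calls({"g1": ("A", 30), "g2": ("T", 30)})
        assert concordance_filter(calls, 2, ancestral={"s1": "T"})["s1"] == {"T"}

    def test_filter_reduces_spurious_variants_vs_unfiltered(self):
        """On planted-invariant sites with 5% error, requiring 2 concordant
        genomes cuts the fraction of sites acquiring a spurious variant."""
        cfg = PanelConfig(n_sites_per_category={"MHU": 1000}, seed=0)
        panel, _ = simulate_site_panel(cfg)  # AH planted invariant at MHU sites
        sim = simulate_archaic_calls(panel, error_rate=0.05, mq_mean=37, seed=8)
        truth = {p.site_id: p.alleles[AH] for p in panel}
        spurious = {}
        for mg in (1, 2):
            sets = concordance_filter(sim.calls, mg)
            spurious[mg] = sum(sets[s] != truth[s] for s in truth) / len(truth)
        assert spurious[2] < spurious[1]
        assert spurious[1] > 0.2  # unfiltered error leakage is substantial

    def test_composition_order_mq_then_concordance(self):
        calls = make_calls({"g1": ("A", 30), "g2": ("T", 10), "g3": ("T", 30),
                            "g4": ("A", 30)})
        direct = concordance_filter(filter_by_mq(calls, 25), 2)
        # low-MQ T support removed first, so T is a singleton and drops out
        assert direct["s1"] == {"A"}


class TestOutlierGenomes:
    def test_identical_genomes_no_exclusions(self):
        calls = ArchaicCallSet({f"g{i}": {f"s{j}": [("A", 30)] for j in range(10)}
                                for i in range(5)})
        excluded, rates = flag_outlier_genomes(calls)
        assert excluded == [] and all(r == 0 for r in rates.values())

    def test_forced_outlier_excluded(self):
        calls = {f"g{i}": {f"s{j}": [("A", 30)] for j in range(20)} for i in range(5)}
        calls["dev"] = {f"s{j}": [("T" if j < 10 else "A", 30)] for j in range(20)}
        excluded, rates = flag_outlier_genomes(ArchaicCallSet(calls))
        assert excluded == ["dev"] and rates["dev"] == pytest.approx(0.5)

    def test_fewer_than_three_genomes_noop(self):
        calls = make_calls({"g1": ("A", 30), "g2": ("T", 30)})
        assert flag_outlier_genomes(calls) == ([], {})

    def test_planted_deviant_recovered_from_simulation(self):
        """Deviant genome (30% flips vs 2% background over 500 sites) is the
        sole exclusion."""
        import numpy as np

        rng = np.random.default_rng(17)
        sites = [f"s{j}" for j in range(500)]
        calls = {}
        for i in range(8):
            rate = 0.3 if i == 0 else 0.02
            calls[f"g{i}"] = {s: [("T" if rng.random() < rate else "A", 30.0)]
                              for s in sites}
        excluded, _ = flag_outlier_genomes(ArchaicCallSet(calls))
        assert excluded == ["g0"]

    def test_exclusion_does_not_touch_missing_sites(self):
        calls = {f"g{i}": {"s1": [("A", 30)], "s2": [("A", 30)]} for i in range(4)}
        calls["dev"] = {"s1": [("T", 30)]}  # missing at s2
        cs = ArchaicCallSet(calls)
        excluded, _ = flag_outlier_genomes(cs)
        kept = cs.drop_genomes(excluded)
        assert cs.alleles_at("s2") == kept.alleles_at("s2")


def test_call_frame_round_trip():
    panel, _ = simulate_site_panel(PanelConfig(seed=30))
    sim = simulate_archaic_calls(panel, 0.05, 37, seed=1)
    back = archaic_calls_from_frame(archaic_calls_frame(sim.calls))
    assert back.calls == sim.calls.calls
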