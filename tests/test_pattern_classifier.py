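"""Five-category classifier: worked examples, exhaustive exclusivity, invariants."""

import itertools

import pytest

from oxvar.ancestral_inference import AncestralCall, infer_panel_ancestral
from oxvar.pattern_classifier import (PatternClass, classify_panel, classify_site)
from oxvar.site_profiles import AlleleProfile
from oxvar.synthetic_data import PanelConfig, simulate_site_panel

ANC_A = AncestralCall("s", frozenset("A"), False, 0, 5)


def profile(**groups) -> AlleleProfile:
    missing = frozenset(t for t, s in groups.items() if not s)
    alleles = {t: frozenset(s) for t, s in groups.items() if s}
    return AlleleProfile("s", "G", 1, alleles, missing)


class TestClassifySite:
    """One example per category, matching the category definitions."""

    @pytest.mark.parametrize("groups,expected,species", [
        (dict(MH="TA", AH="A", chimpanzee="A", bonobo="A", macaque="A"),
         PatternClass.MHU, None),
        (dict(MH="TA", AH="TA", chimpanzee="A", bonobo="A", macaque="A"),
         PatternClass.HU, None),
        (dict(MH="TA", AH="T", chimpanzee="A", bonobo="A", macaque="A"),
         PatternClass.HS, None),
        (dict(MH="TA", AH="A", chimpanzee="A", bonobo="TA", macaque="A"),
         PatternClass.MH_NHP, "bonobo"),
        (dict(MH="TA", AH="A", chimpanzee="CA", bonobo="A", macaque="A"),
         PatternClass.MHS, None),
        # derived allele in both AH and an NHP: neither HU nor convergent
        (dict(MH="TA", AH="TA", chimpanzee="A", bonobo="TA", macaque="A"),
         PatternClass.NON_SPECIFIC, None),
    ])
    def test_category_examples(self, groups, expected, species):
        cs = classify_site(profile(**groups), ANC_A)
        assert cs.site_class is expected
        assert cs.matched_species == species

    def test_mh_invariant_is_uninformative(self):
        cs = classify_site(profile(MH="A", AH="A", chimpanzee="A"), ANC_A)
        assert cs.site_class is PatternClass.UNINFORMATIVE

    def test_unresolved_ancestral_propagates(self):
        anc = AncestralCall("s", frozenset("AT"), True, 1, 5)
        cs = classify_site(profile(MH="TA", AH="A", chimpanzee="A"), anc)
        assert cs.site_class is PatternClass.UNRESOLVED

    def test_missing_mh_raises(self):
        with pytest.raises(ValueError, match="MH"):
            classify_site(profile(AH="A", chimpanzee="A"), ANC_A)

    def test_ah_missing_downgrades_mhu_to_flagged_mhs(self):
        cs = classify_site(profile(MH="TA", AH="", chimpanzee="A", bonobo="A",
                                   macaque="A"), ANC_A)
        assert cs.site_class is PatternClass.MHS
        assert "AH-uninformed" in cs.flags

    def test_triallelic_mh_site_yields_two_mhu_alleles(self):
        cs = classify_site(profile(MH="TAG", AH="A", chimpanzee="A", bonobo="A",
                                   macaque="A"), ANC_A)
        assert [ac.pattern for ac in cs.allele_classes] == [PatternClass.MHU] * 2


# Direct transcription of the category definitions, used as the independent
# route in the exhaustive mutual-exclusivity check.
def _independent_predicates(d, anc, mh, ah, nhp):
    others = {**nhp, "AH": ah}
    a = frozenset({anc})
    return {
        "MHU": all(s == a for s in others.values()),
        "MHS": (d not in ah and all(d not in s for s in nhp.values())
                and any(s - {anc, d} for s in others.values())),
        "HU": d in ah and anc in ah and all(d not in s for s in nhp.values()),
        "HS": ah == frozenset({d}) and all(s == a for s in nhp.values()),
        "MH-NHP": (ah == a
                   and sum(d in s for s in nhp.values()) == 1
                   and all(s == a or s == frozenset({anc, d}) for s in nhp.values())
                   and any(s == frozenset({anc, d}) for s in nhp.values())),
    }


def test_predicates_mutually_exclusive_by_enumeration():
    """Over every 2-letter profile of 5 groups, at most one category fires,
    and the classifier returns exactly the firing category (else non-specific)."""
    anc, d = "A", "T"
    options = [frozenset("A"), frozenset("T"), frozenset("AT")]
    groups = ["AH", "chimpanzee", "bonobo", "macaque"]
    for mh in (frozenset("AT"), frozenset("T")):
        for combo in itertools.product(options, repeat=4):
            sets = dict(zip(groups, combo))
            ah = sets["AH"]
            nhp = {g: sets[g] for g in groups[1:]}
            preds = _independent_predicates(d, anc, mh, ah, nhp)
            firing = [k for k, v in preds.items() if v]
            assert len(firing) <= 1, (mh, sets, firing)
            prof = AlleleProfile("s", "G", 1, {"MH": mh, **sets})
            cs = classify_site(prof, ANC_A)
            got = cs.allele_classes[0].pattern.value
            expected = firing[0] if firing else "non-specific"
            assert got == expected, (mh, sets, got, expected)


def test_sharing_is_anti_monotone_toward_non_specific():
    """Adding the derived allele to more taxa never moves a site toward MHU."""
    order = ["MHU", "MHS", "HU", "HS", "MH-NHP", "non-specific"]
    base = dict(MH="TA", AH="A", chimpanzee="A", bonobo="A", macaque="A")
    rank0 = order.index(classify_site(profile(**base), ANC_A).site_class.value)
    for extras in itertools.chain.from_iterable(
            itertools.combinations(["AH", "chimpanzee", "bonobo", "macaque"], k)
            for k in (1, 2, 3, 4)):
        groups = dict(base)
        for t in extras:
            groups[t] = groups[t] + "T"
        rank = order.index(classify_site(profile(**groups), ANC_A).site_class.value)
        assert rank >= rank0


def test_nhp_label_permutation_invariance():
    """Classes are invariant to permuting NHP species, except the MH-NHP naming."""
    g1 = profile(MH="TA", AH="A", chimpanzee="CA", bonobo="A", macaque="A")
    g2 = profile(MH="TA", AH="A", chimpanzee="A", bonobo="A", macaque="CA")
    assert classify_site(g1, ANC_A).site_class is classify_site(g2, ANC_A).site_class


class TestClassifyPanel:
    def test_noiseless_planted_panel_recovered_perfectly(self, species_tree):
        panel, truth = simulate_site_panel(PanelConfig(seed=11))
        calls = infer_panel_ancestral(species_tree, panel)
        result = classify_panel(panel, calls)
        assert {c.site_id: c.allele for c in calls.values()} == truth.ancestral
        assert {s: c.value for s, c in result.site_classes.items()} == truth.site_class

    def test_convergent_species_recovered(self, species_tree):
        panel, truth = simulate_site_panel(PanelConfig(seed=7))
        result = classify_panel(panel, infer_panel_ancestral(species_tree, panel))
        for cs in result.sites:
            if cs.site_class is PatternClass.MH_NHP:
                assert cs.matched_species == truth.convergent_species[cs.profile.site_id]

    def test_empty_panel_gives_empty_counts(self):
        result = classify_panel([], {})
        assert result.allele_counts().empty and result.site_counts().empty
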