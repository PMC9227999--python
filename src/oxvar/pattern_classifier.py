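"""Five-category classification of cross-species variation patterns.

Given a site's per-taxon-group allele sets and its inferred ancestral allele
``a*``, every modern-human derived allele ``d`` (an MH allele other than
``a*``) is assigned exactly one category:

MHU
    ``d`` is found nowhere outside MH and every other group is fixed for the
    ancestral allele -- the heterozygous variation is unique to modern humans.
MHS
    ``d`` is found nowhere outside MH, but at least one other group is
    variant in a different way (carries some allele other than ``a*`` and
    ``d``) -- a modern-human specific pattern against a different background.
HU
    ``d`` is shared with archaic humans, who also retain ``a*`` (variant in
    the same fashion), and ``d`` is absent from every NHP species.
HS
    Archaic humans are fixed for ``d`` while every NHP species is fixed for
    ``a*`` -- modern humans variant, archaic humans homozygous derived.
MH_NHP
    ``d`` is shared with exactly one NHP species, itself variant
    ``{a*, d}``, while archaic humans and all remaining NHP are fixed for
    ``a*`` -- convergent variation between modern humans and that species.

Anything else is NON_SPECIFIC (in particular, a derived allele present in
both AH and an NHP species).  MH-invariant sites are UNINFORMATIVE;
sites whose ancestral allele could not be resolved are UNRESOLVED.  The
predicates are mutually exclusive by construction (verified exhaustively in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from oxvar.ancestral_inference import AncestralCall
from oxvar.site_profiles import AH, MH, AlleleProfile


class PatternClass(str, Enum):
    MHU = "MHU"
    MHS = "MHS"
    HU = "HU"
    HS = "HS"
    MH_NHP = "MH-NHP"
    NON_SPECIFIC = "non-specific"
    UNINFORMATIVE = "uninformative"
    UNRESOLVED = "unresolved"


#: Site-level roll-up order for multi-allelic sites: most specific first.
SPECIFICITY_ORDER = [
    PatternClass.MHU, PatternClass.MHS, PatternClass.HU, PatternClass.HS,
    PatternClass.MH_NHP, PatternClass.NON_SPECIFIC,
    PatternClass.UNINFORMATIVE, PatternClass.UNRESOLVED,
]

CATEGORY_CLASSES = frozenset({
    PatternClass.MHU, PatternClass.MHS, PatternClass.HU,
    PatternClass.HS, PatternClass.MH_NHP,
})


@dataclass(frozen=True)
class AlleleClassification:
    allele: str
    pattern: PatternClass
    matched_species: str | None = None  # set for MH_NHP only


@dataclass
class ClassifiedSite:
    """Classification result with per-derived-allele detail and evidence."""

    profile: AlleleProfile
    ancestral: AncestralCall
    allele_classes: list[AlleleClassification]
    site_class: PatternClass
    matched_species: str | None = None
    flags: list[str] = field(default_factory=list)
    evidence: dict[str, str] = field(default_factory=dict)


def _classify_derived(d: str, anc: str, ah: frozenset[str] | None,
                      nhp: dict[str, frozenset[str]]) -> AlleleClassification:
    anc_only = frozenset({anc})
    nhp_with_d = [sp for sp, s in nhp.items() if d in s]
    others = dict(nhp)
    if ah is not None:
        others[AH] = ah

    if ah is None:
        # AH-uninformed: MHU is unreachable without archaic evidence; a
        # would-be-unique allele is downgraded to an MHS candidate.
        if not nhp_with_d:
            return AlleleClassification(d, PatternClass.MHS)
        if (len(nhp_with_d) == 1 and nhp[nhp_with_d[0]] == frozenset({anc, d})
                and all(s == anc_only for sp, s in nhp.items() if sp != nhp_with_d[0])):
            return AlleleClassification(d, PatternClass.MH_NHP, nhp_with_d[0])
        return AlleleClassification(d, PatternClass.NON_SPECIFIC)

    d_in_ah = d in ah
    if d_in_ah and nhp_with_d:
        return AlleleClassification(d, PatternClass.NON_SPECIFIC)
    if not d_in_ah and not nhp_with_d:
        if all(s == anc_only for s in others.values()):
            return AlleleClassification(d, PatternClass.MHU)
        if any(s - {anc, d} for s in others.values()):
            return AlleleClassification(d, PatternClass.MHS)
        return AlleleClassification(d, PatternClass.NON_SPECIFIC)
    if d_in_ah:
        if anc in ah and not nhp_with_d:
            return AlleleClassification(d, PatternClass.HU)
        if ah == frozenset({d}) and all(s == anc_only for s in nhp.values()):
            return AlleleClassification(d, PatternClass.HS)
        return AlleleClassification(d, PatternClass.NON_SPECIFIC)
    # d in some NHP, not in AH
    if (len(nhp_with_d) == 1 and nhp[nhp_with_d[0]] == frozenset({anc, d})
            and ah == anc_only
            and all(s == anc_only for sp, s in nhp.items() if sp != nhp_with_d[0])):
        return AlleleClassification(d, PatternClass.MH_NHP, nhp_with_d[0])
    return AlleleClassification(d, PatternClass.NON_SPECIFIC)


def classify_site(profile: AlleleProfile, ancestral: AncestralCall) -> ClassifiedSite:
    """Classify one site; each MH derived allele gets exactly one category.

    Requires MH data; raises otherwise.  Unresolved ancestral calls yield an
    UNRESOLVED site.  When AH has no usable call the classification is
    computed without archaic evidence and flagged ``AH-uninformed``.
    """
    if MH not in profile.alleles:
        raise ValueError(f"profile for {profile.site_id} has no MH data")
    evidence = {t: "/".join(sorted(s)) for t, s in profile.alleles.items()}
    flags: list[str] = []

    if not ancestral.resolved:
        return ClassifiedSite(profile, ancestral, [], PatternClass.UNRESOLVED,
                              flags=["ancestral-unresolved"], evidence=evidence)
    anc = ancestral.allele
    mh = profile.alleles[MH]
    derived = sorted(mh - {anc})
    if not derived:
        return ClassifiedSite(profile, ancestral, [], PatternClass.UNINFORMATIVE,
                              evidence=evidence)

    ah = profile.alleles.get(AH)
    if ah is None:
        flags.append("AH-uninformed")
    nhp = {t: s for t, s in profile.alleles.items() if t not in (MH, AH)}

    allele_classes = [_classify_derived(d, anc, ah, nhp) for d in derived]
    site_class = min((ac.pattern for ac in allele_classes),
                     key=SPECIFICITY_ORDER.index)
    matched = next((ac.matched_species for ac in allele_classes
                    if ac.pattern is site_class and ac.matched_species), None)
    return ClassifiedSite(profile, ancestral, allele_classes, site_class,
                          matched, flags, evidence)


@dataclass
class PanelClassification:
    """Classification of a whole panel with allele- and site-level count tables."""

    sites: list[ClassifiedSite]

    @property
    def site_classes(self) -> dict[str, PatternClass]:
        return {cs.profile.site_id: cs.site_class for cs in self.sites}

    def frame(self) -> pd.DataFrame:
        """One row per site, mirroring a variant-clustering table layout."""
        taxa: list[str] = []
        for cs in self.sites:
            for t in cs.profile.alleles:
                if t not in taxa:
                    taxa.append(t)
        rows = []
        for cs in self.sites:
            row = {"site_id": cs.profile.site_id, "gene": cs.profile.gene,
                   "position": cs.profile.position}
            for t in taxa:
                row[t] = cs.evidence.get(t, ".")
            row["type"] = ";".join(
                ac.pattern.value + (f"({ac.matched_species})" if ac.matched_species else "")
                for ac in cs.allele_classes) or cs.site_class.value
            row["site_class"] = cs.site_class.value
            row["flags"] = ";".join(cs.flags)
            rows.append(row)
        return pd.DataFrame(rows)

    def allele_counts(self) -> pd.DataFrame:
        """Per-gene counts of derived-allele category labels (long format)."""
        rows = []
        for cs in self.sites:
            for ac in cs.allele_classes:
                rows.append({"gene": cs.profile.gene, "pattern": ac.pattern.value})
            if not cs.allele_classes:
                rows.append({"gene": cs.profile.gene, "pattern": cs.site_class.value})
        if not rows:
            return pd.DataFrame(columns=["gene", "pattern", "count"])
        df = pd.DataFrame(rows)
        return df.value_counts(["gene", "pattern"]).rename("count").reset_index()

    def site_counts(self) -> pd.DataFrame:
        """Per-gene counts of site-level classes (long format)."""
        rows = [{"gene": cs.profile.gene, "pattern": cs.site_class.value}
                for cs in self.sites]
        if not rows:
            return pd.DataFrame(columns=["gene", "pattern", "count"])
        df = pd.DataFrame(rows)
        return df.value_counts(["gene", "pattern"]).rename("count").reset_index()

    def count(self, gene: str, pattern: PatternClass | str, level: str = "allele") -> int:
        """Count of one (gene, category) cell at ``allele`` or ``site`` level."""
        pattern = getattr(pattern, "value", pattern)
        table = self.allele_counts() if level == "allele" else self.site_counts()
        hit = table[(table["gene"] == gene) & (table["pattern"] == pattern)]
        return int(hit["count"].sum())


def classify_panel(panel: list[AlleleProfile],
                   ancestral_calls: dict[str, AncestralCall]) -> PanelClassification:
    """Classify every site of a panel against its ancestral call."""
    out = []
    for profile in panel:
        call = ancestral_calls.get(profile.site_id)
        if call is None:
            call = AncestralCall(profile.site_id, frozenset(), False, None, 0)
        out.append(classify_site(profile, call))
    return PanelClassification(out)
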