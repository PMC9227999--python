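"""Ancestral-allele inference by set-based parsimony on a rooted species tree.

Each site's per-taxon allele sets are placed on the leaves of a fixed rooted
primate phylogeny and the ancestral allele at the root is inferred by
minimizing substitutions.  Heterozygous taxa contribute their full allele
set: a leaf may take any of its observed alleles at no cost, so polymorphism
data enter the inference directly.  On binary trees the bottom-up pass is
Fitch's algorithm (intersection where non-empty, else union with one
substitution charged); multifurcating nodes are handled with Hartigan-style
majority counts, which reduces to Fitch in the binary case.  The root set
equals the set of alleles attainable at the root by a minimum-substitution
labeling; a root set of size > 1 is ambiguous, and ambiguous sites are
carried downstream as "unresolved", never guessed.

This is a deliberate, exactly-reproducible stand-in for probabilistic,
indel-aware reconstruction (Ortheus-style): the pipeline needs only one
ancestral allele per SNV.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


@dataclass
class Phylogeny:
    """Rooted species tree with uniquely named leaves (dendropy-backed)."""

    tree: dendropy.Tree
    multifurcating: bool = False

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate leaf names in tree: {e}") from None
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names: {sorted(dupes)}")
        multi = any(len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter())
        return cls(tree, multifurcating=multi)

    @classmethod
    def from_newick_path(cls, path) -> "Phylogeny":
        from pathlib import Path

        return cls.from_newick_string(Path(path).read_text())

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root(self):
        return self.tree.seed_node


@dataclass(frozen=True)
class AncestralCall:
    """Root allele set, ambiguity flag and parsimony score for one site.

    ``ambiguous`` is true iff the root set has more than one allele.
    ``n_informative`` counts leaves that contributed data; with fewer than
    two the call is unresolved regardless of the root set.
    """

    site_id: str
    alleles: frozenset[str]
    ambiguous: bool
    score: int | None
    n_informative: int = 0

    def __post_init__(self):
        if self.ambiguous != (len(self.alleles) > 1):
            raise ValueError("ambiguous flag must equal |alleles| > 1")

    @property
    def resolved(self) -> bool:
        return self.n_informative >= 2 and not self.ambiguous

    @property
    def allele(self) -> str | None:
        """The single ancestral allele, or None when unresolved."""
        return next(iter(self.alleles)) if self.resolved else None


def _parsimony(node, leaf_sets: dict[str, frozenset[str]]):
    """Postorder pass: (candidate set, score, n_informative) or None if no data below.

    At an internal node with informative children, each allele scores the
    number of child sets containing it; alleles attaining the maximum count K
    form the node set and (children - K) substitutions are charged.  Leaves
    missing from ``leaf_sets`` are pruned; a node left with one informative
    child passes it through unchanged.
    """
    if node.is_leaf():
        s = leaf_sets.get(node.taxon.label)
        return (frozenset(s), 0, 1) if s else None
    results = [_parsimony(c, leaf_sets) for c in node.child_nodes()]
    results = [r for r in results if r is not None]
    if not results:
        return None
    if len(results) == 1:
        return results[0]
    score = sum(r[1] for r in results)
    n_leaves = sum(r[2] for r in results)
    counts: dict[str, int] = {}
    for aset, _, _ in results:
        for a in aset:
            counts[a] = counts.get(a, 0) + 1
    k = max(counts.values())
    node_set = frozenset(a for a, c in counts.items() if c == k)
    return node_set, score + len(results) - k, n_leaves


def fitch_parsimony(tree: Phylogeny, leaf_allele_sets: dict[str, frozenset[str] | set[str]],
                    site_id: str = "site") -> AncestralCall:
    """Infer the root allele set and minimal substitution count for one site.

    ``leaf_allele_sets`` maps leaf names to non-empty allele sets; leaves
    absent from the map are pruned.  Raises if no leaf carries data.
    """
    sets = {t: frozenset(s) for t, s in leaf_allele_sets.items() if s}
    for t, s in sets.items():
        if t not in set(tree.leaf_names):
            raise ValueError(f"leaf {t!r} not in tree")
    result = _parsimony(tree.root, sets)
    if result is None:
        raise ValueError(f"all leaves missing at {site_id}")
    alleles, score, n_inf = result
    return AncestralCall(site_id, alleles, len(alleles) > 1, score, n_inf)


def infer_panel_ancestral(tree: Phylogeny, panel) -> dict[str, AncestralCall]:
    """Per-site ancestral calls for a panel of allele profiles.

    Missing taxa are pruned per site.  Sites with fewer than two informative
    leaves, or with an ambiguous root set, come back unresolved (flagged, and
    excluded from derived-allele logic downstream).
    """
    leaves = set(tree.leaf_names)
    calls: dict[str, AncestralCall] = {}
    for profile in panel:
        sets = {t: s for t, s in profile.alleles.items() if t in leaves}
        if not sets:
            calls[profile.site_id] = AncestralCall(profile.site_id, frozenset(), False, None, 0)
            continue
        calls[profile.site_id] = fitch_parsimony(tree, sets, profile.site_id)
    return calls


def ancestral_calls_frame(calls: dict[str, AncestralCall]):
    """TSV-ready table: site_id, ancestral, ambiguous, score, resolved."""
    import pandas as pd

    rows = [{
        "site_id": c.site_id,
        "ancestral": "/".join(sorted(c.alleles)) if c.alleles else ".",
        "ambiguous": c.ambiguous,
        "score": c.score,
        "resolved": c.resolved,
    } for c in calls.values()]
    return pd.DataFrame(rows, columns=["site_id", "ancestral", "ambiguous", "score", "resolved"])
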