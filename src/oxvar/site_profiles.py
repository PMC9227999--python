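"""Per-site, per-taxon allele profiles.

The unit of analysis is a single nucleotide site together with the set of
alleles each taxon group (modern humans ``MH``, archaic humans ``AH``, and
one group per non-human primate species) has been observed to carry there.
Profiles are built from multi-species alignment columns and then widened
with population SNV tables, so that an allele seen in any individual of a
species counts toward that species' set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from oxvar.io_formats import AlignmentColumnSet

logger = logging.getLogger(__name__)

MH = "MH"
AH = "AH"

VALID_ALLELES = frozenset("ACGT")

#: IUPAC ambiguity codes expanded to allele sets (heterozygous reference calls).
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"),
}

#: Characters that mark a taxon as missing at a site (never treated as alleles).
MISSING_CHARS = frozenset({"-", "N", ".", "?"})


@dataclass(frozen=True)
class AlleleProfile:
    """Alleles observed per taxon group at one site.

    Parameters
    ----------
    site_id : str
        Site identifier, typically an rsID.
    gene : str
        Gene label (e.g. ``OTR``, ``VTR1A``, ``VTR1B``).
    position : int
        1-based reference coordinate.
    alleles : dict
        Taxon group -> frozenset of alleles (subset of ``{A, C, G, T}``).
    missing : frozenset
        Taxon groups with no usable call at this site.  A missing group has
        no entry in ``alleles``.
    provenance : dict
        Optional taxon -> {allele -> source} map recording whether an allele
        came from a reference assembly or a population SNV table.
    """

    site_id: str
    gene: str
    position: int
    alleles: dict[str, frozenset[str]]
    missing: frozenset[str] = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for taxon, aset in self.alleles.items():
            if not aset:
                raise ValueError(f"empty allele set for taxon {taxon!r} at {self.site_id}")
            bad = set(aset) - VALID_ALLELES
            if bad:
                raise ValueError(f"invalid alleles {sorted(bad)} for {taxon!r} at {self.site_id}")
        overlap = self.missing & set(self.alleles)
        if overlap:
            raise ValueError(f"taxa both missing and called at {self.site_id}: {sorted(overlap)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.alleles)

    def allele_set(self, taxon: str) -> frozenset[str]:
        return self.alleles[taxon]


def _column_allele_sets(column: dict[str, str], groups: dict[str, list[str]]):
    """Collapse per-taxon characters of one alignment column into per-group sets."""
    sets: dict[str, frozenset[str]] = {}
    missing: set[str] = set()
    for group, members in groups.items():
        alleles: set[str] = set()
        any_missing = False
        for taxon in members:
            ch = column[taxon].upper()
            if ch in MISSING_CHARS:
                any_missing = True
                continue
            try:
                alleles |= IUPAC[ch]
            except KeyError:
                raise ValueError(f"unexpected character {ch!r} for taxon {taxon!r}") from None
        if alleles:
            sets[group] = frozenset(alleles)
            if any_missing:
                # partial data: at least one member missing, but group still informative
                pass
        else:
            missing.add(group)
    return sets, frozenset(missing)


def extract_variant_sites(
    alignment: AlignmentColumnSet,
    taxon_groups: dict[str, list[str]],
    gene: str = "gene",
    site_ids: dict[int, str] | None = None,
) -> list[AlleleProfile]:
    """Extract candidate variant sites from a multi-species alignment.

    A column is kept when it is polymorphic within the ``MH`` group or when
    any two groups differ in their allele sets; columns identical across all
    informative groups are dropped.  Columns where a focal taxon shows only
    gap/N are retained with that group flagged missing.

    Parameters
    ----------
    alignment : AlignmentColumnSet
    taxon_groups : dict
        Group name -> list of alignment record names; must partition the
        alignment's taxa.  Must include ``MH``.
    gene : str
        Gene label stamped onto every profile.
    site_ids : dict, optional
        1-based reference position -> site identifier; defaults to
        ``pos<position>``.
    """
    known = set(alignment.taxa)
    grouped: set[str] = set()
    for group, members in taxon_groups.items():
        for taxon in members:
            if taxon not in known:
                raise ValueError(f"group {group!r} references unknown taxon {taxon!r}")
            grouped.add(taxon)
    if MH not in taxon_groups:
        raise ValueError("taxon_groups must include an 'MH' group")

    profiles: list[AlleleProfile] = []
    for idx in range(alignment.length):
        column = alignment.column(idx)
        sets, missing = _column_allele_sets(column, taxon_groups)
        if not sets:
            continue
        mh_poly = MH in sets and len(sets[MH]) > 1
        distinct = len({aset for aset in sets.values()}) > 1
        if not (mh_poly or distinct):
            continue
        pos = alignment.positions[idx]
        sid = site_ids.get(pos, f"pos{pos}") if site_ids else f"pos{pos}"
        profiles.append(
            AlleleProfile(site_id=sid, gene=gene, position=pos, alleles=sets, missing=missing)
        )
    return profiles


def merge_population_snvs(
    panel: list[AlleleProfile],
    snv_table: pd.DataFrame,
    taxon_group: str,
) -> list[AlleleProfile]:
    """Widen one taxon group's allele sets with population SNV observations.

    ``snv_table`` columns: ``position`` (1-based), ``ref_allele``,
    ``alt_allele`` (comma-separated alternates allowed), optional
    ``observed_count`` and ``source``.  Any allele observed at nonzero count
    joins the group's set -- presence-based, with no frequency floor.
    Positions absent from the panel are ignored (logged).  Merging is
    monotone and idempotent: allele sets only grow, by set union.
    """
    by_pos = {p.position: i for i, p in enumerate(panel)}
    out = list(panel)
    for row in snv_table.itertuples(index=False):
        pos = int(row.position)
        if pos not in by_pos:
            logger.info("population SNV at position %d not in panel; ignored", pos)
            continue
        count = int(getattr(row, "observed_count", 1))
        if count <= 0:
            continue
        alleles = {str(row.ref_allele).upper()}
        alleles |= {a.strip().upper() for a in str(row.alt_allele).split(",") if a.strip()}
        bad = alleles - VALID_ALLELES
        if bad:
            raise ValueError(f"invalid SNV alleles {sorted(bad)} at position {pos}")
        i = by_pos[pos]
        prof = out[i]
        current = prof.alleles.get(taxon_group, frozenset())
        merged = current | alleles
        new_alleles = dict(prof.alleles)
        new_alleles[taxon_group] = frozenset(merged)
        prov = {k: dict(v) for k, v in prof.provenance.items()}
        tp = prov.setdefault(taxon_group, {})
        for a in merged:
            tp.setdefault(a, "reference" if a in current else "population")
        out[i] = replace(
            prof,
            alleles=new_alleles,
            missing=prof.missing - {taxon_group},
            provenance=prov,
        )
    return out


def panel_to_frame(panel: list[AlleleProfile]) -> pd.DataFrame:
    """Long-format table (site_id, gene, position, taxon, alleles) for export."""
    rows = []
    for p in panel:
        for taxon, aset in p.alleles.items():
            rows.append(
                {"site_id": p.site_id, "gene": p.gene, "position": p.position,
                 "taxon": taxon, "alleles": "/".join(sorted(aset))}
            )
        for taxon in sorted(p.missing):
            rows.append(
                {"site_id": p.site_id, "gene": p.gene, "position": p.position,
                 "taxon": taxon, "alleles": "."}
            )
    return pd.DataFrame(rows, columns=["site_id", "gene", "position", "taxon", "alleles"])


def panel_from_frame(frame: pd.DataFrame) -> list[AlleleProfile]:
    """Inverse of :func:`panel_to_frame`."""
    panel = []
    for (sid, gene, pos), grp in frame.groupby(["site_id", "gene", "position"], sort=False):
        alleles: dict[str, frozenset[str]] = {}
        missing: set[str] = set()
        for row in grp.itertuples(index=False):
            if row.alleles == ".":
                missing.add(row.taxon)
            else:
                alleles[row.taxon] = frozenset(row.alleles.split("/"))
        panel.append(AlleleProfile(str(sid), str(gene), int(pos), alleles, frozenset(missing)))
    return panel
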