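"""Bundled reference fixture: the 29-site oxytocin/vasotocin receptor panel.

Encodes the study's candidate-site landscape for the three receptor genes
(*OTR* on chr3, *VTR1A* on chr12, *VTR1B* on chr1): 61 literature-associated
SNPs of which 29 combine a sociality association with a restricted
cross-species variation pattern (19 OTR / 7 VTR1A / 3 VTR1B), the
per-taxon allele patterns behind the five-category classification, global
derived-allele frequencies, the bonobo genotype sample at the convergent
sites, per-archaic-genome calls at the two hominin-shared sites, and the
four planted co-inheritance groups used for LD block detection.

SYNTHETIC STAND-IN: rsIDs, per-gene totals, category structure, and the
reported carrier counts / frequency magnitudes follow the published
analysis, but per-taxon allele letters, genomic positions and any frequency
not explicitly reported are reconstructed values chosen to be consistent
with the published counts.  Archaic genome names are generic labels, not
the published individuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from oxvar.archaic_filter import ArchaicCallSet
from oxvar.site_profiles import AH, MH, AlleleProfile
from oxvar.synthetic_data import BlockSpec, genotype_table_from_frequencies
from oxvar.popgen_stats import GenotypeTable

NHP_SPECIES = ("chimpanzee", "bonobo", "macaque")

#: Rooted species tree used for ancestral inference.
SPECIES_TREE_NEWICK = "(((MH,AH),(chimpanzee,bonobo)),macaque);"

# site_id, gene, type, ancestral, derived allele(s), global derived frequency,
# extra pattern detail: (species, allele) for MHS third alleles and MH-NHP
# convergent species.
_SITES = [
    # --- OTR (chr3): 11 MHU sites (two triallelic -> 13 MHU alleles),
    #     2 HU, 4 HS, 2 MH-NHP(bonobo)
    ("rs53576",     "OTR", "MHU",    "A", ["G"],      0.40, None),
    ("rs1042778",   "OTR", "MHU",    "T", ["G"],      0.59, None),
    ("rs237885",    "OTR", "MHU",    "G", ["T"],      0.51, None),
    ("rs6770632",   "OTR", "MHU",    "A", ["C", "G"], 0.74, None),
    ("rs2254298",   "OTR", "MHU",    "G", ["A"],      0.12, None),
    ("rs2268493",   "OTR", "MHU",    "T", ["C"],      0.18, None),
    ("rs237889",    "OTR", "MHU",    "C", ["T"],      0.31, None),
    ("rs237911",    "OTR", "MHU",    "A", ["G"],      0.09, None),
    ("rs2268490",   "OTR", "MHU",    "C", ["T"],      0.27, None),
    ("rs237917",    "OTR", "MHU",    "T", ["C", "A"], 0.33, None),
    ("rs11131149",  "OTR", "MHU",    "G", ["A"],      0.44, None),
    ("rs59190448",  "OTR", "HU",     "C", ["G"],      0.88, None),
    ("rs60902022",  "OTR", "HU",     "T", ["C"],      0.36, None),
    ("rs237888",    "OTR", "HS",     "C", ["T"],      0.86, None),
    ("rs13316193",  "OTR", "HS",     "C", ["T"],      0.22, None),
    ("rs4686302",   "OTR", "HS",     "C", ["T"],      0.15, None),
    ("rs9872310",   "OTR", "HS",     "G", ["C"],      0.11, None),
    ("rs2228485",   "OTR", "MH-NHP", "A", ["G"],      0.28, ("bonobo", "G")),
    ("rs237897",    "OTR", "MH-NHP", "G", ["A"],      0.40, ("bonobo", "A")),
    # --- VTR1A (chr12): 4 MHU, 1 HU, 1 HS, 1 MH-NHP(bonobo)
    ("rs10877969",  "VTR1A", "MHU",    "C", ["T"], 0.72, None),
    ("rs11174811",  "VTR1A", "MHU",    "C", ["A"], 0.13, None),
    ("rs3021529",   "VTR1A", "MHU",    "A", ["G"], 0.19, None),
    ("rs3759292",   "VTR1A", "MHU",    "A", ["G"], 0.08, None),
    ("rs3803107",   "VTR1A", "HU",     "G", ["A"], 0.21, None),
    ("rs10784339",  "VTR1A", "HS",     "A", ["C"], 0.47, None),
    ("rs1042615",   "VTR1A", "MH-NHP", "G", ["A"], 0.35, ("bonobo", "A")),
    # --- VTR1B (chr1): 3 MHS (third allele planted in chimpanzee)
    ("rs33985287",  "VTR1B", "MHS", "C", ["T"], 0.71, ("chimpanzee", "G")),
    ("rs28676508",  "VTR1B", "MHS", "G", ["A"], 0.24, ("chimpanzee", "C")),
    ("rs28632197",  "VTR1B", "MHS", "G", ["A"], 0.16, ("chimpanzee", "T")),
]

_GENE_CHROM = {"OTR": "3", "VTR1A": "12", "VTR1B": "1"}
_GENE_BASE = {"OTR": 8_750_000, "VTR1A": 63_000_000, "VTR1B": 206_000_000}
_GENE_OFFSET = {"OTR": 0, "VTR1A": 100_000_000, "VTR1B": 200_000_000}

ARCHAIC_GENOMES = [f"AH_genome_{i}" for i in range(1, 9)]


def reference_site_table() -> pd.DataFrame:
    """Per-site metadata: gene, chrom, position, type, alleles, derived frequency."""
    rows = []
    counters: dict[str, int] = {}
    for sid, gene, typ, anc, derived, freq, extra in _SITES:
        counters[gene] = counters.get(gene, 0) + 1
        pos = _GENE_BASE[gene] + 1500 * counters[gene]
        rows.append({
            "site_id": sid, "gene": gene, "chrom": _GENE_CHROM[gene],
            "position": pos, "sort_position": _GENE_OFFSET[gene] + pos,
            "type": typ, "ancestral": anc, "derived": "/".join(derived),
            "derived_freq": freq,
        })
    return pd.DataFrame(rows)


def reference_panel() -> list[AlleleProfile]:
    """The 29-site panel as per-taxon allele profiles."""
    meta = reference_site_table().set_index("site_id")
    panel = []
    for sid, gene, typ, anc, derived, freq, extra in _SITES:
        anc_set = frozenset({anc})
        alleles: dict[str, frozenset[str]] = {MH: frozenset({anc, *derived})}
        alleles[AH] = anc_set
        for sp in NHP_SPECIES:
            alleles[sp] = anc_set
        d = derived[0]
        if typ == "HU":
            alleles[AH] = frozenset({anc, d})
        elif typ == "HS":
            alleles[AH] = frozenset({d})
        elif typ == "MH-NHP":
            species, allele = extra
            alleles[species] = frozenset({anc, allele})
        elif typ == "MHS":
            species, allele = extra
            alleles[species] = frozenset({anc, allele})
        panel.append(AlleleProfile(sid, gene, int(meta.loc[sid, "position"]), alleles))
    return panel


def reference_truth() -> dict[str, dict[str, str]]:
    """Planted site-level types and ancestral alleles."""
    return {
        "site_class": {sid: typ for sid, _, typ, *_ in _SITES},
        "ancestral": {sid: anc for sid, _, _, anc, *_ in _SITES},
    }


def candidate_site_table(seed: int = 0) -> pd.DataFrame:
    """The 61-SNP literature table feeding the candidate funnel.

    Columns: site_id, gene, has_sociality_association, pattern (a category
    name, or ``non-specific``/``uninformative`` for unrestricted sites).
    42 OTR / 8 VTR1A / 11 VTR1B sites; exactly the 29 reference sites pass
    both the association and restricted-pattern filters.  The 32 non-passing
    rows carry generated identifiers (synthetic placeholders).
    """
    rng = np.random.default_rng(seed)
    rows = [{"site_id": sid, "gene": gene, "has_sociality_association": True,
             "pattern": typ} for sid, gene, typ, *_ in _SITES]
    # non-passing: (gene, n, failure mode)
    fillers = [("OTR", 23), ("VTR1A", 1), ("VTR1B", 8)]
    i = 0
    for gene, n in fillers:
        for _ in range(n):
            i += 1
            mode = ["no-association", "unrestricted", "neither"][i % 3]
            rows.append({
                "site_id": f"rs9{i:06d}", "gene": gene,
                "has_sociality_association": mode == "unrestricted",
                "pattern": (str(rng.choice(["MHU", "HU", "HS"]))
                            if mode == "no-association" else "non-specific"),
            })
    return pd.DataFrame(rows)


RESTRICTED_PATTERNS = frozenset({"MHU", "MHS", "HU", "HS", "MH-NHP"})


def select_candidate_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Funnel filter: sociality association AND restricted variation pattern."""
    keep = table["has_sociality_association"] & table["pattern"].isin(RESTRICTED_PATTERNS)
    return table[keep].reset_index(drop=True)


def reference_genotype_table(n_individuals: int = 1000) -> GenotypeTable:
    """Deterministic modern-human genotypes at the reference derived frequencies."""
    site_alleles = {}
    freqs = {}
    for sid, gene, typ, anc, derived, freq, extra in _SITES:
        site_alleles[sid] = (anc, derived[0])
        freqs[sid] = freq
    return genotype_table_from_frequencies(site_alleles, freqs, n_individuals,
                                           population="GLOBAL")


def bonobo_genotype_table() -> GenotypeTable:
    """The 15-bonobo sample at the convergent site rs2228485 (13 G / 2 A carriers)."""
    genotypes: dict[str, dict[str, tuple[str, ...] | None]] = {}
    for i in range(13):
        genotypes[f"bonobo{i + 1:02d}"] = {"rs2228485": ("G", "G")}
    for i in range(13, 15):
        genotypes[f"bonobo{i + 1:02d}"] = {"rs2228485": ("A", "A")}
    return GenotypeTable(genotypes, {ind: "bonobo" for ind in genotypes})


def archaic_call_table() -> ArchaicCallSet:
    """Per-archaic-genome calls at the two hominin-shared sites.

    At rs237888 (HS, derived T) six of the eight genomes carry T; at
    rs59190448 (HU, derived G) one genome's only read maps below the MQ-25
    cut (so the site has 7 informative genomes) and five of the seven carry
    G.  Mapping qualities otherwise sit in the high-30s.
    """
    t_carriers = {1, 2, 3, 5, 6, 8}      # 6/8 carry derived T at rs237888
    g_carriers = {1, 2, 4, 6, 7}         # 5/7 informative carry derived G
    calls: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for i, genome in enumerate(ARCHAIC_GENOMES, start=1):
        calls[genome] = {
            "rs237888": [("T" if i in t_carriers else "C", 36.0 + i)],
            "rs59190448": [("G" if i in g_carriers else "C",
                            18.0 if i == 3 else 35.0 + i)],
        }
    return ArchaicCallSet(calls)


def reference_block_spec(n_haplotypes: int = 500, within_r2: float = 0.9,
                         between_r2: float = 0.2) -> BlockSpec:
    """The four reported co-inheritance groups over the 29 sites."""
    groups = [
        ["rs60902022", "rs13316193", "rs11131149"],   # OTR
        ["rs10784339", "rs10877969"],                 # VTR1A
        ["rs11174811", "rs3021529"],                  # VTR1A
        ["rs33985287", "rs28676508"],                 # VTR1B
    ]
    return BlockSpec(groups, within_r2, between_r2, n_haplotypes)


def reference_ld_site_order() -> tuple[list[str], list[int]]:
    """All 29 site_ids with genome-wide sortable positions for LD analysis."""
    meta = reference_site_table().sort_values("sort_position")
    return list(meta["site_id"]), [int(p) for p in meta["sort_position"]]


def reference_score_table() -> pd.DataFrame:
    """Pathogenicity scores for the scored sites (reported magnitudes).

    CADD above 20 only at the two convergent coding sites (rs2228485,
    rs1042615) with rs4686302 just below at 19; GERP positive only at
    rs2254298 and rs13316193; missense-predictor scores for the coding
    sites.  Values not explicitly reported are representative reconstructions.
    """
    rows = [
        ("rs2228485", "CADD", 22.1), ("rs1042615", "CADD", 23.4),
        ("rs4686302", "CADD", 19.0), ("rs237888", "CADD", 5.8),
        ("rs59190448", "CADD", 3.2), ("rs6770632", "CADD", 4.1),
        ("rs1042778", "CADD", 0.9), ("rs237885", "CADD", 2.7),
        ("rs2254298", "GERP", 2.1), ("rs13316193", "GERP", 1.4),
        ("rs237888", "GERP", -1.3), ("rs2228485", "GERP", -0.6),
        ("rs4686302", "MutationAssessor", 0.62), ("rs4686302", "REVEL", 0.21),
        ("rs4686302", "MetaLR", 0.18), ("rs4686302", "SIFT", 0.31),
        ("rs4686302", "PolyPhen2", 0.12),
        ("rs1042615", "MutationAssessor", 0.71), ("rs1042615", "REVEL", 0.58),
        ("rs1042615", "MetaLR", 0.33), ("rs1042615", "SIFT", 0.02),
        ("rs1042615", "PolyPhen2", 0.91),
        ("rs28632197", "SIFT", 0.44), ("rs28632197", "PolyPhen2", 0.08),
    ]
    return pd.DataFrame(rows, columns=["site_id", "tool", "value"])


def reference_selection_table() -> pd.DataFrame:
    """Published selection-test statistics at the reference sites.

    The significant values are the reported ones; the non-significant rows
    are representative fillers above the 0.05 cut.
    """
    rows = [
        ("rs59190448", "FDIST", "p", 0.0004),
        ("rs59190448", "BayeScan", "q", 0.0004),
        ("rs59190448", "FLK", "p", 0.001),
        ("rs237888", "FLK", "p", 0.011),
        ("rs237911", "FDIST", "p", 0.0485),
        ("rs11174811", "FDIST", "p", 0.0),
        ("rs11174811", "BayeScan", "q", 0.0336),
        ("rs3021529", "FDIST", "p", 0.0001),
        ("rs3021529", "BayeScan", "q", 0.0266),
        ("rs3759292", "FLK", "p", 0.001),
        ("rs2228485", "FDIST", "p", 0.0149),
        ("rs237897", "FDIST", "p", 0.41),
        ("rs1042615", "FLK", "p", 0.27),
        ("rs237885", "BayeScan", "q", 0.62),
    ]
    return pd.DataFrame(rows, columns=["site_id", "test", "statistic_kind", "value"])


def reference_regulome_ranks() -> dict[str, str]:
    """RegulomeDB confidence ranks for the ranked sites."""
    return {
        "rs237889": "1f", "rs2228485": "2b", "rs2268493": "3a",
        "rs60902022": "3a", "rs237888": "3a", "rs28632197": "3a",
        "rs2268490": "4", "rs4686302": "5", "rs237917": "4",
        "rs6770632": "5", "rs59190448": "6", "rs9872310": "5",
        "rs10877969": "4", "rs1042615": "6", "rs33985287": "5",
    }
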