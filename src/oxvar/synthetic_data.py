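"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure each stage assumes --
per-taxon allele panels with planted category patterns, archaic calls with
sequencing error and mapping qualities, phased haplotypes with planted
co-inheritance blocks, and association-study tables with known category
mixtures -- and return truth labels alongside, so classification, filtering,
LD detection and scoring are all verifiable without external data.  A single
seed makes every generator bit-reproducible.

Defaults mirror the study conditions of the motivating analysis: five
category patterns over MH / AH / chimpanzee / bonobo / macaque groups with
category counts 13 MHU, 3 MHS, 3 HU, 5 HS, 3 MH-NHP; 8 archaic genomes; the
mapping-quality spread (normal, sd 5) crossing the MQ >= 25 admission cut.
Sequencing errors are substitutions only, and no coalescent/demographic
realism is attempted -- blocks are planted through a latent tag haplotype
copied with a per-site flip probability tuned to the target r-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oxvar.archaic_filter import ArchaicCallSet
from oxvar.ld_analysis import HaplotypeMatrix, ld_matrix
from oxvar.popgen_stats import GenotypeTable
from oxvar.site_profiles import AH, MH, AlleleProfile

DEFAULT_CATEGORY_COUNTS = {"MHU": 13, "MHS": 3, "HU": 3, "HS": 5, "MH-NHP": 3}
DEFAULT_TAXA = (MH, AH, "chimpanzee", "bonobo", "macaque")


@dataclass
class PanelConfig:
    """Configuration for the planted site panel generator."""

    n_sites_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS))
    taxa: tuple[str, ...] = DEFAULT_TAXA
    n_individuals_per_taxon: dict[str, int] = field(default_factory=dict)
    n_archaic_genomes: int = 8
    allele_alphabet: str = "ACGT"
    gene: str = "SYNGENE"
    seed: int = 0

    def __post_init__(self):
        if not self.allele_alphabet:
            raise ValueError("empty allele alphabet")
        if MH not in self.taxa:
            raise ValueError("taxa must include MH")
        if AH not in self.taxa:
            raise ValueError("taxa must include AH")
        if len(self.nhp_taxa) < 1:
            raise ValueError("taxa must include at least one NHP species")
        if any(n < 0 for n in self.n_sites_per_category.values()):
            raise ValueError("negative site counts")
        unknown = set(self.n_sites_per_category) - set(DEFAULT_CATEGORY_COUNTS)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    @property
    def nhp_taxa(self) -> list[str]:
        return [t for t in self.taxa if t not in (MH, AH)]


@dataclass
class TruthLabels:
    """Planted ground truth: one category and ancestral allele per site."""

    site_class: dict[str, str] = field(default_factory=dict)
    ancestral: dict[str, str] = field(default_factory=dict)
    blocks: dict[str, list[str]] = field(default_factory=dict)
    convergent_species: dict[str, str] = field(default_factory=dict)


def _pick_distinct(rng: np.random.Generator, alphabet: str, k: int) -> list[str]:
    if len(alphabet) < k:
        raise ValueError(f"alphabet too small for {k} distinct alleles")
    return list(rng.choice(list(alphabet), size=k, replace=False))


def simulate_site_panel(config: PanelConfig) -> tuple[list[AlleleProfile], TruthLabels]:
    """Generate a panel where each site satisfies its category's predicate exactly.

    Sites are noiseless: classifying them against the planted ancestral
    allele recovers the planted category with certainty.  MHS sites plant a
    third allele in one NHP species; MH-NHP sites plant the convergent
    derived allele in one NHP species.
    """
    rng = np.random.default_rng(config.seed)
    panel: list[AlleleProfile] = []
    truth = TruthLabels()
    nhp = config.nhp_taxa
    pos = 0
    for category in DEFAULT_CATEGORY_COUNTS:  # fixed order for determinism
        n = config.n_sites_per_category.get(category, 0)
        for i in range(n):
            pos += 1000
            sid = f"syn_{category}_{i + 1:03d}"
            need = 3 if category == "MHS" else 2
            picked = _pick_distinct(rng, config.allele_alphabet, need)
            anc, der = picked[0], picked[1]
            anc_set = frozenset({anc})
            alleles: dict[str, frozenset[str]] = {MH: frozenset({anc, der})}
            alleles[AH] = anc_set
            for sp in nhp:
                alleles[sp] = anc_set
            if category == "MHS":
                sp = str(rng.choice(nhp))
                alleles[sp] = frozenset({anc, picked[2]})
            elif category == "HU":
                alleles[AH] = frozenset({anc, der})
            elif category == "HS":
                alleles[AH] = frozenset({der})
            elif category == "MH-NHP":
                sp = str(rng.choice(nhp))
                alleles[sp] = frozenset({anc, der})
                truth.convergent_species[sid] = sp
            panel.append(AlleleProfile(sid, config.gene, pos, alleles))
            truth.site_class[sid] = category
            truth.ancestral[sid] = anc
    return panel, truth


@dataclass
class ArchaicSimulation:
    """Simulated archaic calls plus the per-genome planted truth alleles."""

    calls: ArchaicCallSet
    truth: dict[str, dict[str, str]]  # genome -> site -> planted allele


def simulate_archaic_calls(panel: list[AlleleProfile], error_rate: float,
                           mq_mean: float, seed: int, n_genomes: int = 8,
                           mq_sd: float = 5.0,
                           alphabet: str = "ACGT") -> ArchaicSimulation:
    """Per-genome archaic calls with substitution error and MQ values.

    Each genome carries one planted allele per site drawn from the site's AH
    set (every AH allele is carried by at least two genomes when possible,
    matching the concordance assumption); with probability ``error_rate``
    the call is flipped to a uniformly chosen non-truth allele.  Mapping
    qualities are drawn from a floor-0 truncated normal.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    if mq_mean < 0:
        raise ValueError("mq_mean must be >= 0")
    rng = np.random.default_rng(seed)
    genomes = [f"archaic_{g + 1}" for g in range(n_genomes)]
    truth: dict[str, dict[str, str]] = {g: {} for g in genomes}
    calls: dict[str, dict[str, list[tuple[str, float]]]] = {g: {} for g in genomes}
    for profile in panel:
        ah = sorted(profile.alleles.get(AH, frozenset()))
        if not ah:
            continue
        if len(ah) == 1:
            planted = [ah[0]] * n_genomes
        else:
            # split genomes between the AH alleles, >= 2 carriers each if possible
            n_first = int(rng.integers(2, n_genomes - 1)) if n_genomes >= 4 \
                else max(1, n_genomes // 2)
            planted = [ah[0]] * n_first + [ah[1]] * (n_genomes - n_first)
            rng.shuffle(planted)
        for g, t in zip(genomes, planted):
            truth[g][profile.site_id] = t
            allele = t
            if error_rate > 0 and rng.random() < error_rate:
                options = [a for a in alphabet if a != t]
                allele = str(rng.choice(options))
            mq = max(0.0, float(rng.normal(mq_mean, mq_sd)))
            calls[g][profile.site_id] = [(allele, mq)]
    return ArchaicSimulation(ArchaicCallSet(calls), truth)


@dataclass
class BlockSpec:
    """Planted co-inheritance structure for the haplotype generator."""

    groups: list[list[str]]
    within_r2: float = 0.9
    between_r2: float = 0.2
    n_haplotypes: int = 500

    def __post_init__(self):
        if not 0 <= self.within_r2 <= 1 or not 0 <= self.between_r2 <= 1:
            raise ValueError("r2 targets must be in [0, 1]")
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        seen: set[str] = set()
        for grp in self.groups:
            for sid in grp:
                if sid in seen:
                    raise ValueError(f"site {sid} appears in multiple groups")
                seen.add(sid)


def simulate_haplotypes(spec: BlockSpec, seed: int,
                        site_ids: list[str] | None = None,
                        max_retries: int = 50) -> HaplotypeMatrix:
    """Phased 0/1 haplotypes with planted within-group linkage.

    Each group shares a latent Bernoulli(0.5) tag haplotype; member columns
    copy the tag with a per-site flip probability chosen so the expected
    pairwise r2 clears the ``within_r2`` target.  Columns outside any group
    are independent Bernoulli(0.5).  The output is verified with
    :func:`~oxvar.ld_analysis.ld_matrix` (min within-group r2 >= target, max
    between-group r2 <= target up to sampling noise) and regenerated with a
    fresh substream on failure, up to ``max_retries`` times.
    """
    grouped = [sid for grp in spec.groups for sid in grp]
    if site_ids is None:
        site_ids = list(grouped)
    if set(grouped) - set(site_ids):
        raise ValueError("groups reference sites not in site_ids")
    n, m = spec.n_haplotypes, len(site_ids)
    idx = {sid: j for j, sid in enumerate(site_ids)}
    # flip probability from the within-r2 target, with headroom for noise
    aim = spec.within_r2 + 0.6 * (1.0 - spec.within_r2)
    flip_p = (1.0 - aim ** 0.25) / 2.0
    between_slack = max(spec.between_r2, 10.0 / n)

    master = np.random.default_rng(seed)
    for _ in range(max_retries):
        rng = np.random.default_rng(master.integers(2 ** 31))
        data = rng.integers(0, 2, size=(n, m), dtype=np.int8)
        for grp in spec.groups:
            tag = rng.integers(0, 2, size=n, dtype=np.int8)
            for sid in grp:
                flips = rng.random(n) < flip_p
                data[:, idx[sid]] = tag ^ flips.astype(np.int8)
        hap = HaplotypeMatrix(data, list(site_ids))
        ld = ld_matrix(hap)
        ok = True
        for gi, grp in enumerate(spec.groups):
            for a in range(len(grp)):
                for b in range(a + 1, len(grp)):
                    v = ld.r2[idx[grp[a]], idx[grp[b]]]
                    if not np.isfinite(v) or v < spec.within_r2:
                        ok = False
            for other in spec.groups[gi + 1:]:
                for sa in grp:
                    for sb in other:
                        v = ld.r2[idx[sa], idx[sb]]
                        if np.isfinite(v) and v > between_slack:
                            ok = False
        if ok:
            return hap
    raise RuntimeError(
        f"could not satisfy block spec (within_r2={spec.within_r2}, "
        f"between_r2={spec.between_r2}) in {max_retries} attempts")


def simulate_association_table(per_gene_category_props: dict[str, tuple[float, float, float]],
                               n_snps: int | dict[str, int], studies_per_snp: int,
                               seed: int) -> pd.DataFrame:
    """Association records with planted per-gene category proportions.

    For every SNP, ``studies_per_snp`` study labels are drawn from the
    gene's (strong, possible, unrelated) mixture; empirical gene-level means
    converge to the planted proportions as the study count grows.
    """
    from oxvar.association_scoring import CATEGORIES

    rng = np.random.default_rng(seed)
    if studies_per_snp < 0:
        raise ValueError("negative study count")
    rows = []
    for gene, props in per_gene_category_props.items():
        props = np.asarray(props, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions for {gene} must be >= 0 and sum to 1")
        k = n_snps[gene] if isinstance(n_snps, dict) else n_snps
        if k < 0:
            raise ValueError("negative SNP count")
        for j in range(k):
            snp = f"{gene}_snp{j + 1:03d}"
            cats = rng.choice(list(CATEGORIES), size=studies_per_snp, p=props)
            for s, cat in enumerate(cats):
                rows.append({"snp_id": snp, "gene": gene,
                             "study_id": f"{snp}_study{s + 1:03d}", "category": str(cat)})
    return pd.DataFrame(rows, columns=["snp_id", "gene", "study_id", "category"])


def simulate_genotype_table(site_alleles: dict[str, tuple[str, str]],
                            derived_freqs: dict[str, float], n_individuals: int,
                            seed: int,
                            populations: dict[str, dict[str, float]] | None = None
                            ) -> GenotypeTable:
    """Diploid genotypes drawn binomially at planted derived-allele frequencies.

    ``site_alleles`` maps site_id -> (ancestral, derived); ``populations``
    optionally maps population -> {site_id -> derived frequency} to plant
    per-population structure (individuals are split evenly).
    """
    rng = np.random.default_rng(seed)
    pops = populations or {"pop0": derived_freqs}
    pop_names = sorted(pops)
    per_pop = n_individuals // len(pop_names)
    genotypes: dict[str, dict[str, tuple[str, ...] | None]] = {}
    pop_labels: dict[str, str] = {}
    i = 0
    for pop in pop_names:
        freqs = {**derived_freqs, **pops[pop]}
        for _ in range(per_pop):
            ind = f"ind{i + 1:05d}"
            i += 1
            pop_labels[ind] = pop
            calls: dict[str, tuple[str, ...] | None] = {}
            for sid, (anc, der) in site_alleles.items():
                f = freqs[sid]
                gt = tuple(der if rng.random() < f else anc for _ in range(2))
                calls[sid] = tuple(sorted(gt))
            genotypes[ind] = calls
    return GenotypeTable(genotypes, pop_labels)


def genotype_table_from_frequencies(site_alleles: dict[str, tuple[str, str]],
                                    derived_freqs: dict[str, float],
                                    n_individuals: int,
                                    population: str = "pop0") -> GenotypeTable:
    """Deterministic genotype table hitting each planted frequency exactly.

    Allocates ``round(2 * n * f)`` derived-allele copies per site across the
    individuals' chromosomes; no randomness is involved, so the realized
    allele frequency equals the planted one to within half a copy.
    """
    genotypes: dict[str, dict[str, tuple[str, ...] | None]] = {
        f"ind{i + 1:05d}": {} for i in range(n_individuals)}
    inds = list(genotypes)
    for sid, (anc, der) in site_alleles.items():
        copies = round(2 * n_individuals * derived_freqs[sid])
        for i, ind in enumerate(inds):
            k = min(2, max(0, copies - 2 * i))
            genotypes[ind][sid] = tuple(sorted([der] * k + [anc] * (2 - k)))
    return GenotypeTable(genotypes, {ind: population for ind in inds})
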