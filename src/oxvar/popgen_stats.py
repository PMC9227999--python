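"""Allele, carrier and derived-allele frequency summaries.

Frequencies are computed from genotype tables (individual x site diploid
allele pairs, with missing data allowed).  Archaic genomes with haploid or
pseudo-haploid calls are handled by allowing allele "pairs" of size one,
each genome counting as one individual; missing genomes drop out of the
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor

logger = logging.getLogger(__name__)


@dataclass
class GenotypeTable:
    """Individuals x sites, each cell an unordered allele tuple or ``None``.

    ``genotypes[individual][site_id]`` is a tuple of 1 or 2 allele strings,
    or ``None`` when the individual is missing at the site.  ``populations``
    labels each individual (default: one pooled population).
    """

    genotypes: dict[str, dict[str, tuple[str, ...] | None]]
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for ind in self.genotypes:
            self.populations.setdefault(ind, "pop0")

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes)

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for calls in self.genotypes.values():
            for s in calls:
                seen.setdefault(s)
        return list(seen)

    def calls_at(self, site: str, population: str | None = None):
        """Non-missing (individual, allele-tuple) pairs at a site."""
        out = []
        for ind, calls in self.genotypes.items():
            if population is not None and self.populations[ind] != population:
                continue
            gt = calls.get(site)
            if gt is not None:
                out.append((ind, gt))
        return out


@dataclass(frozen=True)
class CarrierFrequency:
    """Carrier count with raw proportion and nearest-integer percent."""

    carriers: int
    n: int
    proportion: float
    percent: int


@dataclass(frozen=True)
class SiteFrequencySummary:
    site_id: str
    major_allele: str
    major_freq: float
    maf: float
    derived_allele: str | None
    derived_freq: float | None
    top_population: str
    top_population_maf: float
    major_tie: bool = False


def _freqs_from_calls(calls) -> dict[str, float]:
    counts: dict[str, int] = {}
    total = 0
    for _, gt in calls:
        for a in gt:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    return {a: c / total for a, c in counts.items()}


def allele_frequency(table: GenotypeTable, site: str, allele: str,
                     population: str | None = None) -> float:
    """Copies of ``allele`` over total allele copies among non-missing calls."""
    calls = table.calls_at(site, population)
    if not calls:
        raise ValueError(f"no non-missing genotypes at {site}")
    freqs = _freqs_from_calls(calls)
    if allele not in freqs:
        logger.warning("allele %r never observed at %s; frequency 0", allele, site)
        return 0.0
    return freqs[allele]


def carrier_frequency(table: GenotypeTable, site: str, allele: str,
                      population: str | None = None) -> CarrierFrequency:
    """Fraction of non-missing individuals carrying at least one copy."""
    calls = table.calls_at(site, population)
    if not calls:
        raise ValueError(f"no non-missing genotypes at {site}")
    carriers = sum(1 for _, gt in calls if allele in gt)
    n = len(calls)
    prop = carriers / n
    return CarrierFrequency(carriers, n, prop, int(floor(prop * 100 + 0.5)))


def site_frequency_summary(table: GenotypeTable, site: str,
                           ancestral: str | None) -> SiteFrequencySummary:
    """Major allele, MAF, derived-allele frequency, and highest per-population MAF.

    MAF is the second-highest allele frequency (equals 1 - major frequency at
    a biallelic site).  The derived allele is the most frequent non-ancestral
    allele; its frequency is ``None`` when the ancestral allele is unknown.
    Major-allele ties break to the lexicographically smallest allele and are
    flagged.
    """
    calls = table.calls_at(site)
    if not calls:
        raise ValueError(f"no non-missing genotypes at {site}")
    freqs = _freqs_from_calls(calls)
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    major, major_freq = ranked[0]
    tie = len(ranked) > 1 and abs(ranked[1][1] - major_freq) < 1e-12
    maf = ranked[1][1] if len(ranked) > 1 else 0.0

    derived_allele = None
    derived_freq = None
    if ancestral is not None:
        non_anc = [(a, f) for a, f in ranked if a != ancestral]
        if non_anc:
            derived_allele, derived_freq = non_anc[0]
        else:
            derived_freq = 0.0

    pops = sorted(set(table.populations.values()))
    top_pop, top_maf = pops[0], -1.0
    for pop in pops:
        pcalls = table.calls_at(site, pop)
        if not pcalls:
            continue
        pranked = sorted(_freqs_from_calls(pcalls).items(), key=lambda kv: (-kv[1], kv[0]))
        pmaf = pranked[1][1] if len(pranked) > 1 else 0.0
        if pmaf > top_maf:
            top_pop, top_maf = pop, pmaf
    if top_maf < 0:
        top_pop, top_maf = pops[0], maf

    return SiteFrequencySummary(site, major, major_freq, maf, derived_allele,
                                derived_freq, top_pop, top_maf, tie)


def count_major_derived_sites(
    site_classes: dict[str, str],
    summaries: dict[str, SiteFrequencySummary],
    classes: frozenset[str] | set[str] = frozenset({"MHU", "MHS"}),
    threshold: float = 0.5,
) -> int:
    """Sites in the given categories whose derived allele is the global major allele.

    ``site_classes`` maps site_id to the site-level category name; the count
    covers sites whose category is in ``classes`` and whose derived-allele
    frequency exceeds ``threshold``.
    """
    wanted = {getattr(c, "value", c) for c in classes}
    n = 0
    for sid, cls in site_classes.items():
        cls = getattr(cls, "value", cls)
        if cls not in wanted:
            continue
        summ = summaries.get(sid)
        if summ is None or summ.derived_freq is None:
            continue
        if summ.derived_freq > threshold:
            n += 1
    return n
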