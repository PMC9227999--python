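"""Quality control for archaic-genome allele calls.

Ancient-genome calls are noisy: reads map with varying confidence and
sequencing error can plant singleton "variants".  Three successive guards
keep spurious alleles out of the archaic-human (AH) allele set:

1. mapping-quality filter -- only calls with MQ >= threshold (default 25)
   survive;
2. concordance filter -- an allele differing from the site's majority allele
   enters the AH set only when carried by at least ``min_genomes`` distinct
   genomes (default 2);
3. outlier-genome exclusion -- genomes whose discordance rate against the
   per-site majority exceeds median + k*MAD (default k=3) are dropped
   entirely.

The composition order is fixed: MQ filtering first, then concordance on the
surviving calls.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

DEFAULT_MQ_THRESHOLD = 25
DEFAULT_MIN_GENOMES = 2


@dataclass
class ArchaicCallSet:
    """Per-genome, per-site allele calls, each with a mapping quality.

    ``calls[genome_id][site_id]`` is a list of ``(allele, mq)`` tuples
    (multiple calls per site allowed, e.g. from independent reads).
    """

    calls: dict[str, dict[str, list[tuple[str, float]]]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for genome, sites in self.calls.items():
            for sid, entries in sites.items():
                for allele, mq in entries:
                    if mq < 0:
                        raise ValueError(
                            f"negative mapping quality for {genome}/{sid}")

    @property
    def genomes(self) -> list[str]:
        return list(self.calls)

    @property
    def site_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sites in self.calls.values():
            for sid in sites:
                seen.setdefault(sid)
        return list(seen)

    def alleles_at(self, site_id: str) -> dict[str, frozenset[str]]:
        """Genome -> allele set at a site (genomes with no call omitted)."""
        out = {}
        for genome, sites in self.calls.items():
            entries = sites.get(site_id)
            if entries:
                out[genome] = frozenset(a for a, _ in entries)
        return out

    def drop_genomes(self, excluded) -> "ArchaicCallSet":
        excluded = set(excluded)
        return ArchaicCallSet(
            {g: {s: list(e) for s, e in sites.items()}
             for g, sites in self.calls.items() if g not in excluded},
            {g: dict(m) for g, m in self.metadata.items() if g not in excluded},
        )


def filter_by_mq(calls: ArchaicCallSet, threshold: float = DEFAULT_MQ_THRESHOLD) -> ArchaicCallSet:
    """Keep only calls with mapping quality >= threshold.

    A genome with no surviving call at a site becomes missing there (the
    site key is dropped for that genome).
    """
    if threshold < 0:
        raise ValueError("MQ threshold must be >= 0")
    filtered: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for genome, sites in calls.calls.items():
        kept = {sid: [(a, mq) for a, mq in entries if mq >= threshold]
                for sid, entries in sites.items()}
        filtered[genome] = {sid: entries for sid, entries in kept.items() if entries}
    return ArchaicCallSet(filtered, {g: dict(m) for g, m in calls.metadata.items()})


def majority_allele(calls: ArchaicCallSet, site_id: str,
                    ancestral: str | None = None) -> str | None:
    """Modal allele across genomes at a site (each genome one vote per allele).

    Ties break toward the inferred ancestral allele when provided, else to
    the lexicographically smallest allele.  ``None`` when no genome is called.
    """
    per_genome = calls.alleles_at(site_id)
    if not per_genome:
        return None
    counts: dict[str, int] = {}
    for aset in per_genome.values():
        for a in aset:
            counts[a] = counts.get(a, 0) + 1
    top = max(counts.values())
    tied = sorted(a for a, c in counts.items() if c == top)
    if ancestral is not None and ancestral in tied:
        return ancestral
    return tied[0]


def concordance_filter(calls: ArchaicCallSet, min_genomes: int = DEFAULT_MIN_GENOMES,
                       ancestral: dict[str, str] | None = None) -> dict[str, frozenset[str]]:
    """Per-site AH allele set after the multi-genome concordance rule.

    The majority allele always enters (some genome carries it by
    definition); any other allele needs support from at least ``min_genomes``
    distinct genomes.  Expects MQ-filtered calls.  Sites with no surviving
    genome are absent from the result.
    """
    if min_genomes < 1:
        raise ValueError("min_genomes must be >= 1")
    ancestral = ancestral or {}
    out: dict[str, frozenset[str]] = {}
    for sid in calls.site_ids:
        per_genome = calls.alleles_at(sid)
        if not per_genome:
            continue
        maj = majority_allele(calls, sid, ancestral.get(sid))
        support: dict[str, int] = {}
        for aset in per_genome.values():
            for a in aset:
                support[a] = support.get(a, 0) + 1
        kept = {a for a, n in support.items() if a == maj or n >= min_genomes}
        out[sid] = frozenset(kept)
    return out


def flag_outlier_genomes(calls: ArchaicCallSet, mad_multiplier: float = 3.0):
    """Exclude genomes that strongly deviate from the remaining individuals.

    A genome is discordant at a site when every *other* called genome is
    unanimous for a single allele the genome does not carry; sites where the
    others disagree among themselves (genuine polymorphism) are left out of
    the denominator, so carrying a real minority allele is never penalized.
    Genomes with discordance rate > median + ``mad_multiplier`` * MAD are
    flagged.  With fewer than 3 genomes this is a no-op (warning logged).

    Returns ``(excluded_genome_ids, rates)``.
    """
    genomes = calls.genomes
    rates: dict[str, float] = {}
    if len(genomes) < 3:
        logger.warning("outlier filtering needs >= 3 genomes; skipping")
        return [], rates
    per_site = {sid: calls.alleles_at(sid) for sid in calls.site_ids}
    for genome in genomes:
        n = disc = 0
        for sid, aset in ((s, g2a[genome]) for s, g2a in per_site.items()
                          if genome in g2a):
            others = [a for g, a in per_site[sid].items() if g != genome]
            if not others:
                continue
            consensus = frozenset().union(*others)
            if len(consensus) != 1 or any(len(a) != 1 for a in others):
                continue  # remaining genomes not unanimous: uninformative
            n += 1
            if consensus != aset and not consensus <= aset:
                disc += 1
        rates[genome] = disc / n if n else 0.0
    values = list(rates.values())
    med = statistics.median(values)
    mad = statistics.median(abs(v - med) for v in values)
    cut = med + mad_multiplier * mad
    excluded = [g for g, r in rates.items() if r > cut]
    for g in excluded:
        logger.info("excluding outlier genome %s (discordance %.3f > %.3f)", g, rates[g], cut)
    return excluded, rates


def archaic_calls_frame(calls: ArchaicCallSet):
    """TSV-ready long table: genome_id, site_id, allele, mq."""
    import pandas as pd

    rows = [{"genome_id": g, "site_id": sid, "allele": a, "mq": mq}
            for g, sites in calls.calls.items()
            for sid, entries in sites.items()
            for a, mq in entries]
    return pd.DataFrame(rows, columns=["genome_id", "site_id", "allele", "mq"])


def archaic_calls_from_frame(frame) -> ArchaicCallSet:
    """Inverse of :func:`archaic_calls_frame`."""
    calls: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for row in frame.itertuples(index=False):
        calls.setdefault(str(row.genome_id), {}).setdefault(str(row.site_id), []).append(
            (str(row.allele), float(row.mq)))
    return ArchaicCallSet(calls)
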