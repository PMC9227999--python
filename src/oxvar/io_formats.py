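"""Readers and writers for the standard formats the pipeline touches.

FASTA alignments (Biopython), a minimal VCF v4.2 dialect
(CHROM POS ID REF ALT QUAL FILTER INFO FORMAT=GT; read through pysam,
written by hand), Newick trees (dendropy), and TSV tables (pandas).
Coordinates are 1-based inclusive everywhere, following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from oxvar.ld_analysis import MISSING, HaplotypeMatrix
from oxvar.popgen_stats import GenotypeTable

ALIGNMENT_ALPHABET = frozenset("ACGTN-") | frozenset("RYSWKMBDHV")


@dataclass
class AlignmentColumnSet:
    """A multi-species alignment addressed by column.

    ``sequences`` maps each taxon to its aligned sequence (all equal length,
    upper case).  ``positions`` maps each column to a 1-based reference
    coordinate (monotone increasing; defaults to 1..length).
    """

    sequences: dict[str, str]
    positions: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("alignment has no records")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            ragged = [t for t, s in self.sequences.items()
                      if len(s) != len(next(iter(self.sequences.values())))]
            raise ValueError(f"ragged alignment: record(s) {ragged} differ in length")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}
        for taxon, seq in self.sequences.items():
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in record {taxon!r}")
        if not self.positions:
            self.positions = list(range(1, self.length + 1))
        if len(self.positions) != self.length:
            raise ValueError("positions length does not match alignment length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("reference positions must be strictly increasing")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, i: int) -> dict[str, str]:
        return {t: s[i] for t, s in self.sequences.items()}

    def gap_columns(self) -> list[int]:
        """Column indices where any taxon shows a gap or N."""
        return [i for i in range(self.length)
                if any(c in "-N" for c in self.column(i).values())]


def read_alignment_fasta(path) -> AlignmentColumnSet:
    """Read a multi-FASTA alignment; sequences are upper-cased and validated."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 records")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return AlignmentColumnSet(seqs)


def write_alignment_fasta(path, alignment: AlignmentColumnSet) -> None:
    records = [SeqRecord(Seq(s), id=t, description="") for t, s in alignment.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VcfGenotypes:
    """Parsed genotype data: one biallelic record per (site, ALT allele).

    ``haplotypes`` holds two 0/1 rows per fully phased diploid sample and is
    ``None`` when no sample is phased; samples with any unphased
    heterozygous call are listed in ``unphased_samples`` and excluded from
    the matrix.
    """

    sites: "object"  # pandas DataFrame: site_id, chrom, position, ref, alt
    genotypes: GenotypeTable
    haplotypes: HaplotypeMatrix | None
    unphased_samples: list[str]


def read_genotypes_vcf(path) -> VcfGenotypes:
    """Read a VCF v4.x with GT calls.

    Biallelic SNVs are kept; multiallelic records are split per ALT allele.
    ``./.`` genotypes become missing data.  1-based positions are preserved.
    """
    import pandas as pd

    vcf = pysam.VariantFile(str(path))
    if "GT" not in vcf.header.formats:
        raise ValueError("VCF has no GT format field")
    samples = list(vcf.header.samples)
    site_rows = []
    calls: dict[str, dict[str, tuple[str, ...] | None]] = {s: {} for s in samples}
    phase_ok = {s: True for s in samples}
    hap_cols: list[list[int]] = []  # per split site, 2 entries per sample

    for rec in vcf:
        ref = rec.ref or ""
        alts = [a for a in (rec.alts or ()) if a is not None]
        if len(ref) != 1 or ref not in "ACGT":
            continue
        snv_alts = [a for a in alts if len(a) == 1 and a in "ACGT"]
        if not snv_alts:
            continue
        letters = {0: ref}
        for k, a in enumerate(alts, start=1):
            letters[k] = a
        sample_gt = {}
        for s in samples:
            sd = rec.samples[s]
            gt = sd.get("GT")
            if gt is None or all(a is None for a in gt):
                sample_gt[s] = None
                continue
            sample_gt[s] = (tuple(gt), bool(sd.phased))
            if len(gt) > 1 and not sd.phased:
                phase_ok[s] = False

        for alt in snv_alts:
            alt_idx = alts.index(alt) + 1
            base_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}:{ref}:{alt}"
            site_id = base_id if len(snv_alts) == 1 else f"{base_id}:{alt}"
            site_rows.append({"site_id": site_id, "chrom": rec.chrom,
                              "position": rec.pos, "ref": ref, "alt": alt})
            col: list[int] = []
            for s in samples:
                entry = sample_gt[s]
                if entry is None:
                    calls[s][site_id] = None
                    col.extend([MISSING, MISSING])
                    continue
                gt, phased = entry
                calls[s][site_id] = tuple(letters.get(a, ".") if a is not None else "."
                                          for a in gt)
                coded = [1 if a == alt_idx else (0 if a == 0 else MISSING)
                         if a is not None else MISSING for a in gt]
                if len(coded) == 1:
                    coded = coded + [MISSING]
                col.extend(coded[:2])
            hap_cols.append(col)

    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "position", "ref", "alt"])
    table = GenotypeTable(calls)
    unphased = [s for s in samples if not phase_ok[s]]

    haplotypes = None
    phased_samples = [s for s in samples if phase_ok[s]]
    if phased_samples and len(sites):
        rows = []
        labels = []
        for si, s in enumerate(samples):
            if s not in phased_samples:
                continue
            for h in range(2):
                rows.append([hap_cols[c][2 * si + h] for c in range(len(sites))])
                labels.append(f"{s}_h{h + 1}")
        data = np.array(rows, dtype=np.int8)
        if data.shape[0] >= 2:
            haplotypes = HaplotypeMatrix(
                data, list(sites["site_id"]), [int(p) for p in sites["position"]], labels
            )
    return VcfGenotypes(sites, table, haplotypes, unphased)


def write_phased_vcf(path, hap: HaplotypeMatrix, chrom: str = "1",
                     ref_alt: dict[str, tuple[str, str]] | None = None) -> None:
    """Write a haplotype matrix as a minimal phased VCF (pairs of rows = samples).

    REF/ALT letters default to A/T per site.  Missing calls become ``.``.
    """
    if hap.n_haplotypes % 2 != 0:
        raise ValueError("haplotype count must be even to form diploid samples")
    n_samples = hap.n_haplotypes // 2
    sample_names = [f"S{i + 1}" for i in range(n_samples)]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    for j, sid in enumerate(hap.site_ids):
        ref, alt = (ref_alt or {}).get(sid, ("A", "T"))
        fields = [chrom, str(hap.positions[j]), sid, ref, alt, ".", ".", ".", "GT"]
        for i in range(n_samples):
            a, b = hap.data[2 * i, j], hap.data[2 * i + 1, j]
            fields.append(f"{'.' if a == MISSING else int(a)}|{'.' if b == MISSING else int(b)}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_newick(path_or_string):
    """Read a single rooted Newick tree into a :class:`~oxvar.ancestral_inference.Phylogeny`."""
    from oxvar.ancestral_inference import Phylogeny

    s = str(path_or_string)
    if s.lstrip().startswith("(") and ";" in s:
        return Phylogeny.from_newick_string(s)
    return Phylogeny.from_newick_string(Path(s).read_text())


def write_haplotypes_tsv(path, hap: HaplotypeMatrix) -> None:
    """0/1 haplotype matrix as TSV (rows = haplotypes, columns = site_ids)."""
    import pandas as pd

    df = pd.DataFrame(hap.data, columns=hap.site_ids)
    df.insert(0, "haplotype", hap.populations)
    df.to_csv(path, sep="\t", index=False)
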