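# Methods

## Scope and data model

The package analyses *sites*, not sequences: the unit of input is an
`AlleleProfile` — one nucleotide position with the set of alleles each taxon
group has been observed to carry.  Groups are `MH` (modern humans), `AH`
(archaic humans, pooled over genomes after quality control) and one group
per non-human primate species.  An allele joins a species' set if it is seen
in any reference assembly or population SNV record for that species, at any
nonzero frequency: the category logic below is presence-based, so a single
database observation is enough to disqualify "uniqueness" claims, and no
minor-allele-frequency floor is applied.  Multiple reference assemblies of
one species are treated as additional individuals of its group.  A gap or
`N` marks a taxon as *missing* at a site — never as an allele — and IUPAC
ambiguity codes in reference sequences expand to allele sets (W → {A,T}),
since reference genomes encode heterozygosity this way.  Coordinates are
1-based inclusive throughout (VCF convention).

## Archaic-call quality control

Ancient-DNA calls pass three successive guards before entering the AH set:

1. **Mapping quality.** Only calls with MQ ≥ `mq_threshold` (default 25)
   survive; a genome with no surviving call at a site is missing there.
2. **Concordance.** At each site the *majority allele* (modal across
   MQ-passing genomes; ties break toward the inferred ancestral allele, then
   lexicographically) always enters; any other allele needs support from at
   least `min_genomes` (default 2) distinct genomes.  This trades
   sensitivity to real singleton variation for robustness to sequencing
   error, which is the right trade for heterogeneous ancient data.
3. **Outlier genomes.** A genome's discordance rate is the fraction of its
   called sites where *all other* genomes are unanimous for an allele it
   does not carry; genomes above median + 3·MAD are excluded.  Restricting
   the denominator to others-unanimous sites is deliberate: measuring
   discordance against a bare majority penalises genomes that carry a
   legitimate minority allele at genuinely polymorphic (e.g. HU) sites, and
   under that definition a noise-free dataset can still lose a genome.  The
   MAD multiplier is configurable; the criterion as a whole is this
   package's concretisation of "strongly deviating" — the literature does
   not pin down a statistic.

The composition order is fixed and tested: MQ filter, then outliers, then
concordance.

## Ancestral inference

Ancestral alleles come from set-based parsimony on a fixed rooted primate
tree.  Leaves carry full allele sets (a heterozygous taxon may take any of
its alleles at no cost); the bottom-up pass is Fitch's algorithm on binary
nodes and Hartigan-style majority counts at multifurcations (which reduces
to Fitch when binary).  The root set equals the set of alleles attainable
under a minimum-substitution labelling; the test suite verifies both score
and root set against exhaustive enumeration over all node labelings on
random trees of up to ~8 leaves.  A root set larger than one allele, or
fewer than two informative leaves, makes the site *unresolved*; unresolved
sites are excluded from derived-allele logic rather than guessed.
Parsimony deliberately replaces probabilistic, indel-aware reconstruction:
the pipeline needs one ancestral allele per SNV, and parsimony is exactly
reproducible with no tuning.

## The five-category classifier

With ancestral allele *a\** and MH derived allele *d* (an MH allele ≠ *a\**),
exactly one category applies (mutual exclusivity is proven in the tests by
exhaustive enumeration over all two-letter profiles of five groups):

- **MHU** — every non-MH group equals {*a\**};
- **MHS** — *d* absent from every other group, and some other group carries
  an allele outside {*a\**, *d*};
- **HU** — *d* ∈ AH, *a\** ∈ AH, *d* absent from all NHP;
- **HS** — AH = {*d*}, every NHP = {*a\**};
- **MH-NHP** — exactly one NHP species = {*a\**, *d*}; AH and all remaining
  NHP = {*a\**};
- otherwise **non-specific** (in particular, *d* in both AH and an NHP).
  MH-invariant sites are *uninformative*; unresolved ancestry propagates.

Classification is per derived allele — a triallelic MH site yields one label
per derived allele — and the site-level label is the most specific among
them, ordered MHU > MHS > HU > HS > MH-NHP > non-specific.  When AH has no
usable call, the classification is computed without archaic evidence and
flagged `AH-uninformed`; MHU is then unreachable (a would-be-unique allele
is reported as a flagged MHS candidate), because a uniqueness claim against
archaic humans requires archaic data.

## Frequencies

Allele frequency is copies / total copies among non-missing calls; carrier
frequency is carriers / non-missing individuals, reported both raw and as a
nearest-integer percent (13/15 → 87%).  Archaic genomes enter carrier
arithmetic as one "individual" each with allele tuples of size one
(pseudo-haploid), so missing genomes drop out of the denominator — this is
how a site can have 7 rather than 8 informative genomes.  MAF is the
second-highest allele frequency (the complement of the major frequency at
biallelic sites, always ≤ 0.5); the derived-allele frequency is that of the
most frequent non-ancestral allele.  Major-allele ties break
lexicographically and are flagged.

## Linkage disequilibrium

For sites with allele frequencies `p_A`, `p_B` and joint haplotype frequency
`p_AB`: `D = p_AB − p_A·p_B`, `r² = D²/(p_A p_a p_B p_b)`,
`D′ = D/D_max` with `D_max = min(p_A p_b, p_a p_B)` for positive D and
`min(p_A p_B, p_a p_b)` otherwise.  Haplotypes missing at either site drop
out pairwise; monomorphic pairs are undefined-with-reason, not errors.
Blocks at threshold r² > 0.8 are connected components (size ≥ 2) of the
thresholded graph: transitive grouping keeps a three-site block together
even when one of its three pairs is weak, which a clique definition would
split.  Input is phased only; composite-LD estimation from unphased
genotypes is out of scope.  D′ keeps its sign internally; exports use |D′|.

## Association scoring

Study records are ingested with categories `strong` / `possible` /
`unrelated` (the literature-reading step that produces them is outside the
package).  Percentages are computed per SNP first and then averaged
unweighted over each gene's SNPs, so a SNP with 100 studies weighs the same
as one with a single study — the anti-publication-bias normalisation, tested
as invariance under duplicating one SNP's studies.  Gene pairs are compared
with an uncorrected Pearson χ² on the 2×2 collapse (category vs rest);
Yates' correction is not applied (small expected cells are flagged instead),
and a 2×3 variant is exposed but not default.  No multiple-testing
correction is applied across gene pairs.

## Annotation

Pathogenicity scores are inputs, never computed.  Cuts: CADD > 20,
GERP > 0, REVEL > 0.5, SIFT < 0.05 (inverted direction), MetaLR > 0.5,
MutationAssessor rank ≥ 0.5, PolyPhen-2 binned at 0.45/0.85.  The last
three cuts are conventional concretisations (the corresponding sources give
class names without printing thresholds) and are configurable; binning is
monotone per tool by construction.  RegulomeDB ranks order numerically then
by letter (1a < 1f < 2b < … < 6).  Selection-test records (FDIST, BayeScan,
FLK) are filtered at p or q strictly < 0.05.

## Synthetic data

Generators plant known structure and return truth labels:

- **Site panels** plant each category's defining pattern exactly
  (noiseless), with ancestral and derived alleles drawn per site from the
  configured alphabet.  Default category counts are 13 MHU / 3 MHS / 3 HU /
  5 HS / 3 MH-NHP over MH, AH, chimpanzee, bonobo, macaque — the composition
  of the reference panel.
- **Archaic calls** give each of (default) 8 genomes one allele per site
  drawn from the site's AH set (each AH allele carried by ≥ 2 genomes when
  possible), flip it to a random other allele with probability
  `error_rate`, and attach an MQ from a floor-0 normal (sd 5) whose spread
  crosses the 25 cut.  Substitutions only; no indels, deamination profiles
  or contamination.
- **Haplotypes** plant each co-inheritance group via a latent Bernoulli(0.5)
  tag column copied with a flip probability tuned from the within-group r²
  target (aiming above the target to leave room for sampling noise);
  ungrouped columns are independent.  The output is verified with the
  package's own LD matrix and regenerated on failure (bounded retries).  No
  coalescent realism, recombination maps or demography — the generator
  reproduces the *decision problem* (blocks straddling the 0.8 threshold),
  not population history, so passing tests certify threshold behaviour, not
  performance on real 1000 Genomes haplotypes.
- **Association tables** draw per-study categories from per-gene
  multinomial mixtures; **genotype tables** come in a binomially sampled
  variant and a deterministic variant that hits planted frequencies exactly
  (used where a count must be reproduced exactly rather than in
  expectation).

One seed threads every generator; fixed seed ⇒ bit-identical output.

## The bundled reference fixture

`oxvar.datasets` encodes the 29-site receptor panel (19 *OTR*, 7 *VTR1A*,
3 *VTR1B*) with per-taxon patterns, the 61-SNP candidate table it funnels
from, derived-allele frequencies, the 15-bonobo sample at the convergent
site, per-archaic-genome calls at the two hominin-shared sites, and the four
planted co-inheritance groups.  It is a labelled synthetic stand-in: rsIDs,
totals, category structure and explicitly reported magnitudes follow the
published analysis; allele letters, positions and unreported frequencies are
reconstructions consistent with the published counts.  Two *OTR* sites are
encoded as triallelic (two MHU derived alleles each), which reconciles the
21 OTR category labels with its 19 sites under per-allele typing.

## Numerical and degenerate-input choices

Percent display rounds half up (`floor(x·100 + 0.5)`).  Frequency sums are
exact to 1e-12.  LD returns undefined-with-reason for monomorphic or
all-missing pairs.  Empty panels classify to empty count tables.  The
haplotype generator raises after bounded retries on unsatisfiable specs.
Problem sizes in the tests and acceptance script (500–2000 haplotypes,
1000-individual genotype tables, 100 LD seeds, ≤ 8-leaf enumeration oracles)
are chosen so every stochastic check sits inside a 3-SD envelope while the
whole suite runs in seconds.

## Known limitations

- Parsimony, not probabilistic reconstruction, defines the ancestral allele;
  sites where the two would disagree (long branches, indel context) are not
  modelled.
- The AH pool treats genomes symmetrically; no population structure among
  archaic individuals is modelled.
- Block detection is threshold-based connected components; it reports no
  uncertainty and inherits the threshold's arbitrariness.
- The association categories are subjective inputs; the package only
  normalises and tests them.
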