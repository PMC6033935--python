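# Methods

## Scope and model

`mendelsieve` implements single-family Mendelian triage of a joint-called
exome cohort. Families are processed independently; all implemented models
are autosomal and diploid (the motivating disease gene sits on chromosome
11, so X-linked and mitochondrial modes are out of scope). Genotype phase
in the input VCF is deliberately ignored: phase is re-derived from pedigree
transmission, which is the only phase evidence the method relies on.

### Frequency filter

A variant's population frequency is the maximum over reference-cohort
sources (table keyed by chrom/pos/ref/alt; absent means never observed,
frequency 0). The default ceiling `max_af = 0.002` (0.2%) is applied with
strict inequality — a variant at exactly 0.2% survives. "In either of the
sources" is read as the pooled maximum, the conservative interpretation: a
variant common in any one cohort is removed. A looser 1% ceiling is a
meaningful reporting bin in this field; it is available by setting
`max_af`, but it is not the default filter.

### Consequence annotation

Coordinates are 1-based inclusive everywhere (VCF/GFF convention); there is
no internal 0-based layer. A transcript model is an ordered set of exons
plus CDS bounds; the spliced CDS must be a multiple of 3. Projection of a
genomic position onto a transcript yields a 1-based coding coordinate in
translation order (strand-aware), and codon index is `ceil(c/3)`.
Substitution effects are computed by translating the affected codon before
and after with the standard genetic code (via Biopython): synonymous,
missense, stop-gained, stop-lost, or start-lost (any amino-acid change in
codon 1). Indels are classified by length modulo 3 into frameshift or
in-frame, without repeat left-alignment — adequate because SNVs dominate
the intended use and indels arise only in simulation. Intronic positions
1–2 bases from an exon boundary are splice-site; 3–8 bases are
splice-region, the package's operationalization of "potentially
protein-altering", counted as impact only behind the
`include_potentially_altering` flag.

Every transcript spanning a variant gets its own consequence, and all are
retained: the same substitution can be missense on one isoform and intronic
on another. Gene membership for inheritance testing is the union of genes
over isoforms with a protein-altering consequence ("gene-level
collapsing"), which is what lets a compound-heterozygous pair span two
isoforms of one gene. A fixed severity order (stop-gained > frameshift >
stop-lost ≈ start-lost > splice-site > missense > in-frame indel >
splice-region > synonymous > non-coding) provides deterministic collapsing
where one effect per gene is needed; the order itself is a convention, not
a claim.

### Segregation models

*AR-hom*: every affected member hom-alt; no unaffected member hom-alt;
every genotyped parent of an affected member exactly heterozygous (obligate
carrier). *AD strict*: every affected a carrier, no unaffected a carrier
(de novo in a child with two non-carrier parents is allowed). *AD with
incomplete penetrance*: unaffected carriers are tolerated but each is
reported as an `unaffected_carrier` exception, so the analyst sees exactly
which members require a non-penetrance explanation.

*Compound heterozygosity* requires every affected member heterozygous for
both variants of a same-gene pair and the pair in trans. Trans is decided
by exact enumeration: assign each member an ordered pair of two-site
haplotypes consistent with their genotypes, require each child's paternal
(maternal) haplotype to be one of the father's (mother's) two, with no
recombination between two sites of one gene; an absent parent leaves that
haplotype free. If every transmission-consistent assignment places the two
variants on different haplotypes in every affected member, trans is forced
and the pair fits; if no assignment does, the configuration is cis (or
Mendelian-inconsistent) and the pair is rejected; if both kinds exist the
phase is ambiguous — reported as a `phase_unknown` exception and rejected
unless `allow_phase_unknown` is set. The enumeration subsumes the familiar
rule of thumb (each parent carries exactly one of the two variants) and
also resolves cases the rule cannot, e.g. a sibling's genotype pinning a
double-carrier parent's phase. An unaffected member carrying both variants
vetoes the pair — unless that member is a parent of an affected member, in
which case the carriage is a phase question: if transmission pins the
parent to trans, the parent is an unaffected compound heterozygote and is
flagged `unaffected_carrier` (incomplete penetrance) rather than silently
accepted.

Missing genotypes: under the default strict policy any missing genotype in
a family member fails the model (and is listed as a `missing_genotype`
exception); a lenient policy treats missing as compatible. Strict is the
default because the intended use case has complete genotypes for all
members.

### Funnel

Stage order is fixed: multiallelic split → rarity → impact → per-family
segregation → panel intersection → known-gene review union. Review runs
after the panel so a reviewed gene outside the panel still surfaces, and it
is unfiltered by design — every variant touching any transcript of the
reviewed gene, per family that carries it, regardless of frequency, impact,
or model fit. When several models fit the same family/variant, the report
keeps the highest-priority one (AR-hom > comp-het > AD strict > AD
incomplete > review) so a homozygote is not redundantly re-reported as a
dominant candidate. The funnel records distinct surviving variants after
each stage; sequential filter stages are non-increasing, and only the
review union may add. Reports are deterministic: rows sort by family, gene,
position, variant key, model.

## Splice-junction support

A junction is the last base of an upstream exon and the first base of the
downstream exon. A split read supports it when two consecutive aligned
blocks match both coordinates exactly, with at least `min_overhang = 3`
aligned bases on each side; there is no fuzzy window, matching standard
junction quantifiers. Duplicate read ids count once. Junctions private to
one isoform of the supplied set are flagged discriminating; an isoform with
a supported discriminating junction is positively expressed. Per-base
coverage, where needed, is raw block-overlap depth with no normalization.

## Synthetic data

The packaged fixture is the package's study-conditions object: four nuclear
pedigrees totalling 20 members (8 affected) and a synthetic two-isoform
gene on a 6 kb toy contig. The coding sequences are generated (fixed
internal seed — the fixture is a constant), with only the checkable facts
constrained: the canonical isoform (180 codons, scaled down from the real
585-aa protein) carries Arg47, Thr91, Tyr131, Arg150; the alternate isoform
(240 codons) shares the first 160 codons and adds a private exon placing
Val216; the five planted variants produce Arg47His, Thr91Ile, Tyr131Cys,
Arg150Pro, Val216Ile with the study's per-member zygosities. The family-C
pedigree follows the pedigree figure's labeling (proband II.3, affected
siblings II.1/II.2/II.4; the source table's labels are internally
inconsistent) and includes the proband's two unaffected children with an
absent, ungenotyped father. The previously reported variant (Arg47His
analog) carries a reference frequency of 1e-4 — rare but nonzero — while
the four novel variants are absent from all sources. Three decoys in an
off-panel second gene exercise the rarity, impact, and panel stages, so the
funnel's stage counts are informative (8 → 7 → 6 → 6 → 5 → 5).

Cohort simulation is gene drop: founders are Hardy–Weinberg draws at the
variant's population frequency; each child receives one uniformly chosen
allele per genotyped parent (an absent parent contributes a fresh
population draw). Causal configurations are planted directly
(model-consistent by construction, haplotype-aware for the
compound-heterozygous pair so there is no within-gene recombination), and
affection is assigned from the causal genotype with probability
`penetrance` (default 1.0); one proband is always affected, mirroring
ascertainment, and phenocopies are not simulated. Defaults are the
validation conditions: 50 quartet families, causal allele frequency 0.001
(novel-rare), 200 background variants per family with frequencies uniform
on [0.01, 0.5] (all of which the 0.2% filter must remove), genotyping error
rate 0. Background variants land anywhere on the toy contig with the
reference base taken from the contig, so coding hits annotate correctly;
causal sites are reserved up front so backgrounds never shadow a causal
variant's frequency. Genotyping errors, when enabled, replace a call with a
different random call (including missing) at the configured rate.

What the simulator does **not** emulate: linkage disequilibrium and
realistic haplotype structure, population stratification, phenocopies,
sequencing-level artifacts (the genotypes are calls, not reads), and the
scale of a real exome (thousands of genes; here two). Passing recovery
tests therefore demonstrates the correctness of the filtering and
segregation logic under clean Mendelian inheritance, not robustness to real
exome noise.

Spliced-read simulation plants an exact number of junction-spanning reads
per junction (seeded random overhangs, minimum 3 bp, block coordinates
consistent with the exon structure) plus optional non-spanning exonic
reads, so planted counts are ground truth for the counter.

## Numerical and design choices

- Problem sizes in the shipped tests: exhaustive oracle sweeps cover trios
  and quartets over all 3^n single-variant and 9^n two-variant genotype
  assignments; recovery experiments use 50 families per model with 200
  background variants each. The haplotype enumeration is capped at 10^6
  assignments (beyond which phase is reported unknown); family sizes in
  scope are far below the cap.
- Determinism: all randomness flows through explicit seeds
  (`random.Random`); identical configurations produce byte-identical
  outputs, including written VCF/PED/TSV files.
- The multiallelic split remaps the focal ALT to allele 1 and marks other
  ALT alleles missing per-allele, conserving the total count of non-missing
  ALT observations; per-ALT annotation values are split positionally.
- Half-missing genotypes: a call like `./1` counts as a carrier (het); a
  half-missing reference call is indistinguishable from het and is treated
  as missing.
- RefSeq-style cross-references are carried as opaque annotations only;
  their exon structures are not reconstructed.

## Known limitations

- No statistical linkage (LOD), burden testing, kinship/IBD checking, or
  read-backed phasing; trans inference uses genotypes only.
- Indel consequences are frame-arithmetic only (no HGVS normalization).
- X-linked, mitochondrial, and imprinting models are not implemented.
- The known-gene review stage is intentionally unfiltered and can re-add
  common or synonymous variants in reviewed genes; it reflects a manual
  curation step, and its output is labelled `known_gene_review` so
  downstream consumers can treat it separately.
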