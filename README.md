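# mendelsieve

Family-based rare-variant prioritization for Mendelian disease exomes.

Given a joint-called multi-sample VCF, pedigrees, transcript models, and
population allele-frequency tables, `mendelsieve` runs the triage funnel
used in rare-disease genetics — and in particular the workflow that
identifies *BEST1* mutations in bestrophinopathy families:

1. **Rarity.** Variants present at more than 0.2% in any reference cohort
   (1000 Genomes / EVS / ExAC-style sources) are removed. The ceiling is
   the *maximum* frequency across sources, with strict inequality.
2. **Impact.** Only protein-altering (or, optionally, potentially
   protein-altering splice-region) variants survive. Consequences are
   computed **per transcript isoform**: a variant may be missense on one
   isoform and intronic on another, and both consequences are kept.
3. **Segregation.** Each family is tested against autosomal inheritance
   models:
   - *AR-hom* — every affected member homozygous for the alternate allele,
     no unaffected member homozygous, every genotyped parent of an affected
     member an obligate heterozygous carrier;
   - *compound heterozygous* — every affected member heterozygous for both
     variants of a same-gene pair, with the trans configuration **forced**
     by Mendelian transmission (an exhaustive two-site haplotype
     enumeration over the pedigree; in the common case this reduces to
     "each parent carries exactly one of the two variants"). Pairs may span
     *different isoforms* of one gene, because gene membership is collapsed
     across isoforms;
   - *AD* — every affected member a carrier; in `incomplete_penetrance`
     mode unaffected carriers are tolerated and reported as exceptions.
4. **Panel.** Candidates are intersected with a disease-gene panel
   (RetNet-style list).
5. **Known-gene review.** Every variant in an explicitly reviewed gene is
   added back per family, regardless of earlier filters.

The package also counts RNA-seq split reads supporting
isoform-discriminating splice junctions (exact donor/acceptor match,
minimum overhang 3 bp) — the evidence that an alternate transcript is
actually expressed in the affected tissue — and ships a gene-drop simulator
(`ar_hom` / `comp_het` / `ad` with configurable penetrance, background
variants, genotyping errors) for validation cohorts.

Core relations, in the usual notation: codon index of a spliced coding
position is `ceil(c/3)` (so c.392 → codon 131, c.646 → codon 216); founder
genotypes in simulation are Hardy–Weinberg draws at allele frequency *q*
with one allele transmitted per parent per child; a variant passes the
frequency filter iff `max_s AF_s <= 0.002`.

## Worked example

The packaged fixture encodes four nuclear families (20 members, 8
affected) and a synthetic two-isoform gene `BEST1L` with five planted
missense variants. Export it and run the funnel:

```bash
mendelsieve fixture --out fixture/
mendelsieve prioritize \
    --vcf fixture/cohort.vcf --ped fixture/families.ped \
    --transcripts fixture/transcripts.tsv --fasta fixture/coding.fa \
    --freq fixture/population_af.tsv --panel fixture/panel_genes.tsv \
    --review-genes BEST1L
```

Output (TSV; funnel counts as comments, then one line per candidate):

```
## funnel	input_sites	8
## funnel	biallelic	8
## funnel	rare	7
## funnel	protein_altering	6
## funnel	segregating	6
## funnel	panel	5
## funnel	with_review	5
family	gene	variant	model	zygosities	notes
FAM_A	BEST1L	chr11L:1652:A>G	AR_hom	FAM_A_I.1=het;FAM_A_I.2=het;FAM_A_II.1=hom_alt;FAM_A_II.2=hom_alt	
FAM_B	BEST1L	chr11L:1709:G>C	AR_hom	FAM_B_I.1=het;FAM_B_I.2=het;FAM_B_II.1=hom_alt;FAM_B_II.2=hom_ref	
FAM_C	BEST1L	chr11L:1140:G>A	comp_het	FAM_C_I.1=het;FAM_C_I.2=hom_ref;FAM_C_II.1=het;FAM_C_II.2=het;FAM_C_II.3=het;FAM_C_II.4=het;FAM_C_III.1=het;FAM_C_III.2=hom_ref	in trans with chr11L:2766:G>A
FAM_C	BEST1L	chr11L:2766:G>A	comp_het	FAM_C_I.1=hom_ref;FAM_C_I.2=het;FAM_C_II.1=het;FAM_C_II.2=het;FAM_C_II.3=het;FAM_C_II.4=het;FAM_C_III.1=hom_ref;FAM_C_III.2=het	in trans with chr11L:1140:G>A
FAM_D	BEST1L	chr11L:1532:C>T	AD_incomplete_penetrance	FAM_D_I.1=het;FAM_D_I.2=hom_ref;FAM_D_II.1=het;FAM_D_II.2=het	FAM_D_I.1:unaffected_carrier;FAM_D_II.2:unaffected_carrier
```

Reading it: eight input sites shrink to five candidates — one common decoy
dies at the rarity stage, one synonymous decoy at the impact stage, and
one off-panel recessive decoy at the panel stage. Families A and B carry
recessive homozygotes (hom-alt affecteds, het parents); family C carries a
compound heterozygote whose two variants sit on *different isoforms* of
`BEST1L` — all four affected siblings carry both, each unaffected member
carries exactly one, and parental genotypes force the trans phase; family
D carries a dominant variant whose unaffected carrier father and sister
are flagged as incomplete-penetrance exceptions. The variant at
`chr11L:2766` is codon 216 of the alternate isoform only (c.646 G>A,
Val→Ile); on the canonical isoform it is intronic.

The same objects are available in Python:

```python
from mendelsieve import build_paper_fixture, run_pipeline, PipelineConfig

fx = build_paper_fixture()
report = run_pipeline(
    fx.records, fx.pedigrees, fx.transcripts, fx.freqs,
    PipelineConfig(panel_genes=fx.panel_genes, review_genes=fx.review_genes),
    fx.coding_sequences,
)
print(len(report.distinct_variants()))  # 5
```

Simulated cohorts come from `mendelsieve simulate --model comp_het
--n-families 50 --out cohort/` or `simulate_cohort(SimulationConfig(...))`.

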