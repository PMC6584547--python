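# hlacall

HLA class-I genotyping from short sequencing reads, built around three
ideas:

1. **A read-mixture model fitted by variational Bayes.** Reads from the HLA
   cluster multi-map pervasively — alleles of one gene are >95% identical —
   so no single best hit identifies an allele. Each fragment *i* is modelled
   as drawn from an unknown panel allele with mixing proportions
   θ ~ Dirichlet(α₀); given per-fragment per-allele alignment
   log-likelihoods ℓᵢⱼ, mean-field updates

   &nbsp;&nbsp;&nbsp;&nbsp;z<sub>ij</sub> ∝ exp(ψ(α<sub>j</sub>) − ψ(Σ<sub>k</sub>α<sub>k</sub>)) · exp(ℓ<sub>ij</sub>), &nbsp;&nbsp; α<sub>j</sub> = α₀ + Σ<sub>i</sub> z<sub>ij</sub>

   soft-assign fragments to alleles. A sparse prior (α₀ = 0.2 per allele)
   reflects that a diploid sample uses at most two alleles per gene out of
   hundreds. An EM mode (maximum-likelihood θ) serves as an independent
   cross-check.

2. **A population-augmentable full-length reference panel.** Allele
   sequences with exon/intron annotations; a population panel can be merged
   into a base panel (byte-identical sequences deduplicated into aliases).
   Full-length (intron-containing) sequence is what resolves allele pairs
   that are identical across exons 2 and 3 — the peptide-binding-domain
   exons that probe-based typing chemistries read — and therefore
   inherently ambiguous to exon-limited methods.

3. **A depth-based diploid caller with an explicit fail state.** Per-allele
   normalized depths (expected assigned bases / allele length) are collapsed
   to 2-field resolution, ranked, and a two-threshold rule (het ratio
   τ = 0.4, minimum depth fraction δ = 0.3 of half the genome mean depth)
   yields heterozygous / homozygous / fail per gene.

The package also ships the evaluation machinery used to benchmark such
callers (allele-slot accuracy tables, discordance listings, cross-method
ambiguity reports with exon-2/3 identity grouping) and a seeded simulator
that generates panels with engineered exon-identical "twin" allele pairs
plus diploid read sets with full ground truth — so everything is testable
without external data.

## Worked example

Generate a synthetic experiment — 3 genes × 20 alleles (one exon-identical
twin pair per gene), 5 diploid samples at 30× with 0.5% base error — and
genotype it:

```bash
$ hlacall simulate --genes 3 --alleles 20 --samples 5 --coverage 30 --seed 7 --out fix
allele-level accuracy: 100.0%
  A: 10/10 = 100.0%
  B: 10/10 = 100.0%
  C: 10/10 = 100.0%
```

Each gene line reads *correct allele slots / total slots* (two slots per
sample per gene). The fixture directory holds the panel FASTA + feature
sidecar, reads, truth and the calls/accuracy/discordance tables:

```bash
$ head -4 fix/calls.tsv
sample	gene	status	allele1	allele2	depth1	depth2
S001	A	called	A*07:01	A*15:01	16.327229363121678	15.237091231565612
S001	B	called	B*01:82	B*05:01	15.997134791074437	14.439371321731498
S001	C	called	C*04:01	C*07:01	15.927378932424533	13.893831008019497
```

S001 is heterozygous at all three genes; each allele carries ≈15× — half
the 30× genome depth, as a heterozygous haplotype should. `B*01:82` is a
twin allele: identical to `B*01:01` over all exons, distinguishable only
through its introns, which the full-length panel provides.

The same steps decompose into `score` (alignments → evidence matrix),
`infer` (variational fit → abundances/depths), `call` and `evaluate`;
`build-panel` merges a population panel into a base panel, and `extract`
pulls MHC-region + unmapped reads from a WGS BAM for re-alignment.

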