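# Methods

This note documents the models, conventions and deliberate design choices
behind `exomescreen`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, alleles and formats

All coordinates are 1-based with closed intervals on both ends, matching the
`chrom:pos` style of mouse-genetics reporting and GFF3; the single conversion
to 0-based half-open happens in the BED writer. Alleles are always stored on
the forward strand; gene-oriented alleles are computed by the consequence
annotator and never stored, which removes the usual ambiguity about whether
a reported substitution is in chromosome or transcript orientation.

The VCF dialect is deliberately minimal: fixed columns plus one sample,
MQ in INFO, DP preferentially in the per-sample FORMAT block, multi-allelic
lines split into one record per alternate allele, unknown INFO keys carried
as opaque string annotations, missing genotypes rendered `./.`. Record-level
parse failures raise errors naming the offending line. Phasing, symbolic
alleles and breakends are out of scope. GFF3 is read through `gffutils` and
FASTA through `pyfaidx`; a written call set is byte-level re-readable and the
test suite additionally checks that `pysam` parses our output identically.

## Backcross model and linkage mapping

Gametes are simulated under the Haldane model: per chromosome, the crossover
count is Poisson with mean equal to the map length in Morgans, crossover
positions are uniform, and there is no interference. This is the simplest
model consistent with an unspecified historical mapping protocol; for the
marker densities involved, interference would change interval widths only
marginally. Physical↔genetic distance uses a single configurable constant,
default 0.5 cM/Mb (mouse-like).

Phenotype is read off the causal-locus genotype with full penetrance
(affected ⇔ homozygous mutant), which is the model the colony data support.
Missing marker calls (default rate 1%) reduce the informative count n rather
than being imputed.

The two-point backcross LOD is evaluated at the MLE θ̂ = r/n with the
convention 0^0 = 1, so LOD(θ̂=0.5) = 0 exactly and LOD ≥ 0 always. The
critical interval is delimited by the nearest markers flanking the LOD peak
that show ≥ 1 recombinant; chromosome ends (or, when lengths are unknown,
the outermost markers) are used when no flanking recombinant marker exists.
A LOD-drop support interval was considered and rejected: for a fully
penetrant binary trait in a backcross, individual recombinants are decisive
evidence about interval boundaries. Peak ties break toward the proximal
(smaller-coordinate) marker.

## Funnel semantics

Every stage is a pure predicate of (variant, fixed context), so the final
candidate **set** is invariant to stage order (a property test permutes the
stages); the per-stage survivor counts are order-dependent and always
reported in the canonical order. Decisions that needed fixing:

* **Quality.** Thresholds are inclusive (≥ 45 MQ, ≥ 10 DP). A variant called
  in both affected animals must pass in both.
* **Shared by both homozygotes** means the same (chrom, pos, ref, alt) key is
  called non-hom-ref in both affected samples. Zygosity is *not* a filter:
  heterozygous calls are retained throughout (candidate tables in this kind
  of screen legitimately contain het calls, e.g. in repeat tracts).
* **Panel subtraction is allele-aware**: a different alternate allele at a
  known position is not excluded.
* **"Exonic" vs "nonsynonymous."** Gene models here carry CDS intervals, so
  "exonic" is CDS overlap; the nonsynonymous stage additionally requires a
  codon-level consequence. Indels get a location class only, never codon
  annotation.
* **Above-average quality (indel branch)** is "strictly greater than the
  arithmetic mean call quality of the funnel's initial input set"; the mean
  is frozen into the context at funnel start so the stage stays a pure
  predicate. Coding-region overlap and ES-line membership of surviving
  indels are reported as evidence, not applied as exclusions; capillary
  confirmation status is an externally supplied flag, not a computed stage.

## Consequence annotation

Translation uses the standard nuclear genetic code (Biopython's table);
stop codons render `*`, so a stop gain labels like `Q120*`. For
reverse-strand genes both alleles are complemented and the CDS coordinate is
measured from the transcript 5′ end; the codon is rebuilt from the spliced
CDS and both versions translated. When a variant hits several transcripts
the most severe consequence is reported (nonsynonymous > synonymous >
non-CDS). The reference allele is verified against the genome and a mismatch
is an error naming the position. Correctness is established two independent
ways in the tests: per-codon calls are diffed against whole-protein
translation of the mutated CDS for *every* CDS SNV of a toy genome, and
reverse-strand annotation is checked against the coordinate-mirrored
forward-strand construct (strand involution).

## Segregation statistics

Affected calling uses the click-ABR threshold with a 60 dB SPL cutoff
(inclusive) or the NO_RESPONSE sentinel; when no click value exists the best
(minimum) tone threshold stands in. The cutoff is a declared convention: the
source colony's "raised thresholds" criterion was never stated, and 60 dB
sits several control SDs above the control mean while below the
severe-loss mutant distribution. Animals under 4 weeks are *indeterminate*,
not unaffected — homozygotes are phenotypically normal at 2 weeks, and
calling them unaffected would manufacture discordance.

Mendelian ratios use the 1-df χ² goodness of fit. The second-locus
comparison is a two-sided Mann–Whitney U per (genotype, age) stratum: exact
null enumeration when both groups have ≤ 8 observations without ties,
otherwise the tie-corrected normal approximation with continuity correction;
two degenerate identical groups return p = 1. NO_RESPONSE animals rank above
the 95 dB ceiling (as a tie among themselves), treating them as
right-censored rather than dropping them. Group summaries report the n−1
sample SD, exclude NO_RESPONSE from numeric reductions and count it
separately; reductions run over sorted values so summaries are exactly
invariant to record order. No multiple-testing correction is applied; the
stratified test reports per-stratum p-values, matching how such colony
checks are reported.

## The synthetic world

The generator's defaults are the stated conditions of the source screen
wherever those were printed, and a single declared choice elsewhere:

* **Backcross size** 161 (79 affected + 82 unaffected expected under 1:1).
* **Map scale** 0.5 cM/Mb; default chromosomes "9" (25 Mbp, causal locus at
  12 Mbp) and "2" (15 Mbp); markers every 2.5 cM. At this scale the
  flanking-recombinant interval is ~10 Mbp wide — the same order as the real
  mapping outcome — while staying cheap enough to regenerate hundreds of
  times in tests. The real screen's genome-wide call counts (~700k calls
  down to 46 on chromosome 9) require the deposited exomes and are out of
  desk scope; the tests instead assert structural properties (coverage,
  unique recovery, monotone shrinkage).
* **Quality scores**: passing calls draw MQ ~ N(57, 3) clipped ≥ 46 and
  DP ~ Poisson(130) (the real exomes averaged 120–140×); failing decoys draw
  ≥ 5 units below both thresholds so boundary behaviour is never load-bearing
  in tests.
* **The causal gene** is engineered, not sampled: a two-exon reverse-strand
  gene laid down so the causal position is the middle base of an ACA
  threonine codon. The planted variant is then a forward-strand G>C that
  reads C>G in gene orientation and produces Thr→Arg — reproducing the real
  mutation's strand mechanics deterministically.
* **Decoy classes** each fail exactly one stage: private to one animal;
  present in the strain/known panels; outside the linked region (placed on
  the other chromosome or ≥ 10 cM from the locus, where the mapped interval
  essentially never reaches); exonic synonymous near the locus;
  nonsynonymous but carried by the ancestral ES line; below-threshold
  quality. Background counts default to 32/24/6 (+8 indels), giving funnels
  with a visible count at every stage.
* **Phenotypes.** Endocochlear-potential parameters are the published group
  values (controls 100.0 ± 11.8 → 125.5 ± 6.5 → 120.5 ± 9.8 mV at 2/4/8
  weeks; mutants 98.0 ± 12.5 → 47.9 ± 22.2 → 53.7 ± 17.9 mV). Click
  thresholds were not published as group means, so the defaults are a
  package choice fixed once: controls 30 ± 8 dB SPL at all ages; mutants
  32 ± 8 at 2 weeks (normal), 70 ± 15 at 4 weeks (the wide-range phase),
  90 ± 6 with P(no response) = 0.35 at 8 weeks and 93 ± 4 with
  P(no response) = 0.6 at 14 weeks (severe/profound). Thresholds are
  **censored at the 95 dB stimulus ceiling**: draws above it become
  NO_RESPONSE. Consequently raw moments are recovered exactly for EP (and
  for click in groups far from the ceiling), but *not* for late-age mutant
  clicks, whose observed numeric distribution is truncated — this is a
  feature of the stated world, and the moment-recovery tests are scoped
  accordingly.

What a green test does **not** establish: the generator draws independent
Gaussian phenotypes (no litter effects, no longitudinal correlation within
animals, no measurement quantisation to 5 dB steps), simulates calls rather
than reads (no mapping artefacts, no shared systematic false positives
between the two exomes), and plants decoys by class rather than from an
empirical site-frequency spectrum. Conclusions about the *pipeline logic*
transfer; conclusions about real-data error rates do not.

## Determinism and seeds

Every generator takes an explicit seed and derives independent numpy
`default_rng` streams per stage (`[seed, k]` seed sequences), so outputs are
byte-identical under a fixed seed and adding variants does not perturb the
backcross. The genome/gene-model "world furniture" takes its own seed
(default 0) separate from the per-replicate screen seed, so Monte-Carlo
replications share one world — matching the statistical design (one genome,
many crosses) and keeping 100-replicate runs cheap.

## Known limitations

* Two-point linkage only; no multipoint likelihoods or pedigree models
  beyond the backcross design.
* Gene models carry CDS intervals only — UTR exons are not represented, so
  "exonic" means "coding-exon overlap" here.
* No splice-site, frameshift-protein or pathogenicity/conservation
  predictions; those sit outside the filtering logic this package owns.
* The minimal VCF dialect intentionally omits phasing, symbolic alleles and
  multi-sample columns.
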