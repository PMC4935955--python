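# exomescreen

Forward-genetics mutation identification at desk scale: the inference chain
that takes a deafness (or any fully penetrant recessive binary) phenotype in
a mouse colony to a single candidate point mutation, implemented as a tested,
reusable Python package.

The package is aimed at people who analyse ENU/spontaneous-mutation screens
and knockout-colony surprises: a new recessive phenotype appears, a
backcross is set up against a mapping strain, two affected animals are exome
sequenced, and the causal variant must be pulled out of hundreds of
thousands of calls by systematic filtering rather than luck.

## What it computes

**Backcross linkage mapping.** In a [(mut × mapping-strain)F1 × mut]
backcross every offspring is M (homozygous mutant-strain) or H
(heterozygous) at each marker; for a fully penetrant recessive trait a
recombinant is any (affected, H) or (unaffected, M) animal. With r
recombinants among n informative animals, θ̂ = r/n and the two-point LOD is

    LOD = log10[ θ̂^r (1−θ̂)^(n−r) / 0.5^n ],   0^0 := 1

The critical interval is delimited by the nearest markers flanking the LOD
peak that show at least one recombinant (a recombinant at a flanking marker
places the locus on its peak-ward side).

**Variant-prioritisation funnels.** The SNV funnel applies eight auditable
stages in order: mapping quality ≥ 45 and read depth ≥ 10 (boundary
inclusive); called in both affected homozygotes; absent from the
known-variant and wildtype-strain panels (allele-aware); on the linked
chromosome; inside the critical interval; exonic; nonsynonymous; absent from
the ancestral ES-cell line (whose variants pre-date the new mutation). The
indel branch filters by above-average call quality, sharing and interval,
then reports coding overlap and ES-line membership as evidence. Every run
yields per-stage survivor counts plus a per-variant audit trail naming the
first failing stage.

**Strand-aware consequence annotation.** Alleles are stored on the forward
strand; for a reverse-strand gene they are complemented and the CDS
coordinate is measured from the transcript 5′ end before the codon is
rebuilt and translated — the classic trap in which a forward-strand G>C
"appears as" C>G in the reading direction of the gene.

**Segregation statistics.** Affected calling from click-ABR thresholds
(cutoff 60 dB SPL or no response at the 95 dB ceiling; animals under 4 weeks
are indeterminate because recessive mutants are still phenotypically normal
at 2 weeks), concordance and per-genotype penetrance under the recessive
model, χ² goodness of fit to Mendelian ratios, and stratified two-sided
Mann–Whitney tests for a second locus (exact enumeration for small tie-free
groups, tie-corrected normal approximation otherwise).

**Synthetic screens.** A generator produces the whole stated world offline:
Haldane-model backcross gametes (Poisson crossovers, no interference,
0.5 cM/Mb), a toy genome with multi-exon genes on both strands including an
engineered reverse-strand causal gene (planted forward G>C ⇒ gene-oriented
C>G ⇒ ACA→AGA, Thr→Arg), exome-like call sets with six decoy classes each
designed to fail exactly one funnel stage, and colony phenotypes whose
endocochlear-potential means and SDs are the published colony values.

## Worked example

Run the analysis scripts in order (each is a thin driver over the library):

```bash
python analysis/01_simulate_screen.py --seed 1
python analysis/02_map_linkage.py
python analysis/03_filter_candidates.py
python analysis/04_segregation_stats.py --seed 1
```

Output of the mapping and filtering stages for seed 1:

```
phenotyped 161 offspring: 88 affected
peak marker D9S2 at 9:10000000 (r=1/161, LOD=45.83)
critical interval 9:5000000-15000000 (10.0 Mbp)

SNV funnel:
  Input: 71
  Mapping quality and read depth: 63
  Present in both homozygotes: 55
  Not in known-variant panels: 31
  On chromosome 9: 25
  Within mapped region: 21
  Exonic: 15
  Nonsynonymous: 7
  Not present in ES cells: 1
sole candidate: 9:12000000 G>C in toy9gC (strand -); gene-oriented ACA->AGA, consequence T60R
indel branch: 4 survivors in region; 0 in coding sequence, 2 in the ancestral ES line

backcross 79 affected : 82 unaffected vs 1:1 -> chi2=0.0559, p=0.813
colony n=204: concordance=1.000; penetrance stdf/stdf=1.00, het=0.00, wt=0.00
```

Reading: the trait maps to a 10 Mbp interval around the peak marker (LOD
45.8 ≈ the theoretical maximum 161·log₁₀2 = 48.5 minus the cost of one
recombinant); of 71 exome calls, exactly one — the planted reverse-strand
missense variant — survives all eight stages, and its codon-level call shows
the strand logic (forward G>C, gene-oriented ACA→AGA, threonine→arginine).
The colony statistics are consistent with a fully penetrant monogenic
recessive trait.

The same stages are available as a CLI (`exomescreen simulate|map|annotate|
funnel|segregate`), and the seven published critical-region candidate
records plus the four published indel records are bundled in
`exomescreen.fixtures` as desk-scale inputs.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole chain from scratch at the given seed — simulates the
default screen, maps the interval, runs both funnels, annotates the
surviving candidate and computes the colony segregation statistics — and
writes the results JSON to `--out`.
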