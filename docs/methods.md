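# Methods

## Read model

Every template read is modelled as

```
[b₆₋ₜ][M13(−21)][fwd primer][insert…]      (forward read)
[rev primer][revcomp(insert)…]            (mate, paired runs)
```

where `b` is a 6-base sample barcode 5′-truncated by `t ∈ {0,…,6}` bases
(exonuclease damage before adapter ligation is assumed strictly 5′-acting,
so repair matches barcode *suffixes*, never prefixes). The M13(−21) anchor
must match perfectly; it is searched only at offsets 0–6, since a longer
prefix cannot be a 6-base barcode. The default anchor is the standard
18-mer `TGTAAAACGACGGCCAGT`, overridable in `RunConfig` — the method is
agnostic to the exact universal-primer sequence.

Coordinates everywhere are 1-based, closed, within the amplicon insert (the
template between the locus-specific primers); references are stored in
forward-read orientation.

## Barcode repair and munging

A barcode panel is valid only if the trailing `address_suffix_len`
(default 4) bases of its barcodes are pairwise distinct. Repair maps an
observed ≥4-base suffix to the unique panel barcode ending in it, requiring
consistency at the *full* observed length (a 5-base observation must be a
true 5-suffix, not merely share its last four bases). Observations shorter
than the address space are unrepairable.

Munging replicates the repaired barcode four-fold (6-mer → 24-mer) on both
reads and references. This multiplies pairwise barcode Hamming distance by
exactly 4, so with the mapper's default budget of 2 mismatches a read can
never attain its best alignment on a foreign barcode — the property is
checked exhaustively on small panels in the test suite. Synthesized bases
(munged prefix, mate tags) carry Phred 40: they encode identity, not
base-call evidence, and must never fail quality filters.

## Mapping

Because all products share the exact munged-prefix structure, the mapper is
an offset-0, ungapped, end-anchored Hamming comparison against every
occupied (barcode × target) pseudo-reference, vectorised over read blocks.
A read is used only when its minimal mismatch count is ≤
`max_map_mismatches` (default 2, emulating a conventional short-read
mapper's seed tolerance) **and** strictly unique; any tie — including ties
between co-amplified paralogues — leaves the read unmapped rather than risk
misassignment. Indels are not modelled: EMS induces substitutions and
amplicons are fixed-length.

Paired-end handling: the reverse read carries no barcode, so it is tagged
with its forward pair's munged barcode + M13 and mapped against
reverse-orientation pseudo-references (`munged barcode + M13 + rev primer +
revcomp(insert)`). This keeps the single offset-0 mapping contract for both
ends; pileup accumulation complements mate base calls back into forward
insert coordinates, so one coordinate system serves all reports. Pairs
whose forward barcode cannot be repaired are discarded whole.

Pileups count only base calls with Phred ≥ `min_base_quality` (20); the
synthesized prefix and the locus primer are excluded.

## Genotype calling

Hemi-SNP model: the amplicon is amplified from both ancestral genomes, only
one of which varies between the parents, so a homozygous line carrying the
variant shows it at an expected read fraction of ~0.5 while the other
parent shows ~0. Calls at a declared SNP position use the variant fraction
*f* = variant calls / depth:

| condition | call |
|---|---|
| depth < `min_genotype_depth` (20) | U |
| *f* ≥ `het_fraction_call` (0.15) | variant-bearing parent |
| *f* ≤ `ref_fraction_call` (0.05) | other parent |
| otherwise (dead zone) | U |

The two fraction cutoffs are this package's own operating points, chosen to
sit far from both expected fractions (0.5 and 0) of a homozygous
doubled-haploid line; both are config-exposed and echoed in reports.
Raising the depth floor can only convert calls to U, never flip an allele.
Low-yield lines come out as runs of U rather than being dropped. Scoring
strings (one A/B/U character per line, in panel order) are exported as a
marker × line TSV for external linkage-mapping software; linkage mapping
itself is out of scope.

## Mutation detection

Only EMS-consistent sites are scanned: each reference G (candidate A) and C
(candidate T). Per pool and site, with quality-filtered counts:

* **signal** = candidate calls / reference-base calls (zero reference with
  candidate evidence reports an infinite, flagged signal; an uncovered site
  is skipped);
* **SNR** = candidate calls / max of the two non-candidate, non-reference
  base counts — the *max*, not the sum: the larger competing substitution
  is the relevant noise floor, and the sum would reject genuine calls whose
  two noise bases are individually small;
* criteria: candidate reads ≥ `min_variant_reads` (10, implemented
  inclusively), signal > 1 % (mixed-paralogue target) or 0.2 %
  (locus-specific; the looser mixed threshold reflects the candidate's
  dilution across co-amplified copies), SNR > 10.

Positions where any two co-amplified paralogues differ are masked before
scanning (criterion 4): divergence between gene copies would otherwise
masquerade as high-signal variants. Equal insert lengths are required for
positional comparison; unequal co-amplified inserts are a panel error.

Rows failing a criterion but within a `near_miss_margin` (default 0.8×) of
all thresholds are reported with `pass=false` and per-criterion booleans.
This matters in practice: published screens contain borderline rows (e.g. a
mixed-amplicon signal of 0.0097 against the 0.01 threshold, and an SNR of
~8 against 10), and the detector surfaces these for review instead of
tuning thresholds to absorb them.

Coding effects are annotated through the standard genetic code using the
target's exon/intron track and per-exon frame offsets; codons truncated by
an exon boundary and positions outside the annotation report
`not_covered`.

## Spike-prefix design

Monotemplate cycles (every cluster incorporating the same base) fault
real-time base calling over the barcode + M13 window, so runs are spiked
(default 1:10 molar, i.e. a read fraction of 1/11) with molecules whose
prefix complements the library's base composition. The design rule
implemented here — per cycle, emit the IUPAC code of the bases whose pooled
frequency across the panel is below uniform (¼), degenerating to N on a
perfectly uniform cycle — is this package's own concrete definition of that
contract; it guarantees at least one base differing from the modal library
base at every cycle. Spike *classification* is by IUPAC-aware ungapped
alignment to the spike references (not prefix pattern matching), because
each spike molecule instantiates the degenerate positions randomly.

## Simulator

The generator emulates: 5′ barcode truncation with mode-specific default
mixes (2.3 / 18.4 / 42.2 / 37.1 % for 0/1/2/≥3 lost bases in genotyping
mode; 89.5 / 3.7 / 1.7 / 3.8 %, renormalised, in mutation-screen mode —
the observed class compositions of the two original run types), spike
admixture at 1/11, per-base substitution error (default 0.1 %), paralogue
amplification bias weights, 8-fold pooling with per-line DNA weights, and
planted het/hom EMS mutations (a het mutation in one of eight equal lines
gives the expected 1/16 variant fraction). Read length defaults to 76;
nothing assumes a fixed length. Reads per product are Poisson (optionally
negative-binomial) around a configurable mean. Identical seeds give
byte-identical output.

Quality model: fixed Phred 38 everywhere, with error bases assigned a
random quality uniform on [2, 38] so that roughly half of all errors are
removed by the default Phred-20 filter — enough to exercise the filter
without modelling instrument-specific error profiles. The simulator does
not model indels, chimeras, PCR-chemistry dynamics, position-dependent
error rates, or homoeologue sequence divergence outside declared SNP
positions; passing recovery tests therefore demonstrates correctness of
the deconvolution/calling logic under the stated noise processes, not
robustness to every artefact of real instruments.

## Problem sizes and numerical choices

The recovery tests run at deliberately chosen scales: genotyping recovery
uses 46 lines × 24 hemi-SNP markers (12 synthetic targets × 2 SNPs) at a
mean of 80 reads per product, error-free, with one line thinned to ~6 % of
its reads to exercise the depth-floor U rule; pooled-screen recovery uses
50 replicates of single 8-fold pools at ≥ 2,000× per-site depth and 0.1 %
error, alternating mixed-trio and locus-specific targets with the planted
site drawn per replicate from the covered, unmasked EMS-mutable positions.
Synthetic mutation-screen paralogues are diverged at fixed rotations so
every pair differs at ≥ 3 positions inside each read window, guaranteeing
error-free reads never tie across paralogues.

Tie-breaks and degenerate inputs: mapping ties of any kind → unmapped;
all-zero pileup sites → skipped; zero reference count with variant
evidence → infinite signal, flagged; empty category streams → all-zero
tallies; reads shorter than the munged prefix → unmapped. Percentages in
reports use one decimal place.

## Known limitations

* The mapper is deliberately not a general aligner; reads requiring gaps
  or non-amplicon layouts go unmapped.
* Pool deconvolution stops at the pool: identifying *which* pooled line
  carries a detected mutation requires follow-up on the unpooled samples.
* Inter-paralogue masking needs positionally comparable (equal-length)
  co-amplified inserts.
* The genotyper's fraction cutoffs are heuristics for homozygous
  doubled-haploid material; heterozygous material would need different
  operating points.
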