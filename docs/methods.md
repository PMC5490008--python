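# Methods

`virodiv` simulates viral populations with controlled fine-scale diversity
("microdiversity"), spikes them into a synthetic background community, and
re-measures them with the standard read-level instruments of viral
ecogenomics: fragment recruitment, normalized abundance (KPKG), identity
histograms, binomial SNP calling, and assembly evaluation against known
truth. Its purpose is to make one phenomenon reproducible at desk scale:
co-occurring genome variants that differ by as little as a handful of SNPs
derail de Bruijn assembly of the very population they belong to, producing
chimeric consensus contigs, while distantly related genomes assemble
cleanly.

## Alignment and identity

All nucleotide comparisons go through one local aligner
(`virodiv.align.align_local`). Candidate placements come from edlib's
bit-parallel infix edit-distance alignment on both strands; the end-to-end
path is then trimmed to the maximum-scoring contiguous run of alignment
columns under a BLASTN-like scheme (match +1, mismatch −2, gap open −5, gap
extend −2; the first column of a gap run carries open + extend). This gives
local-alignment semantics — terminal noise is dropped, a read hanging off a
genome end aligns only its inboard part — without a full Smith–Waterman per
pair. Reported fields follow the 12-column BLAST tabular convention, with
two deliberate differences: column 11 is the raw alignment score (filtering
uses fixed `min_aln_score`/`min_aln_length` floors, default 20/30, instead
of database-size-dependent e-values) and column 12 is query coverage. Gap
columns count against percent identity, and `N` never counts as a match.
Internally all coordinates are 0-based half-open; every exported table is
1-based inclusive.

## Fragment-based ANI

Average nucleotide identity is computed Gegenees-style: one genome is tiled
into 100-bp fragments at 50-bp steps, each fragment is placed on the other
genome, and ANI is the mean identity of accepted fragments; the symmetric
result pools both tiling directions. Two choices matter here:

- Fragment identity is taken over **every column of the whole-fragment
  placement**, not the locally trimmed segment. Local trimming clips
  terminal mismatches and makes the identity of highly diverged homologs
  saturate well above their true divergence; the untrimmed identity tracks
  the substitution rate essentially unbiased down to ~70% and is what the
  dosing calibration (below) measures against.
- A fragment is accepted when its identity reaches a floor of 66%. Under
  edit-distance placement, unrelated 100-mers reach ~55–64% identity by
  chance against kilobase-scale targets, so the floor cleanly separates
  homologous from unrelated fragments while conditioning the ANI of ≥75%
  ANI genome pairs on essentially nothing. Fragments without an accepted
  hit are excluded from the mean but reported through `aligned_fraction`,
  keeping identity and coverage separable.

## Population generator

The focal reference is an i.i.d. random sequence at a target GC (default
0.40, typical for marine phage genomes; default scale 18 kb, with 15 kb
used throughout the test conditions). Variants are derived by substitution
only — uniform positions, uniform choice among the three alternative bases,
no transition bias, no indels or recombination — because substitutions are
what drive identity thresholds, SNP calling and bubble formation.

Three presets define the study conditions:

- **A (no microdiversity):** focal + one variant at exactly 20 SNPs.
- **B (low):** focal + four variants dosed to ANI targets evenly spaced
  over 96–99%, so every variant stays ≥95% ANI to the focal genome after
  the ±1-point dosing tolerance.
- **C (high):** focal + nine variants with ANI targets evenly spaced over
  75–95% and a hypervariable island.

ANI targets are reached by iterative dosing: apply a substitution rate,
measure with `fragment_ani`, rescale the rate by the ratio of target to
measured divergence, up to 20 passes (±1 percentage point tolerance). The
measurement instrument is the same ANI statistic used downstream, so any
residual estimator bias is absorbed into the calibration.

The hypervariable island defaults to positions 9,000–9,700 (scaled
proportionally for genomes shorter than the 18-kb reference scale), with
divergence parameter 0.10. In preset C the island substitution rate is the
backbone rate **plus** 0.10: an additive elevation keeps the island the
most diverged region of every variant, including those whose backbone is
already 20–25% diverged — a flat 10% island rate would paradoxically make
the island the *most conserved* region of a 75%-ANI variant. In
`mutate_genome` (used for preset A and the planted-SNP suites) the exact
SNP count is drawn outside the island so the advertised count stays exact.
The ANI range of preset C is enforced variant-vs-focal; all-pairs ANI is
not constrained.

Abundances default to uniform. Every child records its substitutions, and
replaying the record on the parent reconstructs the child byte-for-byte —
this mutation record is also the source of truth-discriminating sites for
the assembly evaluator.

## Read simulation

Paired 150-bp reads, insert 300 ± 30 bp (normal, clamped to
[read length, genome length]), substitution-only errors i.i.d. along the
read, constant Q40 quality strings. The source genome of each pair is drawn
with probability proportional to abundance × genome length; fragment starts
are uniform. Every read carries a truth record (genome, start, strand,
error count). Background genomes — mutually unrelated random sequences
standing in for a natural virome — each enter the sampling mix with one
community-member share (the mean population abundance). The simulator does
not model platform error profiles, indel errors, quality decay or
amplification bias; what passing tests show is therefore the behaviour of
the statistics under clean substitution noise, not under real instrument
artifacts.

## Recruitment and KPKG

Reads are recruited single-ended against each reference; hits below the
identity search floor (default 50%) or under 80% query coverage are
removed, and `best_hit` assignment keeps one hit per read (ties broken by
score, then lexicographic genome id — the same deterministic rule the
reciprocal-best-hit mode uses). Abundance is summarized as KPKG = kb of
aligned query sequence per kb of genome per Gb of metagenome, at 95%
(species-level) and 70% (genus-level) identity cutoffs; "kb recruited" is
the query-side aligned span. Identity histograms over 1-point bins from 70
to 100 expose microdiversity as recruitment mass below the species cutoff.

## SNP calling

Hits at ≥95% identity and ≥70% read coverage contribute to a per-position
pileup (gap columns contribute nothing). At each site the most frequent
non-reference allele is tested against an exact binomial error null:
p = P(X ≥ alt_count), X ~ Binomial(depth, error_rate), with error_rate an
explicit parameter (default 0.01) rather than derived from the constant
quality strings. A site is a SNP iff depth ≥ 5 and p < 10⁻⁶. The model is
bi-allelic by design — only the top alternative allele is tested. SNP
burden is reported as SNPs per kb of effective genome (positions at ≥5×)
per Mb of mapped read sequence, where mapped sequence is restricted to the
reads contributing to this genome's pileup.

## Assembly and chimera evaluation

The assembler is a minimal de Bruijn pipeline: k-mers (default k=31,
packed 2 bits/base into uint64) counted on both strands, counts < 2
dropped, unbranched paths compacted to unitigs, and simple two-path
bubbles — the graph signature of an isolated SNP between co-occurring
haplotypes — popped by keeping the higher-mean-coverage branch (exact ties
keep the lexicographically smaller canonical sequence, which makes popping
deterministic and strand-consistent). Because each bubble is decided
independently, the surviving consensus mixes alleles from different source
genomes — the mechanism behind chimeric contigs. Contigs shorter than 2k
are suppressed and each contig is emitted once, in canonical orientation.

The evaluator places each contig on each truth genome (whole-contig
edit-distance placement, both strands; a distance-only screen skips the
full path computation where the placement cannot matter). Per-genome
recovery is the fraction of the genome covered by placements at ≥99%
identity — strict enough that a collapsed consensus of ≤95%-ANI variants
cannot count as recovering any one of them. At every truth-discriminating
site covered by the contig's focal placement, the evaluator reads the
contig's allele and records which genomes carry it; a contig is chimeric
when each covered site matches some genome but no single genome is
consistent with all of them (with at least two informative sites).
External contigs enter through the same `Contig` objects/FASTA path and
produce the identical report schema.

## Peptide recruitment

ORFs are called stop-to-stop on both strands (starts ATG/GTG, translation
table 11, alternative starts read as Met, default minimum 60 aa). Tryptic
digestion cleaves after K/R except before P, emitting peptides with up to
4 missed cleavages (default minimum length 6). Recruitment is exact,
full-length substring matching of peptides against target proteomes — a
single mismatching residue is a miss — with per-genome counts normalized
by genome size in kb. Peptide masses and the carboxymethyl-cysteine
modification are recorded nowhere: the comparison is sequence-level by
construction, and spectrum-level search is out of scope. A permissive
six-frame proteome is available for matching against unannotated genomes.

## Sorter droplet arithmetic

With drops generated at the piezoelectric frequency f and a net particle
rate r (detected events minus electronic-noise baseline), the
drops-per-particle ratio is f/r, reported raw and rounded to the nearest
hundred (38,700 Hz and 30 s⁻¹ give 1,290 → 1,300). The same numbers give a
Poisson occupancy λ = r/f and the conditional doublet probability
P(N≥2 | N≥1) = (1 − e^{−λ} − λe^{−λ})/(1 − e^{−λ}) ≈ λ/2 for small λ.
When ranges are quoted for the event and noise rates, the worked
configuration fixes the net rate at 30 s⁻¹.

## Pipeline and reproducibility

`run_scenario` executes popgen → readsim → recruit → snpstat → asmeval,
writes every artifact as plain text (FASTA/FASTQ/TSV/BED/VCF/JSON), and
records a manifest with a SHA-256 digest per file. One global seed is
expanded into per-stage seeds by a fixed affine rule
(`seed·1000003 + 7919·(stage index+1) mod 2³¹−1`) recorded in the
manifest, so identical configurations yield identical digests and any
stage can be re-run in isolation.

## Problem sizes and test conditions

The test and verification suites run on 15-kb genomes: scenario presets at
their defining parameters; planted-SNP recovery with 30 SNPs at population
frequency 0.5 and 20× error-free coverage per haplotype; assembly contrasts
at 50× per-genome coverage with k=31 over 5 replicates; bubble counts on
constructed haplotypes with SNPs spaced >k apart. These sizes are the
package's chosen desk-scale study conditions; the statistics themselves
carry no size assumptions.

## Known limitations

- The generator's substitution-only model cannot exercise indel handling,
  and the aligner's gap parameters are correspondingly untested beyond
  constructed cases.
- The identity floor in fragment ANI biases the statistic upward for
  genome pairs near or below ~70% true identity; the generator's dosing
  loop compensates within its calibrated range (ANI ≥ 75%) only.
- The assembler resolves nothing a real assembler resolves (no paired-end
  graph disentanglement, no repeat logic); it exists to reproduce the
  consensus-collapsing failure mode, not to compete on contiguity.
- The binomial caller tests one alternative allele per site and assumes a
  site-independent, position-independent error rate.
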