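# Methods

This note documents the models, conventions and defaults behind
`ribothrough`, and what its synthetic benchmarks do and do not establish.

## Coordinates and region model

All internal coordinates are 0-based, half-open, on the transcript strand
(5′→3′); human-readable reports and BED exports keep the same convention.
A transcript is annotated by its CDS interval `[cds_start, cds_end)`,
whose last three nucleotides are the canonical stop codon, and by the
first downstream in-frame stop at `stop2_start`. The ISR is
`[cds_end, stop2_start)` and contains no in-frame stop by construction;
deeper in-frame stops are ignored, since the readthrough product of
interest terminates at the first one. `annotate_isr` raises
`NoDownstreamStop` when no complete in-frame stop codon precedes the
transcript end.

For counting, the transcript tiles into four regions: 5′UTR, CDS
(canonical stop *included*), ISR (downstream stop *included*), and the
distal 3′UTR. A P-site on either stop codon is thus attributed to the
region translated up to that stop. Three 12-nt exclusion zones start
immediately after the start codon, the canonical stop and the downstream
stop; they remove the initiation and termination peaks that would
otherwise dominate local densities. Zones are clamped at the transcript
end and merged if they overlap (possible for ISRs shorter than 12 nt).

**Density denominators.** Exclusion zones remove both counts and
positions, so by default densities are counts over *effective* lengths
(nominal length minus excluded positions inside the region); counts and
denominators then refer to the same position set and the density of a
uniformly covered region is unbiased. Whether published analyses of this
kind divided by nominal or exclusion-adjusted lengths is generally not
stated; both are computed (`RegionStats.density(adjusted=...)`) with the
adjusted form as default. On the default locus the two ratios differ by
~4% — immaterial for a threefold criterion.

## P-site and mapping

The P-site is estimated as the central nucleotide of the footprint. For
even lengths "central" is ambiguous; the left-central convention
(`start + (length − 1) // 2`, identical arithmetic for odd lengths) is
used everywhere, simulator included, so the estimate is deterministic.

Mapping is exact: a read of length ≥ 24 must occur verbatim (no
mismatches, gaps, or reverse-strand matches) in a transcript. Reads
containing N cannot satisfy 100% identity and are dropped. Reads matching
more than one position across the transcript set are discarded by default
(ambiguous placements would double-count density); `multi="keep-all"`
retains them. Only full-read matches are considered; partial (local)
matches of length ≥ 24 from a local aligner would be a possible extension.
Pre-aligned transcript-space SAM/BAM is ingested under the same filters
(forward strand, single-`M` CIGAR, `NM == 0` and sequence identity when
transcript sequences are available). Adapter/quality preprocessing is
assumed upstream and not reimplemented.

## Readthrough criteria

A transcript/dataset is readthrough-positive iff all four hold, each
compared inclusively (≥):

1. ≥ 45 P-sites in the CDS (enough signal to trust the locus at all);
2. ≥ 1 P-site in the second half of the ISR (density concentrated just
   after the stop could otherwise be termination spillover);
3. ≥ 10% of the ISR covered by footprint *spans* — coverage is about
   footprints, not P-sites, so full spans are intersected with the
   nominal ISR (stop codons excluded) and their union length divided by
   the nominal ISR length;
4. ISR/distal-3′UTR density ratio ≥ 3, on P-site counts over effective
   lengths.

Conventions chosen where the criteria leave room: the "second half"
starts at `cds_end + ceil(isr_length / 2)` on the nominal ISR and runs
through the downstream stop codon, with exclusion zones *not* applied (a
read there either exists or not); a zero-length ISR auto-fails criterion
3; the density ratio is 0 when the ISR is empty and +∞ when only the
distal 3′UTR is empty, avoiding NaN propagation. The verdict is the
conjunction of the four booleans, so adding an ISR footprint can never
turn a positive call negative.

## Periodicity and CV

The metagene profile pools P-site offsets relative to the start codon
over the window −24..62 (87 columns; A of ATG at 0) per fragment length,
reported as log(count + 1). Fragment lengths retained for frame analysis
default to the fixed set {27, 28, 29}; an auto mode instead keeps lengths
whose in-CDS frame-0 share exceeds 0.4 (vs. the uniform 1/3), warning if
none qualifies.

The frame of a P-site is `(p_site − cds_start) mod 3`: UTRs inherit the
CDS frame grid, which is what makes "ISR frame bias" well defined. Per
region, the three frame proportions are computed over counting positions
(exclusions applied) and summarized by their coefficient of variation,
CV = sd/mean. The sample standard deviation (n−1) is the default; because
the mean of the three proportions is exactly 1/3, the population
convention differs only by the constant √(2/3) and is available via
`ddof=0`. Closed forms: equal proportions → 0; one occupied frame → √3.

## Proteogenomics

The residue inserted at a recoded stop is unknown, so the search database
holds 20 variants, `base + X + extension` for each standard amino acid
X. Tryptic digestion cleaves after K/R, by default not before P
(`--rule trypsin/p` disables the proline exception; search engines
differ); peptides are all boundary pairs spanning ≤ `max_missed` internal
cleavage sites, annotated with position and missed-cleavage count. The
default missed-cleavage cap is 5 — ISR-encoded extensions can be K/R-rich,
and a generous cap keeps junction-spanning peptides in the database.
Reported peptides default to 7–40 residues (a typical search-engine
range); the digest itself is unbounded.

A peptide evidences readthrough when it overlaps the readthrough residue
or extension (any position ≥ `len(base)`), and *uniquely* so when it also
occurs as an exact substring of no proteome entry and not within the base
protein. I/L equivalence (indistinguishable by mass) is off by default
and switchable. Spectrum matching, scoring and FDR control are out of
scope: this module prepares and interprets databases only.

## Reporter quantification

Readthrough efficiency compares a stop-containing construct to a matched
no-stop (sense-codon) control: per replicate the FLuc/RLuc ratio is
formed, the ratios are averaged within each condition, and the quotient
of the two means × 100 is reported. The mean-of-per-replicate-ratios
estimator is the headline (stable for small replicate counts, the typical
n = 3); a pooled `mean(FLuc)/mean(RLuc)` mode is also available. The
standard error propagates the two replicate standard errors by the delta
method. The estimator is invariant to rescaling all FLuc or all RLuc
readouts. For tethering assays the regulated reporter is RLuc, so
`normalized_reporter_change` uses RLuc/FLuc and reports percent change.

## Synthetic data

`SimSpec` defaults define the benchmark conditions: a 1,202-nt transcript
(100-nt 5′UTR, 600-nt CDS, 99-nt ISR — the ISR length of the motivating
human readthrough locus — and 400-nt distal 3′UTR); expected densities
utr5:cds:isr:utr3_rest = 0.2:5:0.5:0.1 reads/nt, i.e. the
cds ≫ isr > utr3 structure of a readthrough locus with a true fivefold
ISR/3′UTR ratio; frame-0 probability 0.6 in CDS and ISR (within the
frame-bias range real Ribo-seq shows for translated regions) and uniform
frames in UTRs; fragment lengths uniform on 27–29 nt; 20,000 reads.

Reads are allocated to regions multinomially ∝ density × nominal length,
P-sites are drawn uniformly within the region (frame-stratified in CDS
and ISR), and each read is laid out so its central nucleotide is the
drawn P-site, rejection-resampling placements that would overhang the
transcript. Transcripts are resampled until every 24-mer is unique, so
the exact matcher recovers each read's true span with zero loss — real
transcript repeats are deliberately outside the simulator's scope, as are
sequencing errors, adapters and rRNA contamination. Reporter noise is
mean-one multiplicative log-normal, parameterized by its CV (luminescence
is positive and right-skewed). All randomness flows from the spec seed.

Passing tests on these data show the chain is self-consistent — mapping
inverts simulation, estimated ratios converge to designed ratios,
calibration behaves — not that the pipeline is robust to multimapping
repeats, biased nuclease digestion, or library artefacts present in real
Ribo-seq.

## Benchmark sizes and numerical choices

Test and acceptance runs use one 20,000-read run for parameter recovery
(designed ratios 1, 3, 5, 20 re-estimated within 15%) and 200 replicates
of 5,000 reads each for call calibration (≥ 95% positive at a true
fivefold enrichment, ≤ 5% under the null); these sizes put sampling error
comfortably inside the asserted bounds while keeping a full run in
seconds. At 20,000 reads and the default densities the ISR receives only
a few hundred reads, so the recovered ratio carries ~9–14% relative
sampling error depending on the design — the 15% recovery band is a
sampling-error bound, not an accuracy claim about smaller datasets.
Calibration replicates bypass the string matcher and count the
simulator's true spans directly (mapping is exact and separately shown to
be lossless, so the shortcut changes nothing but runtime).

## Known limitations

Transcript space only: no splicing or genomic/negative-strand
coordinates. Exact matching cannot place reads on repetitive transcripts.
Single-ISR model: only the first downstream in-frame stop is annotated.
No statistical test accompanies the four criteria (they are deterministic
filters, as published); no spectrum-level mass-spec processing; no
multiple-sequence alignment of extensions across species.
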