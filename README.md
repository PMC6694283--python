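# ribothrough

Detection and quantification of programmed stop-codon readthrough from
ribosome profiling and reporter data.

Some mRNAs direct the ribosome to decode their canonical stop codon as a
sense codon and continue translating, in frame, to the next downstream
stop. The transcript segment between the two stops — the **inter-stop
codon region (ISR)** — then encodes a C-terminal protein extension. The
human *AGO1* mRNA is a prominent example: a 99-nt ISR separates its TGA
stop from a conserved in-frame TAA, so readthrough appends 34 residues
(one for the recoded stop plus 33 ISR codons) and yields the extended
isoform Ago1x. `ribothrough` implements the computational evidence chain
for such events, end to end, for anyone analysing a candidate readthrough
transcript:

* **ISR annotation** (`transcript_model`) — locate the first downstream
  in-frame stop, translate the extension, and partition the transcript
  into counting regions (5′UTR, CDS incl. canonical stop, ISR incl.
  downstream stop, distal 3′UTR) with 12-nt post-codon exclusion zones.
* **Footprint mapping** (`footprint_mapper`) — place reads by 100%-identity
  full-length matching (length ≥ 24, no mismatches/gaps, forward strand),
  or ingest transcript-space SAM/BAM, and assign each read its
  central-nucleotide P-site (left-central for even lengths).
* **Readthrough calling** (`readthrough_caller`) — a dataset is positive
  for readthrough iff: ≥ 45 P-sites in the CDS, ≥ 1 P-site in the second
  half of the ISR, ≥ 10% of the ISR covered by footprints, and ISR
  footprint density ≥ 3× that of the rest of the 3′UTR
  (density = reads / region length).
* **Periodicity** (`periodicity`) — metagene P-site profile around the
  start codon (offsets −24..62), periodic fragment-length selection
  (default 27–29 nt), and per-region frame proportions *(f₀, f₁, f₂)* with
  their coefficient of variation: CV ≈ 0 for untranslated (frame-uniform)
  regions, large CV for translated ones.
* **Proteogenomics** (`proteogenomics`) — the 20-variant readthrough
  protein database (each standard amino acid substituted at the stop),
  in-silico tryptic digestion with missed cleavages (default ≤ 5), and
  extension-specific peptides absent from a reference proteome.
* **Assay quantification** (`assay_quant`) — dual-luciferase readthrough
  efficiency, 100 × (FLuc/RLuc)ₜₑₛₜ / (FLuc/RLuc)ₙₒ₋ₛₜₒₚ with a
  delta-method standard error; tethering-assay percent change; identifier
  set overlaps.
* **Synthetic data** (`synthetic_data`) — seeded generator of readthrough
  loci, region/frame-structured footprints and noisy reporter readouts,
  so the whole chain is testable without downloads.

## Worked example

```python
import ribothrough as rt

spec = rt.SimSpec(seed=42)                      # 99-nt ISR, cds:isr:utr3 densities 50:5:1
ann = rt.make_transcript(spec)
print(f"locus: {ann.length} nt, CDS {ann.cds}, ISR {ann.isr} ({ann.isr_codons} codons)")
print(f"extension: {rt.translate_extension(ann)}")

reads, _ = rt.simulate_footprints(ann, spec)
footprints, mstats = rt.map_reads(reads, {ann.transcript_id: ann.sequence})
print(f"mapped {mstats.n_mapped}/{mstats.n_input} reads")

stats, call = rt.analyze_transcript(footprints, ann)
print(f"region P-site counts: {stats.counts} (+{stats.n_excluded} excluded)")
print(f"ISR coverage {stats.isr_coverage_fraction:.2f}, "
      f"density ratio {stats.density_ratio():.2f}, verdict {'POSITIVE' if call.verdict else 'negative'}")

table = rt.frame_table(footprints, ann, rt.partition_regions(ann), rt.select_periodic_lengths())
print(table.round(3).to_string(index=False))
```

prints

```
locus: 1202 nt, CDS (100, 700), ISR (700, 799) (33 codons)
extension: XHNPSKCDRQDHTGGTHMGVVLVHTAWLMMKRDD
mapped 20000/20000 reads
region P-site counts: {'utr5': 132, 'cds': 18898, 'isr': 308, 'utr3_rest': 236} (+426 excluded)
ISR coverage 1.00, density ratio 5.63, verdict POSITIVE
   region     n    f0    f1    f2    cv
      cds 18898 0.597 0.205 0.198 0.685
      isr   308 0.594 0.201 0.205 0.678
utr3_rest   236 0.305 0.314 0.381 0.125
```

The 99-nt ISR yields a 33-codon / 34-residue extension (`X` marks the
unknown residue inserted at the recoded stop). Every simulated read maps
back uniquely; the exclusion-adjusted ISR/3′UTR density ratio (5.63)
recovers the simulated fivefold enrichment within sampling error and all
four criteria hold, so the locus is called readthrough-positive. The frame
table shows the Ribo-seq signature: strong frame-0 bias (high CV) in the
CDS and ISR — evidence that the ISR is translated — and a near-uniform
frame distribution (CV ≈ 0.13) in the distal 3′UTR.

The same pipeline is scriptable from the shell (`ribothrough simulate`,
`annotate`, `map`, `call`, `periodicity`, `proteome-db`, `digest`,
`extension-peptides`, `reporter`, `overlap`); see `ribothrough --help`.

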