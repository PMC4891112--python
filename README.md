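# shattercall

Detection of chromothripsis-like chromosomal rearrangements, driven end to
end by a synthetic-data generator so every stage is verifiable against a
known truth set without any downloads.

The pipeline re-implements, as tested reusable components, the computational
procedure used to characterize radiation-induced rearrangements in an
irradiated carcinoma subline:

- **`synthetic_data`** — random reference genomes; planting of
  rearrangements (translocation CT, long deletion LD, inversion-type FF,
  duplication-type RF) with exact junction chemistry (microhomology, blunt,
  or insertion with optional templated origin); FR paired-end read
  simulation with mapping emulated by coordinate lifting; SNP-probe
  copy-number/BAF tracks with Gaussian noise; proton-microbeam dosimetry
  (`compute_absorbed_dose`).
- **`sv_calling`** — the identification cascade: orientation/distance
  classification of read pairs (FR proper, CT/LD/FF/RF discordant, RR
  folded into FF), single-linkage clustering within 500 bp on both
  footprints, support ≥ 3, subtraction of clusters shared with parental
  samples, a blastn-like ungapped realignment filter (pairs re-aligning
  concordantly at E < 1e-7 are dropped; Karlin–Altschul statistics),
  ≤ 2 mismatches per read, and ≥ 1 perfect pair per call.
- **`junction_analysis`** — junction chemistry classification by maximal
  anchored exact extension (overlap = microhomology, gap = insertion,
  abutment = blunt), templated-insertion origin search (± 500 bp, both
  orientations), breakpoint proximity statistics, and the class census.
- **`cna_calling`** — baseline subtraction (differential re-centred at 2
  copies), recursive binary segmentation with a Welch t-test split rule
  (min 30 probes, p < 0.001, SNR 0.3) plus least-squares boundary
  refinement and pruning, and Amp/Del thresholds (≥ 2.6 / ≤ 1.8 copies).
- **`chromothripsis_report`** — per-chromosome scoring of the three
  chromothripsis criteria: breakpoint localization against a
  length-weighted permutation null, copy-state oscillation between the two
  predominant states, and retained heterozygosity from folded BAF.  The
  flagging rule is an explicit, configurable operationalization.
- **`io_cli`** — FASTA / BEDPE / SEG / TSV / SAM readers and writers
  (internal coordinates are 1-based inclusive; conversion happens only at
  format boundaries), YAML configuration, and the CLI.

A bundled demo truth set (`shattercall.datasets`) carries the 14 validated
rearrangements and 16 copy-number segments of the characterized subline in
GRCh37-style coordinates.  A gap-capping rescale maps them onto small
synthetic chromosomes while preserving order and small distances exactly
(the 5 bp and 377 bp breakpoint proximities survive unchanged).

## CLI

```bash
shattercall simulate  --seed 1 --outdir out          # genome, reads, tracks
shattercall call-sv   --pairs out/sample_pairs.tsv \
                      --parental out/parental1_pairs.tsv \
                      --parental out/parental2_pairs.tsv \
                      --ref out/reference.fa --out calls.bedpe
shattercall call-cna  --track out/track_sample.tsv --baseline out/track_baseline.tsv
shattercall junctions --calls calls.bedpe --ref out/reference.fa --seqs amplicons.fa
shattercall assess    --calls calls.bedpe --cna segments.seg --track out/track_sample.tsv
shattercall run-all   --seed 1 --outdir out          # full pipeline + manifest
```

`run-all` executes simulate → call-cna → call-sv → junctions → assess and
writes a provenance manifest (config hash, seed, version, stage outputs).
Identical config + seed give byte-identical outputs.

## Notes and deliberate simplifications

- Read mapping is emulated by coordinate lifting through the planted
  block structure (no aligner): a read overlapping a junction is assigned
  to the side covering at least half of it, overhang treated as clipped.
- The realignment filter is a self-contained blastn surrogate (ungapped
  seed-and-extend, +1/−2, λ = 1.33, K = 0.621), not NCBI BLAST.
- The segmentation is a deterministic functional surrogate for the
  proprietary algorithm the original analysis used; only its three
  published parameters are mapped onto the split rule.
- Events sharing a chromosome are planted on separate derivative contigs,
  the way they would occur on distinct copies of that chromosome.
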