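# flanklift

Flanking-sequence based liftover of SNP-array markers between genome assembly
versions, with a full validation cascade, result classification, MAF spectrum
statistics, and a synthetic genome-pair simulator that provides ground truth
for testing.

Given a marker table (id, chromosome, 1-based position, ref/alt alleles) on a
*source* assembly and a *target* assembly FASTA, flanklift:

1. extracts the ±50 bp flank around each marker and aligns it against the
   target with a k-mer seeded, locally extended aligner (defaults mirror
   BLAT-style thresholds: tile size 12, min score 100, min identity 98%);
2. classifies hits as unique / multi-mapped / unmapped, projects the SNP base
   through the alignment column map, and builds collinear chains from the
   accepted alignments; markers without an acceptable alignment of their own
   get one chain-lift attempt through their neighbours' chains;
3. validates lifted sites: the target base must be one of the marker's two
   alleles (strand-normalized), and the source/target flank windows must match
   base-by-base at a configurable identity threshold (default 100%, SNP base
   excluded);
4. classifies markers positionally (genic / near-genic / intergenic with
   upstream/downstream resolution) and attributes failures to transposable
   element classes or cross-assembly low-identity windows;
5. emits a lifted VCF (plus a rejects file), a UCSC-format chain file,
   per-marker result TSVs, and Table-style summaries with filter-cascade
   accounting.

Every coordinate is 0-based half-open internally; conversion to 1-based
conventions happens only at the I/O boundary.

## CLI

```sh
# generate a synthetic source/target pair with known marker fates
flanklift simulate --out-dir fx --seed 1 --n-markers 500

# run the liftover pipeline
flanklift lift \
    --source-fasta fx/source.fa --target-fasta fx/target.fa \
    --markers fx/markers.tsv --genes fx/genes.gff3 --tes fx/tes.bed \
    --out-dir out

# MAF spectrum of a genotype matrix over the lifted markers
flanklift mafstats --genotypes fx/genotypes_a.tsv --out maf.json

# Venn counts of lifted markers between two runs
flanklift compare-versions --results-a out/results.tsv --results-b out2/results.tsv
```

`flanklift lift` writes `lifted.vcf`, `rejects.tsv`, `lift.chain`,
`results.tsv`, `low_identity.bed` and `summary.json` (per-chromosome counts,
failure breakdown, strand breakdown, and stage-by-stage cascade log) to the
output directory. Alignment thresholds (`--k`, `--min-score`,
`--min-identity`), the validation identity threshold
(`--validate-identity`), and the near-genic window (`--near-window`) are all
configurable.

## Python API

```python
from flanklift import SimConfig, simulate_pair, lift_markers, PipelineConfig

fx = simulate_pair(SimConfig(seed=1))
out = lift_markers(fx.markers, fx.source, fx.target, PipelineConfig())
```

The simulator (`flanklift.simulate`) derives the target from the source by
background substitutions, segmental duplications, deletions, diverged
windows, single-site divergences, scaffold-to-chromosome anchoring and
optional whole-chromosome inversion — each planted marker carries a
`TruthRecord` with its expected fate and coordinate, and the exact
source→target block map is returned as a chain set.

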