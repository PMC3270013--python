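# ngsqc

Quality control, filtering, trimming, format conversion and statistics for
short-read sequencing data: Illumina reads in FASTQ (any of the three
historical quality encodings, plain or gzip-compressed) and Roche 454
pyrosequencing reads in FASTA + qual form.

It is aimed at anyone who receives raw reads and needs clean, well-documented
high-quality (HQ) data before assembly, mapping, SNP calling or expression
analysis — with paired-end integrity preserved and a full accounting of what
was removed and why.

## What it computes

**Quality encodings.** FASTQ stores one ASCII character per base encoding a
quality score. Sanger files use Phred scores Q = −10·log₁₀(p_error) at ASCII
offset 33 (Q 0–93); Illumina 1.3+ uses Phred at offset 64 (Q 0–62); early
Solexa files use offset 64 but log-odds scores Q_solexa =
−10·log₁₀(p/(1−p)) spanning −5–62. The variant is auto-detected from the
observed ASCII code range (minimum < 59 ⇒ Sanger; 59–63 ⇒ Solexa; ≥ 64 ⇒
Illumina 1.3+, flagged ambiguous because high-quality Solexa data is
indistinguishable there — an explicit override always wins). Solexa scores
convert to Phred via Q_phred = 10·log₁₀(10^(Q_solexa/10) + 1), rounded to
the nearest integer.

**Illumina QC.** A read is HQ when at least *f*% of its bases (default 70)
score ≥ a Phred cutoff (default 20), i.e. #{q_i ≥ Q_cut} ≥ ⌈f/100 · ℓ⌉.
HQ reads are then screened for primer/adaptor contamination: the first and
last 20 bases of each adaptor are slid over the read and a Hamming match
with at most 1 mismatch (configurable; no indels) discards the read. In
paired-end mode both mates must pass for the pair to be kept; a lone
survivor is diverted to an unpaired output, so mate files stay synchronized
line-for-line and no HQ data is lost.

**Roche 454 QC.** Stages, each followed by a length filter (default 50 bp):
optional homopolymer trimming (truncate at the first base of the leftmost
single-base run of a chosen length — long runs are miscalled by
pyrosequencing), a mean-read-quality filter (default ≥ 20), and adaptor
end-trimming (adaptor windows matched against the first/last 50 bases of the
read; the contaminated end is cut off). Paired-end 454 reads are a single
physical read with a linker joining the mates; the linker's best full-length
Hamming match (≤ 2 mismatches by default) splits the read before QC.

**Statistics.** Per-run reports cover read/base counts, min/max/mean/median
and Nx lengths (Nx = the length L such that reads ≥ L contain at least x% of
all bases, scanning lengths in decreasing order), HQ and non-ATCG base
counts, GC%, per-position mean quality and quality-range fractions, GC /
quality / length histograms — for input and filtered data side by side, as
formatted text, TSV and a self-contained HTML report with charts.

A deterministic synthetic-read generator (`ngsqc.fixtures`) produces
datasets with planted low-quality reads, adaptor contamination at stated
mismatch counts, homopolymer runs and linker inserts, together with a
manifest of each read's expected fate — the ground truth used throughout the
test suite.

## Worked example

Generate a 1,000-read Illumina dataset with 10% unambiguously low-quality
reads and 10% adaptor-contaminated reads planted, then run QC against the
planted adaptor:

```sh
ngsqc fixtures --spec spec.txt --seed 7 --out data     # spec.txt: n_reads=1000,
                                                       # frac_low_quality=0.1, frac_adaptor=0.1
ngsqc illuqc -se data/reads.fastq GATCGGAAGAGCACACGTCTGAACTCCAGT sanger -o out
```

prints

```
FASTQ variant: sanger
Input reads: 1000  HQ reads: 800 (80.00%)
```

and `out/reads_stats.txt` begins

```
QC statistics
-------------
Step                                           Reads  % of input
Input reads                                    1000  100.00
Reads discarded: low quality                   100  10.00
Reads discarded: primer/adaptor contamination  100  10.00
HQ filtered reads                              800  80.00
```

Exactly the 100 planted low-quality reads fail the 70%-of-bases-≥-Q20 rule
and exactly the 100 adaptor plants are caught by the 20-base-window scan;
the remaining 800 reads are written to `out/reads_filtered.fastq` with
detailed input-vs-filtered statistics in the text/TSV/HTML reports beside
it. `ngsqc --help` lists the other tools (454 QC, trimmers, encoding
converters, `avgqual`, `n50stat`).

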