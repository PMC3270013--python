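# Methods

## Scope and model

`ngsqc` implements per-read quality control for two sequencing platforms
whose raw data differ in format and failure modes.

Illumina reads arrive as FASTQ. The per-base error model is summarized by
Phred scores, Q = −10·log₁₀(p_error), and the only subtlety is historical:
three incompatible ASCII encodings circulated (Sanger: offset 33, Phred
0–93; Solexa: offset 64, log-odds −5–62; Illumina 1.3+: offset 64, Phred
0–62). All internal arithmetic uses decoded integer scores; Solexa scores
are marked as log-odds and mapped to Phred with
Q_phred = 10·log₁₀(10^(Q_solexa/10) + 1) before any thresholding.

Roche 454 pyrosequencing reads arrive as FASTA plus a companion qual file.
Their characteristic artifact is the homopolymer: signal intensity scales
with run length, so long single-base runs are miscalled and everything 3′
of such a run is suspect. 454 paired-end libraries circularize the
fragment, so both mates plus a synthetic linker appear inside one physical
read and must be separated before QC.

## Pipeline definitions

**Illumina.** A read is high-quality iff #{qᵢ ≥ Q_cut} ≥ ⌈f/100·ℓ⌉ with
Q_cut = 20 and f = 70 by default. "At least f% of bases" is an integer
count of bases, and the ceiling is the conservative reading of "at least";
both knobs are exposed. Adaptor screening runs only on reads that already
passed the quality filter, so each discarded read is charged to exactly one
stage and the counters always satisfy
input = HQ + low-quality + adaptor-contaminated. In paired-end mode mates
are consumed in lockstep; a pairing-key mismatch (identifier token with any
trailing /1, /2 stripped; Casava 1.8 mate fields live in the description
and need no stripping) or a length mismatch between the files is an error
naming the record ordinal. Pairs survive together or not at all; single
survivors go to the unpaired output.

**454.** Stage order: input length filter; optional homopolymer truncation
at the first base of the leftmost run ≥ n (off by default — it is an
aggressive filter); mean-read-quality filter (mean of the qual-file scores
≥ 20 by default; the field-standard reading of a qual-file-based Phred
filter for this platform, exposed as a parameter); adaptor end-trimming;
with the length filter (default 50 bp) re-applied after every stage. A read
removed because homopolymer truncation left it too short is counted in the
homopolymer stage, not the quality stage. With every filter disabled
(length 1, no homopolymer, quality 0, no adaptors) the pipeline is the
identity.

**Adaptor matching** is pure Hamming distance — the underlying idea is
"single bp mismatch", not edit distance, so indels are deliberately not
tolerated. The first and last 20 bases of each adaptor are the probe
windows (shorter adaptors are matched whole); candidate offsets cover the
whole read for Illumina (discard semantics make the position irrelevant)
and only offsets whose window lies entirely inside the first or last 50
bases for 454 (trim semantics need an end). The lowest-mismatch hit wins,
ties break leftmost; matching is case-insensitive and an N in the read
never matches. 454 trimming removes read-start..match-end for a 5′-region
hit and match-start..read-end for a 3′-region hit.

**Linker splitting** finds the best full-length Hamming match of the linker
(allowance 2 by default; linkers are long, e.g. the 44 bp FLX-style
palindrome bundled in the catalog) and splits the read there, with quality
scores partitioned in lockstep and /1, /2 suffixes added to the mate
identifiers. Only the single best hit is split on. A hit flush with a read
end leaves one mate empty; the pair is demoted and the surviving piece
continues as unpaired.

## Encoding detection

Detection uses only the minimum and maximum ASCII codes over a bounded
sample of quality lines (default 100,000 lines; 0 scans everything), so it
is deterministic and order-insensitive. The rule table — min < 59 ⇒ Sanger,
59 ≤ min < 64 ⇒ Solexa, min ≥ 64 ⇒ Illumina 1.3+ with an ambiguity flag —
is a declared convention: codes 59–63 exist only in Solexa, while an
all-≥ 64 file is genuinely undecidable (high-quality Solexa data never dips
below code 64), hence the flag plus a user override rather than a guess.
Codes outside 33–126 abort with "not FASTQ". Conversions never clamp: a
Phred score above 62 cannot be represented at offset 64 and is a hard
error naming the read and position, because silent clamping corrupts data.
Solexa→Phred rounding is half-away-from-zero, pinned so the exhaustive
68-value table is reproducible bit-for-bit.

## Statistics conventions

All accumulators are single-pass and mergeable (length and base histograms,
score-sum vectors), which makes chunk-wise execution exactly equivalent to
a single pass — the contract behind the `-c` flag, enforced by tests for
k ∈ {2, 3, 7}. Conventions the formats leave open, pinned here for
determinism: lower median for even counts; Nx is the first length, in
decreasing order, whose cumulative base count reaches x% of the total
(computed with integer cross-multiplication, no floating point); "HQ
bases" counts bases ≥ the run's Phred cutoff (default 20); overall average
quality is base-weighted (score sum / base count); GC% is G+C over all
bases including N. Per-position series use position-specific denominators
— a read contributes only to positions it covers — and the per-position
quality-range fractions use bins [0,10), [10,20), [20,30), [30,∞) by
default.

## I/O

Both readers are streaming: memory is bounded by one record regardless of
file size (tested by byte-count accounting on a large in-memory stream).
gzip is detected by the two magic bytes `1f 8b`, never by filename, on
input; gzip output pins mtime to 0 so identical runs produce identical
bytes. FASTQ is the strict 4-line form; multi-line FASTQ and SFF are out
of scope. 454 qual headers must match the sequence file's headers in
order — the pairing of the two files is positional in practice, and a
name disagreement is treated as corruption rather than silently re-paired.
Parsers are implemented in-package because the error contract (record
ordinal and line number in every FASTQ error, both headers in a qual
mismatch, encoding-range checks at decode time) is part of the tool's
job; Biopython independently re-parses round-trip fixtures in the test
suite as a cross-check.

## Synthetic data generator

`ngsqc.fixtures` emulates exactly the artifact classes the pipelines act
on, with crisp, manifest-recorded ground truth: high-quality backgrounds at
Q35 ± 2 (far above the Q20 boundary), low-quality plants at a flat Q2
(Illumina) or Q5 (454, mean-quality filtered), adaptor windows planted
with exactly 0/1/2 substitutions, homopolymer runs planted with guard
bases on both flanks so the recorded start and length are the true maximal
run, and linker inserts sized so both mates clear the length cutoff.
Backgrounds are rejection-free by construction (no single-base run beyond
4, so they can never fake a homopolymer plant) and the jitter bound keeps
every planted class on its intended side of the pass/fail boundary, making
expected fates deterministic rather than probabilistic. Read lengths
default to 100 bp fixed (Illumina) and 80–150 bp (454).

What the generator does **not** emulate: position-dependent quality decay,
platform error profiles (substitution/indel spectra), duplicate reads, low
complexity sequence, or adaptor read-through at fragment ends. Passing the
planted-fate tests therefore demonstrates that the decision logic is exact
under unambiguous conditions; it does not quantify behaviour on borderline
real-world reads, which is governed by the user-chosen thresholds.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale, chosen to
exercise every code path with exact expected values: 10,000 random triples
for the adaptor-scan/brute-force comparison, 1,000 random multisets for
Nx, 10,000 vectors for the quality trimmer, 90 generated files for variant
detection, fixtures of 500–2,000 reads per pipeline scenario. The quality
filter's ceiling threshold is computed as ⌈f·ℓ/100 − 10⁻⁹⌉ to keep exact
integer boundaries stable under binary floating point; Nx and the report
percentages avoid the issue entirely by integer arithmetic and fixed
2-decimal formatting.

## Known limitations

No sliding-window quality trimming, adaptor discovery, duplicate or
low-complexity filtering (out of scope by design); `-p`/`-c` are
correctness contracts (equivalence to a sequential single pass) rather
than true multiprocessing; the bundled adaptor catalog is a small
user-editable starting set, not a vendor assay database; Illumina-1.5
`#`-segment semantics and colour-space data are unsupported.
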