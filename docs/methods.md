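# Methods

## Model

`ukq` quantifies expression at the gene level from k-mers that are
informative on their own. A k-mer is **indexed** when (a) across the whole
transcriptome — counting both strands unless the library is strand-specific —
it occurs in transcripts of exactly one gene, and (b) every isoform of that
gene contains it. Condition (a) makes a single hit attribute a read to one
gene with no probabilistic reassignment; condition (b) makes the count
insensitive to which isoform a read came from, which is what lets the method
ignore isoform mixture entirely. Uniqueness is judged on **canonical**
k-mers (the lexicographic minimum of a k-mer and its reverse complement), so
"also occurs on the other strand of another gene" is handled exactly rather
than heuristically; in strand-specific mode the k-mer itself is used.
Within-gene repeats are allowed: K_i counts *distinct* indexed k-mers, and a
k-mer repeated inside one gene is still unique to that gene.

Reads are scanned sparsely: k-mers are sampled at start positions
0, S, 2S, … while p ≤ len − k, with no extra window at len − k. This works
because indexed k-mers form long contiguous cover islands — a read inside an
island is hit at every sampled position — while chance matches are isolated,
which is also why the accept count M (minimum hits to a single gene)
suppresses them. A read hitting ≥ 2 genes is discarded as ambiguous *before*
the M threshold is applied: exclusion is unconditional in the underlying
model, and thresholding first would let a gene that cleared M win against a
single stray hit, quietly converting ambiguity into signal. A single
substitution corrupts up to 2k − 1 consecutive windows, so the mapping rate
falls with the error rate, fastest at large k.

Expression follows in closed form with K_i as the effective length:
F_i = (C_i/K_i)/(Σ_j C_j)·10⁹ and T_i = (C_i/K_i)/(Σ_j C_j/K_j)·10⁶, where
C_i counts gene-specific reads only (ambiguous and unassigned reads appear
in no denominator) and the sums run over covered genes. Σ T_i = 10⁶ holds by
construction. Genes with K_i = 0 get `NA`, not 0: the method has no
information about them, which is different from observing zero expression.
Mates of a pair are processed as independent reads; C_i is a read count,
not a fragment count.

## Parameters

| name | default | meaning |
|------|---------|---------|
| k    | 32      | k-mer length (nt). Larger k → more unique k-mers but stricter matching and fewer usable positions per read; must stay below the read length, and k ≤ 32 keeps one k-mer per 64-bit word. |
| S    | 12      | step between sampled positions in a read (nt). Cover islands are typically much longer than S, so sparse sampling loses little; larger S also skips isolated chance matches. |
| M    | 2       | minimum hits to a single gene to assign a read. M = 1 admits chance matches; very large M discards genuine reads. |

The defaults are the operating point used throughout the package's
simulation checks (75 nt reads).

## Synthetic data

The generator produces the structures the two index filters exist for:
isoforms of a gene share a central core (`shared_exon_fraction` of the
length) flanked by isoform-specific sequence, and a `paralog_fraction` of
genes are clones of another gene with optional per-base divergence.
Transcript lengths are **equal by default** (1000 nt): reads are drawn
gene-proportionally to the true TPM vector directly, and with equal lengths
that weight equals the expected read share, keeping ground truth free of
length-bias modelling. Reads get iid per-base substitutions (default rate
0.005, a typical short-read figure; no indels — substitutions already
exercise the M mechanism) and are reverse-complemented with probability 1/2
unless strand-specific. Everything is a pure function of its seed.

What this does *not* emulate: fragment-length, GC and positional bias,
quality-score structure, indels, intergenic/contaminant reads, and
expression-dependent library effects. Passing the recovery checks on this
generator therefore shows the estimator is correct under its own model —
uniform sampling within transcripts — not that it matches the accuracy
achievable on real libraries, where coverage bias and incomplete annotation
dominate the error budget.

`evaluate_estimates` scores estimated against true TPM (Spearman rank
correlation and mean absolute difference). When uncovered genes are
included, their `NA` estimate is scored as 0 — the method can never assign
them signal — and the `--exclude-uncovered` variant reports the covered-gene
subset instead.

## Numerical and design choices

- Expression is computed in double precision; the output table prints 6
  significant digits. `NA` marks K_i = 0 genes in both FPKM and TPM columns.
- A **cover island** is a maximal continuous run of nucleotides covered by
  indexed k-mer windows. Runs of start positions separated by a gap smaller
  than k overlap in nucleotide space and are merged into one island; this
  keeps islands disjoint and makes island lengths sum exactly to the covered
  base count (the nucleotide-coverage identity). Coordinates are 0-based,
  half-open.
- Gene-level coverage summaries and the k-sweep table use the longest
  transcript per gene (ties broken by id) as the representative isoform.
- The `.ukx` index file is a portable little-endian layout (2-bit-packed
  canonical k-mers sorted by packed value, gene string table in
  lexicographic order with K_i). Gene ordinals are lexicographic for
  reproducible bytes; magic and version are checked on load.
- Transcripts present in the FASTA but missing from the gene map are a hard
  error — dropping them silently would silently change which k-mers are
  unique. `--skip-unmapped` downgrades this to a warning plus exclusion.
- Self-reverse-complementary k-mers (possible at even k) need no special
  case: their canonical form is themselves.
- Windows containing N are skipped during both indexing and scanning, never
  counted as mismatches; a scan continues at the next multiple of S.
- Empty read streams and all-unassigned runs yield zero totals with `NA`
  expression and a warning, not a division error.

## Problem sizes used in checks

The recovery checks run 200 repeat-free single-isoform genes of 1000 nt with
100,000 error-free 75 nt reads at k = 16, S = 4, M = 2 — small enough to
re-derive from scratch in seconds while giving ~500 reads per gene, where
Poisson rank noise is well below the 0.95 correlation bar. Index/oracle
agreement uses dozens of randomized toy transcriptomes (≤ ~12 genes, ≤ 3
isoforms, ≤ 800 nt) at k ∈ {8, 16, 32} against an exhaustive set-based
reference.

## Known limitations

- Genes with no unique k-mers (recent paralogs, very short or non-coding
  genes) are unquantifiable by construction; they are reported, not imputed.
- Accuracy is bounded by annotation quality: uniqueness is relative to the
  supplied transcript set, and missing or spurious isoforms change the index.
- A single SNP between sample and reference suppresses up to 2k − 1 bases of
  matching signal in every overlapping read, biasing that gene's estimate
  downward more than alignment-based methods would.
- No isoform-level estimates, bias correction, or quality-aware matching.
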