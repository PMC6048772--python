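"""Seeded toy transcriptomes and reads with known ground-truth expression.

The generator emulates the two sequence-sharing structures the index filters
exist for: isoforms of one gene sharing a common core (so the all-isoforms
filter has work to do) and paralogous genes cloned across genes (so the
cross-gene uniqueness filter collapses them).  Reads are drawn uniformly
along a transcript with iid per-base substitution errors — no indels, no
fragment-size or GC bias — which is exactly enough to exercise the step-size
and accept-count machinery.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConfigError, GeneMap, Mate, QuantResult, SequencedRead, TranscriptRecord, revcomp

__all__ = [
    "TranscriptomeSimConfig",
    "ReadSimConfig",
    "simulate_transcriptome",
    "simulate_reads",
    "write_read_set",
    "evaluate_estimates",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TranscriptomeSimConfig:
    """Shape of the simulated transcriptome.

    Defaults give a modest multi-gene transcriptome with realistic isoform
    sharing and a small paralog fraction; ranges are inclusive.
    """

    n_genes: int = 100
    isoforms_per_gene: tuple[int, int] = (1, 3)
    # equal lengths by default: true_tpm is used directly as the read-draw
    # weight, so unequal lengths would put length bias into the ground truth
    transcript_length: tuple[int, int] = (1000, 1000)
    paralog_fraction: float = 0.05
    paralog_divergence: float = 0.0
    shared_exon_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ConfigError("paralog_fraction must be in [0, 1]")
        if not 0.0 <= self.shared_exon_fraction <= 1.0:
            raise ConfigError("shared_exon_fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.transcript_length
        if lo < 2 or hi < lo:
            raise ConfigError("transcript_length range must satisfy 2 <= lo <= hi")
        if self.shared_exon_fraction > 0 and round(self.shared_exon_fraction * lo) < 1:
            raise ConfigError(
                "shared_exon_fraction too small to yield a shared core at the "
                "minimum transcript length"
            )


@dataclass
class ReadSimConfig:
    """Read-generation parameters with per-gene ground-truth TPM.

    ``true_tpm`` maps gene_id -> abundance and must sum to 1e6.  Reads are
    drawn gene-proportionally to TPM (transcript lengths are equal by default
    in the transcriptome generator, so no length re-weighting is modelled);
    in non-strand-specific mode each read is reverse-complemented with
    probability 1/2.
    """

    true_tpm: dict[str, float]
    n_reads: int = 10_000
    read_length: int = 75
    error_rate: float = 0.005
    paired: bool = False
    strand_specific: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.true_tpm.values())
        if abs(total - 1e6) > 1e-6 * 1e6:
            raise ConfigError(f"true_tpm must sum to 1e6, got {total}")
        if any(v < 0 for v in self.true_tpm.values()):
            raise ConfigError("true_tpm entries must be nonnegative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.n_reads < 0 or self.read_length < 1:
            raise ConfigError("n_reads and read_length must be positive")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """iid per-base substitutions to a uniformly chosen *different* base."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # shift by 1..3 in base space so the substituted base always differs
    codes = np.searchsorted(_BASES, arr[hit])
    arr[hit] = _BASES[(codes + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode()


def simulate_transcriptome(
    config: TranscriptomeSimConfig,
) -> tuple[list[TranscriptRecord], GeneMap]:
    """Generate a toy transcriptome; deterministic for a fixed seed.

    Isoforms of a gene share a central core of ``shared_exon_fraction`` of the
    transcript length, flanked by isoform-specific sequence.  A
    ``paralog_fraction`` of genes are clones of another gene's isoforms with
    optional per-base divergence, so cross-gene uniqueness collapse is
    exercised.
    """
    rng = np.random.default_rng(config.seed)
    lo_len, hi_len = config.transcript_length
    lo_iso, hi_iso = config.isoforms_per_gene
    n_paralogs = int(round(config.paralog_fraction * config.n_genes))
    n_base = config.n_genes - n_paralogs

    width = max(4, len(str(config.n_genes)))
    transcripts: list[TranscriptRecord] = []
    entries: dict[str, str] = {}
    gene_isoforms: list[list[str]] = []  # sequences per gene, for paralog cloning

    def add_gene(gene_idx: int, isoform_seqs: list[str]) -> None:
        gid = f"g{gene_idx:0{width}d}"
        gene_isoforms.append(isoform_seqs)
        for j, seq in enumerate(isoform_seqs, start=1):
            tid = f"{gid}.t{j}"
            entries[tid] = gid
            transcripts.append(TranscriptRecord(tid, gid, seq))

    for i in range(config.n_genes):
        if i >= n_base and gene_isoforms:
            # paralog: clone a previously generated gene, with divergence
            src = gene_isoforms[int(rng.integers(0, len(gene_isoforms)))]
            add_gene(i, [_mutate(rng, s, config.paralog_divergence) for s in src])
            continue
        length = int(rng.integers(lo_len, hi_len + 1))
        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        core_len = int(round(config.shared_exon_fraction * length))
        if config.shared_exon_fraction > 0 and core_len < 1:
            raise ConfigError("shared core would be empty at this transcript length")
        core = _random_seq(rng, core_len)
        isoforms = []
        for _ in range(n_iso):
            flank = length - core_len
            pre = flank // 2
            isoforms.append(
                _random_seq(rng, pre) + core + _random_seq(rng, flank - pre)
            )
        add_gene(i, isoforms)

    # note: with paralog_fraction == 1.0 the first gene is still generated
    # fresh (there is nothing to clone yet), so every gene ends up duplicated
    return transcripts, GeneMap(entries)


def simulate_reads(
    transcripts: list[TranscriptRecord],
    gene_map: GeneMap,
    config: ReadSimConfig,
) -> tuple[list[SequencedRead], pd.DataFrame]:
    """Draw reads gene-proportionally to true TPM; deterministic per seed.

    Returns the reads and a ground-truth table (gene_id, true_tpm,
    n_reads_drawn).  For paired mode each drawn fragment yields a mate1 read
    from its 5' end and a reverse-complemented mate2 from its 3' end, and
    ``n_reads`` counts individual reads (two per fragment).
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for tr in transcripts:
        if len(tr.sequence) >= rl:
            by_gene.setdefault(tr.gene_id, []).append(tr)
    genes = sorted(g for g, tpm in config.true_tpm.items() if tpm > 0)
    for g in genes:
        if g not in by_gene:
            raise ConfigError(
                f"gene {g!r} has true_tpm > 0 but no transcript of length >= {rl}"
            )
    weights = np.array([config.true_tpm[g] for g in genes], dtype=float)
    weights /= weights.sum()

    if not genes:
        raise ConfigError("no gene has true_tpm > 0")
    n_units = config.n_reads // 2 if config.paired else config.n_reads
    gene_draws = rng.choice(len(genes), size=n_units, p=weights)
    drawn = dict.fromkeys(sorted(config.true_tpm), 0)
    reads: list[SequencedRead] = []
    frag_len = min(int(round(2.5 * rl)), min(len(t.sequence) for g in genes for t in by_gene[g]))
    for i, gi in enumerate(gene_draws):
        gene = genes[gi]
        cands = by_gene[gene]
        tr = cands[int(rng.integers(0, len(cands)))]
        seq = tr.sequence
        if config.paired:
            flen = min(frag_len, len(seq))
            start = int(rng.integers(0, len(seq) - flen + 1))
            frag = seq[start : start + flen]
            m1 = _mutate(rng, frag[:rl], config.error_rate)
            m2 = _mutate(rng, revcomp(frag[-rl:]), config.error_rate)
            if not config.strand_specific and rng.random() < 0.5:
                m1, m2 = revcomp(m2), revcomp(m1)
            reads.append(SequencedRead(f"r{i:07d}", m1, Mate.MATE1))
            reads.append(SequencedRead(f"r{i:07d}", m2, Mate.MATE2))
            drawn[gene] += 2
        else:
            start = int(rng.integers(0, len(seq) - rl + 1))
            window = _mutate(rng, seq[start : start + rl], config.error_rate)
            if not config.strand_specific and rng.random() < 0.5:
                window = revcomp(window)
            reads.append(SequencedRead(f"r{i:07d}", window, Mate.SINGLE))
            drawn[gene] += 1

    truth = pd.DataFrame(
        {
            "gene_id": sorted(config.true_tpm),
            "true_tpm": [config.true_tpm[g] for g in sorted(config.true_tpm)],
            "n_reads_drawn": [drawn[g] for g in sorted(config.true_tpm)],
        }
    )
    return reads, truth


def write_read_set(
    reads: list[SequencedRead],
    truth: pd.DataFrame,
    out_prefix: str | Path,
    *,
    paired: bool = False,
    compress: bool = False,
) -> list[Path]:
    """Write FASTQ file(s) plus the ground-truth TSV next to them."""
    from .io_formats import write_fastq

    out_prefix = Path(out_prefix)
    ext = ".fastq.gz" if compress else ".fastq"
    written: list[Path] = []
    if paired:
        for mate, suffix in ((Mate.MATE1, "_1"), (Mate.MATE2, "_2")):
            path = out_prefix.with_name(out_prefix.name + suffix + ext)
            write_fastq([r for r in reads if r.mate is mate], path, compress=compress)
            written.append(path)
    else:
        path = out_prefix.with_name(out_prefix.name + ext)
        write_fastq(reads, path, compress=compress)
        written.append(path)
    truth_path = out_prefix.with_name(out_prefix.name + ".truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)
    return written


def evaluate_estimates(
    truth: pd.DataFrame,
    result: QuantResult,
    *,
    exclude_uncovered: bool = False,
) -> tuple[float, float]:
    """Spearman correlation and mean |T_est - T_true| of TPM against truth.

    With ``exclude_uncovered`` genes with K_i = 0 are dropped (they carry no
    information); otherwise their NA estimate is scored as 0, since the method
    can never assign them signal.
    """
    rows = truth.set_index("gene_id")["true_tpm"]
    genes = [g for g in result.gene_ids if g in rows.index]
    if exclude_uncovered:
        genes = [g for g in genes if result.kmer_counts.get(g, 0) > 0]
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to evaluate estimates")
    true_vals = np.array([rows[g] for g in genes], dtype=float)
    est_vals = np.array(
        [result.tpm.get(g, float("nan")) for g in genes], dtype=float
    )
    est_vals = np.nan_to_num(est_vals, nan=0.0)
    scc = stats.spearmanr(true_vals, est_vals).statistic
    mad = float(np.mean(np.abs(est_vals - true_vals)))
    return float(scc), mad
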