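"""Index diagnostics: gene coverage, nucleotide coverage and cover islands.

A *cover island* is a maximal run of consecutive transcript positions whose
k-mers are all indexed; a run of starts p..q spans q - p + k nucleotides.
Long islands are what makes sparse read sampling (step size S) safe: a read
falling inside an island is hit at every sampled position.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .index_builder import build_index, canonical, enumerate_kmers
from .model import BuildParams, CoverageStats, GeneMap, KmerIndex, TranscriptRecord

__all__ = [
    "indexed_positions",
    "cover_islands",
    "nucleotide_coverage",
    "transcript_coverage",
    "gene_coverage",
    "sweep_k",
    "uncovered_gene_report",
]


def indexed_positions(transcript: TranscriptRecord, index: KmerIndex) -> list[int]:
    """Sorted start positions in ``transcript`` whose canonical k-mer is
    indexed to this transcript's gene."""
    out = []
    for pos, kmer in enumerate_kmers(transcript.sequence, index.k):
        if index.kmer_to_gene.get(canonical(kmer, index.strand_specific)) == transcript.gene_id:
            out.append(pos)
    return out


def cover_islands(positions: Sequence[int], k: int) -> list[tuple[int, int]]:
    """Collapse sorted distinct start positions into (start, nt_length) islands.

    An island is a maximal continuous stretch of nucleotides covered by
    indexed k-mer windows: a run p..q of consecutive starts spans q - p + k
    bases, and runs whose windows overlap or abut (gap < k in start space)
    belong to the same continuous region and are merged.  A lone position is
    an island of exactly k nucleotides.  Islands are therefore disjoint and
    their lengths sum to the covered-base count.
    """
    islands: list[tuple[int, int]] = []
    cur_start: int | None = None
    cur_end = 0
    for p in positions:
        if cur_start is None:
            cur_start, cur_end = p, p + k
        elif p <= cur_end:
            cur_end = max(cur_end, p + k)
        else:
            islands.append((cur_start, cur_end - cur_start))
            cur_start, cur_end = p, p + k
    if cur_start is not None:
        islands.append((cur_start, cur_end - cur_start))
    return islands


def nucleotide_coverage(positions: Sequence[int], k: int, transcript_length: int) -> float:
    """Fraction of transcript bases covered by at least one indexed k-mer window."""
    covered = sum(length for _, length in cover_islands(positions, k))
    return covered / transcript_length


def transcript_coverage(transcript: TranscriptRecord, index: KmerIndex) -> CoverageStats:
    """Full per-transcript diagnostics bundle."""
    positions = indexed_positions(transcript, index)
    islands = cover_islands(positions, index.k)
    return CoverageStats(
        transcript_id=transcript.transcript_id,
        transcript_length=len(transcript.sequence),
        indexed_positions=positions,
        nucleotide_coverage=nucleotide_coverage(positions, index.k, len(transcript.sequence)),
        islands=islands,
    )


def gene_coverage(index: KmerIndex) -> float:
    """Fraction of genes with at least one indexed k-mer."""
    if not index.gene_ids:
        raise ValueError("index lists no genes")
    covered = sum(1 for g in index.gene_ids if index.gene_kmer_count.get(g, 0) > 0)
    return covered / len(index.gene_ids)


def _representative(transcripts: list[TranscriptRecord]) -> dict[str, TranscriptRecord]:
    """Longest transcript per gene (ties broken by transcript_id) — the
    representative isoform used for gene-level coverage summaries."""
    best: dict[str, TranscriptRecord] = {}
    for tr in sorted(transcripts, key=lambda t: (-len(t.sequence), t.transcript_id)):
        best.setdefault(tr.gene_id, tr)
    return best


def sweep_k(
    transcripts: list[TranscriptRecord],
    gene_map: GeneMap,
    k_values: Sequence[int],
    strand_specific: bool = False,
) -> pd.DataFrame:
    """Rebuild the index for each k and tabulate coverage statistics.

    Returns a DataFrame with columns (k, gene_coverage,
    mean_nucleotide_coverage); the nucleotide mean is over the representative
    (longest) transcript of each gene.
    """
    reps: list[TranscriptRecord] | None = None
    rows = []
    for k in k_values:
        index = build_index(transcripts, gene_map, BuildParams(k, strand_specific))
        if reps is None:
            reps = list(_representative(transcripts).values())
        cov = [
            nucleotide_coverage(indexed_positions(tr, index), k, len(tr.sequence))
            for tr in reps
        ]
        rows.append(
            {
                "k": k,
                "gene_coverage": gene_coverage(index),
                "mean_nucleotide_coverage": sum(cov) / len(cov) if cov else 0.0,
            }
        )
    return pd.DataFrame(rows)


def uncovered_gene_report(index: KmerIndex, gene_map: GeneMap | None = None) -> list[str]:
    """Lexicographically sorted gene_ids with no indexed k-mers (K_i = 0)."""
    genes = gene_map.gene_ids if gene_map is not None else index.gene_ids
    return sorted(g for g in genes if index.gene_kmer_count.get(g, 0) == 0)
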