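"""Build the gene-unique k-mer index.

A k-mer is *indexed* when it satisfies two filters:

1. **Uniqueness across genes** — in canonical form (collapsing a k-mer with
   its reverse complement unless the library is strand-specific) it occurs in
   transcripts of exactly one gene.  Repeats *within* one gene are allowed.
2. **Presence in all isoforms** — every transcript of that gene contains the
   k-mer (on either strand in non-strand-specific mode).

The per-gene count of distinct indexed k-mers, K_i, plays the role of
effective length in the FPKM/TPM formulas, so genes with K_i = 0 cannot be
quantified and stay listed as uncovered.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

from .model import BuildParams, GeneMap, KmerIndex, TranscriptRecord, revcomp

__all__ = [
    "MULTI",
    "enumerate_kmers",
    "canonical",
    "build_kmer_gene_table",
    "filter_all_isoforms",
    "build_index",
]


class _MultiGene:
    """Sentinel marking a k-mer seen in two or more genes."""

    def __repr__(self) -> str:  # pragma: no cover
        return "MULTI"


MULTI = _MultiGene()

_ACGT = frozenset("ACGT")


def enumerate_kmers(sequence: str, k: int) -> list[tuple[int, str]]:
    """All (start, k-mer) windows of ``sequence`` free of ambiguous bases.

    Positions are 0-based and ascending; a sequence shorter than k yields an
    empty list.  Windows containing N (or any non-ACGT symbol) are skipped.
    """
    n = len(sequence)
    out: list[tuple[int, str]] = []
    if k > n:
        return out
    last_bad = -1  # rightmost non-ACGT position seen so far
    for i, base in enumerate(sequence):
        if base not in _ACGT:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            out.append((start, sequence[start : i + 1]))
    return out


def canonical(kmer: str, strand_specific: bool = False) -> str:
    """Canonical form: the k-mer itself, or the smaller of it and its
    reverse complement when the library is not strand-specific."""
    bad = set(kmer) - _ACGT
    if bad:
        raise ValueError(f"ambiguous base {bad.pop()!r} in k-mer {kmer!r}")
    if strand_specific:
        return kmer
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_kmer_gene_table(
    transcripts: Iterable[TranscriptRecord], params: BuildParams
) -> dict[str, object]:
    """First pass: canonical k-mer -> owning gene, or MULTI if shared.

    Uniqueness is judged at the gene level: the same k-mer appearing in two
    isoforms of one gene is still unique.
    """
    table: dict[str, object] = {}
    for tr in transcripts:
        for _, kmer in enumerate_kmers(tr.sequence, params.k):
            kc = canonical(kmer, params.strand_specific)
            owner = table.get(kc)
            if owner is None:
                table[kc] = tr.gene_id
            elif owner is not MULTI and owner != tr.gene_id:
                table[kc] = MULTI
    return table


def filter_all_isoforms(
    unique_kmers: dict[str, str],
    transcripts: Iterable[TranscriptRecord],
    params: BuildParams,
) -> dict[str, str]:
    """Second pass: keep a k-mer only if every isoform of its gene carries it.

    Membership is canonical: in non-strand-specific mode a k-mer present only
    as its reverse complement in some isoform still counts.
    """
    per_transcript: dict[str, list[set[str]]] = {}
    for tr in transcripts:
        kset = {
            canonical(kmer, params.strand_specific)
            for _, kmer in enumerate_kmers(tr.sequence, params.k)
        }
        per_transcript.setdefault(tr.gene_id, []).append(kset)
    kept: dict[str, str] = {}
    for kmer, gene in unique_kmers.items():
        isoform_sets = per_transcript.get(gene, [])
        if isoform_sets and all(kmer in s for s in isoform_sets):
            kept[kmer] = gene
    return kept


def build_index(
    transcripts: list[TranscriptRecord],
    gene_map: GeneMap,
    params: BuildParams,
    *,
    skip_unmapped: bool = False,
) -> KmerIndex:
    """Full pipeline: enumerate -> canonicalize -> uniqueness -> isoform filter.

    Every transcript must appear in ``gene_map``; with ``skip_unmapped`` the
    offenders are dropped with a warning instead (silent dropping would
    silently change which k-mers are unique).  ``gene_ids`` lists every gene
    in the map, including genes that end up with K_i = 0.
    """
    if not transcripts:
        raise ValueError("empty transcriptome")
    resolved: list[TranscriptRecord] = []
    for tr in transcripts:
        if tr.transcript_id not in gene_map.entries:
            if skip_unmapped:
                warnings.warn(
                    f"transcript {tr.transcript_id!r} absent from gene map; excluded",
                    stacklevel=2,
                )
                continue
            raise ValueError(
                f"transcript {tr.transcript_id!r} is not in the gene map"
            )
        gid = gene_map.gene_of(tr.transcript_id)
        if tr.gene_id != gid:
            tr = TranscriptRecord(tr.transcript_id, gid, tr.sequence)
        resolved.append(tr)
    if not resolved:
        raise ValueError("no transcripts left after dropping unmapped ones")

    table = build_kmer_gene_table(resolved, params)
    unique = {kmer: gene for kmer, gene in table.items() if gene is not MULTI}
    indexed = filter_all_isoforms(unique, resolved, params)  # type: ignore[arg-type]

    gene_ids = gene_map.gene_ids
    counts = {g: 0 for g in gene_ids}
    for gene in indexed.values():
        counts[gene] += 1
    return KmerIndex(
        k=params.k,
        strand_specific=params.strand_specific,
        kmer_to_gene=indexed,
        gene_kmer_count=counts,
        gene_ids=gene_ids,
    )
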