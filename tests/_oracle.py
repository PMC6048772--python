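"""Independent brute-force reference for the gene-unique k-mer index.

Deliberately structured unlike the package implementation: it materializes
every k-mer of every transcript on both strands explicitly (no canonical-form
collapsing during discovery) and decides uniqueness / all-isoform membership
with plain set algebra, then canonicalizes only at the end for comparison.
"""

from __future__ import annotations

from collections import defaultdict

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _raw_kmers(seq: str, k: int) -> set[str]:
    ok = set("ACGT")
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if set(seq[i : i + k]) <= ok
    }


def oracle_index(transcripts, gene_map, k: int, strand_specific: bool = False):
    """Return (canonical_kmer -> gene_id, gene_id -> K_i) by exhaustive search."""
    per_transcript: list[tuple[str, set[str]]] = []
    gene_kmers: dict[str, set[str]] = defaultdict(set)
    for tr in transcripts:
        strands = [tr.sequence] if strand_specific else [tr.sequence, _rc(tr.sequence)]
        seen: set[str] = set()
        for s in strands:
            seen |= _raw_kmers(s, k)
        gid = gene_map.entries[tr.transcript_id]
        per_transcript.append((gid, seen))
        gene_kmers[gid] |= seen

    indexed: dict[str, str] = {}
    every_kmer = set().union(*(s for _, s in per_transcript)) if per_transcript else set()
    for km in every_kmer:
        owners = [g for g, s in gene_kmers.items() if km in s]
        if len(owners) != 1:
            continue
        gene = owners[0]
        if all(km in s for g, s in per_transcript if g == gene):
            canon = km if strand_specific else min(km, _rc(km))
            indexed[canon] = gene

    counts = {g: 0 for g in sorted(set(gene_map.entries.values()))}
    for gene in indexed.values():
        counts[gene] += 1
    return indexed, counts
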