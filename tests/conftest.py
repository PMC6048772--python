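from __future__ import annotations

import random

import numpy as np
import pytest

from ukq.index_builder import canonical
from ukq.model import GeneMap, KmerIndex, TranscriptRecord

BASES = "ACGT"


def random_toy_transcriptome(
    rng: random.Random,
    max_genes: int = 12,
    max_isoforms: int = 3,
    max_length: int = 400,
) -> tuple[list[TranscriptRecord], GeneMap]:
    """Small random transcriptome with deliberate cross-gene and cross-isoform
    sequence sharing so both index filters are exercised."""
    n_genes = rng.randint(2, max_genes)
    transcripts: list[TranscriptRecord] = []
    entries: dict[str, str] = {}
    gene_seqs: list[str] = []
    for gi in range(n_genes):
        length = rng.randint(30, max_length)
        if gene_seqs and rng.random() < 0.2:
            # borrow a chunk from an earlier gene to create shared sequence
            src = rng.choice(gene_seqs)
            take = rng.randint(10, min(len(src), length))
            borrowed = src[:take]
            seq = borrowed + "".join(rng.choice(BASES) for _ in range(length - take))
        else:
            seq = "".join(rng.choice(BASES) for _ in range(length))
        gene_seqs.append(seq)
        gid = f"g{gi:03d}"
        n_iso = rng.randint(1, max_isoforms)
        for ti in range(n_iso):
            if ti == 0:
                iso = seq
            else:
                # isoform = window of the gene sequence plus a private tail
                lo = rng.randint(0, max(0, len(seq) - 20))
                hi = rng.randint(lo + 15, len(seq))
                iso = seq[lo:hi] + "".join(
                    rng.choice(BASES) for _ in range(rng.randint(0, 30))
                )
            tid = f"{gid}.t{ti}"
            entries[tid] = gid
            transcripts.append(TranscriptRecord(tid, gid, iso))
    return transcripts, GeneMap(entries)


def random_index(rng: random.Random, k: int = 8) -> KmerIndex:
    """Random but internally consistent KmerIndex for serialization tests."""
    strand_specific = rng.random() < 0.5
    n_genes = rng.randint(1, 10)
    gene_ids = sorted(f"gene-{rng.randrange(10**6):06d}" for _ in range(n_genes))
    gene_ids = sorted(set(gene_ids))
    kmer_to_gene: dict[str, str] = {}
    for _ in range(rng.randint(0, 200)):
        kmer = "".join(rng.choice(BASES) for _ in range(k))
        kmer_to_gene[canonical(kmer, strand_specific)] = rng.choice(gene_ids)
    counts = {g: 0 for g in gene_ids}
    for g in kmer_to_gene.values():
        counts[g] += 1
    return KmerIndex(
        k=k,
        strand_specific=strand_specific,
        kmer_to_gene=kmer_to_gene,
        gene_kmer_count=counts,
        gene_ids=gene_ids,
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def np_rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
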