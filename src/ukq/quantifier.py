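"""Assign reads to genes by skip-sampled k-mer lookup and compute FPKM/TPM.

Instead of hashing every k-mer of a read, start positions are sampled at a
fixed step S (positions 0, S, 2S, ... while p <= len - k).  Because indexed
k-mers form long contiguous cover islands on real transcripts, sparse
sampling loses little information but cuts lookups by a factor of S.

Assignment rules, applied per read (mates of a pair are independent reads):

* hits to two or more distinct genes  -> AMBIGUOUS (excluded; applied to the
  raw hit list before any thresholding)
* all hits to one gene, at least M    -> ASSIGNED to that gene
* fewer than M hits                   -> UNASSIGNED (treated as chance matches)
* read shorter than k                 -> TOO_SHORT

Expression is computed directly from the per-gene read counts C_i and
indexed-k-mer counts K_i, with K_i playing the role of effective length —
no EM step is needed because every counted k-mer identifies a single gene:

    F_i = (C_i / K_i) / (sum_j C_j)        * 1e9    (FPKM)
    T_i = (C_i / K_i) / (sum_j C_j / K_j)  * 1e6    (TPM)

where the sums run over genes with K_j > 0.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Sequence

import numpy as np

from .model import (
    AssignmentOutcome,
    KmerIndex,
    QuantParams,
    QuantResult,
    ReadAssignment,
    SequencedRead,
    revcomp,
)

__all__ = [
    "scan_read",
    "assign_read",
    "compute_fpkm",
    "compute_tpm",
    "quantify",
]

_ACGT = frozenset("ACGT")


def scan_read(read: SequencedRead, index: KmerIndex, step_size: int) -> list[str]:
    """Gene hits at sampled positions 0, S, 2S, ... while p <= len(read) - k.

    Windows containing an ambiguous base are skipped (not counted as
    mismatches); lookups respect the index strandedness via canonical form.
    """
    k = index.k
    seq = read.sequence
    table = index.kmer_to_gene
    strand_specific = index.strand_specific
    hits: list[str] = []
    for p in range(0, len(seq) - k + 1, step_size):
        kmer = seq[p : p + k]
        if not _ACGT.issuperset(kmer):
            continue
        if not strand_specific:
            rc = revcomp(kmer)
            if rc < kmer:
                kmer = rc
        gene = table.get(kmer)
        if gene is not None:
            hits.append(gene)
    return hits


def assign_read(
    hits: Sequence[str], accept_count: int, was_too_short: bool = False
) -> ReadAssignment:
    """Turn a hit list into an assignment outcome (see module docstring)."""
    if was_too_short:
        return ReadAssignment(AssignmentOutcome.TOO_SHORT)
    genes = set(hits)
    if len(genes) >= 2:
        return ReadAssignment(AssignmentOutcome.AMBIGUOUS)
    if genes and len(hits) >= accept_count:
        return ReadAssignment(AssignmentOutcome.ASSIGNED, gene_id=hits[0])
    return ReadAssignment(AssignmentOutcome.UNASSIGNED)


def compute_fpkm(C: Sequence[float], K: Sequence[float]) -> np.ndarray:
    """FPKM: F_i = (C_i/K_i) / (sum_j C_j) * 1e9, over genes with K_i > 0.

    A zero total count yields all-NaN with a warning rather than a division
    error.
    """
    C = np.asarray(C, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("compute_fpkm requires K_i > 0 for every gene passed")
    total = C.sum()
    if total == 0:
        warnings.warn("no assigned reads; FPKM undefined", stacklevel=2)
        return np.full(C.shape, np.nan)
    return (C / K) / total * 1e9


def compute_tpm(C: Sequence[float], K: Sequence[float]) -> np.ndarray:
    """TPM: T_i = (C_i/K_i) / (sum_j C_j/K_j) * 1e6; sums to 1e6 by construction."""
    C = np.asarray(C, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("compute_tpm requires K_i > 0 for every gene passed")
    rates = C / K
    denom = rates.sum()
    if denom == 0:
        warnings.warn("no assigned reads; TPM undefined", stacklevel=2)
        return np.full(C.shape, np.nan)
    return rates / denom * 1e6


def quantify(
    reads: Iterable[SequencedRead], index: KmerIndex, params: QuantParams
) -> QuantResult:
    """Stream reads through scan/assign and finalize per-gene FPKM/TPM.

    Deterministic for fixed inputs.  An empty read stream returns all-zero
    totals with NA expression values.
    """
    k = index.k
    counts: dict[str, int] = {g: 0 for g in index.gene_ids}
    n_processed = n_assigned = n_ambiguous = n_unassigned = n_too_short = 0
    for read in reads:
        n_processed += 1
        if len(read.sequence) < k:
            n_too_short += 1
            continue
        hits = scan_read(read, index, params.step_size)
        assignment = assign_read(hits, params.accept_count)
        if assignment.outcome is AssignmentOutcome.ASSIGNED:
            n_assigned += 1
            counts[assignment.gene_id] += 1  # type: ignore[index]
        elif assignment.outcome is AssignmentOutcome.AMBIGUOUS:
            n_ambiguous += 1
        else:
            n_unassigned += 1

    covered = [g for g in index.gene_ids if index.gene_kmer_count.get(g, 0) > 0]
    fpkm = {g: math.nan for g in index.gene_ids}
    tpm = {g: math.nan for g in index.gene_ids}
    if covered and n_assigned > 0:
        C = [counts[g] for g in covered]
        K = [index.gene_kmer_count[g] for g in covered]
        for g, f, t in zip(covered, compute_fpkm(C, K), compute_tpm(C, K)):
            fpkm[g] = float(f)
            tpm[g] = float(t)
    return QuantResult(
        gene_ids=list(index.gene_ids),
        counts=counts,
        kmer_counts={g: index.gene_kmer_count.get(g, 0) for g in index.gene_ids},
        fpkm=fpkm,
        tpm=tpm,
        reads_processed=n_processed,
        reads_assigned=n_assigned,
        reads_ambiguous=n_ambiguous,
        reads_unassigned=n_unassigned,
        reads_too_short=n_too_short,
    )
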