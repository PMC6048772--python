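"""Core data types shared across the package.

The central objects are :class:`KmerIndex` (the gene-unique k-mer index) and
:class:`QuantResult` (per-gene counts and FPKM/TPM values).  Everything here is
a plain dataclass; file I/O lives in :mod:`ukq.io_formats`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "FormatError",
    "ConfigError",
    "Mate",
    "TranscriptRecord",
    "SequencedRead",
    "GeneMap",
    "KmerIndex",
    "BuildParams",
    "QuantParams",
    "AssignmentOutcome",
    "ReadAssignment",
    "QuantResult",
    "CoverageStats",
    "revcomp",
]


class FormatError(ValueError):
    """A file violates its expected on-disk format."""


class ConfigError(ValueError):
    """A simulation or run configuration is infeasible or out of range."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercase nucleotide string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


class Mate(str, enum.Enum):
    SINGLE = "single"
    MATE1 = "mate1"
    MATE2 = "mate2"


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript with its transcript and gene identifiers."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.transcript_id!r} has empty sequence")


@dataclass(frozen=True)
class SequencedRead:
    """A sequencing read; FASTQ quality strings are never interpreted."""

    read_id: str
    sequence: str
    mate: Mate = Mate.SINGLE


@dataclass
class GeneMap:
    """Transcript-to-gene association; every transcript maps to exactly one gene."""

    entries: dict[str, str]

    def gene_of(self, transcript_id: str) -> str:
        return self.entries[transcript_id]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(set(self.entries.values()))


@dataclass(frozen=True)
class BuildParams:
    """Index-building parameters: k-mer length and library strandedness."""

    k: int
    strand_specific: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


@dataclass
class KmerIndex:
    """Mapping from canonical k-mer to the single gene it identifies.

    ``gene_kmer_count`` holds K_i, the number of distinct indexed k-mers per
    gene, for every gene in ``gene_ids`` (including genes with K_i = 0, which
    remain listed so their absence of information is reportable downstream).
    """

    k: int
    strand_specific: bool
    kmer_to_gene: dict[str, str]
    gene_kmer_count: dict[str, int]
    gene_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Check internal consistency; raises ValueError on violation."""
        counts: dict[str, int] = {g: 0 for g in self.gene_ids}
        for kmer, gene in self.kmer_to_gene.items():
            if len(kmer) != self.k:
                raise ValueError(f"k-mer {kmer!r} has length != k={self.k}")
            if gene not in counts:
                raise ValueError(f"k-mer assigned to unlisted gene {gene!r}")
            counts[gene] += 1
            if not self.strand_specific and revcomp(kmer) < kmer:
                raise ValueError(f"stored k-mer {kmer!r} is not canonical")
        if counts != self.gene_kmer_count:
            raise ValueError("gene_kmer_count inconsistent with kmer_to_gene")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerIndex):
            return NotImplemented
        return (
            self.k == other.k
            and self.strand_specific == other.strand_specific
            and self.kmer_to_gene == other.kmer_to_gene
            and self.gene_kmer_count == other.gene_kmer_count
            and self.gene_ids == other.gene_ids
        )


@dataclass(frozen=True)
class QuantParams:
    """Read-scanning parameters: step size S and accept count M."""

    step_size: int = 12
    accept_count: int = 2

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise ValueError(f"step_size must be >= 1, got {self.step_size}")
        if self.accept_count < 1:
            raise ValueError(f"accept_count must be >= 1, got {self.accept_count}")


class AssignmentOutcome(enum.Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"
    TOO_SHORT = "too_short"


@dataclass(frozen=True)
class ReadAssignment:
    outcome: AssignmentOutcome
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if (self.outcome is AssignmentOutcome.ASSIGNED) != (self.gene_id is not None):
            raise ValueError("gene_id must be set iff outcome is ASSIGNED")


@dataclass
class QuantResult:
    """Per-gene quantification output plus read-level totals.

    ``fpkm``/``tpm`` hold NaN for genes with K_i = 0 (no information, written
    as "NA" in the output table — distinguishable from zero expression).
    """

    gene_ids: list[str]
    counts: dict[str, int]
    kmer_counts: dict[str, int]
    fpkm: dict[str, float]
    tpm: dict[str, float]
    reads_processed: int = 0
    reads_assigned: int = 0
    reads_ambiguous: int = 0
    reads_unassigned: int = 0
    reads_too_short: int = 0

    @property
    def mapping_rate(self) -> float:
        if self.reads_processed == 0:
            return math.nan
        return self.reads_assigned / self.reads_processed

    def summary(self) -> dict:
        return {
            "reads_processed": self.reads_processed,
            "reads_assigned": self.reads_assigned,
            "reads_ambiguous": self.reads_ambiguous,
            "reads_unassigned": self.reads_unassigned,
            "reads_too_short": self.reads_too_short,
            "mapping_rate": self.mapping_rate,
        }


@dataclass
class CoverageStats:
    """Index-coverage diagnostics for one transcript.

    ``islands`` are maximal runs of consecutive indexed k-mer start positions,
    reported as (start, nucleotide length); intervals are 0-based, half-open.
    """

    transcript_id: str
    transcript_length: int
    indexed_positions: list[int]
    nucleotide_coverage: float
    islands: list[tuple[int, int]]
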