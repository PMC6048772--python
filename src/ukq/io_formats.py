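"""Readers and writers for FASTA, FASTQ, gene maps, quantification tables and
the portable ``.ukx`` binary index format.

All text readers transparently decompress gzip, detected by the 0x1f8b magic
bytes rather than the file extension.  FASTQ quality lines are carried through
but never interpreted.

The ``.ukx`` layout (little-endian throughout):

* bytes 0-3: magic ``UKQ1``
* u32 format_version, u32 k, u8 strand_specific, u32 n_genes, u32 n_kmers
* gene table: n_genes x [u16 name length, UTF-8 name, u64 K_i],
  in lexicographic gene_id order (the gene ordinal used below)
* k-mer records sorted ascending by packed value:
  n_kmers x [ceil(2k/8)-byte 2-bit-packed canonical k-mer, u32 gene ordinal]
"""

from __future__ import annotations

import gzip
import io
import struct
from collections.abc import Iterable, Iterator
from pathlib import Path
from typing import IO

from .model import (
    FormatError,
    GeneMap,
    KmerIndex,
    Mate,
    QuantResult,
    SequencedRead,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gene_map",
    "write_gene_map",
    "pack_kmer",
    "unpack_kmer",
    "serialize_index",
    "deserialize_index",
    "write_quant_table",
]

MAGIC = b"UKQ1"
FORMAT_VERSION = 1

_GZIP_MAGIC = b"\x1f\x8b"


def open_text_auto(path: str | Path) -> IO[str]:
    """Open a text file, decompressing gzip if the magic bytes say so."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (transcript_id, sequence) from a FASTA file in file order.

    The identifier is the header token before the first whitespace; sequences
    are uppercased.  A sequence line before any header is a FormatError naming
    the offending line number.
    """
    with open_text_auto(path) as fh:
        name: str | None = None
        chunks: list[str] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks).upper()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"sequence line before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
        if name is not None:
            yield name, "".join(chunks).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, *, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from one 4-line-record FASTQ file."""
    with open_text_auto(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: FASTQ record header must start with '@'")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not plus or not qual:
                raise FormatError(f"{path}: truncated FASTQ record {header!r}")
            # '+' line content and quality length deliberately not validated
            read_id = header[1:].split()[0] if header[1:].split() else ""
            yield read_id, seq.upper()


def read_fastq(*paths: str | Path) -> Iterator[SequencedRead]:
    """Stream reads from one (single-end) or two (paired-end) FASTQ files.

    Paired files are interleaved mate1/mate2; each mate is emitted as an
    independent read because downstream assignment treats mates separately.
    """
    if len(paths) == 1:
        for read_id, seq in _fastq_records(paths[0]):
            yield SequencedRead(read_id, seq, Mate.SINGLE)
    elif len(paths) == 2:
        it1 = _fastq_records(paths[0])
        it2 = _fastq_records(paths[1])
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FormatError("paired FASTQ files have unequal record counts")
            yield SequencedRead(r1[0], r1[1], Mate.MATE1)
            yield SequencedRead(r2[0], r2[1], Mate.MATE2)
    else:
        raise ValueError("read_fastq takes one or two paths")


def write_fastq(reads: Iterable[SequencedRead], path: str | Path, *, compress: bool = False) -> None:
    """Write reads as 4-line FASTQ with a constant dummy quality line."""
    opener = gzip.open if compress else open
    with opener(path, "wt", encoding="utf-8") as fh:  # type: ignore[operator]
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


# ---------------------------------------------------------------------------
# Gene map


def read_gene_map(path: str | Path) -> GeneMap:
    """Parse a 2-column transcript_id<TAB>gene_id TSV; '#' lines are comments."""
    entries: dict[str, str] = {}
    with open_text_auto(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"gene map line {lineno}: expected >= 2 columns")
            tid, gid = fields[0], fields[1]
            if tid in entries and entries[tid] != gid:
                raise FormatError(
                    f"gene map line {lineno}: transcript {tid!r} maps to both "
                    f"{entries[tid]!r} and {gid!r}"
                )
            entries[tid] = gid
    return GeneMap(entries)


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(gene_map.entries):
            fh.write(f"{tid}\t{gene_map.entries[tid]}\n")


# ---------------------------------------------------------------------------
# 2-bit k-mer packing

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


def pack_kmer(kmer: str) -> int:
    """Encode an ACGT string as a 2-bit-per-base integer, most significant first."""
    value = 0
    for base in kmer:
        try:
            value = (value << 2) | _BASE_CODE[base]
        except KeyError:
            raise ValueError(f"cannot pack ambiguous base {base!r}") from None
    return value


def unpack_kmer(value: int, k: int) -> str:
    """Inverse of :func:`pack_kmer` for a fixed k."""
    bases = []
    for _ in range(k):
        bases.append(_CODE_BASE[value & 3])
        value >>= 2
    return "".join(reversed(bases))


# ---------------------------------------------------------------------------
# Index serialization

_HEADER = struct.Struct("<IIBII")  # version, k, strand_specific, n_genes, n_kmers


def serialize_index(index: KmerIndex, path: str | Path) -> None:
    """Write a KmerIndex in the portable ``.ukx`` layout."""
    gene_ids = list(index.gene_ids)
    ordinal = {g: i for i, g in enumerate(gene_ids)}
    nbytes = -(-2 * index.k // 8)  # ceil(2k/8)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(
            _HEADER.pack(
                FORMAT_VERSION,
                index.k,
                int(index.strand_specific),
                len(gene_ids),
                len(index.kmer_to_gene),
            )
        )
        for gid in gene_ids:
            name = gid.encode("utf-8")
            fh.write(struct.pack("<H", len(name)))
            fh.write(name)
            fh.write(struct.pack("<Q", index.gene_kmer_count.get(gid, 0)))
        records = sorted(
            (pack_kmer(kmer), ordinal[gene]) for kmer, gene in index.kmer_to_gene.items()
        )
        for packed, gene_ord in records:
            fh.write(packed.to_bytes(nbytes, "little"))
            fh.write(struct.pack("<I", gene_ord))


def _read_exact(fh: IO[bytes], n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FormatError(f"truncated index file while reading {what}")
    return data


def deserialize_index(path: str | Path) -> KmerIndex:
    """Read a ``.ukx`` index; rejects bad magic, version, or truncation."""
    with open(path, "rb") as fh:
        if _read_exact(fh, 4, "magic") != MAGIC:
            raise FormatError(f"{path}: not a ukx index file (bad magic)")
        version, k, strand_byte, n_genes, n_kmers = _HEADER.unpack(
            _read_exact(fh, _HEADER.size, "header")
        )
        if version != FORMAT_VERSION:
            raise FormatError(f"{path}: unsupported index format version {version}")
        gene_ids: list[str] = []
        gene_kmer_count: dict[str, int] = {}
        for _ in range(n_genes):
            (name_len,) = struct.unpack("<H", _read_exact(fh, 2, "gene name length"))
            name = _read_exact(fh, name_len, "gene name").decode("utf-8")
            (count,) = struct.unpack("<Q", _read_exact(fh, 8, "gene k-mer count"))
            gene_ids.append(name)
            gene_kmer_count[name] = count
        nbytes = -(-2 * k // 8)
        kmer_to_gene: dict[str, str] = {}
        for _ in range(n_kmers):
            packed = int.from_bytes(_read_exact(fh, nbytes, "k-mer"), "little")
            (gene_ord,) = struct.unpack("<I", _read_exact(fh, 4, "gene ordinal"))
            if gene_ord >= n_genes:
                raise FormatError(f"{path}: gene ordinal {gene_ord} out of range")
            kmer_to_gene[unpack_kmer(packed, k)] = gene_ids[gene_ord]
        if fh.read(1):
            raise FormatError(f"{path}: trailing bytes after k-mer records")
    return KmerIndex(
        k=k,
        strand_specific=bool(strand_byte),
        kmer_to_gene=kmer_to_gene,
        gene_kmer_count=gene_kmer_count,
        gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------------
# Quantification table


def write_quant_table(result: QuantResult, path: str | Path) -> None:
    """Write the per-gene TSV; genes with K_i = 0 get "NA" expression values."""

    def fmt(x: float) -> str:
        return "NA" if x != x else f"{x:.6g}"  # NaN != NaN

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tkmer_count\tread_count\tfpkm\ttpm\n")
        for gid in sorted(result.gene_ids):
            fh.write(
                f"{gid}\t{result.kmer_counts.get(gid, 0)}\t{result.counts.get(gid, 0)}\t"
                f"{fmt(result.fpkm.get(gid, float('nan')))}\t"
                f"{fmt(result.tpm.get(gid, float('nan')))}\n"
            )
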