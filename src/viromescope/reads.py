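"""Read QC, de-duplication, host decontamination and alignment.

The processing order mirrors a standard shotgun virome workflow:
quality-trim, de-duplicate exact copies, remove reads matching the host
genome at >=95% identity, then align the survivors to the viral reference
database. The read count left after the first three stages is the sample's
"decontaminated read number", the denominator of the downstream
median-coverage normalization.

The built-in mapper is deliberately minimal: exact k-mer seeding (both
strands) followed by ungapped full-read extension, which is exact for
substitution-only synthetic reads. Real alignments should enter through
:func:`read_sam` instead, where percent identity is derived from the NM
tag over aligned (non-clipped) bases.

Coordinates are 0-based half-open internally; SAM's 1-based coordinates
are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "AlignmentHit",
    "read_fastq",
    "quality_trim",
    "deduplicate",
    "KmerIndex",
    "map_reads",
    "remove_host",
    "read_sam",
    "process_sample",
]

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


@dataclass(frozen=True)
class Read:
    """A single read; ``qualities`` is the Phred+33 string, same length as the sequence."""

    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    def phred(self) -> np.ndarray:
        return np.frombuffer(self.qualities.encode("ascii"), dtype=np.uint8) - 33


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped alignment of a read against a reference genome."""

    read_id: str
    genome_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+" or "-"
    matches: int
    aligned_length: int
    is_best: bool = False

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.aligned_length

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if not 0 <= self.matches <= self.aligned_length:
            raise ValueError("matches must be within [0, aligned_length]")


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a Phred+33 FASTQ file into a list of :class:`Read`.

    Malformed records raise a ``ValueError`` naming the record index.
    """
    from Bio import SeqIO

    out = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(Read(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {len(out)} in {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# QC


def quality_trim(
    reads: Sequence[Read], phred_min: int = 10, min_length: int = 30
) -> tuple[list[Read], int]:
    """Trim low-quality bases from both ends; drop reads shorter than ``min_length``.

    Bases are removed from each end while their quality is below
    ``phred_min``. Returns ``(retained_reads, dropped_count)``.
    """
    if phred_min < 0:
        raise ValueError("phred_min must be >= 0")
    kept: list[Read] = []
    dropped = 0
    for r in reads:
        q = r.phred()
        lo, hi = 0, len(q)
        while lo < hi and q[lo] < phred_min:
            lo += 1
        while hi > lo and q[hi - 1] < phred_min:
            hi -= 1
        if hi - lo < min_length:
            dropped += 1
            continue
        if lo == 0 and hi == len(q):
            kept.append(r)
        else:
            kept.append(Read(r.read_id, r.sequence[lo:hi], r.qualities[lo:hi]))
    return kept, dropped


def deduplicate(reads: Sequence[Read]) -> tuple[list[Read], int]:
    """Remove exact sequence duplicates, keeping the first occurrence."""
    seen: set[str] = set()
    kept: list[Read] = []
    for r in reads:
        if r.sequence in seen:
            continue
        seen.add(r.sequence)
        kept.append(r)
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# Minimal exact-seed / ungapped-extension mapper


class KmerIndex:
    """Exact k-mer index over a set of reference sequences.

    Every k-mer of every genome is indexed; reads query a strided subset of
    their k-mers on both strands, so a single error-free seed suffices to
    recover the true ungapped alignment.
    """

    def __init__(self, genomes: Mapping[str, str], k: int = 21):
        if not genomes:
            raise ValueError("empty genome set")
        if k < 4:
            raise ValueError("seed_k must be >= 4")
        self.k = k
        self.genome_ids = sorted(genomes)
        self.seqs = {g: genomes[g] for g in self.genome_ids}
        self.arrays = {
            g: np.frombuffer(s.encode("ascii"), dtype=np.uint8) for g, s in self.seqs.items()
        }
        index: dict[str, list[tuple[str, int]]] = {}
        for g in self.genome_ids:
            s = self.seqs[g]
            for p in range(len(s) - k + 1):
                index.setdefault(s[p : p + k], []).append((g, p))
        self._index = index

    def candidates(self, seq: str, stride: int | None = None) -> set[tuple[str, int, str]]:
        """Candidate placements ``(genome_id, diag_start, strand)`` for a read."""
        k = self.k
        stride = stride or k
        out: set[tuple[str, int, str]] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            n = len(s) - k
            if n < 0:
                continue
            offsets = list(range(0, n + 1, stride))
            if offsets[-1] != n:
                offsets.append(n)
            for o in offsets:
                for g, p in self._index.get(s[o : o + k], ()):
                    out.add((g, p - o, strand))
        return out


def _score_placement(
    read_arr: np.ndarray, genome_arr: np.ndarray, diag_start: int
) -> tuple[int, int, int] | None:
    """Ungapped comparison of the read against the genome at ``diag_start``.

    Returns ``(start, matches, aligned_length)`` over the overlapping bases,
    or None if the overlap is empty.
    """
    L = len(read_arr)
    g0 = max(0, diag_start)
    g1 = min(len(genome_arr), diag_start + L)
    if g1 <= g0:
        return None
    r0 = g0 - diag_start
    matches = int(np.count_nonzero(read_arr[r0 : r0 + (g1 - g0)] == genome_arr[g0:g1]))
    return g0, matches, g1 - g0


def map_reads(
    reads: Sequence[Read],
    genomes: Mapping[str, str] | "KmerIndex",
    seed_k: int = 21,
    min_identity_pct: float = 95.0,
    seed_stride: int | None = None,
) -> list[AlignmentHit]:
    """Align reads to reference genomes with exact seeding and ungapped extension.

    All genomes sharing an exact k-mer with the read (either strand) are
    extension-scored over the full read; hits at ``min_identity_pct`` or
    better are reported. Each read's best hit (highest identity, ties broken
    by lowest ``(genome_id, start)``) carries ``is_best=True``.
    """
    if not 0.0 <= min_identity_pct <= 100.0:
        raise ValueError("min_identity_pct must be in [0, 100]")
    index = genomes if isinstance(genomes, KmerIndex) else KmerIndex(genomes, k=seed_k)
    hits: list[AlignmentHit] = []
    for r in reads:
        seq = r.sequence
        read_hits: list[AlignmentHit] = []
        fwd = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        rev = np.frombuffer(revcomp(seq).encode("ascii"), dtype=np.uint8)
        for g, diag, strand in index.candidates(seq, stride=seed_stride):
            arr = fwd if strand == "+" else rev
            scored = _score_placement(arr, index.arrays[g], diag)
            if scored is None:
                continue
            start, matches, alen = scored
            if 100.0 * matches / alen >= min_identity_pct:
                read_hits.append(
                    AlignmentHit(r.read_id, g, start, start + alen, strand, matches, alen)
                )
        if not read_hits:
            continue
        read_hits.sort(key=lambda h: (-h.percent_identity, h.genome_id, h.start))
        best = read_hits[0]
        hits.append(
            AlignmentHit(
                best.read_id, best.genome_id, best.start, best.end, best.strand,
                best.matches, best.aligned_length, is_best=True,
            )
        )
        hits.extend(read_hits[1:])
    return hits


def remove_host(
    reads: Sequence[Read],
    host_genome: str | KmerIndex,
    min_identity_pct: float = 95.0,
    seed_k: int = 21,
) -> tuple[list[Read], int]:
    """Drop reads aligning to the host genome at ``min_identity_pct`` or better.

    Returns ``(decontaminated_reads, removed_count)``; the retained count is
    the sample's decontaminated read number.
    """
    index = host_genome if isinstance(host_genome, KmerIndex) else KmerIndex({"host": host_genome}, k=seed_k)
    hits = map_reads(reads, index, min_identity_pct=min_identity_pct)
    contaminated = {h.read_id for h in hits}
    kept = [r for r in reads if r.read_id not in contaminated]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# SAM input


def read_sam(
    path: str | Path,
    reference_lengths: Mapping[str, int] | None = None,
    keep_secondary: bool = False,
) -> list[AlignmentHit]:
    """Load alignments from a SAM file as :class:`AlignmentHit` records.

    Percent identity is ``100 * (aligned_length - NM) / aligned_length``
    where ``aligned_length`` counts M/=/X/I/D columns (non-clipped). When NM
    is missing, it is reconstructed from =/X CIGAR operators; records with
    neither raise a ``ValueError`` naming the QNAME. Unmapped reads are
    skipped; secondary/supplementary records are skipped unless
    ``keep_secondary``.
    """
    import pysam

    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if (rec.is_secondary or rec.is_supplementary) and not keep_secondary:
                continue
            cig = rec.cigartuples or []
            # ops: 0=M 1=I 2=D 7== 8=X
            aligned_length = sum(n for op, n in cig if op in (0, 1, 2, 7, 8))
            if aligned_length == 0:
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif any(op in (7, 8) for op, _ in cig):
                nm = sum(n for op, n in cig if op in (8, 1, 2))
            else:
                raise ValueError(f"record {rec.query_name}: no NM tag and no =/X CIGAR operators")
            matches = aligned_length - nm
            start = rec.reference_start  # pysam is already 0-based
            end = rec.reference_end if rec.reference_end is not None else start + aligned_length
            if reference_lengths is not None:
                ref_len = reference_lengths.get(rec.reference_name)
                if ref_len is not None and end > ref_len:
                    raise ValueError(
                        f"record {rec.query_name}: alignment end {end} beyond reference length {ref_len}"
                    )
            hits.append(
                AlignmentHit(
                    rec.query_name,
                    rec.reference_name,
                    start,
                    end,
                    "-" if rec.is_reverse else "+",
                    max(0, matches),
                    aligned_length,
                    is_best=not (rec.is_secondary or rec.is_supplementary),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Per-sample orchestration


def process_sample(
    reads: Sequence[Read],
    host_genome: str | KmerIndex,
    viral_index: KmerIndex,
    phred_min: int = 10,
    min_length: int = 30,
    min_identity_pct: float = 95.0,
) -> tuple[list[AlignmentHit], dict[str, int]]:
    """Run trim -> dedup -> host removal -> viral mapping for one sample.

    Returns the viral alignment hits plus a read-accounting dict whose
    ``decontaminated`` entry is the denominator for abundance normalization.
    """
    trimmed, n_dropped = quality_trim(reads, phred_min=phred_min, min_length=min_length)
    deduped, n_dup = deduplicate(trimmed)
    decon, n_host = remove_host(deduped, host_genome, min_identity_pct=min_identity_pct)
    hits = map_reads(decon, viral_index, min_identity_pct=min_identity_pct)
    accounting = {
        "raw": len(reads),
        "trim_dropped": n_dropped,
        "duplicates_removed": n_dup,
        "host_removed": n_host,
        "decontaminated": len(decon),
        "viral_mapped": len({h.read_id for h in hits}),
    }
    logger.info("sample processed: %s", accounting)
    return hits, accounting
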