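"""Coverage-based viral presence calling and median-coverage abundances.

A viral population counts as present in a sample when qualifying reads
(>= 95% identity by default) cover a consecutive stretch of its genome of
at least 200 bp. For present populations, abundance is the median read
depth over ALL genome positions (zeros included) scaled per million
decontaminated reads; absent populations get abundance 0. Abundances can
then be row-normalized to relative values and summed by host taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reads import AlignmentHit

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "PresenceCall",
    "coverage_track",
    "longest_covered_run",
    "call_presence",
    "median_coverage_abundance",
    "quantify_sample",
    "build_abundance_matrix",
    "aggregate_by_host",
]


@dataclass
class CoverageTrack:
    """Per-position read depth for one genome in one sample."""

    genome_id: str
    sample_id: str
    depth: np.ndarray  # int depth, length == genome length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class PresenceCall:
    genome_id: str
    sample_id: str
    present: bool
    longest_run_bp: int
    n_qualifying_reads: int


def coverage_track(
    hits: Iterable[AlignmentHit],
    genome_length: int,
    min_identity_pct: float = 95.0,
    genome_id: str = "",
    sample_id: str = "",
    best_only: bool = True,
) -> CoverageTrack:
    """Accumulate read depth from qualifying hits on one genome.

    ``depth[p]`` counts qualifying hits whose half-open interval contains
    ``p``. With ``best_only`` (the default) only each read's best hit
    contributes, so multi-mapping reads are not double counted.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    n_reads = 0
    for h in hits:
        if best_only and not h.is_best:
            continue
        if h.percent_identity < min_identity_pct:
            continue
        if h.end > genome_length:
            raise ValueError(f"hit {h.read_id} ends at {h.end} beyond genome length {genome_length}")
        diff[h.start] += 1
        diff[h.end] -= 1
        n_reads += 1
    track = CoverageTrack(genome_id, sample_id, np.cumsum(diff[:-1]))
    track.n_qualifying_reads = n_reads  # type: ignore[attr-defined]
    return track


def longest_covered_run(depth: np.ndarray) -> int:
    """Length of the longest maximal run of positions with depth >= 1."""
    covered = np.asarray(depth) > 0
    if not covered.any():
        return 0
    # run-length encode via boundaries of the boolean signal
    padded = np.concatenate(([False], covered, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def call_presence(track: CoverageTrack, min_run_bp: int = 200) -> PresenceCall:
    """Apply the consecutive-coverage presence rule (inclusive boundary)."""
    run = longest_covered_run(track.depth)
    return PresenceCall(
        genome_id=track.genome_id,
        sample_id=track.sample_id,
        present=run >= min_run_bp,
        longest_run_bp=run,
        n_qualifying_reads=getattr(track, "n_qualifying_reads", int((track.depth > 0).sum())),
    )


def median_coverage_abundance(
    track: CoverageTrack,
    decontaminated_read_count: int,
    min_run_bp: int = 200,
    covered_only: bool = False,
) -> float:
    """Median depth per million decontaminated reads; 0 when absent.

    The median is taken over all genome positions including zeros (an
    even-length median is the mean of the two central order statistics);
    ``covered_only=True`` restricts it to positions with depth >= 1. The
    presence gate is applied first: a genome failing the consecutive-run
    rule gets abundance 0.
    """
    if decontaminated_read_count <= 0:
        raise ValueError("decontaminated_read_count must be positive")
    if not call_presence(track, min_run_bp=min_run_bp).present:
        return 0.0
    depth = track.depth
    if covered_only:
        depth = depth[depth > 0]
        if depth.size == 0:
            return 0.0
    med = float(np.median(depth))
    return med / (decontaminated_read_count / 1e6)


def quantify_sample(
    hits: Sequence[AlignmentHit],
    genome_lengths: Mapping[str, int],
    decontaminated_read_count: int,
    sample_id: str = "",
    min_identity_pct: float = 95.0,
    min_run_bp: int = 200,
    covered_only: bool = False,
) -> tuple[pd.Series, list[PresenceCall]]:
    """Presence calls and median-coverage abundances for every genome of one sample."""
    by_genome: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_genome.setdefault(h.genome_id, []).append(h)
    abund: dict[str, float] = {}
    calls: list[PresenceCall] = []
    for gid, length in genome_lengths.items():
        track = coverage_track(
            by_genome.get(gid, ()), length, min_identity_pct=min_identity_pct,
            genome_id=gid, sample_id=sample_id,
        )
        calls.append(call_presence(track, min_run_bp=min_run_bp))
        abund[gid] = median_coverage_abundance(
            track, decontaminated_read_count, min_run_bp=min_run_bp, covered_only=covered_only
        )
    return pd.Series(abund, name=sample_id), calls


def build_abundance_matrix(
    per_sample: Mapping[str, Mapping[str, float] | pd.Series],
    normalize: str = "relative",
) -> pd.DataFrame:
    """Assemble per-sample quantifications into a samples x features matrix.

    The feature universe is the union across samples (absent -> 0); features
    absent in every sample are dropped. ``normalize="relative"`` divides each
    row by its sum (all-zero rows are preserved and logged);
    ``normalize="none"`` keeps the median-coverage scale.
    """
    if normalize not in ("relative", "none"):
        raise ValueError("normalize must be 'relative' or 'none'")
    df = pd.DataFrame({s: pd.Series(v) for s, v in per_sample.items()}).T.fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise ValueError("abundance values must be non-negative")
    df = df.loc[:, df.sum(axis=0) > 0]
    if normalize == "relative":
        sums = df.sum(axis=1)
        zero_rows = sums[sums == 0].index.tolist()
        if zero_rows:
            logger.warning("all-zero abundance rows preserved: %s", zero_rows)
        df = df.div(sums.replace(0, 1.0), axis=0)
    return df


def aggregate_by_host(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, str],
    rank: str = "genus",
) -> pd.DataFrame:
    """Sum feature columns by host taxon; row totals are conserved exactly.

    ``taxonomy`` maps feature id -> taxon label at the requested rank
    (eukaryotic viruses appear under their own class label). Features
    missing from the map raise a ``KeyError`` listing them.
    """
    missing = [f for f in matrix.columns if f not in taxonomy or not taxonomy[f]]
    if missing:
        raise KeyError(f"features without {rank} taxonomy: {missing[:10]}")
    groups = pd.Series({f: taxonomy[f] for f in matrix.columns}, name=rank)
    return matrix.T.groupby(groups).sum().T
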