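"""Synthetic viral communities, shotgun reads and companion omics matrices.

Everything downstream of this module (read processing, quantification,
ecology) is exercised on data produced here: a set of reference viral
genomes annotated with bacterial host taxonomy, per-sample ground-truth
community compositions for two unbalanced subject groups (a "smoker"-like
and a "nonsmoker"-like group), shotgun reads with host-genome contamination
and PCR/optical-style duplicates, and metabolite / cytokine / bacterial
matrices with configurable planted group effects.

The defaults emulate the structure of a 30-subject bronchoalveolar-lavage
virome study: 20 vs 10 samples, a few hundred candidate viral populations
with sparse per-sample detection, phage hosts dominated by Proteobacteria,
Firmicutes and Actinobacteria, lower viral richness/evenness in the smoker
group, 10-fold planted phage enrichments, strong metabolite group shifts,
and NO planted group effect in the bacterial matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord",
    "ReferenceGenomeSet",
    "CommunityDesign",
    "SimulationConfig",
    "PlantedEffect",
    "CommunityEffectSpec",
    "OmicsEffectSpec",
    "DEFAULT_HOST_TAXONOMY",
    "generate_reference_db",
    "generate_host_genome",
    "design_communities",
    "simulate_reads",
    "simulate_omics",
    "write_fasta",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Host-phylum proportions and the genera drawn within each phylum.
#: Proportions follow the host composition typical of lower-airway phage
#: databases (Proteobacteria-dominated, then Firmicutes and Actinobacteria).
DEFAULT_HOST_TAXONOMY: dict[str, tuple[float, tuple[str, ...]]] = {
    "Proteobacteria": (0.37, ("Neisseria", "Escherichia", "Acinetobacter", "Burkholderia")),
    "Firmicutes": (0.36, ("Streptococcus", "Lactobacillus", "Bacillus", "Veillonella")),
    "Actinobacteria": (0.23, ("Propionibacterium", "Gardnerella", "Actinomyces")),
    "Bacteriodetes": (0.03, ("Prevotella",)),
    "Fusobacteria": (0.01, ("Leptotrichia",)),
}

EUKARYOTIC_CLASS = "Eukaryotic viruses"


@dataclass(frozen=True)
class GenomeRecord:
    """One reference viral genome with its host annotation."""

    genome_id: str
    sequence: str
    host_phylum: str
    host_genus: str
    virus_type: str  # "phage" or "eukaryotic"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1000:
            raise ValueError(f"{self.genome_id}: sequence shorter than 1000 bp")
        if self.virus_type not in ("phage", "eukaryotic"):
            raise ValueError(f"{self.genome_id}: unknown virus_type {self.virus_type!r}")
        if self.virus_type == "phage" and (not self.host_genus or not self.host_phylum):
            raise ValueError(f"{self.genome_id}: phage record lacks host taxonomy")


class ReferenceGenomeSet:
    """Ordered collection of :class:`GenomeRecord` with unique ids."""

    def __init__(self, records: Sequence[GenomeRecord]):
        ids = [r.genome_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("genome_ids are not unique")
        self.records = list(records)
        self._by_id = {r.genome_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._by_id[genome_id]

    @property
    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.records]

    def sequences(self) -> dict[str, str]:
        return {r.genome_id: r.sequence for r in self.records}

    def lengths(self) -> dict[str, int]:
        return {r.genome_id: len(r.sequence) for r in self.records}

    def taxonomy(self, rank: str = "genus") -> dict[str, str]:
        """Map genome_id -> host taxon at ``rank`` ("genus" or "phylum").

        Eukaryotic viruses are grouped under a single class of their own.
        """
        if rank not in ("genus", "phylum"):
            raise ValueError(f"unknown rank {rank!r}")
        out = {}
        for r in self.records:
            if r.virus_type == "eukaryotic":
                out[r.genome_id] = EUKARYOTIC_CLASS
            else:
                out[r.genome_id] = r.host_genus if rank == "genus" else r.host_phylum
        return out

    def taxonomy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genome_id": [r.genome_id for r in self.records],
                "length": [len(r.sequence) for r in self.records],
                "virus_type": [r.virus_type for r in self.records],
                "host_phylum": [r.host_phylum for r in self.records],
                "host_genus": [r.host_genus for r in self.records],
            }
        ).set_index("genome_id")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_reference_db(
    n_genomes: int,
    length_range: tuple[int, int] = (1000, 3000),
    taxonomy_spec: Mapping[str, tuple[float, tuple[str, ...]]] | None = None,
    eukaryotic_fraction: float = 0.02,
    rng_seed: int = 0,
) -> ReferenceGenomeSet:
    """Draw a reference database of i.i.d. uniform-base viral genomes.

    Host phyla are assigned by the proportions in ``taxonomy_spec`` (default
    :data:`DEFAULT_HOST_TAXONOMY`), a genus uniformly within the phylum.
    A small ``eukaryotic_fraction`` of genomes is marked as eukaryotic
    viruses with no bacterial host.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    lo, hi = length_range
    if lo < 1000 or hi < lo:
        raise ValueError("length_range must satisfy 1000 <= min <= max")
    if not 0 <= eukaryotic_fraction < 1:
        raise ValueError("eukaryotic_fraction must be in [0, 1)")
    spec = dict(taxonomy_spec if taxonomy_spec is not None else DEFAULT_HOST_TAXONOMY)
    props = np.array([v[0] for v in spec.values()], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("taxonomy_spec proportions must be non-negative and sum to 1")

    rng = np.random.default_rng(rng_seed)
    phyla = list(spec.keys())
    width = max(4, len(str(n_genomes)))
    records = []
    for i in range(n_genomes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        gid = f"vpop_{i + 1:0{width}d}"
        if rng.random() < eukaryotic_fraction:
            records.append(GenomeRecord(gid, seq, "", "", "eukaryotic"))
        else:
            phylum = phyla[rng.choice(len(phyla), p=props)]
            genus = spec[phylum][1][rng.integers(0, len(spec[phylum][1]))]
            records.append(GenomeRecord(gid, seq, phylum, genus, "phage"))
    return ReferenceGenomeSet(records)


def generate_host_genome(length: int = 100_000, rng_seed: int = 1) -> str:
    """One random host ("human" stand-in) chromosome used as contamination source."""
    if length < 1000:
        raise ValueError("host genome length must be >= 1000")
    return _random_sequence(np.random.default_rng(rng_seed), length)


# ---------------------------------------------------------------------------
# Community design


@dataclass(frozen=True)
class PlantedEffect:
    """A fold-change enrichment planted on a genome or a host genus."""

    target: str  # genome_id or host genus name
    fold_change: float
    enriched_group: str

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")


@dataclass
class CommunityEffectSpec:
    """Planted between-group differences in the viral community.

    ``richness_deflation`` scales the expected per-sample richness of
    ``low_diversity_group`` (1.0 = no effect). Defaults plant the study-like
    pattern: lower richness in the smoker group, 10-fold Lactobacillus and
    Gardnerella phage enrichment in nonsmokers, 2-fold Prevotella phage
    enrichment in smokers.
    """

    planted: list[PlantedEffect] = field(
        default_factory=lambda: [
            PlantedEffect("Lactobacillus", 10.0, "nonsmoker"),
            PlantedEffect("Gardnerella", 10.0, "nonsmoker"),
            PlantedEffect("Prevotella", 2.0, "smoker"),
        ]
    )
    richness_deflation: float = 0.6
    evenness_sigma_factor: float = 2.5
    low_diversity_group: str = "smoker"

    @classmethod
    def null(cls) -> "CommunityEffectSpec":
        """No planted differences; groups are exchangeable."""
        return cls(planted=[], richness_deflation=1.0, evenness_sigma_factor=1.0)


@dataclass
class CommunityDesign:
    """Ground-truth community composition for every sample."""

    sample_ids: list[str]
    groups: pd.Series  # sample_id -> group label
    true_abundance: pd.DataFrame  # samples x genomes, rows sum to 1
    planted: list[PlantedEffect]
    richness_per_group: dict[str, float]

    def __post_init__(self) -> None:
        vals = self.true_abundance.to_numpy()
        if (vals < 0).any():
            raise ValueError("true abundances must be non-negative")
        if not np.allclose(vals.sum(axis=1), 1.0):
            raise ValueError("each abundance row must sum to 1")

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def to_manifest(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "groups": self.groups.to_dict(),
            "planted": [
                {"target": p.target, "fold_change": p.fold_change, "enriched_group": p.enriched_group}
                for p in self.planted
            ],
            "richness_per_group": self.richness_per_group,
        }


def design_communities(
    reference: ReferenceGenomeSet,
    group_sizes: tuple[int, int] = (20, 10),
    group_labels: tuple[str, str] = ("smoker", "nonsmoker"),
    effect_spec: CommunityEffectSpec | None = None,
    base_richness: int = 40,
    rng_seed: int = 0,
) -> CommunityDesign:
    """Draw per-sample true relative abundances for two subject groups.

    Each sample's community is built by (1) drawing a Poisson richness
    around the group's target (``base_richness``, deflated by
    ``richness_deflation`` in the low-diversity group) and choosing that
    many taxa weighted by a shared heavy-tailed per-genome occupancy weight,
    so some populations recur across samples; (2) drawing log-normal
    abundances on the support — sigma 1 at baseline, inflated by
    ``evenness_sigma_factor`` in the low-diversity group so its communities
    are also less even; (3) multiplying planted taxa that landed in the
    support by their fold change in the enriched group; (4) renormalizing to
    proportions. Planted taxa enter the support with the same probability in
    both groups, so a planted taxon's expected group mean ratio equals its
    fold change.
    """
    n1, n2 = group_sizes
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    spec = effect_spec if effect_spec is not None else CommunityEffectSpec()
    if spec.low_diversity_group not in group_labels and spec.richness_deflation != 1.0:
        raise ValueError(f"low_diversity_group {spec.low_diversity_group!r} not in group_labels")

    genome_ids = reference.genome_ids
    taxonomy = reference.taxonomy("genus")
    planted_ids: set[str] = set()
    fold_by_genome: dict[str, tuple[float, str]] = {}
    for eff in spec.planted:
        if eff.enriched_group not in group_labels:
            raise ValueError(f"enriched_group {eff.enriched_group!r} not in group_labels")
        if eff.target in reference.genome_ids:
            targets = [eff.target]
        else:
            targets = [g for g in genome_ids if taxonomy[g] == eff.target]
            if not targets:
                raise ValueError(f"planted target {eff.target!r} matches no genome or genus")
        for g in targets:
            planted_ids.add(g)
            fold_by_genome[g] = (eff.fold_change, eff.enriched_group)

    rng = np.random.default_rng(rng_seed)
    n_genomes = len(genome_ids)
    # shared occupancy weights: heavy-tailed so a handful of taxa are common
    occupancy = rng.lognormal(0.0, 1.0, size=n_genomes)
    occupancy /= occupancy.sum()

    sample_ids, labels = [], []
    for label, n in zip(group_labels, group_sizes):
        for i in range(n):
            sample_ids.append(f"{label}_{i + 1:02d}")
            labels.append(label)
    groups = pd.Series(labels, index=sample_ids, name="group")

    richness_per_group = {
        label: base_richness * (spec.richness_deflation if label == spec.low_diversity_group else 1.0)
        for label in group_labels
    }

    sigma_per_group = {
        label: 1.0 * (spec.evenness_sigma_factor if label == spec.low_diversity_group else 1.0)
        for label in group_labels
    }
    rows = np.zeros((len(sample_ids), n_genomes))
    for si, sid in enumerate(sample_ids):
        label = groups[sid]
        target = richness_per_group[label]
        size = min(max(2, int(rng.poisson(target))), n_genomes)
        support = rng.choice(n_genomes, size=size, replace=False, p=occupancy)
        vals = rng.lognormal(0.0, sigma_per_group[label], size=size)
        for j, gi in enumerate(support):
            gid = genome_ids[gi]
            if gid in fold_by_genome:
                fc, grp = fold_by_genome[gid]
                if label == grp:
                    vals[j] *= fc
        rows[si, support] = vals
        rows[si] /= rows[si].sum()

    true_abundance = pd.DataFrame(rows, index=sample_ids, columns=genome_ids)
    return CommunityDesign(
        sample_ids=sample_ids,
        groups=groups,
        true_abundance=true_abundance,
        planted=list(spec.planted),
        richness_per_group=richness_per_group,
    )


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimulationConfig:
    """Knobs of the shotgun read simulator.

    Defaults reflect a desk-scale rendition of a contamination-dominated
    BAL shotgun library: 50k reads/sample, 150 bp reads, 0.5% substitution
    errors, 30% host contamination and 5% exact duplicates.
    """

    reads_per_sample: int = 50_000
    read_length: int = 150
    substitution_error_rate: float = 0.005
    host_contamination_fraction: float = 0.30
    duplicate_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "host_contamination_fraction", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def simulate_reads(
    reference: ReferenceGenomeSet,
    design: CommunityDesign,
    host_genome: str | None = None,
    config: SimulationConfig | None = None,
) -> tuple[dict[str, list], pd.DataFrame]:
    """Simulate per-sample shotgun reads plus a per-read truth table.

    Reads are drawn from genomes with probability proportional to
    true_abundance x genome_length (longer genomes shed more fragments),
    with uniform start positions, random strand and i.i.d. substitution
    errors. A ``host_contamination_fraction`` of reads comes from
    ``host_genome`` instead, and a ``duplicate_rate`` of reads are exact
    copies of previously emitted reads of the same sample.

    Returns ``(reads_by_sample, truth)`` where each read is a
    :class:`viromescope.reads.Read` and ``truth`` records read_id,
    sample_id, origin, start and duplicate status.
    """
    from .reads import Read  # local import to avoid a cycle

    cfg = config if config is not None else SimulationConfig()
    if host_genome is None:
        host_genome = generate_host_genome(rng_seed=cfg.rng_seed + 1)
    L = cfg.read_length
    if len(host_genome) < L:
        raise ValueError("host genome shorter than read_length")

    usable = [r for r in reference if len(r.sequence) >= L]
    skipped = [r.genome_id for r in reference if len(r.sequence) < L]
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "%d genomes shorter than read_length rejected: %s", len(skipped), skipped[:5]
        )
    lengths = np.array([len(r.sequence) for r in usable], dtype=float)
    seqs = [r.sequence for r in usable]
    ids = [r.genome_id for r in usable]

    ss = np.random.SeedSequence(cfg.rng_seed)
    child_seeds = ss.spawn(len(design.sample_ids))
    reads_by_sample: dict[str, list] = {}
    truth_rows = []
    qual = "F" * L  # constant Q37

    for sample_id, child in zip(design.sample_ids, child_seeds):
        rng = np.random.default_rng(child)
        abund = design.true_abundance.loc[sample_id, ids].to_numpy()
        w = abund * lengths
        total = w.sum()
        n = cfg.reads_per_sample
        is_host = rng.random(n) < cfg.host_contamination_fraction
        if total > 0:
            p = w / total
            origin_idx = rng.choice(len(ids), size=n, p=p)
        else:
            origin_idx = np.zeros(n, dtype=int)
            is_host[:] = True
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        n_err = rng.binomial(L, cfg.substitution_error_rate, size=n)
        dup_flags = rng.random(n) < cfg.duplicate_rate
        dup_flags[0] = False

        sample_reads: list = []
        origins: list[str] = []
        starts: list[int] = []
        for i in range(n):
            rid = f"{sample_id}:r{i:06d}"
            if dup_flags[i]:
                j = int(rng.integers(0, i))
                src = sample_reads[j]
                sample_reads.append(Read(f"{rid}_dup", src.sequence, src.qualities))
                origins.append(origins[j])
                starts.append(starts[j])
                truth_rows.append((f"{rid}_dup", sample_id, origins[j], starts[j], True))
                continue
            if is_host[i]:
                src_seq, origin = host_genome, "host"
            else:
                gi = int(origin_idx[i])
                src_seq, origin = seqs[gi], ids[gi]
            start = int(rng.integers(0, len(src_seq) - L + 1))
            frag = src_seq[start : start + L]
            if strands[i] == "-":
                frag = _revcomp(frag)
            if n_err[i] > 0:
                arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
                pos = rng.choice(L, size=int(n_err[i]), replace=False)
                # substitute with a different base: add 1..3 mod 4 in base index space
                base_idx = np.searchsorted(_BASES, arr[pos])
                arr[pos] = _BASES[(base_idx + rng.integers(1, 4, size=len(pos))) % 4]
                frag = arr.tobytes().decode("ascii")
            sample_reads.append(Read(rid, frag, qual))
            origins.append(origin)
            starts.append(start)
            truth_rows.append((rid, sample_id, origin, start, False))
        reads_by_sample[sample_id] = sample_reads

    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample_id", "origin", "start", "is_duplicate"])
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# Companion omics matrices


@dataclass
class OmicsEffectSpec:
    """Planted group mean shifts (in SD units of log-intensity) per block.

    The bacteriome block defaults to no shift — emulating a study design in
    which metabolites differ strongly between groups while the bacterial
    community does not.
    """

    metabolite_shift: float = 2.5
    cytokine_shift: float = 1.0
    bacteriome_shift: float = 0.0
    metabolite_dropout: float = 0.1
    shifted_group: str = "smoker"


def simulate_omics(
    design: CommunityDesign,
    n_metabolites: int = 83,
    n_cytokines: int = 39,
    n_bacteria: int = 150,
    effect_spec: OmicsEffectSpec | None = None,
    rng_seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate metabolite/cytokine intensity matrices and a bacterial
    relative-abundance matrix over the design's samples.

    Metabolites and cytokines are Gaussian log-intensities (feature means
    N(5, 1), unit SD) with a planted mean shift toward ``shifted_group``;
    a ``metabolite_dropout`` fraction of entries is zeroed (not detected),
    supporting the >=50%-presence reporting filter. The bacteriome is a
    log-normal compositional matrix with no group effect by default.
    """
    if min(n_metabolites, n_cytokines, n_bacteria) <= 0:
        raise ValueError("matrix dimensions must be positive")
    spec = effect_spec if effect_spec is not None else OmicsEffectSpec()
    rng = np.random.default_rng(rng_seed)
    samples = design.sample_ids
    shifted = (design.groups.loc[samples] == spec.shifted_group).to_numpy(dtype=float)

    def intensity_block(n_feat: int, shift: float, dropout: float, prefix: str) -> pd.DataFrame:
        mu = rng.normal(5.0, 1.0, size=n_feat)
        x = rng.normal(0.0, 1.0, size=(len(samples), n_feat)) + mu
        x += shift * shifted[:, None]
        if dropout > 0:
            x[rng.random(x.shape) < dropout] = 0.0
        cols = [f"{prefix}_{j + 1:03d}" for j in range(n_feat)]
        return pd.DataFrame(x, index=samples, columns=cols)

    metabolites = intensity_block(n_metabolites, spec.metabolite_shift, spec.metabolite_dropout, "met")
    cytokines = intensity_block(n_cytokines, spec.cytokine_shift, 0.0, "cyt")

    # bacteriome: sparse compositional rows, identical process in both groups
    bac = np.zeros((len(samples), n_bacteria))
    richness = max(5, n_bacteria // 4)
    for i in range(len(samples)):
        support = rng.choice(n_bacteria, size=richness, replace=False)
        vals = rng.lognormal(0.0, 1.0, size=richness)
        if spec.bacteriome_shift != 0.0 and shifted[i]:
            vals[: richness // 2] *= np.exp(spec.bacteriome_shift)
        bac[i, support] = vals
        bac[i] /= bac[i].sum()
    bacteriome = pd.DataFrame(bac, index=samples, columns=[f"otu_{j + 1:03d}" for j in range(n_bacteria)])
    return {"metabolites": metabolites, "cytokines": cytokines, "bacteriome": bacteriome}


# ---------------------------------------------------------------------------
# Plain-text writers


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


def write_design(design: CommunityDesign, outdir: str | Path) -> None:
    outdir = Path(outdir)
    design.true_abundance.to_csv(outdir / "true_abundance.tsv", sep="\t")
    with open(outdir / "design_manifest.json", "w") as fh:
        json.dump(design.to_manifest(), fh, indent=2)
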