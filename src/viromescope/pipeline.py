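"""End-to-end orchestration: simulate -> process reads -> quantify -> compare.

The pipeline is configured by a small YAML file (see
:class:`PipelineConfig`), threads a single seed through every random
stage, and writes plain-text artifacts (FASTA/FASTQ/TSV/JSON/Newick) that
are re-readable by the package's own readers. Re-running with the same
config and seed reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import ecology, network, quant, stats, synthetic
from .reads import KmerIndex, process_sample
from .synthetic import (
    CommunityEffectSpec,
    OmicsEffectSpec,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "group_feature_sets"]


@dataclass
class PipelineConfig:
    """Validated configuration of a full synthetic-study run.

    Thresholds default to the quantification conventions used throughout
    the package: 95% alignment identity, a 200 bp consecutive-coverage
    presence rule, 9999 permutations for ordination fits and Mantel tests,
    1000 for differential abundance.
    """

    outdir: str = "viromescope_run"
    seed: int = 0
    # synthetic design
    n_genomes: int = 200
    group_sizes: tuple[int, int] = (20, 10)
    group_labels: tuple[str, str] = ("smoker", "nonsmoker")
    base_richness: int = 40
    reads_per_sample: int = 50_000
    read_length: int = 150
    substitution_error_rate: float = 0.005
    host_contamination_fraction: float = 0.30
    duplicate_rate: float = 0.05
    # thresholds
    min_identity: float = 95.0
    min_run_bp: int = 200
    perms_fit: int = 9999
    perms_metastats: int = 1000
    # analysis options
    exclude_samples: list[str] = field(default_factory=list)
    write_reads: bool = False

    def validate(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if self.min_run_bp < 1:
            raise ValueError("min_run_bp must be >= 1")
        if self.perms_fit < 1 or self.perms_metastats < 1:
            raise ValueError("permutation counts must be >= 1")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        SimulationConfig(
            reads_per_sample=self.reads_per_sample,
            read_length=self.read_length,
            substitution_error_rate=self.substitution_error_rate,
            host_contamination_fraction=self.host_contamination_fraction,
            duplicate_rate=self.duplicate_rate,
            rng_seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup_key in ("group_sizes", "group_labels"):
            if tup_key in raw:
                raw[tup_key] = tuple(raw[tup_key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        d["group_labels"] = list(self.group_labels)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class RunReport:
    """Summary numbers of one pipeline run; every entry is also written to disk."""

    config: dict
    read_accounting: dict
    n_populations_detected: int
    shared_fraction: float
    unique_by_group: dict
    alpha_tests: dict
    beta_factor: dict
    bacteriome_factor: dict
    metabolite_factor: dict
    mantel_virus_metabolites: dict
    metabolome_vector_fits: dict
    differential: dict
    network_summary: dict
    elapsed_seconds: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _fit_to_dict(fr: ecology.FitResult) -> dict:
    return {
        "effect": fr.effect,
        "p_raw": fr.p_raw,
        "p_adjusted": fr.p_adjusted,
        "n_permutations": fr.n_permutations,
    }


def group_feature_sets(
    presence: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> dict:
    """Shared and group-unique detected features, with fractions of the union.

    ``presence`` is a samples x features boolean (or 0/1) matrix; a feature
    belongs to a group when it is detected in at least one of the group's
    samples.
    """
    groups = pd.Series(groups)
    detected_by_group: dict[str, set[str]] = {}
    for g in groups.unique():
        sub = presence.loc[groups[groups == g].index]
        detected_by_group[g] = set(presence.columns[(sub.astype(bool)).any(axis=0)])
    if len(detected_by_group) < 2:
        raise ValueError("need at least 2 groups")
    sets = list(detected_by_group.values())
    shared = set.intersection(*sets)
    union = set.union(*sets)
    out = {
        "shared": sorted(shared),
        "shared_fraction": len(shared) / len(union) if union else 0.0,
        "union_size": len(union),
    }
    for g, s in detected_by_group.items():
        only = s - set.union(*(o for h, o in detected_by_group.items() if h != g))
        out[f"unique_{g}"] = sorted(only)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full synthetic-study pipeline and write artifacts.

    Stages: simulate reference/communities/reads/omics; per-sample read
    processing (trim, dedup, host removal, mapping); presence and
    median-coverage quantification; host-genus aggregation; alpha/beta
    diversity group comparisons; differential abundance; metabolite
    ordination with virome vector fits; Mantel correlation; association
    network. Stage timings and read accounting go into the report.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- simulate ---------------------------------------------------------
    reference = synthetic.generate_reference_db(config.n_genomes, rng_seed=config.seed)
    host = synthetic.generate_host_genome(rng_seed=config.seed + 1)
    effect_spec = CommunityEffectSpec()
    genera = set(reference.taxonomy("genus").values())
    keep_planted = [
        p for p in effect_spec.planted
        if p.target in genera or p.target in reference.genome_ids
    ]
    if len(keep_planted) < len(effect_spec.planted):
        logger.warning(
            "dropping planted effects whose genus is absent from this reference: %s",
            [p.target for p in effect_spec.planted if p not in keep_planted],
        )
    effect_spec.planted = keep_planted
    design = synthetic.design_communities(
        reference,
        group_sizes=config.group_sizes,
        group_labels=config.group_labels,
        effect_spec=effect_spec,
        base_richness=config.base_richness,
        rng_seed=config.seed + 2,
    )
    sim_cfg = SimulationConfig(
        reads_per_sample=config.reads_per_sample,
        read_length=config.read_length,
        substitution_error_rate=config.substitution_error_rate,
        host_contamination_fraction=config.host_contamination_fraction,
        duplicate_rate=config.duplicate_rate,
        rng_seed=config.seed + 3,
    )
    reads_by_sample, truth = synthetic.simulate_reads(reference, design, host, sim_cfg)
    omics = synthetic.simulate_omics(design, rng_seed=config.seed + 4)
    synthetic.write_fasta(reference.sequences(), outdir / "reference.fasta")
    synthetic.write_fasta({"host": host}, outdir / "host.fasta")
    synthetic.write_design(design, outdir)
    truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
    for name, df in omics.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t")
    if config.write_reads:
        fq = outdir / "fastq"
        fq.mkdir(exist_ok=True)
        for sid, rr in reads_by_sample.items():
            synthetic.write_fastq(rr, fq / f"{sid}.fastq")
    timings["simulate"] = time.perf_counter() - t0

    # --- read processing + quantification ---------------------------------
    t1 = time.perf_counter()
    viral_index = KmerIndex(reference.sequences())
    host_index = KmerIndex({"host": host})
    lengths = reference.lengths()
    accounting: dict[str, dict] = {}
    per_sample_abund: dict[str, pd.Series] = {}
    presence_rows = []
    for sid in design.sample_ids:
        hits, acct = process_sample(
            reads_by_sample[sid], host_index, viral_index, min_identity_pct=config.min_identity
        )
        accounting[sid] = acct
        abund, calls = quant.quantify_sample(
            hits,
            lengths,
            acct["decontaminated"],
            sample_id=sid,
            min_identity_pct=config.min_identity,
            min_run_bp=config.min_run_bp,
        )
        per_sample_abund[sid] = abund
        presence_rows.append(pd.Series({c.genome_id: c.present for c in calls}, name=sid))
    presence = pd.DataFrame(presence_rows)
    presence.to_csv(outdir / "presence_calls.tsv", sep="\t")
    with open(outdir / "read_accounting.json", "w") as fh:
        json.dump(accounting, fh, indent=2)
    matrix = quant.build_abundance_matrix(per_sample_abund, normalize="relative")
    matrix.to_csv(outdir / "abundance_relative.tsv", sep="\t")
    by_genus = quant.aggregate_by_host(matrix, reference.taxonomy("genus"))
    by_genus.to_csv(outdir / "abundance_by_host_genus.tsv", sep="\t")
    timings["quantify"] = time.perf_counter() - t1

    # --- ecology ----------------------------------------------------------
    t2 = time.perf_counter()
    keep = [s for s in design.sample_ids if s not in set(config.exclude_samples)]
    groups = design.groups.loc[keep]
    g1, g2 = config.group_labels
    vir = matrix.loc[keep]

    alpha = ecology.alpha_diversity_table(vir)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    alpha_tests = {}
    for metric in ("richness", "shannon_h", "pielou_j"):
        res = stats.mann_whitney(
            alpha.loc[groups[groups == g1].index, metric],
            alpha.loc[groups[groups == g2].index, metric],
        )
        alpha_tests[metric] = {"statistic": res.statistic, "p_raw": res.p_raw}

    bc = ecology.bray_curtis(vir)
    bc.to_frame().to_csv(outdir / "bray_curtis_virome.tsv", sep="\t")
    ord_vir = ecology.pcoa(bc)
    pd.DataFrame(ord_vir.coordinates, index=ord_vir.ids).to_csv(
        outdir / "pcoa_virome.tsv", sep="\t"
    )
    beta_factor = ecology.factor_fit(
        ord_vir, groups.to_numpy(), n_perm=config.perms_fit, rng_seed=config.seed + 5,
        name="smoking_status~virome",
    )
    with open(outdir / "upgma_samples.nwk", "w") as fh:
        fh.write(ecology.upgma(bc))

    bac = omics["bacteriome"].loc[keep]
    ord_bac = ecology.pcoa(ecology.bray_curtis(bac))
    bacteriome_factor = ecology.factor_fit(
        ord_bac, groups.to_numpy(), n_perm=config.perms_fit, rng_seed=config.seed + 6,
        name="smoking_status~bacteriome",
    )

    met = ecology.presence_filter(omics["metabolites"].loc[keep])
    met_scaled = ecology.autoscale(met)
    met_shifted = met_scaled - met_scaled.min(axis=0)  # non-negative for Bray-Curtis
    ord_met = ecology.pcoa(ecology.bray_curtis(met_shifted))
    metabolite_factor = ecology.factor_fit(
        ord_met, groups.to_numpy(), n_perm=config.perms_fit, rng_seed=config.seed + 7,
        name="smoking_status~metabolome",
    )
    mantel_vm = ecology.mantel(
        ecology.bray_curtis(vir),
        ecology.euclidean_distance(met_scaled),
        n_perm=config.perms_fit,
        rng_seed=config.seed + 8,
        name="virome~metabolome",
    )

    # vector-fit host-genus virome abundances onto the metabolite ordination,
    # Bonferroni-corrected within the fitted family
    genus_keep = by_genus.loc[keep]
    fits: list[tuple[str, ecology.FitResult]] = []
    for i, genus_name in enumerate(genus_keep.columns):
        v = genus_keep[genus_name].to_numpy()
        if np.ptp(v) == 0:
            continue
        fits.append((
            genus_name,
            ecology.vector_fit(
                ord_met, v, n_perm=config.perms_fit,
                rng_seed=config.seed + 100 + i, name=f"{genus_name}~metabolome",
            ),
        ))
    if fits:
        adj = stats.bonferroni([f.p_raw for _, f in fits])
        for (_, f), pa in zip(fits, adj):
            f.p_adjusted = float(pa)
    vector_fits = {
        g_: {"r2": f.effect, "p_raw": f.p_raw, "p_bonferroni": f.p_adjusted}
        for g_, f in fits
    }
    pd.DataFrame(vector_fits).T.to_csv(outdir / "vector_fits_metabolome.tsv", sep="\t")
    timings["ecology"] = time.perf_counter() - t2

    # --- differential abundance + feature sets ----------------------------
    t3 = time.perf_counter()
    diff = stats.metastats_test(
        by_genus.loc[keep], groups, n_perm=config.perms_metastats, rng_seed=config.seed + 9
    )
    ok = diff["p_raw"].notna()
    diff.loc[ok, "p_bonferroni"] = stats.bonferroni(diff.loc[ok, "p_raw"])
    diff.to_csv(outdir / "differential_abundance_genus.tsv", sep="\t")
    feature_sets = group_feature_sets(presence.loc[keep], groups)
    with open(outdir / "feature_sets.json", "w") as fh:
        json.dump(feature_sets, fh, indent=2)
    timings["differential"] = time.perf_counter() - t3

    # --- association network ----------------------------------------------
    t4 = time.perf_counter()
    # restrict to features detected in enough samples for a meaningful lasso
    common = vir.loc[:, (vir > 0).sum(axis=0) >= max(4, len(keep) // 4)]
    if common.shape[1] >= 3:
        clr = network.clr_transform(common)
        adj = network.mb_network(clr, lambda_="auto")
        clusters = network.detect_clusters(adj)
        pd.DataFrame(adj.edge_list(), columns=["feature_a", "feature_b"]).to_csv(
            outdir / "network_edges.tsv", sep="\t", index=False
        )
        clusters.labels.to_csv(outdir / "network_clusters.tsv", sep="\t")
        network_summary = {
            "n_features": common.shape[1],
            "lambda": adj.lambda_,
            "n_edges": adj.n_edges,
            "n_clusters": clusters.n_clusters,
            "largest_cluster_fraction": (
                max(clusters.sizes.values()) / common.shape[1] if clusters.sizes else 0.0
            ),
        }
    else:
        network_summary = {"n_features": int(common.shape[1]), "skipped": True}
    timings["network"] = time.perf_counter() - t4

    sig = diff[ok][diff.loc[ok, "p_raw"] < 0.05].index.tolist()
    report = RunReport(
        config=asdict(config),
        read_accounting=accounting,
        n_populations_detected=int(matrix.shape[1]),
        shared_fraction=feature_sets["shared_fraction"],
        unique_by_group={
            g1: len(feature_sets[f"unique_{g1}"]),
            g2: len(feature_sets[f"unique_{g2}"]),
        },
        alpha_tests=alpha_tests,
        beta_factor=_fit_to_dict(beta_factor),
        bacteriome_factor=_fit_to_dict(bacteriome_factor),
        metabolite_factor=_fit_to_dict(metabolite_factor),
        mantel_virus_metabolites=_fit_to_dict(mantel_vm),
        metabolome_vector_fits=vector_fits,
        differential={"significant_genera_p05": sig},
        network_summary=network_summary,
        elapsed_seconds=timings,
    )
    report.to_json(outdir / "run_report.json")
    config.to_yaml(outdir / "config_used.yaml")
    return report
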