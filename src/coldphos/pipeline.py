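"""End-to-end orchestration: simulate -> preprocess -> temporal -> enrichment
-> motifs -> network, driven by one structured config with deterministic
per-stage seeding and a hash manifest for reproducibility checks."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, motifs as motifs_mod, network as network_mod
from .enrichment import run_ora, split_localization_groups
from .io_formats import QuantTable
from .preprocess import (FilterParams, eigenms_normalize, filter_class1,
                         filter_reproducible, pca_qc, site_statistics)
from .synthetic_data import SimConfig, simulate_dataset
from .temporal import (DEPParams, call_deps, classify_archetypes,
                       compute_profiles, kmeans_cluster, pairwise_ttests,
                       redistribute_cluster_e)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "temporal", "enrichment", "motifs", "network")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the analysis conventions
    documented in each stage module."""

    out_dir: str = "coldphos_out"
    seed: int = 0
    simulate: bool = True
    quant_path: str | None = None
    proteome_path: str | None = None
    annotations_path: str | None = None
    interactions_path: str | None = None
    sim: dict = field(default_factory=dict)            # SimConfig overrides
    loc_prob_threshold: float = 0.75
    min_replicates: int = 2
    n_permutations: int = 200
    norm_alpha: float = 0.05
    k: int = 8
    n_restarts: int = 50
    archetype_epsilon: float = 0.3
    scale_profiles: bool = False
    equal_var_ttest: bool = True
    dep: dict = field(default_factory=dict)            # DEPParams overrides
    ora_alpha: float = 0.05
    min_mapped: int = 5
    min_occ: dict = field(default_factory=lambda: dict(motifs_mod.DEFAULT_MIN_OCC))
    motif_p_threshold: float = 1e-6
    subnetwork_mode: str = "any"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Counter-based fan-out so stages can be re-run in isolation."""
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _normalized_table(table: QuantTable, norm_log2: pd.DataFrame) -> QuantTable:
    """A QuantTable carrying the normalized (de-logged) intensities."""
    return QuantTable(records=table.records, times=list(table.times),
                      replicates=list(table.replicates),
                      intensities=np.power(2.0, norm_log2))


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "parameters": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        sim_kwargs = dict(config.sim)
        sim_kwargs.setdefault("seed", config.stage_seed("simulate"))
        sim_cfg = SimConfig(**sim_kwargs)
        quant, proteome, annotations, interactions, truth = simulate_dataset(sim_cfg)
        io_formats.write_quant_table(quant, out / "quant.tsv")
        io_formats.write_fasta(proteome, out / "proteome.fasta")
        annotations.table.to_csv(out / "annotations.tsv", sep="\t", index=False)
        interactions.table.to_csv(out / "interactions.tsv", sep="\t", index=False)
        truth.peptides.to_csv(out / "truth.tsv", sep="\t", index=False)
        record("simulate", {**sim_kwargs, "n_per_archetype": sim_cfg.counts()},
               [out / f for f in ("quant.tsv", "proteome.fasta",
                                  "annotations.tsv", "interactions.tsv",
                                  "truth.tsv")])
    else:
        for name in ("quant_path", "proteome_path", "annotations_path",
                     "interactions_path"):
            p = getattr(config, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name} missing or not found: {p}")
        proteome = io_formats.read_fasta(config.proteome_path)
        quant = io_formats.read_quant_table(config.quant_path, proteome=proteome)
        annotations = io_formats.read_annotations(config.annotations_path)
        interactions = io_formats.read_interactions(config.interactions_path)
        truth = None

    # ---- preprocess ------------------------------------------------------
    filtered = filter_class1(quant, config.loc_prob_threshold)
    filtered = filter_reproducible(filtered, config.min_replicates)
    stats = site_statistics(filtered)
    log2 = np.log2(filtered.intensities)
    groups = [c.split("min")[0] for c in log2.columns]
    norm, bias_report = eigenms_normalize(
        log2, groups, n_permutations=config.n_permutations,
        alpha=config.norm_alpha, seed=config.stage_seed("preprocess"))
    scores, var_pct = pca_qc(norm)

    io_formats.write_quant_table(filtered, out / "filtered_quant.tsv")
    norm.to_csv(out / "normalized_matrix.tsv", sep="\t")
    pd.DataFrame([{"residue": r, "count": c, "percent": stats.residue_percent[r]}
                  for r, c in stats.residue_counts.items()]).to_csv(
        out / "site_stats.tsv", sep="\t", index=False)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pd.DataFrame({"singular_value": bias_report.singular_values,
                  "perm_quantile": bias_report.permutation_quantiles,
                  "kept": [i < bias_report.n_trends_kept
                           for i in range(len(bias_report.singular_values))]}
                 ).to_csv(out / "bias_report.tsv", sep="\t", index=False)
    record("preprocess",
           {"loc_prob_threshold": config.loc_prob_threshold,
            "min_replicates": config.min_replicates,
            "n_permutations": config.n_permutations,
            "norm_alpha": config.norm_alpha},
           [out / f for f in ("filtered_quant.tsv", "normalized_matrix.tsv",
                              "site_stats.tsv", "pca_scores.tsv",
                              "bias_report.tsv")])

    # ---- membrane-compartment (Group A) restriction ----------------------
    group_a, _group_b = split_localization_groups(
        {r.protein_id for r in filtered.records}, annotations)
    ga_peps = [r.peptide_id for r in filtered.records
               if r.protein_id in group_a]
    if ga_peps:
        filtered = filtered.subset(ga_peps)
        norm = norm.loc[ga_peps]
    else:
        logger.warning("no Group A proteins; keeping all compartments")

    # ---- temporal --------------------------------------------------------
    norm_table = _normalized_table(filtered, norm)
    profiles = compute_profiles(norm_table)
    ttests = pairwise_ttests(norm_table, equal_var=config.equal_var_ttest)
    clusters = kmeans_cluster(profiles, k=config.k, n_restarts=config.n_restarts,
                              seed=config.stage_seed("temporal"),
                              scale=config.scale_profiles)
    clusters = classify_archetypes(clusters, epsilon=config.archetype_epsilon)
    clusters = redistribute_cluster_e(clusters, profiles)
    dep_params = DEPParams(**config.dep)
    deps = call_deps(profiles, ttests, dep_params)

    profiles.mean_fc.to_csv(out / "profiles.tsv", sep="\t")
    clusters.assignments.to_csv(out / "clusters.tsv", sep="\t")
    clusters.centroids.to_csv(out / "centroids.tsv", sep="\t")
    deps.to_csv(out / "dep_calls.tsv", sep="\t")
    record("temporal",
           {"k": config.k, "n_restarts": config.n_restarts,
            "epsilon": config.archetype_epsilon,
            "dep": dataclasses.asdict(dep_params)},
           [out / f for f in ("profiles.tsv", "clusters.tsv", "centroids.tsv",
                              "dep_calls.tsv")])

    # ---- enrichment ------------------------------------------------------
    prot_of = {r.peptide_id: r.protein_id for r in filtered.records}
    dep_peptides = set(deps.index[(deps != "none").any(axis=1)])
    resp = clusters.assignments["response_class"]
    early_prot = sorted({prot_of[p] for p in deps.index
                         if p in dep_peptides and p in resp.index
                         and resp[p] == "early"})
    late_prot = sorted({prot_of[p] for p in deps.index
                        if p in dep_peptides and p in resp.index
                        and resp[p] == "late"})
    background = sorted(proteome.sequences)
    ora_frames = []
    for label, study in (("early", early_prot), ("late", late_prot)):
        if not study:
            logger.warning("no %s-response proteins; enrichment skipped", label)
            continue
        res = run_ora(study, background, annotations, aspect="BP",
                      min_mapped=config.min_mapped, alpha=config.ora_alpha)
        ora_frames.append(res.table.assign(direction=label))
    enr = (pd.concat(ora_frames, ignore_index=True) if ora_frames
           else pd.DataFrame())
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    record("enrichment", {"min_mapped": config.min_mapped,
                          "alpha": config.ora_alpha},
           [out / "enrichment.tsv"])

    # ---- motifs ----------------------------------------------------------
    dep_table = filtered.subset([p for p in filtered.peptide_ids
                                 if p in dep_peptides])
    fg_windows = motifs_mod.peptide_site_windows(dep_table, proteome)
    bg_windows = motifs_mod.proteome_background_windows(proteome)
    found = []
    for central in "STY":
        found.extend(motifs_mod.motifx(
            fg_windows, bg_windows, central,
            min_occ=config.min_occ.get(central),
            p_threshold=config.motif_p_threshold))
    found = motifs_mod.group_motifs(found)
    dynamics = motifs_mod.motif_dynamics(deps, fg_windows, found, norm_table)
    pd.DataFrame([{
        "pattern": m.pattern(), "central": m.central, "group": m.group,
        "constraints": ";".join(f"{o:+d}{r}" for o, r in m.constraints),
        "fg_matches": m.fg_matches, "fg_size": m.fg_size,
        "bg_matches": m.bg_matches, "bg_size": m.bg_size,
        "fold_enrichment": m.fold_enrichment, "score": m.score,
    } for m in found]).to_csv(out / "motifs.tsv", sep="\t", index=False)
    dynamics.to_csv(out / "motif_dynamics.tsv", sep="\t", index=False)
    record("motifs", {"min_occ": dict(config.min_occ),
                      "p_threshold": config.motif_p_threshold},
           [out / "motifs.tsv", out / "motif_dynamics.tsv"])

    # ---- network ---------------------------------------------------------
    net = network_mod.build_network(interactions)
    dep_proteins = sorted({prot_of[p] for p in dep_peptides})
    study_proteins = sorted({r.protein_id for r in filtered.records})
    sub = network_mod.map_subnetwork(net, study_proteins, dep_proteins,
                                     mode=config.subnetwork_mode)
    files = []
    if sub.number_of_nodes():
        io_formats.write_graph(sub, out / "subnet.sif", "SIF")
        io_formats.write_graph(sub, out / "subnet.graphml", "GraphML")
        files = [out / "subnet.sif", out / "subnet.graphml"]
    fam = network_mod.family_interaction_counts(sub)
    fam.rename_axis("family").rename("interactions").to_csv(
        out / "families.tsv", sep="\t")
    files.append(out / "families.tsv")
    record("network", {"mode": config.subnetwork_mode}, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
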