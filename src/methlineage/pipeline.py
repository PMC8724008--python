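"""End-to-end orchestration: simulate -> preprocess -> DMP/DMR -> annotate /
enrich -> cluster -> score, from a single validated config with one global
seed.

The global seed is split into independent per-stage substreams
(:class:`numpy.random.SeedSequence`), so each stage is reproducible in
isolation and re-running an identical config yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differential, enrichment, io, lineage, preprocessing, similarity, synthetic
from .matrix import MethlineageError, MethylationMatrix


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the standard analysis thresholds
    (detection p 0.01; DMP p 0.01 and |delta M| 2; DMR gap 1000 bp, >= 3
    CpGs, p 0.01; 1000 bootstrap iterations, 95% CIs)."""

    outdir: str = "methlineage_run"
    seed: int = 0
    simulate: bool = True

    # simulated-cohort shape (used only when simulate=True)
    n_per_group: int = 6
    n_probes: int = 8000
    n_lineage_cpgs: int = 150
    n_program_cpgs: int = 150
    effect_delta_beta: float = 0.3
    n_region_sets: int = 8
    region_set_fold: float = 8.0

    # input paths (used when simulate=False)
    beta_path: str | None = None
    detection_p_path: str | None = None
    manifest_path: str | None = None
    sample_sheet_path: str | None = None
    region_sets_dir: str | None = None

    # stage parameters
    offset: float = 100.0
    detection_p_cut: float = 0.01
    drop_sex: bool = True
    dmp_p_cut: float = 0.01
    delta_m_cut: float = 2.0
    dmr_max_gap: int = 1000
    dmr_min_cpgs: int = 3
    dmr_p_cut: float = 0.01
    n_boot: int = 1000
    ci_level: float = 0.95
    selection_method: str = "knee"
    top_k: int | None = None
    tau: float | None = None
    renormalize_all: bool = False
    comparison: tuple[str, str] | None = None
    score_components: tuple[int, int] | None = None
    plots: bool = True

    def validate(self) -> None:
        for name in ("detection_p_cut", "dmp_p_cut", "dmr_p_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise MethlineageError(f"{name} must lie in (0, 1], got {v}")
        if self.offset <= 0:
            raise MethlineageError("offset must be positive")
        if self.delta_m_cut < 0:
            raise MethlineageError("delta_m_cut must be >= 0")
        if self.dmr_min_cpgs < 2:
            raise MethlineageError("dmr_min_cpgs must be >= 2")
        if self.dmr_max_gap < 1:
            raise MethlineageError("dmr_max_gap must be >= 1")
        if self.n_boot < 1:
            raise MethlineageError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise MethlineageError("ci_level must lie in (0, 1)")
        if not self.simulate:
            for name in ("beta_path", "manifest_path"):
                if getattr(self, name) is None:
                    raise MethlineageError(f"{name} is required when simulate=False")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MethlineageError(f"unknown config keys: {sorted(unknown)}")
        if "comparison" in raw and raw["comparison"] is not None:
            raw["comparison"] = tuple(raw["comparison"])
        if "score_components" in raw and raw["score_components"] is not None:
            raw["score_components"] = tuple(raw["score_components"])
        return cls(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    log_lines: list[str] = field(default_factory=list)
    dmps: pd.DataFrame | None = None
    dmrs: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order, checkpointing each output as a TSV."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(outdir=outdir)
    log = result.log_lines
    log.append(f"methlineage {__version__}, numpy {np.__version__}, pandas {pd.__version__}")
    log.append(f"seed: {config.seed}")

    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ("simulate", "region_sets", "bootstrap"), np.random.SeedSequence(config.seed).spawn(3)
        )
    }

    # -- stage 1: simulate or load -------------------------------------------
    truth = None
    region_sets: dict[str, pd.DataFrame] = {}
    if config.simulate:
        design = synthetic.factorial_design(
            n_per_group=config.n_per_group,
            n_probes=config.n_probes,
            n_lineage_cpgs=config.n_lineage_cpgs,
            n_program_cpgs=config.n_program_cpgs,
            effect_delta_beta=config.effect_delta_beta,
            seed=stage_seeds["simulate"],
        )
        manifest = synthetic.generate_manifest(config.n_probes, seed=stage_seeds["simulate"])
        betas, detection_p, truth = synthetic.generate_cohort(design, manifest)
        io.write_manifest(manifest.reset_index(drop=True), outdir / "manifest.tsv")
        io.write_matrix(betas, outdir / "betas.tsv")
        det = detection_p.copy()
        det.index.name = "probe_id"
        io.write_table(det, outdir / "detection_p.tsv", index=True)
        io.write_sample_sheet(betas.group_labels, outdir / "sample_sheet.tsv")
        truth_df = pd.DataFrame(
            {
                "probe_id": truth.lineage_cpg_ids + truth.program_cpg_ids,
                "class": ["lineage"] * len(truth.lineage_cpg_ids)
                + ["program"] * len(truth.program_cpg_ids),
            }
        )
        io.write_table(truth_df, outdir / "planted_truth.tsv")
        log.append(f"simulate: {betas.n_probes} probes x {betas.n_samples} samples, groups {betas.groups()}")
        design_groups = {g.label: g for g in design.groups}
    else:
        manifest = io.read_manifest(config.manifest_path)
        betas = io.read_matrix(config.beta_path, scale="beta", sample_sheet=config.sample_sheet_path)
        detection_p = (
            io.read_detection_p(config.detection_p_path)
            if config.detection_p_path
            else pd.DataFrame(0.0, index=betas.probe_ids, columns=betas.sample_ids)
        )
        if config.region_sets_dir:
            region_sets = io.read_region_sets(config.region_sets_dir)
        log.append(f"load: {betas.n_probes} probes x {betas.n_samples} samples")
        design_groups = {}

    # -- stage 2: preprocess ---------------------------------------------------
    filtered, flog = preprocessing.filter_probes(
        betas, detection_p, manifest, p_cut=config.detection_p_cut, drop_sex=config.drop_sex
    )
    io.write_matrix(filtered, outdir / "filtered_betas.tsv")
    log.append(f"preprocess: {flog}")
    m_matrix = preprocessing.matrix_to_m(filtered)

    # -- stage 3: DMPs ---------------------------------------------------------
    groups = filtered.groups()
    if config.comparison is not None:
        group_a, group_b = config.comparison
    else:
        group_a, group_b = groups[0], groups[1]
    a_ids = filtered.samples_in_group(group_a)
    b_ids = filtered.samples_in_group(group_b)
    stats_table, prior = differential.fit_moderated_t(m_matrix, a_ids, b_ids, beta_matrix=filtered)
    dmps = differential.call_dmps(stats_table, p_cut=config.dmp_p_cut, delta_m_cut=config.delta_m_cut)
    result.dmps = dmps
    out_stats = stats_table.copy()
    out_stats.index.name = "probe_id"
    io.write_table(out_stats, outdir / "dmp_stats.tsv", index=True)
    dmps_out = dmps.copy()
    dmps_out.index.name = "probe_id"
    io.write_table(dmps_out, outdir / "dmps.tsv", index=True)
    log.append(
        f"dmp: {group_a} vs {group_b}; prior d0={prior.d0:.4g} s0_sq={prior.s0_sq:.4g}; "
        f"{len(dmps)} DMPs (p<={config.dmp_p_cut}, |dM|>={config.delta_m_cut})"
    )

    # pairwise overlap across first three groups, when available
    if len(groups) >= 3:
        sets = {}
        for ga, gb in [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]:
            st, _ = differential.fit_moderated_t(
                m_matrix, filtered.samples_in_group(ga), filtered.samples_in_group(gb), beta_matrix=filtered
            )
            called = differential.call_dmps(st, config.dmp_p_cut, config.delta_m_cut)
            sets[f"{ga}_vs_{gb}"] = set(called.index)
        venn = differential.overlap_dmp_sets(sets)
        io.write_table(
            pd.DataFrame({"region": list(venn), "count": list(venn.values())}), outdir / "dmp_venn.tsv"
        )
        log.append(f"dmp venn: {sum(venn.values())} probes in union over {len(sets)} comparisons")

    # -- stage 4: DMRs ---------------------------------------------------------
    dmrs = differential.call_dmrs(
        stats_table,
        filtered,
        manifest,
        a_ids,
        b_ids,
        max_gap=config.dmr_max_gap,
        min_cpgs=config.dmr_min_cpgs,
        p_cut=config.dmr_p_cut,
    )
    result.dmrs = dmrs
    io.write_table(dmrs, outdir / "dmrs.tsv")
    io.write_bed(differential.dmrs_to_bed(dmrs), outdir / "dmrs.bed") if len(dmrs) else None
    effect_counts = differential.filter_dmrs_by_effect(dmrs)
    io.write_table(effect_counts, outdir / "dmr_effect_counts.tsv")
    log.append(f"dmr: {len(dmrs)} regions")

    # -- stage 5: annotation + enrichment ---------------------------------------
    hypo = dmps.index[dmps["direction"] == "hypo_in_A"]
    hyper = dmps.index[dmps["direction"] == "hyper_in_A"]
    for name, ids in (("hypo", hypo), ("hyper", hyper), ("all_array", filtered.probe_ids)):
        if len(ids) == 0:
            log.append(f"annotate: {name} set empty, skipped")
            continue
        props = enrichment.bootstrap_proportions(
            ids, manifest, n_iter=config.n_boot, ci_level=config.ci_level, seed=stage_seeds["bootstrap"]
        )
        for family, table in props.families.items():
            t = table.copy()
            t.index.name = "category"
            io.write_table(t, outdir / f"annotation_{name}_{family}.tsv", index=True)
        log.append(f"annotate: {name} n={len(ids)}")

    if config.simulate and truth is not None and config.n_region_sets > 0:
        axes_differ = []
        ga, gb = design_groups.get(group_a), design_groups.get(group_b)
        if ga and gb:
            if ga.lineage != gb.lineage:
                axes_differ += truth.lineage_cpg_ids
            if ga.program != gb.program:
                axes_differ += truth.program_cpg_ids
        enriched_in = set(axes_differ) or set(truth.all_planted())
        region_sets = synthetic.generate_region_sets(
            manifest,
            enriched_in & set(filtered.probe_ids),
            fold=config.region_set_fold,
            n_sets=config.n_region_sets,
            seed=stage_seeds["region_sets"],
        )
        for name, bed in region_sets.items():
            io.write_bed(bed, outdir / f"region_set_{name}.bed")
    if region_sets and len(dmps):
        query = hypo if len(hypo) >= len(hyper) else hyper
        direction = "hypo_query" if len(hypo) >= len(hyper) else "hyper_query"
        enr = enrichment.region_set_enrichment(
            query, filtered.probe_ids, region_sets, manifest, direction=direction
        )
        result.enrichment = enr
        io.write_table(enr, outdir / "enrichment.tsv")
        log.append(f"enrich: {len(enr)} sets tested, query {direction} n={len(query)}")

    # -- stage 6: clustering -----------------------------------------------------
    dist = similarity.pairwise_distances(filtered)
    d = dist.copy()
    d.index.name = "sample_id"
    io.write_table(d, outdir / "distances.tsv", index=True)
    merges = similarity.hierarchical_cluster(dist)
    io.write_table(merges, outdir / "dendrogram_merges.tsv")
    (outdir / "dendrogram.newick").write_text(similarity.to_newick(merges) + "\n")
    log.append(f"cluster: {len(merges)} merges, max height {merges['height'].max():.4g}")

    if len(dmps):
        profiles = similarity.beta_density_profiles(filtered, dmps.index)
        p = profiles.copy()
        p.index.name = "beta"
        io.write_table(p, outdir / "dmp_beta_densities.tsv", index=True)

    # -- stage 7: scores ----------------------------------------------------------
    pca = lineage.fit_pca(filtered, scale=True)
    scree = pd.DataFrame(
        {
            "component": pca.loadings.columns,
            "explained_variance": pca.explained_variance,
            "explained_pct": 100 * pca.explained_variance_ratio,
        }
    )
    io.write_table(scree, outdir / "pca_scree.tsv")
    if config.score_components is not None:
        comps = config.score_components
    elif config.simulate and design_groups:
        prog_labels = {s: design_groups[filtered.group_labels[s]].program for s in filtered.sample_ids}
        lin_labels = {s: design_groups[filtered.group_labels[s]].lineage for s in filtered.sample_ids}
        f_prog = lineage.component_group_separation(pca, prog_labels)
        f_lin = lineage.component_group_separation(pca, lin_labels)
        comps = (
            int(f_prog.idxmax().removeprefix("PC")),
            int(f_lin.idxmax().removeprefix("PC")),
        )
        log.append(f"score: components chosen by group-separation F: program PC{comps[0]}, lineage PC{comps[1]}")
    else:
        comps = None
        log.append("score: skipped (no score_components configured)")
    if comps is not None:
        score_cols = {}
        for axis, comp in zip(("program", "lineage"), comps):
            if config.simulate and design_groups:
                # axis labels are known: refine the component against
                # rotation inside the top-component span
                positive_val = "neuroendocrine" if axis == "program" else "epithelial"
                axis_lab = {
                    s: getattr(design_groups[filtered.group_labels[s]], axis)
                    for s in filtered.sample_ids
                }
                ranked = lineage.rank_loading_series(
                    lineage.axis_loadings(pca, axis_lab, positive_val)
                )
                pos_samples = [s for s in filtered.sample_ids if axis_lab[s] == positive_val]
            else:
                ranked = lineage.rank_loadings(pca, comp)
                pos_samples = list(filtered.sample_ids)[: filtered.n_samples // 2]
            selected = lineage.select_informative_cpgs(
                ranked, method=config.selection_method, k=config.top_k, tau=config.tau
            )
            sign = lineage.orient_sign(pca, comp, selected, filtered, pos_samples)
            smodel = lineage.build_score_model(pca, comp, selected, sign, filtered, name=f"{axis}_score")
            lineage.save_score_model(smodel, outdir / f"score_model_{axis}.tsv")
            score_cols[f"{axis}_z"] = lineage.score_samples(smodel, filtered)
            log.append(f"score: {axis} PC{comp}, {len(selected)} CpGs selected, sign {sign:+d}")
        scores = pd.DataFrame(score_cols)
        scores.insert(0, "group", [filtered.group_labels[s] for s in scores.index])
        scores.index.name = "sample_id"
        if config.renormalize_all:
            for c in score_cols:
                scores[c] = (scores[c] - scores[c].mean()) / scores[c].std(ddof=1)
        result.scores = scores
        io.write_table(scores, outdir / "scores.tsv", index=True)

    # -- plots ------------------------------------------------------------------
    if config.plots:
        from . import plots

        plots.distance_heatmap(dist, filtered.group_labels, outdir / "distance_heatmap.png")
        plots.scree_plot(pca.explained_variance_ratio, outdir / "pca_scree.png")
        if len(dmps):
            plots.density_plot(
                pd.read_csv(outdir / "dmp_beta_densities.tsv", sep="\t", index_col=0),
                filtered.group_labels,
                outdir / "dmp_beta_densities.png",
            )

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return result
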