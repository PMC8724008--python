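"""Synthetic methylation cohorts with planted lineage and program signals.

The generator emulates the structure of a methylation-array cell-line study:
groups of cell lines (entities) that differ along two biological axes — a
tissue-lineage axis (e.g. epithelial vs neural) and a differentiation-program
axis (neuroendocrine vs none).  A configurable number of CpGs is planted for
each axis; every group's mean beta at a planted CpG is shifted by the design
effect size depending on the group's lineage/program.  All remaining probes
share one bimodal baseline across groups, so the null is exactly null.

Per-sample betas are drawn from a Beta distribution whose mean is the group
target and whose standard deviation maps to ``noise_sd``; this keeps values
inside (0, 1) without truncating a Gaussian.  Per-(group, probe) offsets of
magnitude ``entity_noise_sd`` add entity-specific variation on top of the
planted axes.  Detection p-values are near zero except for independently
injected failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    FEATURE_CATEGORIES,
    ISLAND_CATEGORIES,
    MethlineageError,
    MethylationMatrix,
    validate_manifest,
)

LINEAGES = ("epithelial", "neural", "mesenchymal", "other")
PROGRAMS = ("neuroendocrine", "none")

#: Rough EPIC-like composition of the array annotation; weights in each
#: family sum to one.
EPIC_LIKE_ISLAND_WEIGHTS = {
    "Island": 0.21,
    "N_Shore": 0.12,
    "S_Shore": 0.10,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.47,
}
EPIC_LIKE_FEATURE_WEIGHTS = {
    "TSS1500": 0.13,
    "TSS200": 0.08,
    "5UTR": 0.09,
    "1stExon": 0.04,
    "Body": 0.33,
    "ExonBnd": 0.01,
    "3UTR": 0.03,
    "IGR": 0.29,
}
DEFAULT_FLAG_RATES = {"sex_chrom": 0.03, "snp_flagged": 0.02, "cross_reactive": 0.02}


@dataclass(frozen=True)
class GroupSpec:
    """One entity of the cohort: a label, its position on both axes, and n."""

    label: str
    lineage: str
    program: str
    n_samples: int

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise MethlineageError(f"unknown lineage {self.lineage!r}")
        if self.program not in PROGRAMS:
            raise MethlineageError(f"unknown program {self.program!r}")
        if self.n_samples < 1:
            raise MethlineageError("each group needs at least one sample")


def factorial_design(n_per_group: int = 8, **kwargs) -> "CohortDesign":
    """The default 2x2 factorial cohort: {epithelial, neural} x {NE, none}.

    Mirrors the classical pairing of neuroendocrine/epithelial cancers
    (SCLC-like, LUAD-like, NB-like, GBM-like entities).
    """
    groups = [
        GroupSpec("SCLC_like", "epithelial", "neuroendocrine", n_per_group),
        GroupSpec("LUAD_like", "epithelial", "none", n_per_group),
        GroupSpec("NB_like", "neural", "neuroendocrine", n_per_group),
        GroupSpec("GBM_like", "neural", "none", n_per_group),
    ]
    return CohortDesign(groups=groups, **kwargs)


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    ``effect_delta_beta`` is the mean-beta difference planted between the
    two sides of each axis; ``noise_sd`` the per-sample beta SD around the
    group target; ``entity_noise_sd`` the SD of per-(group, probe) offsets.
    """

    groups: list[GroupSpec]
    n_probes: int = 20_000
    n_lineage_cpgs: int = 200
    n_program_cpgs: int = 200
    effect_delta_beta: float = 0.3
    baseline_modes: tuple[float, float] = (0.1, 0.9)
    baseline_weights: tuple[float, float] = (0.5, 0.5)
    baseline_jitter_sd: float = 0.04
    block_size: int = 4
    noise_sd: float = 0.05
    entity_noise_sd: float = 0.0
    detection_fail_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise MethlineageError("design needs at least one group")
        if self.n_lineage_cpgs + self.n_program_cpgs > self.n_probes:
            raise MethlineageError("planted CpG counts exceed n_probes")
        if not 0 <= self.effect_delta_beta < 1:
            raise MethlineageError("effect_delta_beta must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise MethlineageError("noise_sd must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort.

    ``group_targets`` holds the noise-free mean beta of every planted probe
    in every group (probes x groups).
    """

    lineage_cpg_ids: list[str] = field(default_factory=list)
    program_cpg_ids: list[str] = field(default_factory=list)
    group_targets: pd.DataFrame | None = None

    def all_planted(self) -> set[str]:
        return set(self.lineage_cpg_ids) | set(self.program_cpg_ids)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _check_weights(weights: dict[str, float], allowed: list[str], family: str) -> None:
    unknown = set(weights) - set(allowed)
    if unknown:
        raise MethlineageError(f"unknown {family} categories: {sorted(unknown)}")
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise MethlineageError(f"{family} weights must sum to 1")


def generate_manifest(
    n_probes: int,
    chrom_sizes: dict[str, int] | None = None,
    island_weights: dict[str, float] | None = None,
    feature_weights: dict[str, float] | None = None,
    flag_rates: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an array annotation: coordinates, categories and QC flags.

    Coordinates are synthetic (no real genome build); positions are drawn
    uniformly per chromosome and sorted within it.  Deterministic for a
    fixed seed.
    """
    if n_probes < 1:
        raise MethlineageError("n_probes must be >= 1")
    chrom_sizes = chrom_sizes or {f"chr{i}": 50_000_000 for i in range(1, 9)}
    island_weights = island_weights or EPIC_LIKE_ISLAND_WEIGHTS
    feature_weights = feature_weights or EPIC_LIKE_FEATURE_WEIGHTS
    flag_rates = {**DEFAULT_FLAG_RATES, **(flag_rates or {})}
    _check_weights(island_weights, ISLAND_CATEGORIES, "island_relation")
    _check_weights(feature_weights, FEATURE_CATEGORIES, "gene_feature")

    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms])

    isl_cats = list(island_weights)
    feat_cats = list(feature_weights)
    island = rng.choice(isl_cats, size=n_probes, p=[island_weights[c] for c in isl_cats])
    feature = rng.choice(feat_cats, size=n_probes, p=[feature_weights[c] for c in feat_cats])

    # probes cluster around CpG islands: island probes sit within an island
    # locus, shores/shelves at increasing distance, open-sea probes uniform
    n_islands = max(1, n_probes // 10)
    island_chrom = rng.integers(0, len(chroms), size=n_islands)
    island_center = rng.integers(5_000, sizes[island_chrom] - 5_000 + 1)
    which = rng.integers(0, n_islands, size=n_probes)
    chrom_idx = island_chrom[which]
    center = island_center[which]
    offset = np.zeros(n_probes, dtype=int)
    is_isl = island == "Island"
    offset[is_isl] = rng.integers(-400, 401, is_isl.sum())
    for cats, lo, hi in ((("N_Shore", "S_Shore"), 600, 2000), (("N_Shelf", "S_Shelf"), 2000, 4000)):
        m = np.isin(island, cats)
        side = np.where(np.char.startswith(island[m].astype(str), "N"), -1, 1)
        offset[m] = side * rng.integers(lo, hi + 1, m.sum())
    open_sea = island == "OpenSea"
    pos = np.clip(center + offset, 1, sizes[chrom_idx])
    chrom_idx[open_sea] = rng.integers(0, len(chroms), open_sea.sum())
    pos[open_sea] = rng.integers(1, sizes[chrom_idx[open_sea]] + 1)

    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    island, feature = island[order], feature[order]
    genes = np.where(
        feature == "IGR", "", np.char.add("GENE", (rng.integers(0, max(n_probes // 20, 1), n_probes)).astype(str))
    )
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "chrom": [chroms[i] for i in chrom_idx],
            "pos": pos,
            "island_relation": island,
            "gene_feature": feature,
            "gene_symbol": genes,
            "sex_chrom": rng.random(n_probes) < flag_rates["sex_chrom"],
            "snp_flagged": rng.random(n_probes) < flag_rates["snp_flagged"],
            "cross_reactive": rng.random(n_probes) < flag_rates["cross_reactive"],
        }
    )
    return validate_manifest(manifest)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _beta_draw(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta-distributed draws with the requested mean and (capped) SD."""
    mean = np.clip(mean, 0.02, 0.98)
    var = np.minimum(sd**2, 0.9 * mean * (1 - mean))
    phi = mean * (1 - mean) / var - 1.0
    a = mean * phi
    b = (1 - mean) * phi
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def _axis_assignment(rng: np.random.Generator, values: list[str], n_cpgs: int) -> np.ndarray:
    """For each planted CpG decide which axis values sit on the high side.

    Returns a boolean (n_cpgs x len(values)) matrix with at least one True
    and one False per row whenever more than one distinct value exists.
    """
    k = len(values)
    if k == 1:
        return np.ones((n_cpgs, 1), dtype=bool)
    high = rng.random((n_cpgs, k)) < 0.5
    # degenerate rows (all high or all low) get one entry flipped
    for i in np.where(high.all(axis=1) | (~high).all(axis=1))[0]:
        j = rng.integers(0, k)
        high[i, j] = ~high[i, j]
    return high


def _plant_blocks(
    rng: np.random.Generator, manifest: pd.DataFrame, clean: np.ndarray, n: int, block_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Choose n planted CpG rows as blocks of up to ``block_size`` adjacent
    clean probes on one chromosome (manifest is position-sorted within
    chromosomes).  Returns (rows, block ids)."""
    chrom = manifest["chrom"].to_numpy()
    taken = np.zeros(len(chrom), dtype=bool)
    rows: list[int] = []
    bids: list[int] = []
    bid = 0
    for start in rng.permutation(np.where(clean)[0]):
        if len(rows) >= n:
            break
        if taken[start]:
            continue
        blk = []
        r = start
        while r < len(chrom) and chrom[r] == chrom[start] and len(blk) < block_size:
            if clean[r] and not taken[r] and len(rows) + len(blk) < n:
                blk.append(r)
            r += 1
        for r2 in blk:
            taken[r2] = True
        rows.extend(blk)
        bids.extend([bid] * len(blk))
        bid += 1
    return np.asarray(rows, dtype=int), np.asarray(bids, dtype=int)


def generate_cohort(
    design: CohortDesign, manifest: pd.DataFrame
) -> tuple[MethylationMatrix, pd.DataFrame, PlantedTruth]:
    """Generate betas, detection p-values and the planted ground truth.

    Planted CpGs are chosen among probes free of QC flags so that the
    signal survives standard probe filtering.  Betas lie in
    [1e-6, 1 - 1e-6]; detection p-values are ~0 except for failures
    injected at ``design.detection_fail_rate``.
    """
    manifest = validate_manifest(manifest)
    if len(manifest) < design.n_probes:
        raise MethlineageError("manifest has fewer probes than design.n_probes")
    manifest = manifest.iloc[: design.n_probes]
    rng = np.random.default_rng(design.seed)

    probe_ids = manifest["probe_id"].to_numpy()
    clean = (~(manifest["sex_chrom"] | manifest["snp_flagged"] | manifest["cross_reactive"])).to_numpy()
    n_plant = design.n_lineage_cpgs + design.n_program_cpgs
    if n_plant > clean.sum():
        raise MethlineageError("not enough unflagged probes to plant the design")
    planted_rows, planted_blocks = _plant_blocks(rng, manifest, clean, n_plant, design.block_size)
    lin_rows = planted_rows[: design.n_lineage_cpgs]
    prog_rows = planted_rows[design.n_lineage_cpgs :]
    lin_blocks = planted_blocks[: design.n_lineage_cpgs]
    prog_blocks = planted_blocks[design.n_lineage_cpgs :]
    lineage_ids = probe_ids[lin_rows]
    program_ids = probe_ids[prog_rows]

    # baseline: bimodal mixture with per-probe jitter
    modes = np.asarray(design.baseline_modes)
    which = rng.choice(len(modes), size=design.n_probes, p=np.asarray(design.baseline_weights))
    baseline = np.clip(modes[which] + rng.normal(0, design.baseline_jitter_sd, design.n_probes), 0.03, 0.97)

    delta = design.effect_delta_beta
    lineages = sorted({g.lineage for g in design.groups})
    programs = sorted({g.program for g in design.groups})
    # direction is coherent within a planted block (neighbouring CpGs move
    # together), so assignments are drawn per block and expanded to CpGs
    _, lin_inv = np.unique(lin_blocks, return_inverse=True)
    _, prog_inv = np.unique(prog_blocks, return_inverse=True)
    lin_high = _axis_assignment(rng, lineages, lin_inv.max() + 1 if len(lin_inv) else 0)[lin_inv]
    prog_high = _axis_assignment(rng, programs, prog_inv.max() + 1 if len(prog_inv) else 0)[prog_inv]
    # low side of a planted CpG: leave headroom of delta above
    lin_low = rng.uniform(0.15, max(0.95 - delta, 0.16), design.n_lineage_cpgs)
    prog_low = rng.uniform(0.15, max(0.95 - delta, 0.16), design.n_program_cpgs)

    idx = pd.Index(probe_ids)

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    targets = {}
    detection = {}
    for g in design.groups:
        target = baseline.copy()
        target[lin_rows] = lin_low + delta * lin_high[:, lineages.index(g.lineage)]
        target[prog_rows] = prog_low + delta * prog_high[:, programs.index(g.program)]
        if design.entity_noise_sd > 0:
            target = target + rng.normal(0, design.entity_noise_sd, design.n_probes)
        target = np.clip(target, 0.02, 0.98)
        targets[g.label] = target
        for j in range(g.n_samples):
            sid = f"{g.label}_{j + 1:02d}"
            columns[sid] = _beta_draw(rng, target, design.noise_sd)
            p = rng.uniform(0.0, 0.005, design.n_probes)
            fails = rng.random(design.n_probes) < design.detection_fail_rate
            p[fails] = rng.uniform(0.02, 1.0, fails.sum())
            detection[sid] = p
            labels[sid] = g.label

    values = pd.DataFrame(columns, index=idx)
    values.index.name = "probe_id"
    det = pd.DataFrame(detection, index=idx)
    det.index.name = "probe_id"
    truth = PlantedTruth(
        lineage_cpg_ids=list(lineage_ids),
        program_cpg_ids=list(program_ids),
        group_targets=pd.DataFrame(targets, index=idx).iloc[np.sort(planted_rows)],
    )
    return MethylationMatrix(values, "beta", labels), det, truth


# ---------------------------------------------------------------------------
# region sets
# ---------------------------------------------------------------------------

def generate_region_sets(
    manifest: pd.DataFrame,
    enriched_in: set[str] | list[str],
    fold: float = 8.0,
    n_sets: int = 10,
    base_rate: float = 0.05,
    interval_halfwidth: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Named BED region sets, the first enriched for ``enriched_in`` probes.

    The enriched set covers probes from ``enriched_in`` at ``fold`` times
    the background coverage rate; every other set covers probes uniformly at
    the background rate.  Output intervals are 0-based half-open.
    """
    if fold < 1:
        raise MethlineageError("fold must be >= 1")
    if n_sets == 0:
        return {}
    manifest = validate_manifest(manifest)
    enriched_in = set(enriched_in)
    if not enriched_in <= set(manifest["probe_id"]):
        raise MethlineageError("enriched_in must be a subset of manifest probes")

    rng = np.random.default_rng(seed)
    probe_ids = manifest["probe_id"].to_numpy()
    is_target = np.isin(probe_ids, list(enriched_in))
    out: dict[str, pd.DataFrame] = {}
    for i in range(n_sets):
        name = "enriched_set" if i == 0 else f"random_set_{i}"
        rate = np.full(len(probe_ids), base_rate)
        if i == 0:
            rate[is_target] = min(1.0, fold * base_rate)
        take = rng.random(len(probe_ids)) < rate
        sub = manifest.loc[take]
        start = np.maximum(sub["pos"].to_numpy() - 1 - interval_halfwidth, 0)
        end = sub["pos"].to_numpy() - 1 + interval_halfwidth + 1
        out[name] = pd.DataFrame(
            {"chrom": sub["chrom"].to_numpy(), "start": start, "end": end, "name": name}
        )
    return out
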