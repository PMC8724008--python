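"""Genomic-feature annotation with bootstrap CIs, and region-set enrichment.

Annotation summarises a probe set as proportions over the CpG-island
relation and gene-feature category families, with percentile bootstrap
confidence intervals obtained by resampling the probe set with replacement.

Region-set enrichment follows the locus-overlap-analysis logic: the query
probe set is intersected with each region set at probe level (a probe is
"in" a set when its coordinate falls inside any interval), a 2x2 table is
built against a background universe of probes, the p-value is a two-sided
Fisher exact test, and the effect size is the sample (cross-product) odds
ratio with a Haldane–Anscombe +0.5 correction when any cell is zero and a
Woolf log-scale 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .matrix import FEATURE_CATEGORIES, ISLAND_CATEGORIES, MethlineageError, validate_manifest

CATEGORY_FAMILIES = {"island_relation": ISLAND_CATEGORIES, "gene_feature": FEATURE_CATEGORIES}


@dataclass
class FeatureProportions:
    """Per-family category proportions of a probe set, optionally with
    bootstrap CI bounds and the all-array reference proportions."""

    families: dict[str, pd.DataFrame] = field(default_factory=dict)
    reference: dict[str, pd.Series] = field(default_factory=dict)
    n_probes: int = 0


def _proportions(categories: pd.Series, family: str) -> pd.Series:
    levels = CATEGORY_FAMILIES[family]
    counts = categories.value_counts().reindex(levels, fill_value=0)
    return counts / counts.sum()


def annotate_probe_set(probe_ids, manifest: pd.DataFrame) -> FeatureProportions:
    """Point-estimate category proportions of a probe set plus the
    reference distribution over the whole array."""
    manifest = validate_manifest(manifest)
    probe_ids = list(probe_ids)
    if not probe_ids:
        raise MethlineageError("empty probe set")
    missing = set(probe_ids) - set(manifest.index)
    if missing:
        raise MethlineageError(f"probes not in manifest: {sorted(missing)[:3]} ...")
    sub = manifest.loc[probe_ids]
    out = FeatureProportions(n_probes=len(probe_ids))
    for family in CATEGORY_FAMILIES:
        point = _proportions(sub[family], family)
        out.families[family] = pd.DataFrame({"point": point, "ci_low": point, "ci_high": point})
        out.reference[family] = _proportions(manifest[family], family)
    return out


def bootstrap_proportions(
    probe_ids, manifest: pd.DataFrame, n_iter: int = 1000, ci_level: float = 0.95, seed: int = 0
) -> FeatureProportions:
    """Percentile bootstrap CIs for the category proportions of a probe set.

    Resamples the probe set with replacement ``n_iter`` times; bounds are
    the (1 - ci_level)/2 and 1 - (1 - ci_level)/2 percentiles of each
    category proportion.  Deterministic for a fixed seed.
    """
    if n_iter < 1:
        raise MethlineageError("n_iter must be >= 1")
    result = annotate_probe_set(probe_ids, manifest)
    manifest = validate_manifest(manifest)
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0

    for family, levels in CATEGORY_FAMILIES.items():
        codes = pd.Categorical(manifest.loc[probe_ids, family], categories=levels).codes
        boot = np.empty((n_iter, len(levels)))
        for i in range(n_iter):
            draw = codes[rng.integers(0, n, size=n)]
            boot[i] = np.bincount(draw, minlength=len(levels)) / n
        lo = np.quantile(boot, alpha, axis=0)
        hi = np.quantile(boot, 1.0 - alpha, axis=0)
        fam = result.families[family]
        fam["ci_low"] = np.minimum(lo, fam["point"].to_numpy())
        fam["ci_high"] = np.maximum(hi, fam["point"].to_numpy())
    return result


# ---------------------------------------------------------------------------
# region-set enrichment
# ---------------------------------------------------------------------------

def probes_in_regions(manifest: pd.DataFrame, intervals: pd.DataFrame) -> set[str]:
    """Probe ids whose (1-based) coordinate lies inside any interval of a
    BED table (0-based half-open): probe at pos p overlaps [start, end)
    when start <= p - 1 < end."""
    manifest = validate_manifest(manifest)
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
    hits = set()
    for probe_id, chrom, pos in manifest[["probe_id", "chrom", "pos"]].itertuples(index=False):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(pos - 1):
            hits.add(probe_id)
    return hits


def _haldane_or_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Sample odds ratio with Haldane–Anscombe correction and Woolf 95% CI."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a2, b2, c2, d2 = cells
    odds = (a2 * d2) / (b2 * c2)
    log_se = float(np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2))
    lo = float(odds * np.exp(-1.959963984540054 * log_se))
    hi = float(odds * np.exp(1.959963984540054 * log_se))
    return float(odds), lo, hi


def region_set_enrichment(
    query_probe_ids,
    universe_probe_ids,
    region_sets: dict[str, object],
    manifest: pd.DataFrame | None = None,
    direction: str = "hypo_query",
) -> pd.DataFrame:
    """Fisher-exact enrichment of a query probe set in named region sets.

    ``region_sets`` maps a name either to a BED DataFrame (columns chrom,
    start, end; requires ``manifest``) or directly to an iterable of probe
    ids.  The 2x2 table per set is (a, b, c, d) = (query in set, query not
    in set, background-only in set, rest), where background-only is the
    universe minus the query.  Empty sets are reported with p = 1 and an
    ``empty_set`` flag.
    """
    query = set(query_probe_ids)
    universe = set(universe_probe_ids)
    if not query <= universe:
        raise MethlineageError("query must be a subset of the universe")
    background = universe - query

    rows = []
    for name, spec in region_sets.items():
        if isinstance(spec, pd.DataFrame) and {"start", "end"} <= set(spec.columns):
            if manifest is None:
                raise MethlineageError("manifest required to overlap BED region sets")
            members = probes_in_regions(manifest, spec) & universe
        else:
            members = set(spec) & universe
        a = len(query & members)
        b = len(query) - a
        c = len(background & members)
        d = len(background) - c
        if a + c == 0:
            rows.append(
                {
                    "set_name": name,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": 1.0,
                    "direction": direction,
                    "empty_set": True,
                }
            )
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds, lo, hi = _haldane_or_ci(a, b, c, d)
        rows.append(
            {
                "set_name": name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": float(p),
                "direction": direction,
                "empty_set": False,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True) if len(out) else out
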