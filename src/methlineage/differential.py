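"""Differential methylation: moderated-t DMP calling and window-based DMRs.

DMPs are called on M-values with an empirical-Bayes moderated t-statistic:
per-probe residual variances are shrunk toward a prior variance ``s0_sq``
with ``d0`` prior degrees of freedom, both estimated by moment matching on
the log residual variances (Smyth-style digamma/trigamma inversion).  The
reported effect size ``delta_m`` is the difference of group means on the
M-value scale (the "log2 fold change" of the M-scale linear model);
``delta_beta`` is the difference of group-mean betas.

DMRs chain nearby significant CpGs on each chromosome (consecutive gaps at
most ``max_gap`` bp, at least ``min_cpgs`` members) and combine their
per-probe evidence with a signed Stouffer statistic.  The region effect
size ``mean_delta_beta`` is the difference of group-mean betas averaged
over member CpGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import TSS_FEATURES, MethlineageError, MethylationMatrix, validate_manifest

P_FLOOR = 1e-300  # p-values floored before the z transform


@dataclass(frozen=True)
class EbPrior:
    """Empirical-Bayes variance prior: d0 may be 0 (no shrinkage, ordinary
    pooled t), finite, or infinite (fully shared variance)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise MethlineageError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise MethlineageError("s0_sq must be positive")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise MethlineageError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def estimate_prior(s_sq: np.ndarray, df_resid: int) -> EbPrior:
    """Moment-match (d0, s0_sq) to the observed log residual variances.

    Uses the fact that log(s^2) for chi-square-distributed s^2 has known
    digamma mean and trigamma variance.  Falls back to d0 = inf when the
    excess variance of log(s^2) is non-positive (variances more concordant
    than a finite-d0 model allows).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() == 0:
        raise MethlineageError("need at least one positive residual variance for the prior")
    if ok.sum() == 1:
        # no spread to estimate d0 from: fully shared variance
        return EbPrior(d0=math.inf, s0_sq=float(s_sq[ok][0]))
    z = np.log(s_sq[ok])
    e = z - special.digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if e_var <= 0:
        return EbPrior(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EbPrior(d0=d0, s0_sq=s0_sq)


def fit_moderated_t(
    m_matrix: MethylationMatrix,
    group_a_ids: list[str],
    group_b_ids: list[str],
    beta_matrix: MethylationMatrix | None = None,
    prior: EbPrior | None = None,
) -> tuple[pd.DataFrame, EbPrior]:
    """Per-probe moderated two-group comparison on the M-value scale.

    Returns a stats table (delta_m, moderated_t, df_total, p_value, bh_q,
    delta_beta, direction) and the estimated (or supplied) prior.  Passing
    ``prior`` overrides estimation, e.g. ``EbPrior(0, 1)`` recovers the
    ordinary pooled two-sample t.
    """
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise MethlineageError("each group needs >= 2 samples")
    vals = m_matrix.values
    missing = [s for s in list(group_a_ids) + list(group_b_ids) if s not in vals.columns]
    if missing:
        raise MethlineageError(f"samples not in matrix: {missing}")

    a = vals[list(group_a_ids)].to_numpy()
    b = vals[list(group_b_ids)].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    d = n_a + n_b - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta_m = mean_a - mean_b
    rss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = rss / d

    if prior is None:
        if len(s_sq) < 2:
            raise MethlineageError("need >= 2 probes to estimate the prior")
        prior = estimate_prior(s_sq, d)

    if prior.d0 == 0:
        post_var, df_total = s_sq, float(d)
    elif math.isinf(prior.d0):
        post_var, df_total = np.full_like(s_sq, prior.s0_sq), math.inf
    else:
        post_var = (prior.d0 * prior.s0_sq + d * s_sq) / (prior.d0 + d)
        df_total = prior.d0 + d

    se = np.sqrt(post_var * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta_m / np.where(se > 0, se, 1.0), np.sign(delta_m) * np.inf)
    t = np.where((se == 0) & (delta_m == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "delta_m": delta_m,
            "moderated_t": t,
            "df_total": df_total,
            "p_value": p,
            "bh_q": q,
            "s_sq": s_sq,
            "post_var": post_var,
        },
        index=vals.index,
    )
    if beta_matrix is not None:
        bv = beta_matrix.values.loc[vals.index]
        out["delta_beta"] = bv[list(group_a_ids)].mean(axis=1) - bv[list(group_b_ids)].mean(axis=1)
    else:
        out["delta_beta"] = np.nan
    db = out["delta_beta"].where(out["delta_beta"].notna(), out["delta_m"])
    out["direction"] = np.where(db < 0, "hypo_in_A", "hyper_in_A")
    return out, prior


def call_dmps(stats_table: pd.DataFrame, p_cut: float = 0.01, delta_m_cut: float = 2.0) -> pd.DataFrame:
    """Retain probes with p <= p_cut and |delta_m| >= delta_m_cut."""
    keep = (stats_table["p_value"] <= p_cut) & (stats_table["delta_m"].abs() >= delta_m_cut)
    return stats_table.loc[keep].copy()


def overlap_dmp_sets(sets: dict[str, set]) -> dict[str, int]:
    """Exact Venn-region counts for >= 2 named probe-id sets.

    Keys are '&'-joined sorted member names (e.g. ``"A&B"``); each element
    of the union is counted in exactly one region, so the counts sum to the
    union size.
    """
    if len(sets) < 2:
        raise MethlineageError("need at least two sets")
    names = sorted(sets)
    sets = {k: set(v) for k, v in sets.items()}
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            counts["&".join(combo)] = len(inside - outside)
    return counts


def call_dmrs(
    stats_table: pd.DataFrame,
    beta_matrix: MethylationMatrix,
    manifest: pd.DataFrame,
    group_a_ids: list[str],
    group_b_ids: list[str],
    max_gap: int = 1000,
    min_cpgs: int = 3,
    p_cut: float = 0.01,
    probe_p_cut: float | None = None,
) -> pd.DataFrame:
    """Chain significant CpGs into regions and score them with Stouffer's z.

    Probes with per-probe p <= ``probe_p_cut`` (defaults to ``p_cut``) are
    sorted per chromosome and chained while consecutive gaps are at most
    ``max_gap`` bp.  Chains with fewer than ``min_cpgs`` members are
    dropped.  Member evidence is combined as signed z-scores
    ``z_i = sign(delta_m_i) * Phi^-1(1 - p_i / 2)``, ``combined_z = sum(z_i)
    / sqrt(k)``, with a two-sided normal region p; regions are kept at
    region p <= ``p_cut``.
    """
    probe_p_cut = p_cut if probe_p_cut is None else probe_p_cut
    manifest = validate_manifest(manifest)
    missing = stats_table.index.difference(manifest.index)
    if len(missing):
        raise MethlineageError(f"manifest missing positions for: {list(missing[:3])} ...")

    sig = stats_table.loc[stats_table["p_value"] <= probe_p_cut].copy()
    if sig.empty:
        return _empty_dmr_table()
    ann = manifest.loc[sig.index]
    sig["chrom"] = ann["chrom"]
    sig["pos"] = ann["pos"]
    sig["is_tss"] = ann["gene_feature"].isin(TSS_FEATURES)
    sig = sig.sort_values(["chrom", "pos"], kind="mergesort")

    bmeans = beta_matrix.values.loc[sig.index]
    sig["_delta_beta"] = bmeans[list(group_a_ids)].mean(axis=1) - bmeans[list(group_b_ids)].mean(axis=1)

    p_floored = np.maximum(sig["p_value"].to_numpy(), P_FLOOR)
    sig["_z"] = np.sign(sig["delta_m"].to_numpy()) * stats.norm.isf(p_floored / 2.0)

    new_chrom = sig["chrom"].ne(sig["chrom"].shift())
    gap_break = sig["pos"].diff().gt(max_gap)
    cluster = (new_chrom | gap_break).cumsum()

    rows = []
    for _, grp in sig.groupby(cluster, sort=True):
        k = len(grp)
        if k < min_cpgs:
            continue
        combined_z = float(grp["_z"].sum()) / math.sqrt(k)
        region_p = 2.0 * stats.norm.sf(abs(combined_z))
        if region_p > p_cut:
            continue
        rows.append(
            {
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["pos"].min()),
                "end": int(grp["pos"].max()),
                "n_cpgs": k,
                "combined_z": combined_z,
                "p_value": region_p,
                "mean_delta_beta": float(grp["_delta_beta"].mean()),
                "tss_within_2000bp": bool(grp["is_tss"].any()),
                "probe_ids": ",".join(grp.index),
            }
        )
    return pd.DataFrame(rows) if rows else _empty_dmr_table()


def _empty_dmr_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom",
            "start",
            "end",
            "n_cpgs",
            "combined_z",
            "p_value",
            "mean_delta_beta",
            "tss_within_2000bp",
            "probe_ids",
        ]
    )


def filter_dmrs_by_effect(
    dmrs: pd.DataFrame, abs_delta_beta_cuts: list[float] = (0.1, 0.2, 0.3, 0.4, 0.5)
) -> pd.DataFrame:
    """Count regions surviving each |mean_delta_beta| cut, split by sign of
    the effect (hypo/hyper in group A) and TSS proximity."""
    rows = []
    for cut in abs_delta_beta_cuts:
        kept = dmrs.loc[dmrs["mean_delta_beta"].abs() >= cut] if len(dmrs) else dmrs
        hypo = kept.loc[kept["mean_delta_beta"] < 0] if len(kept) else kept
        hyper = kept.loc[kept["mean_delta_beta"] >= 0] if len(kept) else kept
        rows.append(
            {
                "abs_delta_beta_cut": cut,
                "n_total": len(kept),
                "n_hypo": len(hypo),
                "n_hyper": len(hyper),
                "n_hypo_tss": int(hypo["tss_within_2000bp"].sum()) if len(hypo) else 0,
                "n_hyper_tss": int(hyper["tss_within_2000bp"].sum()) if len(hyper) else 0,
            }
        )
    return pd.DataFrame(rows)


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """DMRs as BED intervals (1-based inclusive -> 0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": [f"dmr_{i + 1}" for i in range(len(dmrs))],
        }
    )
    return out
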