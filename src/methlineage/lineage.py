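"""PCA-derived lineage/program scores.

The procedure: fit a PCA on (optionally scaled) beta values of a reference
cohort; rank the CpG loadings of a chosen component; keep only the CpGs on
the steep tails of the rank curve (where most of the component's signal
concentrates); form a raw score per sample as the signed, loading-weighted
sum of those CpGs' betas; and Z-score normalise against the reference
cohort.  The stored model projects onto any new beta matrix containing the
selected CpGs.

Component choice is deliberately user-driven (components are identified by
inspecting group separation); :func:`component_group_separation` reports a
one-way ANOVA F statistic per component to guide that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MethlineageError, MethylationMatrix


@dataclass
class PcaModel:
    """PCA of samples in probe space: per-probe centering/scaling, an
    orthonormal loading matrix (probes x components) and sample scores."""

    center: pd.Series
    scale_: pd.Series
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    sample_scores: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ScoreModel:
    """A projectable lineage/program score.

    ``selected`` holds (probe_id, loading) pairs; the raw score of a sample
    is ``sign * sum_i loading_i * beta_i`` and the reported score is
    ``(raw - norm_mean) / norm_sd`` with the normalisation fitted on the
    reference cohort.  ``reference_beta_mean`` supplies imputation values
    for a tolerated fraction of missing probes.
    """

    component_index: int
    selected: pd.Series  # index probe_id, values loadings
    sign: int
    norm_mean: float
    norm_sd: float
    name: str = "custom"
    reference_beta_mean: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if len(self.selected) < 1:
            raise MethlineageError("score model needs >= 1 selected CpG")
        if self.sign not in (-1, 1):
            raise MethlineageError("sign must be -1 or +1")
        if self.norm_sd <= 0:
            raise MethlineageError("norm_sd must be positive")


def fit_pca(beta_matrix: MethylationMatrix, scale: bool = True) -> PcaModel:
    """Centered (and optionally unit-variance) PCA via SVD.

    Zero-variance probes are dropped with a warning when ``scale`` is on
    (they carry no signal and would divide by zero).  The sign of each
    component is fixed by forcing its largest-|loading| entry positive so
    loadings are comparable across runs.
    """
    if beta_matrix.n_samples < 2:
        raise MethlineageError("PCA needs >= 2 samples")
    if beta_matrix.n_probes < 2:
        raise MethlineageError("PCA needs >= 2 probes")
    X = beta_matrix.values.T  # samples x probes
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scale:
        keep = sd > 0
        if not keep.all():
            import warnings

            warnings.warn(f"dropping {(~keep).sum()} zero-variance probes before scaled PCA")
            X, center, sd = X.loc[:, keep], center[keep], sd[keep]
        scale_vec = sd
    else:
        scale_vec = pd.Series(1.0, index=center.index)
    Xc = (X - center) / scale_vec

    u, s, vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    n = X.shape[0]
    k = min(n, Xc.shape[1])
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(vt.T[:, :k], index=Xc.columns, columns=comp_names)
    scores = pd.DataFrame(u[:, :k] * s[:k], index=X.index, columns=comp_names)
    # deterministic sign: largest-|loading| entry of each component positive
    for c in comp_names:
        col = loadings[c]
        if col.iloc[int(np.argmax(np.abs(col.to_numpy())))] < 0:
            loadings[c] = -col
            scores[c] = -scores[c]
    ev = s[:k] ** 2 / (n - 1)
    return PcaModel(
        center=center,
        scale_=scale_vec,
        loadings=loadings,
        explained_variance=ev,
        explained_variance_ratio=ev / ev.sum(),
        sample_scores=scores,
    )


def transform_pca(model: PcaModel, beta_matrix: MethylationMatrix) -> pd.DataFrame:
    """Project new samples into the fitted component space."""
    X = beta_matrix.values.loc[model.center.index].T
    Xc = (X - model.center) / model.scale_
    return pd.DataFrame(
        Xc.to_numpy() @ model.loadings.to_numpy(), index=X.index, columns=model.loadings.columns
    )


def component_group_separation(model: PcaModel, group_labels: dict[str, str]) -> pd.Series:
    """One-way ANOVA F of sample scores across groups, per component.

    A selection aid: a large F flags components whose scores stratify the
    labelled groups.
    """
    labels = pd.Series({s: group_labels.get(s, "unknown") for s in model.sample_scores.index})
    out = {}
    for c in model.sample_scores.columns:
        groups = [model.sample_scores.loc[labels == g, c].to_numpy() for g in labels.unique()]
        groups = [g for g in groups if len(g) > 0]
        out[c] = stats.f_oneway(*groups).statistic if len(groups) > 1 else np.nan
    return pd.Series(out)


def axis_loadings(
    model: PcaModel,
    group_labels: dict[str, str],
    positive_value: str,
    candidates: list[int] | None = None,
    ridge: float = 1e-8,
) -> pd.Series:
    """Loading vector for a labelled biological axis.

    Returns the unit direction within the span of the candidate components
    (default: the first ``min(6, k)``) that maximises the Fisher
    discriminant of sample scores between the two sides of the axis —
    i.e. the axis-associated component, refined against rotation.  When one
    principal component carries the axis alone this reduces to (a close
    approximation of) that component; when two components have nearly equal
    variance the plain eigenvectors can mix the axes arbitrarily, and the
    discriminant direction recovers the axis regardless.

    The result is a probe-loading Series with unit norm, usable exactly
    like a single component's loadings (rank, knee-select, score).
    """
    if candidates is None:
        candidates = list(range(1, min(6, model.n_components) + 1))
    cols = [f"PC{i}" for i in candidates]
    missing = [c for c in cols if c not in model.sample_scores.columns]
    if missing:
        raise MethlineageError(f"no such components: {missing}")
    scores = model.sample_scores[cols]
    y = np.array([group_labels.get(s, "unknown") == positive_value for s in scores.index])
    if y.all() or not y.any():
        raise MethlineageError("axis needs samples on both sides")
    pos = scores.loc[y].to_numpy()
    neg = scores.loc[~y].to_numpy()
    within = np.cov(pos, rowvar=False) * (len(pos) - 1) + np.cov(neg, rowvar=False) * (len(neg) - 1)
    within = within / (len(y) - 2) + ridge * np.eye(len(cols))
    w = np.linalg.solve(within, pos.mean(axis=0) - neg.mean(axis=0))
    w = w / np.linalg.norm(w)
    loadings = pd.Series(model.loadings[cols].to_numpy() @ w, index=model.loadings.index)
    # same sign convention as single components
    if loadings.iloc[int(np.argmax(np.abs(loadings.to_numpy())))] < 0:
        loadings = -loadings
    return loadings


def rank_loadings(model: PcaModel, component_index: int) -> pd.Series:
    """Loadings of one component sorted ascending; ties break on probe_id.

    ``component_index`` is 1-based ("PC2" is 2).
    """
    name = f"PC{component_index}"
    if name not in model.loadings.columns:
        raise MethlineageError(f"no such component: {name}")
    return rank_loading_series(model.loadings[name])


def rank_loading_series(loadings: pd.Series) -> pd.Series:
    """Sort any probe-loading vector ascending, ties broken by probe_id."""
    order = sorted(loadings.index, key=lambda p: (loadings[p], p))
    return loadings.loc[order]


def _knee_point(values: np.ndarray) -> tuple[int, float]:
    """Max-chord-distance point of a descending curve.

    Both axes are rescaled to [0, 1] so rank and loading units are
    commensurate; the chord then runs from (0, 1) to (1, 0) and the signed
    distance of point (x, y) is proportional to 1 - x - y (positive below
    the chord, i.e. where the curve is convex).  Returns (index,
    signed distance at the knee); raises when the curve is flat.
    """
    n = len(values)
    y_span = float(values[0] - values[-1])
    if y_span <= 1e-15 * max(1.0, abs(float(values[0]))):
        raise MethlineageError("no curvature in the loading rank curve")
    x = np.arange(n, dtype=float) / (n - 1)
    y = (values.astype(float) - values[-1]) / y_span
    signed = 1.0 - x - y
    i = int(np.argmax(np.abs(signed)))
    return i, float(signed[i])


def _knee_tail_cut(values: np.ndarray) -> int:
    """Iterated knee for one tail of a loading rank curve.

    A single max-chord-distance knee on a curve with a short steep head and
    a very long shallow tail lands inside the tail (the chord is dominated
    by the flat stretch), so the knee is re-applied to the retained head,
    zooming in on the steep part.  While the head still contains the drop
    between informative and background loadings, its knee point lies below
    the chord (the segment is convex there); once the knee point flips
    above the chord the remaining head is a shallow plateau, and that cut
    is accepted as the boundary.  Deterministic; raises when the initial
    curve has no curvature.
    """
    seg = np.asarray(values, dtype=float)
    first = True
    while True:
        if len(seg) < 3:
            return len(seg)  # too short for a knee: keep the whole segment
        try:
            cut, signed_dist = _knee_point(seg)
        except MethlineageError:
            if first:
                raise
            return len(seg)  # zoomed segment is flat: keep all of it
        # a segment whose strongest deviation from the chord is within the
        # order-statistic wiggle of a homogeneous sample has no knee left
        flat_tol = max(0.1, 1.5 / math.sqrt(len(seg)))
        if not first and abs(signed_dist) < flat_tol:
            return len(seg)
        if signed_dist < 0 or cut < 3:
            return cut
        seg = seg[:cut]
        first = False


def select_informative_cpgs(
    ranked: pd.Series, method: str = "knee", k: int | None = None, tau: float | None = None
) -> pd.Series:
    """Pick the high-|loading| CpGs of a ranked loading vector.

    methods:
      * ``knee`` — on each tail (negative and positive loadings)
        independently, order by |loading| descending and keep points before
        the knee of the |loading|-vs-rank curve (iterated max-chord-distance,
        see :func:`_knee_tail_cut`).
      * ``top_k`` — the ``k`` largest |loading| CpGs.
      * ``abs_threshold`` — CpGs with |loading| >= ``tau``.
    """
    if ranked.empty:
        raise MethlineageError("ranked loadings are empty")
    if method == "top_k":
        if k is None or k > len(ranked):
            raise MethlineageError("top_k needs k <= number of probes")
        order = ranked.abs().sort_values(ascending=False, kind="mergesort")
        return ranked.loc[order.index[:k]]
    if method == "abs_threshold":
        if tau is None:
            raise MethlineageError("abs_threshold needs tau")
        sel = ranked[ranked.abs() >= tau]
        if sel.empty:
            raise MethlineageError(f"tau={tau} excludes every CpG; try a smaller tau")
        return sel
    if method != "knee":
        raise MethlineageError(f"unknown selection method {method!r}")

    picked = []
    for tail in (ranked[ranked < 0], ranked[ranked > 0]):
        if tail.empty:
            continue
        tail_desc = tail.abs().sort_values(ascending=False, kind="mergesort")
        try:
            cut = _knee_tail_cut(tail_desc.to_numpy())
        except MethlineageError:
            continue  # flat tail contributes nothing
        picked.extend(tail_desc.index[:cut])
    if not picked:
        raise MethlineageError("no curvature in the loading rank curve")
    return ranked.loc[[p for p in ranked.index if p in set(picked)]]


def build_score_model(
    model: PcaModel,
    component_index: int,
    selected: pd.Series,
    sign: int,
    reference_matrix: MethylationMatrix,
    name: str = "custom",
) -> ScoreModel:
    """Freeze a score: selected loadings, direction sign, and Z-normalisation
    parameters fitted on the reference cohort (sample SD, ddof=1)."""
    missing = selected.index.difference(reference_matrix.probe_ids)
    if len(missing):
        raise MethlineageError(f"selected probes missing from reference: {list(missing[:3])} ...")
    betas = reference_matrix.values.loc[selected.index]
    raw = sign * (selected.to_numpy()[:, None] * betas.to_numpy()).sum(axis=0)
    norm_mean = float(raw.mean())
    norm_sd = float(raw.std(ddof=1))
    if norm_sd <= 0:
        raise MethlineageError("reference raw scores are constant; cannot Z-normalise")
    return ScoreModel(
        component_index=component_index,
        selected=selected.copy(),
        sign=sign,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
        name=name,
        reference_beta_mean=betas.mean(axis=1),
    )


def orient_sign(
    model: PcaModel,
    component_index: int,
    selected: pd.Series,
    reference_matrix: MethylationMatrix,
    positive_group_samples: list[str],
) -> int:
    """Choose the sign that puts the stated positive group on the high side
    (the manual direction adjustment made when defining a score)."""
    betas = reference_matrix.values.loc[selected.index]
    raw = pd.Series(
        (selected.to_numpy()[:, None] * betas.to_numpy()).sum(axis=0), index=reference_matrix.sample_ids
    )
    pos = raw.loc[list(positive_group_samples)].mean()
    rest = raw.drop(list(positive_group_samples)).mean()
    return 1 if pos >= rest else -1


def score_samples(
    score_model: ScoreModel, beta_matrix: MethylationMatrix, max_missing_fraction: float = 0.1
) -> pd.Series:
    """Project a score model onto samples: Z = (raw - norm_mean) / norm_sd.

    Up to ``max_missing_fraction`` of the selected probes may be absent;
    they are imputed with the reference mean beta (with a warning).  Probe
    order in the input is irrelevant.
    """
    sel = score_model.selected
    present = sel.index.intersection(beta_matrix.probe_ids)
    missing = sel.index.difference(present)
    if len(missing) / len(sel) > max_missing_fraction:
        raise MethlineageError(
            f"{len(missing)}/{len(sel)} selected probes missing (> {max_missing_fraction:.0%})"
        )
    betas = beta_matrix.values.reindex(sel.index)
    if len(missing):
        import warnings

        warnings.warn(f"imputing {len(missing)} missing probes with reference mean beta")
        fill = score_model.reference_beta_mean.reindex(sel.index)
        betas = betas.apply(lambda col: col.fillna(fill))
    raw = score_model.sign * (sel.to_numpy()[:, None] * betas.to_numpy()).sum(axis=0)
    z = (raw - score_model.norm_mean) / score_model.norm_sd
    return pd.Series(z, index=beta_matrix.sample_ids, name=score_model.name)


# -- serialization -----------------------------------------------------------

def save_score_model(model: ScoreModel, path) -> None:
    """TSV with a ``#key=value`` header block then (probe_id, loading,
    reference_beta_mean) rows."""
    with open(path, "w") as fh:
        fh.write(f"#name={model.name}\n")
        fh.write(f"#component_index={model.component_index}\n")
        fh.write(f"#sign={model.sign}\n")
        fh.write(f"#norm_mean={float(model.norm_mean)!r}\n")
        fh.write(f"#norm_sd={float(model.norm_sd)!r}\n")
        fh.write("probe_id\tloading\treference_beta_mean\n")
        for p in model.selected.index:
            ref = float(model.reference_beta_mean.get(p, float("nan")))
            fh.write(f"{p}\t{float(model.selected[p])!r}\t{ref!r}\n")


def load_score_model(path) -> ScoreModel:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
            elif line.strip() and not line.startswith("probe_id"):
                p, loading, ref = line.rstrip("\n").split("\t")
                rows.append((p, float(loading), float(ref)))
    sel = pd.Series({p: ld for p, ld, _ in rows})
    ref = pd.Series({p: r for p, _, r in rows})
    return ScoreModel(
        component_index=int(meta["component_index"]),
        selected=sel,
        sign=int(meta["sign"]),
        norm_mean=float(meta["norm_mean"]),
        norm_sd=float(meta["norm_sd"]),
        name=meta.get("name", "custom"),
        reference_beta_mean=ref,
    )
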