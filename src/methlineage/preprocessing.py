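"""Beta/M-value computation and probe-level quality filtering.

Beta values are the standard array methylation fraction
``beta = M / (M + U + offset)`` with methylated signal M, unmethylated
signal U and a stabilising offset (default 100).  M-values are the logit2
transform ``log2(beta / (1 - beta))``, the variance-stabilised scale used
for differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MethlineageError, MethylationMatrix, validate_manifest

DEFAULT_OFFSET = 100.0
DEFAULT_LOGIT_EPS = 1e-6


def compute_beta(meth_signal, unmeth_signal, offset: float = DEFAULT_OFFSET):
    """beta = M / (M + U + offset), elementwise over scalars or arrays.

    Raises on negative signals, naming the offending probe/sample when the
    inputs are labelled DataFrames.
    """
    if offset <= 0:
        raise MethlineageError("offset must be positive")
    meth = np.asarray(meth_signal, dtype=float) if not isinstance(meth_signal, pd.DataFrame) else meth_signal
    unmeth = (
        np.asarray(unmeth_signal, dtype=float) if not isinstance(unmeth_signal, pd.DataFrame) else unmeth_signal
    )
    for name, arr in (("methylated", meth), ("unmethylated", unmeth)):
        vals = arr.to_numpy() if isinstance(arr, pd.DataFrame) else arr
        if vals.size and np.nanmin(vals) < 0:
            if isinstance(arr, pd.DataFrame):
                r, c = np.argwhere(arr.to_numpy() < 0)[0]
                raise MethlineageError(
                    f"negative {name} signal at probe {arr.index[r]!r}, sample {arr.columns[c]!r}"
                )
            raise MethlineageError(f"negative {name} signal")
    return meth / (meth + unmeth + offset)


def beta_to_m(beta, eps: float = DEFAULT_LOGIT_EPS):
    """logit2 transform; betas are clipped to [eps, 1 - eps] first."""
    arr = np.asarray(beta, dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise MethlineageError("beta values must lie in [0, 1]")
    clipped = np.clip(beta, eps, 1 - eps)
    return np.log2(clipped / (1 - clipped))


def m_to_beta(mvalue):
    """Inverse of :func:`beta_to_m`: beta = 2^m / (2^m + 1)."""
    m = np.asarray(mvalue, dtype=float)
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    out[~pos] = np.exp2(m[~pos]) / (1.0 + np.exp2(m[~pos]))
    if np.isscalar(mvalue) or np.ndim(mvalue) == 0:
        return float(out)
    if isinstance(mvalue, pd.DataFrame):
        return pd.DataFrame(out, index=mvalue.index, columns=mvalue.columns)
    return out


def matrix_to_m(matrix: MethylationMatrix, eps: float = DEFAULT_LOGIT_EPS) -> MethylationMatrix:
    """Convert a beta-scale matrix to M-values (no-op if already M-scale)."""
    if matrix.scale == "mvalue":
        return matrix
    vals = pd.DataFrame(
        beta_to_m(matrix.values.to_numpy(), eps=eps), index=matrix.values.index, columns=matrix.values.columns
    )
    return MethylationMatrix(vals, "mvalue", dict(matrix.group_labels))


@dataclass
class FilterLog:
    """Probe counts removed per filter, attributed to the first filter that
    removes each probe (detection-p, sex chromosome, cross-reactive, SNP)."""

    removed: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def __str__(self) -> str:
        parts = ", ".join(f"{k}={v}" for k, v in self.removed.items())
        return f"filtered {self.n_input} -> {self.n_output} probes ({parts})"


def filter_probes(
    matrix: MethylationMatrix,
    detection_p: pd.DataFrame,
    manifest: pd.DataFrame,
    p_cut: float = 0.01,
    drop_sex: bool = True,
    drop_cross_reactive: bool = True,
    drop_snp: bool = True,
) -> tuple[MethylationMatrix, FilterLog]:
    """Apply the four standard probe filters.

    A probe is dropped when its detection p-value exceeds ``p_cut`` in at
    least one sample, or when it is flagged as sex-chromosomal,
    cross-reactive, or SNP-overlapping in the manifest.  The final probe set
    is the intersection of the individual pass sets and therefore does not
    depend on the attribution order used for the log.
    """
    manifest = validate_manifest(manifest)
    missing = matrix.probe_ids.difference(manifest.index)
    if len(missing):
        raise MethlineageError(f"probes absent from manifest: {list(missing[:3])} ...")
    det = detection_p.loc[matrix.probe_ids, matrix.sample_ids]
    ann = manifest.loc[matrix.probe_ids]

    fail_det = (det > p_cut).any(axis=1).to_numpy()
    fail_sex = ann["sex_chrom"].to_numpy() & drop_sex
    fail_cross = ann["cross_reactive"].to_numpy() & drop_cross_reactive
    fail_snp = ann["snp_flagged"].to_numpy() & drop_snp

    log = FilterLog(n_input=matrix.n_probes)
    removed = np.zeros(matrix.n_probes, dtype=bool)
    for name, fail in (
        ("detection_p", fail_det),
        ("sex_chrom", fail_sex),
        ("cross_reactive", fail_cross),
        ("snp", fail_snp),
    ):
        newly = fail & ~removed
        log.removed[name] = int(newly.sum())
        removed |= fail
    keep = matrix.probe_ids[~removed]
    log.n_output = len(keep)
    return matrix.subset_probes(keep), log
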