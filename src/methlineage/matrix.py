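"""Core containers: methylation matrices and probe manifests.

A :class:`MethylationMatrix` holds a probes x samples value matrix on either
the beta scale (methylation fractions in [0, 1]) or the M-value scale
(logit2-transformed betas), plus a group label per sample.  The probe
manifest is a plain :class:`pandas.DataFrame` with one row per probe and the
columns listed in :data:`MANIFEST_COLUMNS`; helper functions validate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: CpG-island relation categories (distance classes around CpG islands).
ISLAND_CATEGORIES = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]

#: Gene-feature categories (position of the probe relative to gene models).
FEATURE_CATEGORIES = ["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "ExonBnd", "3UTR", "IGR"]

#: Gene features counted as promoter-proximal (within 2 kb upstream of a TSS).
TSS_FEATURES = {"TSS1500", "TSS200"}

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "island_relation",
    "gene_feature",
    "gene_symbol",
    "sex_chrom",
    "snp_flagged",
    "cross_reactive",
]


class MethlineageError(ValueError):
    """Base class for input-contract violations."""


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants and return the manifest indexed by probe_id."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise MethlineageError(f"manifest missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        dup = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise MethlineageError(f"duplicate probe_id in manifest: {dup!r}")
    if (manifest["pos"] < 1).any():
        raise MethlineageError("manifest positions must be >= 1 (1-based)")
    bad_island = set(manifest["island_relation"]) - set(ISLAND_CATEGORIES)
    if bad_island:
        raise MethlineageError(f"unknown island_relation values: {sorted(bad_island)}")
    bad_feat = set(manifest["gene_feature"]) - set(FEATURE_CATEGORIES)
    if bad_feat:
        raise MethlineageError(f"unknown gene_feature values: {sorted(bad_feat)}")
    out = manifest.set_index("probe_id", drop=False) if manifest.index.name != "probe_id" else manifest
    return out


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with one column per sample.
    scale
        ``"beta"`` (values in [0, 1]) or ``"mvalue"``.
    group_labels
        Mapping sample_id -> group label; samples without an entry are
        labelled ``"unknown"``.
    """

    values: pd.DataFrame
    scale: str = "beta"
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "mvalue"):
            raise MethlineageError(f"scale must be 'beta' or 'mvalue', got {self.scale!r}")
        if self.values.index.duplicated().any():
            raise MethlineageError("duplicate probe_ids in matrix")
        if self.values.columns.duplicated().any():
            raise MethlineageError("duplicate sample_ids in matrix")
        if self.scale == "beta":
            arr = self.values.to_numpy()
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise MethlineageError("beta values must lie in [0, 1]")
        self.group_labels = {s: self.group_labels.get(s, "unknown") for s in self.values.columns}

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == group]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_labels[s], None)
        return list(seen)

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[list(probe_ids)], self.scale, dict(self.group_labels))

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        sample_ids = list(sample_ids)
        return MethylationMatrix(
            self.values[sample_ids], self.scale, {s: self.group_labels[s] for s in sample_ids}
        )

    def group_means(self, groups: list[str] | None = None) -> pd.DataFrame:
        """Per-probe mean value for each group (columns ordered as given)."""
        groups = groups if groups is not None else self.groups()
        out = {}
        for g in groups:
            cols = self.samples_in_group(g)
            if not cols:
                raise MethlineageError(f"no samples in group {g!r}")
            out[g] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)
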