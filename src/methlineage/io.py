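"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated with a header row.  Matrices have probe_id as
the first column and one column per sample; region sets are BED3+name
(0-based, half-open); sample sheets map sample_id to group.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import MANIFEST_COLUMNS, MethlineageError, MethylationMatrix, validate_manifest

#: Fixed float format so that identical runs produce byte-identical tables.
FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_matrix(path, scale: str = "beta", sample_sheet=None) -> MethylationMatrix:
    """Read a probes x samples TSV (probe_id first column) into a matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = read_sample_sheet(sample_sheet) if sample_sheet is not None else {}
    return MethylationMatrix(df, scale=scale, group_labels=labels)


def write_matrix(matrix: MethylationMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    write_table(df, path, index=True)


def read_detection_p(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_symbol": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("sex_chrom", "snp_flagged", "cross_reactive"):
        df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    df["pos"] = df["pos"].astype(int)
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    write_table(manifest[MANIFEST_COLUMNS], path)


def read_sample_sheet(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise MethlineageError("sample sheet needs columns sample_id and group")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_sheet(labels: dict[str, str], path) -> None:
    write_table(pd.DataFrame({"sample_id": list(labels), "group": list(labels.values())}), path)


def read_bed(path) -> pd.DataFrame:
    """Read BED3(+name); returns columns chrom, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if (df["end"] <= df["start"]).any():
        raise MethlineageError("BED intervals must satisfy start < end")
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_region_sets(directory) -> dict[str, pd.DataFrame]:
    """Read every ``*.bed`` file of a directory as one named region set."""
    out = {}
    for p in sorted(Path(directory).glob("*.bed")):
        out[p.stem] = read_bed(p)
    return out


def read_probe_list(path) -> list[str]:
    return pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
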