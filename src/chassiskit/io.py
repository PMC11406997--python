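"""Plain-text table IO for the pipeline's interchange formats.

Everything is TSV (tables) or CSV (long-format plate-reader data) with
label-based indices -- never positional -- so files survive reordering.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_cluster_matrix(path) -> pd.DataFrame:
    """Clusters x genomes gene-call counts; first column = cluster_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_annotations(path) -> pd.DataFrame:
    """Gene-call annotation map: gene_call_id, genome, cluster_id, cog_category."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_call_id", "genome", "cluster_id", "cog_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns {sorted(missing)}")
    return df


def read_counts(path) -> pd.DataFrame:
    """Gene calls x samples integer counts; first column = gene_call_id."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(int)


def read_design(path) -> pd.DataFrame:
    """Sample sheet: sample, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"}.issubset(df.columns):
        raise ValueError("design file needs 'sample' and 'condition' columns")
    return df


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_plate_csv(path) -> pd.DataFrame:
    """Long-format plate-reader data (well, host, assay, channel, condition,
    inducer, concentration, time_h, value)."""
    df = pd.read_csv(path)
    required = {"well", "host", "assay", "channel", "condition", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate file missing columns {sorted(missing)}")
    return df


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path
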