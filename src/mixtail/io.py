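"""Expression-matrix I/O: delimiter sniffing, orientation, log2 scale.

The library's in-memory orientation is samples x features (genes or
probes in columns).  On disk, microarray matrices conventionally put
probes in rows and samples in columns; ``read_expression_matrix``
auto-detects this (overridable) and records every decision it makes so
runs are reproducible from the manifest.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

__all__ = ["read_expression_matrix", "write_matrix", "write_manifest"]

#: values above this are taken to be linear scale and log2-transformed
LINEAR_SCALE_CUTOFF = 50.0


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(
    path,
    orientation: str = "auto",
    log2_transform: str = "auto",
    delimiter: str | None = None,
):
    """Read a delimited expression matrix into samples x features form.

    Parameters
    ----------
    orientation : {"auto", "features-in-rows", "features-in-columns"}
        ``auto`` assumes features are in rows when the table is taller
        than wide (the common probes x samples layout) or when the index
        header names a gene/probe column.
    log2_transform : {"auto", "yes", "no"}
        ``auto`` log2-transforms when any value exceeds
        :data:`LINEAR_SCALE_CUTOFF` (a heuristic for linear-scale
        input); non-positive values become missing with a warning.

    Returns ``(matrix, info)`` where ``info`` records the choices made.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")

    idx_name = (df.index.name or "").strip().lower()
    feature_markers = {"gene", "genes", "probe", "probes", "probe_set",
                       "gene_id", "probe_id", "feature", "symbol"}
    if orientation == "auto":
        if idx_name in feature_markers or df.shape[0] > df.shape[1]:
            orientation_used = "features-in-rows"
        else:
            orientation_used = "features-in-columns"
    else:
        orientation_used = orientation
    if orientation_used == "features-in-rows":
        df = df.T
    elif orientation_used != "features-in-columns":
        raise ValueError(f"unknown orientation {orientation_used!r}")

    max_val = np.nanmax(df.to_numpy(dtype=float)) if df.size else 0.0
    if log2_transform == "auto":
        do_log = bool(max_val > LINEAR_SCALE_CUTOFF)
    elif log2_transform in ("yes", "no"):
        do_log = log2_transform == "yes"
    else:
        raise ValueError(f"unknown log2_transform {log2_transform!r}")
    if do_log:
        arr = df.to_numpy(dtype=float)
        nonpos = arr <= 0
        if np.isfinite(arr[nonpos]).any():
            warnings.warn(
                "non-positive values set to missing before log2 transform",
                RuntimeWarning,
                stacklevel=2,
            )
        arr = np.where(nonpos, np.nan, arr)
        df = pd.DataFrame(np.log2(arr), index=df.index, columns=df.columns)

    info = {
        "path": str(path),
        "delimiter": sep,
        "orientation": orientation_used,
        "log2_transformed": do_log,
        "n_samples": int(df.shape[0]),
        "n_features": int(df.shape[1]),
    }
    return df, info


def write_matrix(df: pd.DataFrame, path, features_in_rows: bool = True):
    """Write a samples x features frame as TSV (features in rows by
    default, matching the common on-disk layout)."""
    (df.T if features_in_rows else df).to_csv(path, sep="\t")


def write_manifest(path, config: dict):
    """Persist the run configuration (every tunable, seed, version)."""
    from . import __version__

    payload = {"mixtail_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
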