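"""Read and write the wide-table exchange format.

Layout: comment lines start with ``#``; the first column holds sample ids,
followed by the reserved metadata columns ``group``, ``sample_type`` and
(optionally) ``replicate``, then one numeric column per feature.  Empty cells
and ``NA`` are missing values.  Internal standards are flagged either by a
sidecar feature-metadata CSV (columns ``feature_id``, ``is_internal_standard``),
by a feature-name prefix, or by the ``# internal_standards:`` comment that
:func:`write_dataset` emits.
"""

from __future__ import annotations

import csv
import io as _io
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SAMPLE, MetDataset

__all__ = ["read_dataset", "write_dataset"]

_RESERVED = ("group", "sample_type", "replicate")
_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _parse_cell(text: str, row: str, col: str) -> float:
    if text.strip() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric value {text!r} in feature column {col!r}, sample {row!r}"
        ) from None


def read_dataset(
    path: str | os.PathLike,
    *,
    sep: str = ",",
    feature_metadata: str | os.PathLike | None = None,
    is_prefix: str | None = None,
) -> MetDataset:
    """Read a wide CSV/TSV into a :class:`MetDataset`.

    Parameters
    ----------
    path
        CSV/TSV file; ``sep`` selects the delimiter.
    feature_metadata
        Optional sidecar CSV with columns ``feature_id`` and
        ``is_internal_standard`` (truthy values: 1/true/yes).
    is_prefix
        Alternatively, flag every feature whose id starts with this prefix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    unit_tag = "area"
    is_from_comment: list[str] | None = None
    body: list[str] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("unit_tag:"):
                    unit_tag = stripped.split(":", 1)[1].strip()
                elif stripped.startswith("internal_standards:"):
                    raw = stripped.split(":", 1)[1].strip()
                    is_from_comment = [t.strip() for t in raw.split(",") if t.strip()]
                continue
            body.append(line)
    if not body:
        raise ValueError(f"{path}: no header line found")

    reader = csv.reader(_io.StringIO("".join(body)), delimiter=sep)
    header = next(reader)
    if len(header) < 1:
        raise ValueError(f"{path}: empty header")
    meta_cols = [c for c in header[1:] if c in _RESERVED]
    if "group" not in meta_cols:
        raise ValueError(f"{path}: required metadata column 'group' is missing")
    n_meta = len(meta_cols)
    # metadata columns must precede feature columns
    if header[1 : 1 + n_meta] != meta_cols:
        raise ValueError(f"{path}: metadata columns {meta_cols} must directly follow the sample-id column")
    feature_ids = header[1 + n_meta :]

    sample_ids: list[str] = []
    meta_rows: list[list[str]] = []
    data_rows: list[list[float]] = []
    for row in reader:
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        sid = row[0]
        sample_ids.append(sid)
        meta_rows.append(row[1 : 1 + n_meta])
        cells = row[1 + n_meta :]
        if len(cells) != len(feature_ids):
            raise ValueError(f"{path}: row {sid!r} has {len(cells)} feature cells, expected {len(feature_ids)}")
        data_rows.append([_parse_cell(c, sid, f) for c, f in zip(cells, feature_ids)])

    dup_s = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].unique().tolist()
    if dup_s:
        raise ValueError(f"{path}: duplicate sample ids {dup_s}")
    dup_f = pd.Index(feature_ids)[pd.Index(feature_ids).duplicated()].unique().tolist()
    if dup_f:
        raise ValueError(f"{path}: duplicate feature ids {dup_f}")

    values = pd.DataFrame(
        np.asarray(data_rows, dtype=float).reshape(len(sample_ids), len(feature_ids)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(feature_ids, name="feature_id"),
    )
    meta = pd.DataFrame(meta_rows, index=values.index, columns=meta_cols)
    group = meta["group"]
    sample_type = meta["sample_type"] if "sample_type" in meta else pd.Series(SAMPLE, index=values.index)
    sample_type = sample_type.str.lower().replace({"": SAMPLE}).fillna(SAMPLE)
    replicate = meta["replicate"] if "replicate" in meta else None

    flags = pd.Series(False, index=values.columns)
    if feature_metadata is not None:
        fm = pd.read_csv(feature_metadata, comment="#")
        if "feature_id" not in fm.columns or "is_internal_standard" not in fm.columns:
            raise ValueError("feature metadata sidecar needs columns 'feature_id' and 'is_internal_standard'")
        fm = fm.set_index("feature_id")["is_internal_standard"]
        truthy = fm.astype(str).str.strip().str.lower().isin({"1", "true", "yes", "y"})
        for fid in fm.index:
            if fid in flags.index:
                flags.loc[fid] = bool(truthy.loc[fid])
    if is_prefix:
        flags |= values.columns.str.startswith(is_prefix)
    if is_from_comment is not None:
        for fid in is_from_comment:
            if fid in flags.index:
                flags.loc[fid] = True

    return MetDataset(
        values=values,
        group=group,
        sample_type=sample_type,
        replicate=replicate,
        is_internal_standard=flags,
        unit_tag=unit_tag,
    )


def write_dataset(d: MetDataset, path: str | os.PathLike, *, sep: str = ",") -> Path:
    """Write ``d`` as a wide CSV readable by :func:`read_dataset`.

    Missing values become empty cells; ``unit_tag`` and internal-standard flags
    are written as comment header lines so a round trip is lossless.
    """
    path = Path(path)
    is_feats = d.feature_ids[d.is_internal_standard.to_numpy()].tolist()
    with open(path, "w", newline="") as fh:
        fh.write(f"# unit_tag: {d.unit_tag}\n")
        if is_feats:
            fh.write("# internal_standards: " + ",".join(map(str, is_feats)) + "\n")
        writer = csv.writer(fh, delimiter=sep)
        meta_cols = ["group", "sample_type"] + (["replicate"] if d.replicate is not None else [])
        writer.writerow(["sample_id"] + meta_cols + list(map(str, d.feature_ids)))
        for i, sid in enumerate(d.sample_ids):
            meta = [d.group.iloc[i], d.sample_type.iloc[i]]
            if d.replicate is not None:
                meta.append(d.replicate.iloc[i])
            row = [("" if np.isnan(v) else repr(float(v))) for v in d.values.iloc[i]]
            writer.writerow([sid] + meta + row)
    return path
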