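"""Core dataset container and processing-scheme identifiers.

The :class:`MetDataset` is the currency of every stage in the pipeline: a
samples x features intensity (or concentration) matrix together with sample
metadata (biological group, sample type, replicate id) and feature metadata
(internal-standard flags).  Missing values are ``NaN`` and are distinct from
zero, which is always a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "MetDataset",
    "SchemeId",
    "split_standards",
    "NORMALIZATIONS",
    "TRANSFORMATIONS",
    "SCALINGS",
]

NORMALIZATIONS = ("none", "ccmn", "nomis", "is_ratio")
TRANSFORMATIONS = ("none", "cube", "log2", "log10", "glog2", "glog10", "sqrt")
SCALINGS = ("none", "auto", "level", "pareto", "power", "range", "vast")

QC = "qc"
SAMPLE = "sample"


@dataclass
class MetDataset:
    """Samples x features matrix with sample and feature metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_samples, n_features); index holds sample ids,
        columns hold feature ids.  ``NaN`` encodes missingness.
    group
        Biological group label per sample (aligned with ``values.index``).
    sample_type
        ``"sample"`` or ``"qc"`` per sample.
    replicate
        Optional replicate/injection label per sample.
    is_internal_standard
        Boolean flag per feature (aligned with ``values.columns``).
    unit_tag
        Free-text provenance tag: ``"area"``, ``"concentration"`` or
        ``"processed:<scheme-id>"``.
    """

    values: pd.DataFrame
    group: pd.Series
    sample_type: pd.Series
    replicate: pd.Series | None = None
    is_internal_standard: pd.Series | None = None
    unit_tag: str = "area"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        n, p = self.values.shape
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        self.group = pd.Series(np.asarray(self.group, dtype=object), index=self.values.index, name="group")
        self.sample_type = pd.Series(
            np.asarray(self.sample_type, dtype=object), index=self.values.index, name="sample_type"
        )
        bad = set(self.sample_type.unique()) - {QC, SAMPLE}
        if bad:
            raise ValueError(f"sample_type must be 'sample' or 'qc', got {sorted(bad)}")
        if self.replicate is not None:
            self.replicate = pd.Series(
                np.asarray(self.replicate, dtype=object), index=self.values.index, name="replicate"
            )
        if self.is_internal_standard is None:
            self.is_internal_standard = pd.Series(False, index=self.values.columns, name="is_internal_standard")
        else:
            self.is_internal_standard = pd.Series(
                np.asarray(self.is_internal_standard, dtype=bool),
                index=self.values.columns,
                name="is_internal_standard",
            )
        if len(self.group) != n or len(self.sample_type) != n:
            raise ValueError("sample metadata length mismatch")
        if len(self.is_internal_standard) != p:
            raise ValueError("feature metadata length mismatch")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def is_qc(self) -> np.ndarray:
        return (self.sample_type == QC).to_numpy()

    def effective_group(self) -> pd.Series:
        """Group labels with QC samples collapsed into their own ``"QC"`` level."""
        g = self.group.astype(object).copy()
        g[self.is_qc()] = "QC"
        return g

    def copy(self) -> "MetDataset":
        return MetDataset(
            values=self.values.copy(),
            group=self.group.copy(),
            sample_type=self.sample_type.copy(),
            replicate=None if self.replicate is None else self.replicate.copy(),
            is_internal_standard=self.is_internal_standard.copy(),
            unit_tag=self.unit_tag,
        )

    def with_values(self, values: pd.DataFrame, unit_tag: str | None = None) -> "MetDataset":
        """New dataset sharing sample metadata, with a (possibly narrower) value matrix."""
        keep = values.columns
        return MetDataset(
            values=values,
            group=self.group.copy(),
            sample_type=self.sample_type.copy(),
            replicate=None if self.replicate is None else self.replicate.copy(),
            is_internal_standard=self.is_internal_standard.loc[keep].copy(),
            unit_tag=self.unit_tag if unit_tag is None else unit_tag,
        )

    def select_samples(self, mask: np.ndarray) -> "MetDataset":
        return MetDataset(
            values=self.values.loc[mask],
            group=self.group.loc[mask],
            sample_type=self.sample_type.loc[mask],
            replicate=None if self.replicate is None else self.replicate.loc[mask],
            is_internal_standard=self.is_internal_standard.copy(),
            unit_tag=self.unit_tag,
        )

    def equals(self, other: "MetDataset") -> bool:
        if not self.values.equals(other.values):
            return False
        if not self.group.equals(other.group) or not self.sample_type.equals(other.sample_type):
            return False
        if (self.replicate is None) != (other.replicate is None):
            return False
        if self.replicate is not None and not self.replicate.equals(other.replicate):
            return False
        return bool(
            self.is_internal_standard.equals(other.is_internal_standard) and self.unit_tag == other.unit_tag
        )


def split_standards(d: MetDataset) -> tuple[MetDataset, MetDataset]:
    """Partition features into (analytes, internal standards).

    Raises
    ------
    ValueError
        If no feature is flagged as an internal standard.
    """
    flags = d.is_internal_standard
    if not flags.any():
        raise ValueError(
            "no feature is flagged as an internal standard; flag one via the "
            "feature-metadata sidecar (is_internal_standard column) or the IS name prefix"
        )
    analytes = d.with_values(d.values.loc[:, ~flags])
    standards = d.with_values(d.values.loc[:, flags])
    return analytes, standards


@dataclass(frozen=True)
class SchemeId:
    """One cell of the processing grid: normalization, then transformation, then scaling."""

    normalization: str = "none"
    transformation: str = "none"
    scaling: str = "none"

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}; choose from {NORMALIZATIONS}")
        if self.transformation not in TRANSFORMATIONS:
            raise ValueError(f"unknown transformation {self.transformation!r}; choose from {TRANSFORMATIONS}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}; choose from {SCALINGS}")

    @property
    def is_raw(self) -> bool:
        return self.normalization == "none" and self.transformation == "none" and self.scaling == "none"

    def canonical(self) -> str:
        if self.is_raw:
            return "raw"
        return f"{self.normalization}+{self.transformation}+{self.scaling}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical()

    @classmethod
    def parse(cls, text: str) -> "SchemeId":
        text = text.strip()
        if text == "raw":
            return cls()
        parts = text.split("+")
        if len(parts) != 3:
            raise ValueError(
                f"scheme string must be 'raw' or 'norm+transform+scale', got {text!r}"
            )
        return cls(*parts)
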