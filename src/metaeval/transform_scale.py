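"""Transformations, scalings and their fixed-order composition.

Order is always normalization -> transformation -> scaling.  Transformations
are element-wise variance-taming maps; scalings are per-feature
centre-and-divide recipes.  Statistics are computed over all samples of the
dataset being processed (QCs included) with the sample (n-1) standard
deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MetDataset, SchemeId
from .normalization import normalize_ccmn, normalize_is_ratio, normalize_nomis

__all__ = [
    "GlogParameter",
    "select_glog_lambda",
    "transform",
    "scale",
    "apply_scheme",
]


@dataclass(frozen=True)
class GlogParameter:
    """Dataset-specific generalized-log parameter (squared-intensity units)."""

    lam: float
    rule: str = "explicit"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("glog lambda must be non-negative")


def select_glog_lambda(d: MetDataset) -> GlogParameter:
    """Default rule: lambda = (smallest strictly positive value in the dataset)^2."""
    arr = d.matrix
    pos = arr[np.isfinite(arr) & (arr > 0)]
    if pos.size == 0:
        raise ValueError("glog lambda selection needs at least one strictly positive value")
    return GlogParameter(lam=float(pos.min()) ** 2, rule="min-positive-squared")


def _glog(x: np.ndarray, lam: float, base: float) -> np.ndarray:
    return np.log((x + np.sqrt(x * x + lam)) / 2.0) / np.log(base)


def _domain_error(method: str, values: pd.DataFrame, ok: np.ndarray, rule: str) -> None:
    bad = np.argwhere(~ok)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{method}: value {values.iat[i, j]!r} at sample {values.index[i]!r}, "
            f"feature {values.columns[j]!r} violates the domain rule ({rule})"
        )


def transform(
    d: MetDataset,
    method: str,
    glog_lambda: GlogParameter | str | float = "auto",
) -> MetDataset:
    """Element-wise transformation: cube, log2, log10, glog2, glog10, or sqrt."""
    arr = d.matrix
    finite = np.isfinite(arr)
    if method in ("log2", "log10"):
        _domain_error(method, d.values, ~finite | (arr > 0), "log handles only nonzero, nonnegative values")
        out = np.log2(arr) if method == "log2" else np.log10(arr)
    elif method == "sqrt":
        _domain_error(method, d.values, ~finite | (arr >= 0), "sqrt manages only zero and positive values")
        out = np.sqrt(arr)
    elif method == "cube":
        out = np.cbrt(arr)
    elif method in ("glog2", "glog10"):
        if glog_lambda == "auto":
            glog_lambda = select_glog_lambda(d)
        elif not isinstance(glog_lambda, GlogParameter):
            glog_lambda = GlogParameter(lam=float(glog_lambda))
        base = 2.0 if method == "glog2" else 10.0
        with np.errstate(divide="ignore"):
            out = _glog(arr, glog_lambda.lam, base)
        ok = ~finite | np.isfinite(out)
        _domain_error(method, d.values, ok, "glog argument (x + sqrt(x^2+lambda))/2 must be positive")
    else:
        raise ValueError(f"unknown transformation {method!r}")
    res = d.copy()
    res.values = pd.DataFrame(out, index=d.sample_ids, columns=d.feature_ids)
    res.unit_tag = f"{d.unit_tag}|{method}"
    return res


def scale(d: MetDataset, method: str) -> MetDataset:
    """Per-feature scaling: auto, level, pareto, power, range, or vast."""
    arr = d.matrix
    if np.isnan(arr).any():
        raise ValueError("scaling requires a complete matrix; impute first")
    m = arr.mean(axis=0)
    s = arr.std(axis=0, ddof=1)
    mx = arr.max(axis=0)
    mn = arr.min(axis=0)

    def _need(cond: np.ndarray, stat: str) -> None:
        if (~cond).any():
            bad = d.feature_ids[~cond].tolist()
            raise ValueError(f"{method} scaling: degenerate feature(s) {bad} ({stat})")

    if method == "auto":
        _need(s > 0, "zero standard deviation")
        out = (arr - m) / s
    elif method == "level":
        _need(m != 0, "zero mean")
        if (m < 0).any():
            warnings.warn("level scaling with negative feature mean(s); dividing by the mean as-is")
        out = (arr - m) / m
    elif method == "pareto":
        _need(s > 0, "zero standard deviation")
        out = (arr - m) / np.sqrt(s)
    elif method == "power":
        _need((arr >= 0).all(axis=0), "negative values")
        r = np.sqrt(arr)
        out = r - r.mean(axis=0)
    elif method == "range":
        _need(mx > mn, "zero range")
        out = (arr - m) / (mx - mn)
    elif method == "vast":
        _need(s > 0, "zero standard deviation")
        out = (arr - m) / s * (m / s)
    else:
        raise ValueError(f"unknown scaling {method!r}")
    res = d.copy()
    res.values = pd.DataFrame(out, index=d.sample_ids, columns=d.feature_ids)
    res.unit_tag = f"{d.unit_tag}|{method}"
    return res


def apply_scheme(
    d: MetDataset,
    scheme: SchemeId,
    *,
    ccmn_components: int | str = "auto",
    glog_lambda: GlogParameter | str | float = "auto",
    is_ratio_feature: str | None = None,
) -> MetDataset:
    """Apply one processing scheme: normalization, then transformation, then scaling."""
    out = d
    stage = "normalization"
    try:
        if scheme.normalization == "ccmn":
            out, _ = normalize_ccmn(out, n_components=ccmn_components)
        elif scheme.normalization == "nomis":
            out, _ = normalize_nomis(out)
        elif scheme.normalization == "is_ratio":
            if is_ratio_feature is None:
                flagged = out.feature_ids[out.is_internal_standard.to_numpy()]
                if len(flagged) != 1:
                    raise ValueError("is_ratio needs a single flagged IS or an explicit is_ratio_feature")
                is_ratio_feature = str(flagged[0])
            out = normalize_is_ratio(out, is_ratio_feature)
        stage = "transformation"
        if scheme.transformation != "none":
            out = transform(out, scheme.transformation, glog_lambda=glog_lambda)
        stage = "scaling"
        if scheme.scaling != "none":
            out = scale(out, scheme.scaling)
    except (ValueError, KeyError) as exc:
        raise type(exc)(f"scheme {scheme.canonical()!r} failed at {stage}: {exc}") from exc
    res = out if out is not d else d.copy()
    res.unit_tag = f"processed:{scheme.canonical()}" if not scheme.is_raw else d.unit_tag
    return res
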