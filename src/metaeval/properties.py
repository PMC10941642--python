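"""Per-dataset data-property diagnostics.

For every (feature, group) block: Shapiro-Wilk normality, moment skewness
with the e1071-style small-sample factor, and the coefficient of variation.
Also fold/directional differences from a reference metabolite and the
across-group relative log abundance (RLA) matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MetDataset

__all__ = [
    "PropertyProfile",
    "FoldDifferenceTrend",
    "property_profile",
    "fold_difference_trend",
    "rla",
    "skewness",
]

SKEW_BOUND = 0.5
NORMALITY_ALPHA = 0.05


def skewness(x: np.ndarray) -> float:
    """Moment skewness g1 = m3/m2^(3/2) times the ((n-1)/n)^(3/2) small-sample factor."""
    x = np.asarray(x, dtype=float)
    n = x.size
    g1 = stats.skew(x, bias=True)
    return float(g1 * ((n - 1) / n) ** 1.5)


@dataclass
class PropertyProfile:
    """Per-group normality/skewness counts and CV summaries for one dataset."""

    groups: list[str]
    n_normal: pd.Series  # per group
    n_pos_skew: pd.Series
    n_neg_skew: pd.Series
    cv: pd.DataFrame  # features x groups
    mcv: pd.Series  # per group mean CV
    shapiro_p: pd.DataFrame = field(repr=False, default=None)
    skew: pd.DataFrame = field(repr=False, default=None)

    def as_vector(self) -> pd.Series:
        """Flatten to one row for profile-space PCA across schemes."""
        parts = {}
        for g in self.groups:
            parts[f"n_normal:{g}"] = self.n_normal[g]
            parts[f"n_pos_skew:{g}"] = self.n_pos_skew[g]
            parts[f"n_neg_skew:{g}"] = self.n_neg_skew[g]
            parts[f"mcv:{g}"] = self.mcv[g]
        return pd.Series(parts)


def property_profile(d: MetDataset) -> PropertyProfile:
    """Shapiro-Wilk, skewness and CV per (feature, group); QC is its own group level."""
    if d.values.isna().any().any():
        raise ValueError("property profile requires a complete matrix; impute first")
    groups = d.effective_group()
    levels = [str(g) for g in pd.unique(groups)]
    for g in levels:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples; Shapiro-Wilk needs n >= 3")

    shapiro_p = pd.DataFrame(index=d.feature_ids, columns=levels, dtype=float)
    skew = pd.DataFrame(index=d.feature_ids, columns=levels, dtype=float)
    cv = pd.DataFrame(index=d.feature_ids, columns=levels, dtype=float)
    for g in levels:
        sub = d.values.loc[(groups == g).to_numpy()]
        for feat in d.feature_ids:
            x = sub[feat].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(
                    f"feature {feat!r} is constant in group {g!r}; Shapiro-Wilk undefined, "
                    "counted as non-normal"
                )
                shapiro_p.loc[feat, g] = 0.0
                skew.loc[feat, g] = 0.0
            else:
                shapiro_p.loc[feat, g] = stats.shapiro(x).pvalue
                skew.loc[feat, g] = skewness(x)
            m = x.mean()
            cv.loc[feat, g] = x.std(ddof=1) / m if m != 0 else np.nan

    n_normal = (shapiro_p > NORMALITY_ALPHA).sum(axis=0)
    n_pos = (skew > SKEW_BOUND).sum(axis=0)
    n_neg = (skew < -SKEW_BOUND).sum(axis=0)
    mcv = cv.mean(axis=0, skipna=True)
    return PropertyProfile(
        groups=levels,
        n_normal=n_normal,
        n_pos_skew=n_pos,
        n_neg_skew=n_neg,
        cv=cv,
        mcv=mcv,
        shapiro_p=shapiro_p,
        skew=skew,
    )


@dataclass
class FoldDifferenceTrend:
    reference: str
    fold: pd.DataFrame  # features x groups: group-mean(reference) / group-mean(feature)
    direction: pd.DataFrame  # sign of group-mean(reference) - group-mean(feature)

    def agreement(self, other: "FoldDifferenceTrend") -> float:
        """Fraction of (feature, group) cells whose direction signs agree."""
        a = self.direction.to_numpy()
        b = other.direction.reindex(index=self.direction.index, columns=self.direction.columns).to_numpy()
        ok = ~(np.isnan(a) | np.isnan(b))
        if not ok.any():
            return np.nan
        return float((a[ok] == b[ok]).mean())


def fold_difference_trend(d: MetDataset, reference: str = "auto") -> FoldDifferenceTrend:
    """Fold and directional differences of every metabolite from a reference.

    ``reference="auto"`` picks the feature with the largest overall mean, since
    processing acts most strongly on highly abundant metabolites.
    """
    if d.values.isna().any().any():
        raise ValueError("fold differences require a complete matrix; impute first")
    if reference == "auto":
        reference = str(d.values.mean(axis=0).idxmax())
    if reference not in d.feature_ids:
        raise KeyError(f"unknown reference feature {reference!r}")
    groups = d.effective_group()
    levels = [str(g) for g in pd.unique(groups)]
    gmeans = pd.DataFrame(
        {g: d.values.loc[(groups == g).to_numpy()].mean(axis=0) for g in levels}
    )
    ref = gmeans.loc[reference]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = pd.DataFrame(ref.to_numpy() / gmeans.to_numpy(), index=gmeans.index, columns=gmeans.columns)
    fold = fold.mask(gmeans == 0)  # fold undefined at zero group mean
    direction = np.sign(-gmeans.sub(ref, axis=1))
    return FoldDifferenceTrend(reference=reference, fold=fold, direction=direction)


def rla(d: MetDataset, log_base: float = 2) -> pd.DataFrame:
    """Across-group relative log abundance: log value minus the feature's log median over all samples."""
    arr = d.matrix
    if not (arr[np.isfinite(arr)] > 0).all():
        raise ValueError("RLA requires strictly positive values (apply before scaling)")
    logv = np.log(arr) / np.log(log_base)
    med = np.nanmedian(logv, axis=0)
    return pd.DataFrame(logv - med, index=d.sample_ids, columns=d.feature_ids)
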