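"""Two-stage missing-value policy.

Stage 1 (:func:`impute_structural_min`) handles structurally absent
metabolites: when a (feature, group) block has more than ``threshold``
missing, every missing cell in the block is replaced by the feature's minimum
observed value — below-LOD absence is a true negative, not randomness.

Stage 2 (:func:`impute_random_forest`) handles the remaining sporadic
missingness with a missForest-style iterative random-forest regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dataset import MetDataset

__all__ = ["ImputationReport", "impute_structural_min", "impute_random_forest"]


@dataclass
class ImputationReport:
    """Audit trail of what was imputed, how, and with which parameters."""

    missing_fraction: pd.DataFrame  # features x groups, before imputation
    structural_blocks: list[tuple[str, str]] = field(default_factory=list)
    structural_cells: list[tuple[str, str]] = field(default_factory=list)  # (sample, feature)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    untouched_cells: list[tuple[str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _missing_fraction(d: MetDataset) -> pd.DataFrame:
    groups = d.effective_group()
    out = {}
    for g in pd.unique(groups):
        sub = d.values.loc[(groups == g).to_numpy()]
        out[g] = sub.isna().mean(axis=0)
    return pd.DataFrame(out)


def impute_structural_min(
    d: MetDataset, threshold: float = 0.30
) -> tuple[MetDataset, ImputationReport]:
    """Min-substitute (feature, group) blocks whose missing fraction exceeds ``threshold``.

    The substituted value is the feature's minimum observed value across *all*
    samples (a group may be entirely missing, so no group minimum exists).
    Missing cells in blocks at or below the threshold are left untouched.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = d.copy()
    groups = d.effective_group()
    frac = _missing_fraction(d)
    report = ImputationReport(missing_fraction=frac, params={"threshold": threshold})
    for feat in d.feature_ids:
        col = out.values[feat]
        for g in frac.columns:
            if frac.loc[feat, g] <= threshold:
                continue
            gmask = (groups == g).to_numpy()
            miss = gmask & col.isna().to_numpy()
            if not miss.any():
                continue
            observed = col.dropna()
            if observed.empty:
                raise ValueError(
                    f"feature {feat!r} has no observed value anywhere; no minimum exists "
                    f"to substitute in group {g!r}"
                )
            out.values.loc[miss, feat] = float(observed.min())
            report.structural_blocks.append((str(feat), str(g)))
            report.structural_cells.extend((str(s), str(feat)) for s in d.sample_ids[miss])
    # remaining missing cells after this stage
    still = out.values.isna()
    report.untouched_cells = [
        (str(d.sample_ids[i]), str(d.feature_ids[j])) for i, j in zip(*np.nonzero(still.to_numpy()))
    ]
    return out, report


def impute_random_forest(
    d: MetDataset,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> tuple[MetDataset, ImputationReport]:
    """missForest-style iterative random-forest imputation.

    Missing cells are initialised with feature means; each incomplete feature
    is then regressed on all others and refilled, iterating until the
    normalized squared difference between successive imputations first
    increases or ``max_iter`` is reached.  Deterministic under ``seed``.
    """
    if d.n_features < 2:
        raise ValueError("random-forest imputation needs at least 2 features")
    X = d.matrix.copy()
    miss = np.isnan(X)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = d.feature_ids[fully_missing].tolist()
        raise ValueError(
            f"features fully missing: {bad}; run impute_structural_min first"
        )
    report = ImputationReport(
        missing_fraction=_missing_fraction(d),
        params={"n_trees": n_trees, "max_iter": max_iter, "seed": seed},
    )
    if not miss.any():
        return d.copy(), report

    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        X[miss[:, j], j] = col_means[j]

    # columns sorted by increasing missingness, as in missForest
    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()]
    rng = np.random.RandomState(seed)
    prev_diff = np.inf
    X_prev = X.copy()
    for _ in range(max_iter):
        for j in order:
            obs = ~miss[:, j]
            other = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=rng.randint(0, 2**31 - 1),
                n_jobs=1,
            )
            rf.fit(X[obs][:, other], X[obs, j])
            X[miss[:, j], j] = rf.predict(X[miss[:, j]][:, other])
        num = ((X - X_prev)[miss] ** 2).sum()
        den = (X[miss] ** 2).sum()
        diff = num / den if den > 0 else 0.0
        if diff >= prev_diff:
            X = X_prev  # revert to the better iterate
            break
        prev_diff = diff
        X_prev = X.copy()

    out = d.copy()
    out.values = pd.DataFrame(X, index=d.sample_ids, columns=d.feature_ids)
    report.imputed_cells = [
        (str(d.sample_ids[i]), str(d.feature_ids[j])) for i, j in zip(*np.nonzero(miss))
    ]
    return out, report
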