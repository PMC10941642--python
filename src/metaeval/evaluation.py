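"""Benchmark orchestration.

Enumerates the 97-scheme grid (6 transformation-only + 6 scaling-only +
36 transform x scale + ccmn + 6 ccmn+transform + 6 ccmn+scale +
36 ccmn+transform+scale), processes the peak-area data under every scheme,
fits PLS-DA everywhere, and scores each scheme by VIP similarity to the
absolute-concentration reference:

    similarity(x, y) = 1 - sqrt( sum_i (x_i - y_i)^2 )

optionally after normalizing both VIP vectors to unit Euclidean norm (the
bounded variant; both columns are always emitted side by side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .dataset import SCALINGS, TRANSFORMATIONS, MetDataset, SchemeId
from .multivariate import pca, plsda
from .properties import property_profile
from .transform_scale import apply_scheme

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "enumerate_schemes",
    "vip_similarity",
    "cluster_vips",
    "run_benchmark",
]

_TRANSFORMS = [t for t in TRANSFORMATIONS if t != "none"]
_SCALES = [s for s in SCALINGS if s != "none"]


def enumerate_schemes(include_raw: bool = False) -> list[SchemeId]:
    """The benchmark grid, in deterministic canonical order (97 schemes)."""
    schemes: list[SchemeId] = []
    if include_raw:
        schemes.append(SchemeId())
    for t in _TRANSFORMS:
        schemes.append(SchemeId("none", t, "none"))
    for s in _SCALES:
        schemes.append(SchemeId("none", "none", s))
    for t in _TRANSFORMS:
        for s in _SCALES:
            schemes.append(SchemeId("none", t, s))
    schemes.append(SchemeId("ccmn", "none", "none"))
    for t in _TRANSFORMS:
        schemes.append(SchemeId("ccmn", t, "none"))
    for s in _SCALES:
        schemes.append(SchemeId("ccmn", "none", s))
    for t in _TRANSFORMS:
        for s in _SCALES:
            schemes.append(SchemeId("ccmn", t, s))
    return schemes


def vip_similarity(x: np.ndarray, y: np.ndarray, normalize: bool = False) -> float:
    """1 minus the Euclidean distance between two VIP vectors (may be negative)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"VIP vectors have different lengths: {x.shape} vs {y.shape}")
    if normalize:
        nx = np.linalg.norm(x)
        ny = np.linalg.norm(y)
        x = x / nx if nx > 0 else x
        y = y / ny if ny > 0 else y
    return float(1.0 - np.sqrt(((x - y) ** 2).sum()))


def cluster_vips(vip_matrix: pd.DataFrame, method: str = "complete") -> dict:
    """Agglomerative clustering of VIP rows with Euclidean distances.

    Returns the merge sequence and heights (scipy linkage encoding) plus the
    row labels in canonical order.
    """
    if vip_matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    if vip_matrix.isna().any().any():
        raise ValueError("clustering input contains missing values")
    Z = linkage(pdist(vip_matrix.to_numpy(), metric="euclidean"), method=method)
    return {
        "labels": [str(i) for i in vip_matrix.index],
        "linkage": Z.tolist(),
        "method": method,
    }


@dataclass
class EvaluationConfig:
    n_components: int = 2
    ccmn_components: int | str = "auto"
    glog_lambda: float | str = "auto"
    linkage: str = "complete"
    qc_policy: str = "exclude"
    similarity_normalize: bool = False  # which column rankings use
    profile: bool = True  # compute property profiles + their PCA


@dataclass
class EvaluationReport:
    similarity: pd.DataFrame  # per scheme: similarity, similarity_normalized (+ percents)
    vips: pd.DataFrame  # schemes (+ raw + conc) x features
    clustering: dict
    profile_pca: pd.DataFrame | None
    skipped: dict[str, str]
    config: EvaluationConfig
    glog_lambdas: dict[str, float] = field(default_factory=dict)

    def ranking_column(self) -> str:
        return "similarity_normalized" if self.config.similarity_normalize else "similarity"

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.similarity.to_csv(outdir / "similarity.csv")
        self.vips.to_csv(outdir / "vips.csv")
        with open(outdir / "clustering.json", "w") as fh:
            json.dump(self.clustering, fh, indent=1)
        if self.profile_pca is not None:
            self.profile_pca.to_csv(outdir / "profile_pca.csv")
        resolved = {
            "n_components": self.config.n_components,
            "ccmn_components": self.config.ccmn_components,
            "glog_lambda": self.config.glog_lambda,
            "linkage": self.config.linkage,
            "qc_policy": self.config.qc_policy,
            "similarity_normalize": self.config.similarity_normalize,
            "glog_lambdas": self.glog_lambdas,
            "skipped": self.skipped,
        }
        with open(outdir / "config.json", "w") as fh:
            json.dump(resolved, fh, indent=1)
        return outdir


def _check_keys(area: MetDataset, conc: MetDataset) -> None:
    if list(area.sample_ids) != list(conc.sample_ids):
        extra = sorted(set(area.sample_ids) ^ set(conc.sample_ids))
        raise ValueError(f"area and conc sample ids differ: {extra or 'ordering mismatch'}")
    area_analytes = [f for f, isf in zip(area.feature_ids, area.is_internal_standard) if not isf]
    conc_feats = [f for f, isf in zip(conc.feature_ids, conc.is_internal_standard) if not isf]
    if area_analytes != conc_feats:
        extra = sorted(set(area_analytes) ^ set(conc_feats))
        raise ValueError(f"area analytes and conc features differ: {extra or 'ordering mismatch'}")
    if list(area.group) != list(conc.group):
        raise ValueError("area and conc group labels differ")


def _drop_is(d: MetDataset) -> MetDataset:
    mask = d.is_internal_standard.to_numpy()
    if not mask.any():
        return d
    return d.with_values(d.values.loc[:, ~mask])


def run_benchmark(
    area: MetDataset,
    conc: MetDataset,
    config: EvaluationConfig | None = None,
) -> EvaluationReport:
    """Score every grid scheme (plus raw) by VIP similarity to the conc reference.

    Schemes whose preconditions fail on the given data (e.g. log of a zero)
    are recorded as skipped with the reason, never silently dropped.
    """
    config = config or EvaluationConfig()
    _check_keys(area, conc)
    if area.values.isna().any().any() or conc.values.isna().any().any():
        raise ValueError("both datasets must be complete (imputed) before benchmarking")

    ref_fit = plsda(_drop_is(conc), n_components=config.n_components, qc_policy=config.qc_policy)
    ref_vip = ref_fit.vip

    vip_rows: dict[str, pd.Series] = {"conc": ref_vip}
    sims: dict[str, dict[str, float]] = {}
    skipped: dict[str, str] = {}
    glog_lambdas: dict[str, float] = {}
    profiles: dict[str, pd.Series] = {}

    from .transform_scale import select_glog_lambda  # local to avoid cycle at import time

    for scheme in enumerate_schemes(include_raw=True):
        name = scheme.canonical()
        # IS columns feed normalization only; VIPs are always over analytes
        base = _drop_is(area) if scheme.normalization == "none" else area
        try:
            processed = apply_scheme(
                base,
                scheme,
                ccmn_components=config.ccmn_components,
                glog_lambda=config.glog_lambda,
            )
            if scheme.transformation in ("glog2", "glog10") and config.glog_lambda == "auto":
                pre = base
                if scheme.normalization != "none":
                    pre = apply_scheme(base, SchemeId(scheme.normalization, "none", "none"),
                                       ccmn_components=config.ccmn_components)
                glog_lambdas[name] = select_glog_lambda(pre).lam
            fit = plsda(processed, n_components=config.n_components, qc_policy=config.qc_policy)
        except (ValueError, KeyError) as exc:
            skipped[name] = str(exc)
            continue
        v = fit.vip.reindex(ref_vip.index)
        if v.isna().any():
            skipped[name] = "feature set mismatch after processing"
            continue
        vip_rows[name] = v
        sims[name] = {
            "similarity": vip_similarity(v.to_numpy(), ref_vip.to_numpy(), normalize=False),
            "similarity_normalized": vip_similarity(v.to_numpy(), ref_vip.to_numpy(), normalize=True),
        }
        if config.profile:
            try:
                profiles[name] = property_profile(processed).as_vector()
            except ValueError as exc:
                skipped.setdefault(name + ":profile", str(exc))

    sim_df = pd.DataFrame(sims).T
    sim_df["similarity_pct"] = 100 * sim_df["similarity"]
    sim_df["similarity_normalized_pct"] = 100 * sim_df["similarity_normalized"]
    vip_df = pd.DataFrame(vip_rows).T
    clustering = cluster_vips(vip_df, method=config.linkage)

    profile_pca = None
    if config.profile and profiles:
        prof = pd.DataFrame(profiles).T
        if "conc" not in prof.index:
            try:
                prof.loc["conc"] = property_profile(_drop_is(conc)).as_vector()
            except ValueError:
                pass
        std = prof.std(axis=0, ddof=1)
        keep = std > 0
        Xp = (prof.loc[:, keep] - prof.loc[:, keep].mean(axis=0)) / std[keep]
        U, sv, Vt = np.linalg.svd(Xp.to_numpy(), full_matrices=False)
        k = min(2, len(sv))
        coords = U[:, :k] * sv[:k]
        profile_pca = pd.DataFrame(coords, index=prof.index, columns=[f"PC{i+1}" for i in range(k)])

    return EvaluationReport(
        similarity=sim_df,
        vips=vip_df,
        clustering=clustering,
        profile_pca=profile_pca,
        skipped=skipped,
        config=config,
        glog_lambdas=glog_lambdas,
    )
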