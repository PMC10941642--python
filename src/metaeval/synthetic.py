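"""Paired synthetic concentration / peak-area data.

A log-normal generative model produces a ground-truth concentration table and
a semiquantitative peak-area companion that carries a shared multiplicative
sample-specific error on every analyte and internal standard.  The two
presets emulate the structure of a tightly controlled food study (4 unequal
groups, triplicate injections, pooled QCs, a couple of dominant metabolites,
structural below-LOD absence) and a noisy cohort study (2 large groups, high
inter-individual variance, weak group effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import MetDataset

__all__ = ["SimDesign", "simulate_pair", "presets"]


@dataclass(frozen=True)
class SimDesign:
    group_sizes: tuple[int, ...] = (10, 10)
    group_names: tuple[str, ...] | None = None
    n_features: int = 10
    n_dominant: int = 2
    dominant_fold: float = 50.0
    n_is: int = 1
    sigma_group: float = 0.5  # sd of per-(group, feature) log-mean offsets
    sigma_sample: float = 0.2  # per biological sample log effect (inter-individual)
    sigma_analyte: float = 0.1  # per-cell log noise (conc and area measurement)
    sigma_is: float = 0.05  # independent log noise on each IS
    sigma_e: float = 0.3  # sd of the shared log-normal sample error
    is_group_leak: float = 0.0  # couples group identity into the log ISs
    lod_quantile: float = 0.0  # area values below this feature quantile go missing
    structural_absent: tuple[tuple[int, int], ...] = ()  # (feature index, group index)
    structural_drop: float = 4.0  # log-units subtracted from a structurally absent block mean
    n_qc: int = 0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 1 or self.n_features < 1 or self.replicates < 1:
            raise ValueError("counts must be positive")
        if self.n_is < 0 or self.n_qc < 0:
            raise ValueError("n_is and n_qc must be non-negative")
        if min(self.sigma_group, self.sigma_sample, self.sigma_analyte, self.sigma_is, self.sigma_e) < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.n_dominant > self.n_features:
            raise ValueError("n_dominant exceeds n_features")
        for j, g in self.structural_absent:
            if not (0 <= j < self.n_features and 0 <= g < len(self.group_sizes)):
                raise ValueError(f"structural_absent pair {(j, g)} out of range")


def presets(name: str) -> SimDesign:
    """Named designs: ``milk`` (controlled food study) or ``urine`` (noisy cohort)."""
    if name == "milk":
        return SimDesign(
            group_sizes=(13, 6, 7, 3),
            group_names=("bovine", "lactose_free", "soy", "almond"),
            n_features=16,
            n_dominant=2,
            dominant_fold=50.0,
            n_is=1,
            sigma_group=0.5,
            sigma_sample=0.2,
            sigma_analyte=0.1,
            sigma_e=0.3,
            lod_quantile=0.02,
            structural_absent=((2, 3), (3, 3), (4, 3), (5, 3)),
            n_qc=10,
            replicates=3,
        )
    if name == "urine":
        return SimDesign(
            group_sizes=(53, 63),
            group_names=("N", "LN"),
            n_features=8,
            n_dominant=1,
            dominant_fold=20.0,
            n_is=1,
            sigma_group=0.12,
            sigma_sample=0.6,
            sigma_analyte=0.15,
            sigma_e=0.3,
            n_qc=0,
            replicates=1,
        )
    raise ValueError(f"unknown preset {name!r}; available: milk, urine")


def simulate_pair(design: SimDesign) -> tuple[MetDataset, MetDataset, dict]:
    """Generate (conc, area, truth) under ``design``; bit-identical for equal seeds.

    The concentration table is the ground truth (complete, no ISs).  The area
    table multiplies it by a shared per-injection error ``e_i`` plus
    measurement noise, appends the IS columns (which carry ``e_i`` and,
    optionally, a group leak), and truncates below-LOD cells to missing.
    """
    rng = np.random.default_rng(design.seed)
    n_groups = len(design.group_sizes)
    names = design.group_names or tuple(f"G{g + 1}" for g in range(n_groups))
    if len(names) != n_groups:
        raise ValueError("group_names length must match group_sizes")
    p = design.n_features

    feat_ids = [f"met{j + 1:02d}" for j in range(p)]
    is_ids = [f"IS{k + 1}" for k in range(design.n_is)]

    # per-feature base log abundance; dominant features elevated by the stated fold
    base = rng.normal(np.log(100.0), 0.8, size=p)
    base[: design.n_dominant] += np.log(design.dominant_fold)
    # per-(group, feature) offsets = the biological signal
    delta = rng.normal(0.0, design.sigma_group, size=(n_groups, p))
    mu = base[None, :] + delta  # group log means
    structural = np.zeros((n_groups, p), dtype=bool)
    for j, g in design.structural_absent:
        structural[g, j] = True
        mu[g, j] -= design.structural_drop

    # biological-sample level: replicate injections share the true concentration
    rows_logc: list[np.ndarray] = []
    sample_ids: list[str] = []
    groups: list[str] = []
    sample_types: list[str] = []
    replicates: list[str] = []
    sample_effects: list[float] = []
    for g, (gname, size) in enumerate(zip(names, design.group_sizes)):
        for i in range(size):
            b = rng.normal(0.0, design.sigma_sample)
            logc = mu[g] + b + rng.normal(0.0, design.sigma_analyte, size=p)
            bio_id = f"{gname}_{i + 1:02d}"
            for r in range(design.replicates):
                rows_logc.append(logc)
                sample_ids.append(f"{bio_id}_r{r + 1}" if design.replicates > 1 else bio_id)
                groups.append(gname)
                sample_types.append("sample")
                replicates.append(bio_id)
                sample_effects.append(b)
    grand = mu.mean(axis=0)  # pooled QC target
    for i in range(design.n_qc):
        rows_logc.append(grand + rng.normal(0.0, design.sigma_analyte, size=p))
        sample_ids.append(f"QC_{i + 1:02d}")
        groups.append("QC")
        sample_types.append("qc")
        replicates.append("QC")
        sample_effects.append(0.0)

    n = len(sample_ids)
    b = np.asarray(sample_effects)
    conc = np.exp(np.vstack(rows_logc))

    log_e = rng.normal(0.0, design.sigma_e, size=n)
    area = conc * np.exp(log_e[:, None] + rng.normal(0.0, design.sigma_analyte, size=(n, p)))

    # internal standards: same spiked amount everywhere, carrying e_i (+ optional leak)
    group_leak_code = rng.normal(0.0, 1.0, size=n_groups)
    leak_per_row = np.zeros(n)
    gi = 0
    row = 0
    for g, size in enumerate(design.group_sizes):
        cnt = size * design.replicates
        leak_per_row[row : row + cnt] = design.is_group_leak * group_leak_code[g]
        row += cnt
    is_base = rng.normal(np.log(500.0), 0.3, size=design.n_is)
    is_vals = np.exp(
        is_base[None, :]
        + log_e[:, None]
        + leak_per_row[:, None]
        + rng.normal(0.0, design.sigma_is, size=(n, design.n_is))
    )

    area_full = np.concatenate([area, is_vals], axis=1) if design.n_is else area
    area_cols = feat_ids + is_ids
    area_df = pd.DataFrame(area_full, index=pd.Index(sample_ids, name="sample_id"), columns=area_cols)

    # below-LOD truncation (analytes only): structural blocks plus a global feature quantile
    miss = np.zeros((n, p), dtype=bool)
    group_arr = np.asarray(groups, dtype=object)
    for g, gname in enumerate(names):
        for j in range(p):
            if structural[g, j]:
                miss[group_arr == gname, j] = True
    if design.lod_quantile > 0:
        thr = np.quantile(area, design.lod_quantile, axis=0)
        miss |= area < thr[None, :]
    area_df.iloc[:, :p] = area_df.iloc[:, :p].mask(pd.DataFrame(miss, index=area_df.index, columns=feat_ids))

    is_flags = pd.Series([False] * p + [True] * design.n_is, index=area_cols)
    meta = dict(
        group=pd.Series(groups, index=area_df.index),
        sample_type=pd.Series(sample_types, index=area_df.index),
        replicate=pd.Series(replicates, index=area_df.index),
    )
    area_ds = MetDataset(values=area_df, is_internal_standard=is_flags, unit_tag="area", **meta)
    conc_df = pd.DataFrame(conc, index=area_df.index.copy(), columns=feat_ids)
    conc_ds = MetDataset(values=conc_df, unit_tag="concentration", **{k: v.copy() for k, v in meta.items()})

    truth = {
        "log_e": pd.Series(log_e, index=area_df.index, name="log_e"),
        "sample_effect": pd.Series(b, index=area_df.index, name="sample_effect"),
        "group_log_means": pd.DataFrame(mu, index=list(names), columns=feat_ids),
        "structural_blocks": [(feat_ids[j], names[g]) for j, g in design.structural_absent],
        "group_leak_code": dict(zip(names, group_leak_code.tolist())),
        "design": asdict(design),
    }
    return conc_ds, area_ds, truth
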