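"""Internal-standard based normalizations: ccmn, nomis and single-IS ratio.

ccmn treats systematic error and the study factor as independent sources of
variation on the internal standards: the log IS matrix is first projected onto
the orthogonal complement of the one-hot group design, so IS variance
explained by the biology is *not* removed from the analytes.  nomis regresses
analytes on the raw (centered) log IS matrix and therefore may strip
group-correlated variation as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MetDataset, split_standards

__all__ = [
    "NormalizationModel",
    "normalize_ccmn",
    "normalize_nomis",
    "normalize_is_ratio",
]


@dataclass
class NormalizationModel:
    method: str
    design_levels: list[str]
    n_components: int
    scores: np.ndarray  # samples x np systematic-error estimates (ccmn) or centered log IS (nomis)
    coefficients: np.ndarray  # np x analytes regression coefficients
    log_internal: bool
    back_transformed: bool
    is_feature_ids: list[str] = field(default_factory=list)


def _design_matrix(d: MetDataset) -> tuple[np.ndarray, list[str]]:
    """One-hot encoding of the biological group; QC samples form their own level."""
    g = d.effective_group()
    levels = list(pd.unique(g))
    Z = np.column_stack([(g == lv).to_numpy(float) for lv in levels])
    return Z, [str(lv) for lv in levels]


def _check_positive(values: pd.DataFrame, method: str) -> None:
    arr = values.to_numpy()
    bad = np.argwhere(~(arr > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{method}: non-positive value {arr[i, j]!r} at sample "
            f"{values.index[i]!r}, feature {values.columns[j]!r}; log-scale "
            "normalization requires strictly positive data"
        )


def _split_logged(d: MetDataset, method: str) -> tuple[MetDataset, np.ndarray, np.ndarray]:
    analytes, standards = split_standards(d)
    if analytes.values.isna().any().any() or standards.values.isna().any().any():
        raise ValueError(f"{method}: missing values present; impute first")
    _check_positive(analytes.values, method)
    _check_positive(standards.values, method)
    return analytes, np.log(analytes.matrix), np.log(standards.matrix)


def normalize_ccmn(
    d: MetDataset,
    n_components: int | str = "auto",
    log_internal: bool = True,
) -> tuple[MetDataset, NormalizationModel]:
    """Cross-contribution compensating multiple standard normalization.

    Steps: (1) column-center the log IS matrix; (2) project onto the
    orthogonal complement of the one-hot group design; (3) PCA the residual,
    keeping ``n_components`` score vectors; (4) OLS-regress each centered log
    analyte on the scores and subtract the fit; (5) restore analyte means and
    exponentiate.  IS columns are dropped from the output.
    """
    if not log_internal:
        raise NotImplementedError("only log-scale internal computation is supported")
    analytes, logX, logS = _split_logged(d, "ccmn")
    q = logS.shape[1]
    np_ = min(2, q) if n_components == "auto" else int(n_components)
    if np_ < 1 or np_ > q:
        raise ValueError(f"n_components must be in [1, {q}] (number of internal standards)")

    Z, levels = _design_matrix(d)
    Sc = logS - logS.mean(axis=0)
    # residual of IS after the study-factor fit: (I - Z (Z'Z)^+ Z') Sc
    beta, *_ = np.linalg.lstsq(Z, Sc, rcond=None)
    E = Sc - Z @ beta
    # PCA scores of the residual IS matrix
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    T = U[:, :np_] * s[:np_]

    mu = logX.mean(axis=0)
    Xc = logX - mu
    B, *_ = np.linalg.lstsq(T, Xc, rcond=None)
    corrected = Xc - T @ B + mu

    out = analytes.with_values(
        pd.DataFrame(np.exp(corrected), index=analytes.sample_ids, columns=analytes.feature_ids),
        unit_tag=d.unit_tag,
    )
    model = NormalizationModel(
        method="ccmn",
        design_levels=levels,
        n_components=np_,
        scores=T,
        coefficients=B,
        log_internal=True,
        back_transformed=True,
        is_feature_ids=[str(f) for f in d.feature_ids[d.is_internal_standard.to_numpy()]],
    )
    return out, model


def normalize_nomis(d: MetDataset) -> tuple[MetDataset, NormalizationModel]:
    """Regress centered log analytes on the centered log IS matrix and remove the fit.

    No design orthogonalization: biological variation leaking into the ISs is
    removed along with the technical error.
    """
    analytes, logX, logS = _split_logged(d, "nomis")
    Sc = logS - logS.mean(axis=0)
    mu = logX.mean(axis=0)
    Xc = logX - mu
    B, *_ = np.linalg.lstsq(Sc, Xc, rcond=None)
    corrected = Xc - Sc @ B + mu
    out = analytes.with_values(
        pd.DataFrame(np.exp(corrected), index=analytes.sample_ids, columns=analytes.feature_ids),
        unit_tag=d.unit_tag,
    )
    model = NormalizationModel(
        method="nomis",
        design_levels=[],
        n_components=Sc.shape[1],
        scores=Sc,
        coefficients=B,
        log_internal=True,
        back_transformed=True,
        is_feature_ids=[str(f) for f in d.feature_ids[d.is_internal_standard.to_numpy()]],
    )
    return out, model


def normalize_is_ratio(d: MetDataset, is_feature: str) -> MetDataset:
    """Divide every analyte value in sample i by the named IS value in sample i."""
    if is_feature not in d.feature_ids:
        raise KeyError(f"unknown feature {is_feature!r}")
    if not d.is_internal_standard.loc[is_feature]:
        raise ValueError(f"feature {is_feature!r} is not flagged as an internal standard")
    ref = d.values[is_feature]
    if not (ref > 0).all():
        bad = ref.index[~(ref > 0)].tolist()
        raise ValueError(f"IS {is_feature!r} has non-positive values in samples {bad}")
    analytes, _ = split_standards(d)
    out_values = analytes.values.div(ref, axis=0)
    return analytes.with_values(out_values, unit_tag=d.unit_tag)
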