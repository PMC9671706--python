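"""Normalization, expression filters and covariate adjustment.

The preprocessing contract, in the order the pipeline applies it:

1. ``quantile_normalize`` on the linear-scale matrix — every array is forced
   onto the common (row-mean) reference distribution, so array medians (and
   every other quantile) become identical.
2. ``intensity_filter`` — drop transcripts that never rise above the
   background signal (> ``min_signal`` linear units in at least
   ``min_fraction`` of the arrays).
3. ``log2_transform``.
4. ``iqr_filter`` — drop the uninformative half: keep a transcript only if
   its interquartile range on the log2 scale strictly exceeds the median
   IQR over all transcripts.
5. ``adjust_covariates`` — regress out age/gender (the removeBatchEffect
   contract: the group effect and intercept are protected, only the
   centered covariate contribution is subtracted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ConsistencyError

__all__ = [
    "FilterReport",
    "quantile_normalize",
    "log2_transform",
    "intensity_filter",
    "iqr_filter",
    "adjust_covariates",
]

#: Quartile convention used by ``iqr_filter`` (numpy's interpolation name);
#: recorded in every FilterReport so a rerun can reproduce the cut exactly.
QUARTILE_METHOD = "linear"


@dataclass
class FilterReport:
    """Bookkeeping for the expression filters.

    A single filter fills only the fields it knows; the pipeline merges the
    two stage reports into one record with both counts.
    """

    n_input: int
    n_after_intensity: int | None = None
    n_after_iqr: int | None = None
    median_iqr: float | None = None
    removed_ids: list[str] = field(default_factory=list)
    quartile_method: str = QUARTILE_METHOD

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def merge(intensity: "FilterReport", iqr: "FilterReport") -> "FilterReport":
        if intensity.n_after_intensity != iqr.n_input:
            raise ConsistencyError(
                "IQR filter input count does not match intensity filter output"
            )
        return FilterReport(
            n_input=intensity.n_input,
            n_after_intensity=intensity.n_after_intensity,
            n_after_iqr=iqr.n_after_iqr,
            median_iqr=iqr.median_iqr,
            removed_ids=intensity.removed_ids + iqr.removed_ids,
        )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column's sorted values are replaced by that reference.  Ties within a
    column all receive the mean of the reference values at their tied
    ranks, so the map is well defined and permutation-symmetric.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = m.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # ties: average the reference values assigned within each tied group
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=mapped)
        out[:, j] = (sums / counts)[inverse]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), m.scale
    )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Linear -> log2.  Non-positive values are a domain error naming the cell."""
    if m.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    values = m.values
    if values.size and values.min() <= 0:
        g, s = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive value at gene {m.gene_ids[g]!r}, sample {m.sample_ids[s]!r}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values), index=m.data.index, columns=m.data.columns),
        "log2",
    )


def intensity_filter(
    m: ExpressionMatrix,
    min_signal: float = 100.0,
    min_fraction: float = 0.25,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with signal strictly above ``min_signal`` in at least
    ``min_fraction`` of the arrays (fraction compared with >=).

    The threshold is a linear-intensity criterion, so log2 input is refused.
    """
    if m.scale != "linear":
        raise ValueError("intensity filter operates on the linear scale")
    values = m.values
    frac = (values > min_signal).mean(axis=1)
    keep = frac >= min_fraction
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    report = FilterReport(
        n_input=m.shape[0],
        n_after_intensity=int(keep.sum()),
        removed_ids=removed,
    )
    kept = ExpressionMatrix(m.data.loc[keep], m.scale)
    return kept, report


def iqr_filter(m: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes whose log2 IQR strictly exceeds the median gene IQR.

    Strictness means a matrix where every gene has the same IQR loses all
    genes — by construction half the transcriptome (at most) survives.
    """
    if m.scale != "log2":
        raise ValueError("IQR filter operates on the log2 scale")
    if m.shape[1] < 4:
        raise ValueError("IQR filter needs at least 4 samples")
    values = m.values
    q1, q3 = np.percentile(values, [25, 75], axis=1, method=QUARTILE_METHOD)
    iqr = q3 - q1
    median_iqr = float(np.median(iqr))
    keep = iqr > median_iqr
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    report = FilterReport(
        n_input=m.shape[0],
        n_after_iqr=int(keep.sum()),
        median_iqr=median_iqr,
        removed_ids=removed,
    )
    kept = ExpressionMatrix(m.data.loc[keep], m.scale)
    return kept, report


def _design_matrix(
    meta: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Build [intercept | group | centered covariates] aligned to meta rows.

    Returns (X, cov_block) where cov_block is the centered covariate part of
    X (zero columns when no covariates).  Missing ages are mean-imputed;
    a missing gender becomes its own factor level, so no sample is dropped.
    """
    n = len(meta)
    intercept = np.ones(n)
    group = (meta["group"] == "schizophrenic").to_numpy(dtype=float)
    cov_cols: list[np.ndarray] = []
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not present in metadata")
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.to_numpy(dtype=float)
            if np.isnan(vals).all():
                raise ValueError(f"covariate {cov!r} is entirely missing")
            vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
            cov_cols.append(vals - vals.mean())
        else:
            levels = col.fillna("missing").astype(str)
            uniq = sorted(levels.unique())
            for level in uniq[1:]:  # first level is the baseline
                indicator = (levels == level).to_numpy(dtype=float)
                cov_cols.append(indicator - indicator.mean())
    cov_block = np.column_stack(cov_cols) if cov_cols else np.zeros((n, 0))
    X = np.column_stack([intercept, group, cov_block])
    return X, cov_block


def adjust_covariates(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    covariates: list[str] | None = None,
) -> ExpressionMatrix:
    """Remove covariate contributions from a log2 matrix, gene by gene.

    Per gene an ordinary least-squares fit on [intercept, group indicator,
    covariates] is computed and only the fitted *covariate* part (centered)
    is subtracted — the intercept and the case/control effect are left in
    the data.  Applying the adjustment twice is a no-op because the
    refitted covariate coefficients of an adjusted matrix are zero.
    """
    if covariates is None:
        covariates = ["age", "gender"]
    if not covariates:
        return m.copy()
    if m.scale != "log2":
        raise ValueError("covariate adjustment expects a log2-scale matrix")
    meta_idx = meta.set_index("sample_id").loc[m.sample_ids].reset_index()
    X, cov_block = _design_matrix(meta_idx, covariates)
    if cov_block.shape[1] == 0:
        return m.copy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: a covariate is confounded with the group "
            "labels (or constant); adjustment would be unidentifiable"
        )
    Y = m.values  # genes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (1 + 1 + c) x genes
    cov_beta = beta[2:, :]
    adjusted = Y - (cov_block @ cov_beta).T
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=m.data.index, columns=m.data.columns), "log2"
    )
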