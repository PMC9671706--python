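"""Two-group differential expression with empirical-Bayes moderation.

The model is the standard hierarchical one for array data: gene-wise sample
variances s_g^2 on d residual degrees of freedom are treated as scaled
chi-square draws around a true variance, and the true variances follow a
scaled inverse chi-square prior with hyperparameters d0 (prior df) and s0^2
(prior variance).  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

shrinks noisy gene variances toward the prior, and the moderated t

    t_g = log2FC_g / (s~_g * sqrt(1/n1 + 1/n2))

is referred to a t distribution on d0 + d degrees of freedom (standard
normal in the d0 = infinity limit).  d0 = 0 disables moderation and gives
the classical pooled-variance Student t.

Hyperparameters are estimated by the method of moments on log variances:
with e_g = log s_g^2 - digamma(d/2) + log(d/2),

    trigamma(d0/2) = var(e) - trigamma(d/2)
    log s0^2       = mean(e) + digamma(d0/2) - log(d0/2)

and d0 = infinity (with s0^2 = exp(mean(e))) when the right-hand side of
the first equation is non-positive, i.e. when the observed log variances
are no more dispersed than chi-square sampling noise alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionMatrix, GROUP_CASE, GROUP_CONTROL

__all__ = [
    "ModerationFit",
    "fit_moderation",
    "moderated_t_test",
    "benjamini_hochberg",
    "call_degs",
    "partition_lnc_mrna",
    "trigamma_inverse",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NOT_DE = "not_de"


@dataclass(frozen=True)
class ModerationFit:
    """Empirical-Bayes hyperparameters for variance shrinkage.

    d0 may be ``math.inf`` (complete shrinkage: every posterior variance
    equals s0_sq) or 0 (no shrinkage: ordinary Student t).
    """

    d0: float
    s0_sq: float
    residual_df: int

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic inverses 1/sqrt(y) (small y) and 1/y (large y) as
    starting points / shortcuts; converges in a handful of steps.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_moderation(variances: np.ndarray, residual_df: int) -> ModerationFit:
    """Method-of-moments fit of (d0, s0^2) from gene-wise sample variances.

    Zero or non-finite variances are excluded with a warning (they carry no
    information about the variance prior); at least 10 usable variances are
    required for the moments to mean anything.
    """
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    v = np.asarray(variances, dtype=float)
    usable = np.isfinite(v) & (v > 0)
    if usable.sum() < len(v):
        warnings.warn(
            f"excluding {int(len(v) - usable.sum())} zero/non-finite variances "
            "from the moderation fit",
            stacklevel=2,
        )
    v = v[usable]
    if len(v) < 10:
        raise ValueError("moderation fit needs at least 10 positive variances")
    d = residual_df
    e = np.log(v) - special.digamma(d / 2.0) + np.log(d / 2.0)
    ve = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if ve <= 0:
        return ModerationFit(d0=np.inf, s0_sq=float(np.exp(e.mean())), residual_df=d)
    d0 = 2.0 * trigamma_inverse(ve)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationFit(d0=float(d0), s0_sq=s0_sq, residual_df=d)


def _group_masks(m: ExpressionMatrix, meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    groups = meta.set_index("sample_id").loc[m.sample_ids, "group"]
    case = (groups == GROUP_CASE).to_numpy()
    control = (groups == GROUP_CONTROL).to_numpy()
    return case, control


def moderated_t_test(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    fit: ModerationFit | None = None,
    ordinary: bool = False,
) -> pd.DataFrame:
    """Per-gene case-vs-control moderated t-test on a log2 matrix.

    When ``fit`` is omitted the hyperparameters are estimated from the data
    (or fixed at d0 = 0 with ``ordinary=True``, reproducing the plain
    pooled-variance Student t).  Returns a DataFrame indexed by symbol with
    mean_case, mean_control, log2fc, t_stat, p_value and BH-adjusted adj_p.
    """
    case, control = _group_masks(m, meta)
    n1, n2 = int(case.sum()), int(control.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (case={n1}, control={n2})")
    values = m.values
    d = n1 + n2 - 2
    mean_case = values[:, case].mean(axis=1)
    mean_control = values[:, control].mean(axis=1)
    log2fc = mean_case - mean_control
    ss = ((values[:, case] - mean_case[:, None]) ** 2).sum(axis=1) + (
        (values[:, control] - mean_control[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d

    zero_var = s2 <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s); assigned p = 1",
            stacklevel=2,
        )

    if ordinary:
        fit = None
        d0, s0_sq = 0.0, 1.0  # s0 unused at d0 = 0
    elif fit is None:
        fit = fit_moderation(s2[~zero_var], d)
        d0, s0_sq = fit.d0, fit.s0_sq
    else:
        d0, s0_sq = fit.d0, fit.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # a gene with no variance and no mean difference is exactly null
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    p = np.where(zero_var & (log2fc != 0), 1.0, p) if d0 == 0 else p

    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "adj_p": benjamini_hochberg(p),
        },
        index=pd.Index(m.gene_ids, name="symbol"),
    )
    table.attrs["moderation"] = fit
    return table


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values.

    adj_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1; invariant under permutation of the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def call_degs(
    table: pd.DataFrame,
    lfc_cut: float = 0.5,
    fdr_cut: float = 0.001,
    strict_lfc: bool = False,
) -> pd.DataFrame:
    """Assign up/down/not_de status from the fold-change and FDR cut-offs.

    The fold-change comparator defaults to >= ``lfc_cut`` and can be made
    strict (>) with ``strict_lfc``; the FDR comparison is always strict
    (< ``fdr_cut``).
    """
    if "adj_p" not in table.columns:
        raise ValueError("call_degs requires an adj_p column (run the test first)")
    out = table.copy()
    lfc = out["log2fc"].to_numpy()
    if strict_lfc:
        passes_lfc = np.abs(lfc) > lfc_cut
    else:
        passes_lfc = np.abs(lfc) >= lfc_cut
    sig = passes_lfc & (out["adj_p"].to_numpy() < fdr_cut)
    status = np.where(sig & (lfc > 0), STATUS_UP, STATUS_NOT_DE)
    status = np.where(sig & (lfc < 0), STATUS_DOWN, status)
    out["status"] = status
    return out


def partition_lnc_mrna(
    table: pd.DataFrame, lnc_symbols: set[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the DE genes into DElncRNAs and DEmRNAs by exact symbol match.

    Any DE gene whose symbol appears in the (HGNC-style) lncRNA list is a
    DElncRNA; every other DE gene is treated as a DEmRNA.  Matching is
    case-sensitive, mirroring a symbol-merge against the approved list.
    A ``biotype`` column is added to both partitions.
    """
    if "status" not in table.columns:
        raise ValueError("partition requires DE status (run call_degs first)")
    de = table[table["status"] != STATUS_NOT_DE]
    is_lnc = de.index.isin(lnc_symbols)
    delnc = de[is_lnc].copy()
    delnc["biotype"] = "lncRNA"
    demrna = de[~is_lnc].copy()
    demrna["biotype"] = "mRNA"
    return delnc, demrna
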