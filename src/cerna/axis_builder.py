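"""Construction and gating of lncRNA-miRNA-mRNA ceRNA axes.

The ceRNA hypothesis predicts that a lncRNA sponging a miRNA relieves
repression of that miRNA's mRNA targets, so sponge and target should be
*positively* co-expressed.  The procedure implemented here:

1. keep only trustworthy database edges (human, high-confidence
   lncRNA-miRNA; strong-evidence miRNA-mRNA),
2. enumerate candidate triples (L, m, G) where L is a DElncRNA, G a DEmRNA
   and both edges exist,
3. gate each triple on the Pearson correlation of L and G across all
   samples: r > r_min and BH-adjusted correlation p < fdr_max,
4. drop triples whose lncRNA and mRNA moved in opposite directions between
   cases and controls (the omission rule for opposing expression patterns),
5. overlay protein-protein interaction edges among the surviving axis
   mRNAs at a minimum combined score.

The miRNA is purely combinatorial throughout: arrays do not measure mature
miRNAs, so no miRNA expression enters any statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ConsistencyError,
    ExpressionMatrix,
    InteractionEdge,
    LNC_MIR,
    MIR_MRNA,
    PPIEdge,
)
from .diffexpr import benjamini_hochberg, STATUS_NOT_DE

__all__ = [
    "CandidateTriple",
    "CeRNAAxis",
    "filter_interactions",
    "build_candidate_triples",
    "correlate_pairs",
    "assemble_axes",
    "overlay_ppi",
    "axis_summary",
]


@dataclass(frozen=True, order=True)
class CandidateTriple:
    lncrna: str
    mirna: str
    mrna: str


@dataclass(frozen=True, order=True)
class CeRNAAxis:
    """A candidate triple that passed every gate, with its evidence."""

    lncrna: str
    mirna: str
    mrna: str
    r: float
    corr_fdr: float
    direction: str  # shared DE direction: "up" or "down"

    @property
    def triple(self) -> CandidateTriple:
        return CandidateTriple(self.lncrna, self.mirna, self.mrna)


def filter_interactions(edges: list[InteractionEdge], kind: str) -> list[InteractionEdge]:
    """Apply the database trust filters and deduplicate.

    lncRNA-miRNA edges survive only for Homo sapiens at high confidence;
    miRNA-mRNA edges only with strong experimental evidence.  Edge identity
    is the (source, target) pair, so a low-confidence duplicate of a kept
    edge simply disappears.
    """
    kept: dict[tuple[str, str], InteractionEdge] = {}
    for e in edges:
        if e.kind != kind:
            raise ConsistencyError(f"edge {e.source}->{e.target} has kind {e.kind}")
        if kind == LNC_MIR:
            ok = e.species.casefold() == "homo sapiens" and e.qualifier == "high"
        elif kind == MIR_MRNA:
            ok = e.qualifier == "strong"
        else:
            raise ValueError(f"unknown kind {kind!r}")
        if ok:
            kept.setdefault((e.source, e.target), e)
    return list(kept.values())


def build_candidate_triples(
    delnc: set[str],
    demrna: set[str],
    lnc_mir: list[InteractionEdge],
    mir_mrna: list[InteractionEdge],
) -> list[CandidateTriple]:
    """All (L, m, G) with L a DElncRNA, G a DEmRNA and both edges present.

    Output is deduplicated and in deterministic lexicographic order.
    """
    targets_of: dict[str, set[str]] = {}
    for e in mir_mrna:
        targets_of.setdefault(e.source, set()).add(e.target)
    triples = set()
    for e in lnc_mir:
        if e.source not in delnc:
            continue
        for g in targets_of.get(e.target, ()):
            if g in demrna:
                triples.add(CandidateTriple(e.source, e.target, g))
    return sorted(triples)


def correlate_pairs(
    m: ExpressionMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r, p and BH FDR for each unique (lncRNA, mRNA) pair.

    r pools all samples (cases + controls); the p-value is the usual exact
    two-sided one from t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 df.  BH runs
    across the unique pair list.  Zero-variance members make r undefined:
    such pairs are dropped with a warning.
    """
    if m.shape[1] < 4:
        raise ValueError("correlation needs at least 4 samples")
    unique_pairs = sorted(set(pairs))
    missing = [s for p in unique_pairs for s in p if s not in m.data.index]
    if missing:
        raise ConsistencyError(f"symbol {missing[0]!r} not present in the matrix")
    n = m.shape[1]
    rows = []
    for lnc, mrna in unique_pairs:
        x = m.data.loc[lnc].to_numpy()
        y = m.data.loc[mrna].to_numpy()
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            warnings.warn(
                f"pair ({lnc}, {mrna}) dropped: zero variance makes r undefined",
                stacklevel=2,
            )
            continue
        r = float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1, 1))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        rows.append({"lncrna": lnc, "mrna": mrna, "r": r, "p_value": p})
    out = pd.DataFrame(rows, columns=["lncrna", "mrna", "r", "p_value"])
    out["fdr"] = benjamini_hochberg(out["p_value"]) if len(out) else []
    return out


def assemble_axes(
    triples: list[CandidateTriple],
    de_table: pd.DataFrame,
    correlations: pd.DataFrame,
    r_min: float = 0.5,
    fdr_max: float = 0.001,
    dropped_pairs: frozenset[tuple[str, str]] = frozenset(),
) -> list[CeRNAAxis]:
    """Gate candidate triples into ceRNA axes.

    A triple survives iff r > r_min (strict), correlation FDR < fdr_max
    (strict), and the lncRNA and mRNA share a DE direction; a negative or
    discordant pair is the "opposing expression pattern" the method omits.
    A triple lacking a correlation record is a consistency error, unless the
    caller lists the pair in ``dropped_pairs`` (zero-variance pairs removed
    by ``correlate_pairs`` with a warning), in which case it is skipped.
    """
    corr_idx = correlations.set_index(["lncrna", "mrna"])
    axes = []
    for tr in triples:
        key = (tr.lncrna, tr.mrna)
        if key not in corr_idx.index:
            if key in dropped_pairs:
                continue
            raise ConsistencyError(
                f"no correlation record for pair ({tr.lncrna}, {tr.mrna})"
            )
        rec = corr_idx.loc[key]
        for sym in (tr.lncrna, tr.mrna):
            if sym not in de_table.index:
                raise ConsistencyError(f"symbol {sym!r} missing from the DE table")
        d_lnc = de_table.loc[tr.lncrna, "status"]
        d_mrna = de_table.loc[tr.mrna, "status"]
        if d_lnc == STATUS_NOT_DE or d_mrna == STATUS_NOT_DE or d_lnc != d_mrna:
            continue
        if not (rec["r"] > r_min and rec["fdr"] < fdr_max):
            continue
        axes.append(
            CeRNAAxis(
                lncrna=tr.lncrna,
                mirna=tr.mirna,
                mrna=tr.mrna,
                r=float(rec["r"]),
                corr_fdr=float(rec["fdr"]),
                direction=str(d_lnc),
            )
        )
    return sorted(axes)


def overlay_ppi(
    axes: list[CeRNAAxis], ppi: list[PPIEdge], min_score: float = 0.4
) -> list[PPIEdge]:
    """PPI edges at combined score >= min_score linking two distinct axis mRNAs."""
    axis_mrnas = {ax.mrna for ax in axes}
    kept: dict[tuple[str, str], PPIEdge] = {}
    for e in ppi:
        if e.combined_score >= min_score and e.protein_a in axis_mrnas and e.protein_b in axis_mrnas:
            kept.setdefault(e.key, e)
    return [kept[k] for k in sorted(kept)]


def axis_summary(axes: list[CeRNAAxis]) -> dict[str, int]:
    """Counts of axes and distinct members, the shape of the Results narrative."""
    return {
        "n_axes": len(axes),
        "n_lncrna": len({a.lncrna for a in axes}),
        "n_mirna": len({a.mirna for a in axes}),
        "n_mrna": len({a.mrna for a in axes}),
    }


def axes_to_frame(axes: list[CeRNAAxis]) -> pd.DataFrame:
    """Tabular form of an axis list (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "lncrna": a.lncrna,
                "mirna": a.mirna,
                "mrna": a.mrna,
                "r": a.r,
                "corr_fdr": a.corr_fdr,
                "direction": a.direction,
            }
            for a in axes
        ],
        columns=["lncrna", "mirna", "mrna", "r", "corr_fdr", "direction"],
    )
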