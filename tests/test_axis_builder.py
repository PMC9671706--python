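import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerna.axis_builder import (
    CandidateTriple,
    CeRNAAxis,
    assemble_axes,
    build_candidate_triples,
    correlate_pairs,
    filter_interactions,
    overlay_ppi,
)
from cerna.io_formats import ConsistencyError, InteractionEdge, LNC_MIR, MIR_MRNA, PPIEdge
from conftest import make_matrix


def _lm(l, m, species="Homo sapiens", conf="high"):
    return InteractionEdge(l, m, LNC_MIR, species, conf)


def _mm(m, g, evidence="strong"):
    return InteractionEdge(m, g, MIR_MRNA, "Homo sapiens", evidence)


# ---------------------------------------------------------------------------
# interaction filtering
# ---------------------------------------------------------------------------


def test_filter_keeps_high_confidence_human_only():
    edges = [
        _lm("L1", "m1"),
        _lm("L1", "m1", conf="low"),  # duplicate at low confidence
        _lm("L2", "m1", species="Mus musculus"),
        _lm("L3", "m2", conf="low"),
    ]
    kept = filter_interactions(edges, LNC_MIR)
    assert kept == [_lm("L1", "m1")]


def test_filter_keeps_strong_evidence_only():
    edges = [_mm("m1", "G1"), _mm("m1", "G2", evidence="weak")]
    assert filter_interactions(edges, MIR_MRNA) == [_mm("m1", "G1")]


# ---------------------------------------------------------------------------
# candidate triples
# ---------------------------------------------------------------------------


def test_triples_minimal_and_missing_demrna():
    lnc_mir = [_lm("L1", "m1")]
    mir_mrna = [_mm("m1", "G1")]
    assert build_candidate_triples({"L1"}, {"G1"}, lnc_mir, mir_mrna) == [
        CandidateTriple("L1", "m1", "G1")
    ]
    assert build_candidate_triples({"L1"}, set(), lnc_mir, mir_mrna) == []


def test_triples_enumeration_example():
    lnc_mir = [_lm("L1", "m1"), _lm("L1", "m2")]
    mir_mrna = [_mm("m1", "G1"), _mm("m1", "G2"), _mm("m2", "G1")]
    triples = build_candidate_triples({"L1"}, {"G1", "G2"}, lnc_mir, mir_mrna)
    assert triples == [
        CandidateTriple("L1", "m1", "G1"),
        CandidateTriple("L1", "m1", "G2"),
        CandidateTriple("L1", "m2", "G1"),
    ]


def test_triples_agree_with_brute_force(small_study):
    """Exhaustive cross-product enumeration over all symbols as the oracle."""
    study = small_study
    lnc_mir = filter_interactions(study.lnc_mir, LNC_MIR)
    mir_mrna = filter_interactions(study.mir_mrna, MIR_MRNA)
    delnc = {a.lncrna for a in study.truth.planted_axes}
    demrna = {a.mrna for a in study.truth.planted_axes}
    lm_set = {(e.source, e.target) for e in lnc_mir}
    mm_set = {(e.source, e.target) for e in mir_mrna}
    mirnas = {e.target for e in lnc_mir} | {e.source for e in mir_mrna}
    brute = sorted(
        CandidateTriple(l, m, g)
        for l, m, g in itertools.product(delnc, mirnas, demrna)
        if (l, m) in lm_set and (m, g) in mm_set
    )
    assert build_candidate_triples(delnc, demrna, lnc_mir, mir_mrna) == brute


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def test_correlate_perfect_and_anti_correlation():
    x = np.arange(10, dtype=float)
    m = make_matrix([x, x * 2 + 1, -x], genes=["L", "G+", "G-"])
    out = correlate_pairs(m, [("L", "G+"), ("L", "G-")]).set_index(["lncrna", "mrna"])
    assert out.loc[("L", "G+"), "r"] == pytest.approx(1.0)
    assert out.loc[("L", "G+"), "p_value"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc[("L", "G-"), "r"] == pytest.approx(-1.0)


def test_correlation_p_value_formula():
    """r = 0.5 at n = 51 gives p ~ 1.8e-4 (t = 4.041 on 49 df)."""
    rng = np.random.default_rng(0)
    # construct a pair with sample r exactly 0.5 via Gram-Schmidt
    n = 51
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std()
    y = 0.5 * x + np.sqrt(1 - 0.25) * z
    m = make_matrix([x + 8, y + 8], genes=["L", "G"])
    out = correlate_pairs(m, [("L", "G")])
    assert out["r"].iloc[0] == pytest.approx(0.5, abs=1e-12)
    assert out["p_value"].iloc[0] == pytest.approx(1.8e-4, rel=0.05)
    # independent oracle for the full tail computation
    r_ref, p_ref = stats.pearsonr(x, y)
    assert out["p_value"].iloc[0] == pytest.approx(p_ref, rel=1e-9)


def test_correlate_drops_zero_variance_pair():
    m = make_matrix([[1.0] * 6, list(range(6))], genes=["flat", "G"])
    with pytest.warns(UserWarning, match="zero variance"):
        out = correlate_pairs(m, [("flat", "G")])
    assert len(out) == 0


def test_correlate_requires_known_symbols():
    m = make_matrix(np.random.default_rng(0).normal(size=(2, 6)), genes=["A", "B"])
    with pytest.raises(ConsistencyError, match="missing|not present"):
        correlate_pairs(m, [("A", "NOPE")])


# ---------------------------------------------------------------------------
# axis assembly
# ---------------------------------------------------------------------------


def _de(statuses):
    return pd.DataFrame(
        {"status": list(statuses.values()), "log2fc": [1.0 if s == "up" else -1.0 for s in statuses.values()]},
        index=pd.Index(statuses.keys(), name="symbol"),
    )


def _corr(rows):
    return pd.DataFrame(rows, columns=["lncrna", "mrna", "r", "p_value", "fdr"])


def test_assemble_keeps_concordant_strong_pair():
    triples = [CandidateTriple("L1", "m1", "G1")]
    de = _de({"L1": "up", "G1": "up"})
    corr = _corr([["L1", "G1", 0.9, 1e-7, 1e-5]])
    axes = assemble_axes(triples, de, corr)
    assert axes == [CeRNAAxis("L1", "m1", "G1", 0.9, 1e-5, "up")]


@pytest.mark.parametrize(
    "r,fdr,d_lnc,d_mrna",
    [
        (0.6, 0.01, "up", "up"),  # FDR gate
        (0.5, 1e-5, "up", "up"),  # r not strictly above r_min
        (-0.8, 1e-9, "up", "down"),  # opposing directions
        (0.9, 1e-9, "up", "not_de"),  # mRNA no longer DE
    ],
)
def test_assemble_gates_reject(r, fdr, d_lnc, d_mrna):
    triples = [CandidateTriple("L1", "m1", "G1")]
    de = _de({"L1": d_lnc, "G1": d_mrna})
    corr = _corr([["L1", "G1", r, fdr / 10, fdr]])
    assert assemble_axes(triples, de, corr) == []


def test_assemble_missing_correlation_is_error():
    triples = [CandidateTriple("L1", "m1", "G1")]
    de = _de({"L1": "up", "G1": "up"})
    with pytest.raises(ConsistencyError, match="correlation"):
        assemble_axes(triples, de, _corr([]))
    # unless the pair was dropped upstream (zero variance)
    assert assemble_axes(triples, de, _corr([]), dropped_pairs=frozenset({("L1", "G1")})) == []


def test_emitted_axes_satisfy_all_gates_on_synthetic_data(small_config, tmp_path):
    """Re-check every emitted axis against the on-disk inputs and outputs,
    with fresh numpy computations rather than pipeline internals."""
    from cerna.pipeline import run_pipeline

    run_pipeline(
        {"simulate": True, "sim": small_config.to_dict(), "seed": small_config.seed},
        out_dir=tmp_path,
    )
    axes = pd.read_csv(tmp_path / "axes.tsv", sep="\t")
    de = pd.read_csv(tmp_path / "de_table.tsv", sep="\t", index_col=0)
    expr = pd.read_csv(tmp_path / "expression_processed.tsv", sep="\t", index_col=0)
    lm_edges = {
        (r.lncrna, r.mirna)
        for r in pd.read_csv(tmp_path / "inputs/lncrna_mirna.tsv", sep="\t").itertuples()
        if r.species == "Homo sapiens" and r.confidence == "high"
    }
    mm_edges = {
        (r.mirna, r.mrna)
        for r in pd.read_csv(tmp_path / "inputs/mirna_mrna.tsv", sep="\t").itertuples()
        if r.evidence == "strong"
    }
    for ax in axes.itertuples():
        assert (ax.lncrna, ax.mirna) in lm_edges
        assert (ax.mirna, ax.mrna) in mm_edges
        assert de.loc[ax.lncrna, "status"] == de.loc[ax.mrna, "status"] == ax.direction
        r = np.corrcoef(expr.loc[ax.lncrna], expr.loc[ax.mrna])[0, 1]
        assert r > 0.5
        assert r == pytest.approx(ax.r, abs=1e-4)
        assert ax.corr_fdr < 0.001


# ---------------------------------------------------------------------------
# PPI overlay
# ---------------------------------------------------------------------------


def test_overlay_ppi_score_and_membership_gates():
    axes = [
        CeRNAAxis("L1", "m1", "EGR1", 0.9, 1e-5, "up"),
        CeRNAAxis("L1", "m2", "TGFB2", 0.8, 1e-5, "up"),
    ]
    ppi = [
        PPIEdge("EGR1", "TGFB2", 0.45),   # kept (>= 0.4, both in axes)
        PPIEdge("EGR1", "TGFB2", 0.39),   # duplicate below threshold
        PPIEdge("EGR1", "DUSP6", 0.9),    # touches a non-axis gene
    ]
    kept = overlay_ppi(axes, ppi)
    assert kept == [PPIEdge("EGR1", "TGFB2", 0.45)]


def test_overlay_ppi_boundary_inclusive():
    axes = [CeRNAAxis("L", "m", "A", 0.9, 1e-5, "up"),
            CeRNAAxis("L", "m", "B", 0.9, 1e-5, "up")]
    assert overlay_ppi(axes, [PPIEdge("A", "B", 0.4)]) == [PPIEdge("A", "B", 0.4)]
    assert overlay_ppi(axes, [PPIEdge("A", "B", 0.399)]) == []
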