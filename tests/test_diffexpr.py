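import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cerna.diffexpr import (
    ModerationFit,
    benjamini_hochberg,
    call_degs,
    fit_moderation,
    moderated_t_test,
    partition_lnc_mrna,
    trigamma_inverse,
)
from conftest import make_matrix


def _bh_oracle(p):
    """Naive O(m^2) step-up: independent of the vectorised implementation."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    best = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, m * p[i] / rank)
        adj[i] = min(best, 1.0)
    return adj


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def test_bh_hand_example():
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_value():
    np.testing.assert_allclose(benjamini_hochberg([0.5]), [0.5])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.1, 1.5])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from([0.0, 0.001, 0.01, 0.2, 0.5, 0.8, 1.0]), min_size=1, max_size=8))
def test_bh_matches_naive_oracle(p):
    np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(p), atol=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
    st.randoms(use_true_random=False),
)
def test_bh_invariant_under_permutation(p, rnd):
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    direct = benjamini_hochberg(p)
    shuffled = benjamini_hochberg([p[i] for i in perm])
    np.testing.assert_allclose([shuffled[perm.index(i)] for i in range(len(p))], direct)


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=500)
    np.testing.assert_allclose(
        benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
    )


# ---------------------------------------------------------------------------
# moderation hyperparameters
# ---------------------------------------------------------------------------


def test_trigamma_inverse_roundtrip():
    from scipy.special import polygamma

    for y in [1e-5, 0.01, 0.5, 3.0, 1e6]:
        x = trigamma_inverse(y)
        assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


def test_fit_moderation_recovers_prior():
    """Parameter recovery from a scaled-inverse-chi-square variance prior."""
    d0_true, s0_true, d, genes = 4.0, 0.04, 48, 5000
    d0_est, s0_est = [], []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, genes)
        s2 = sigma2 * rng.chisquare(d, genes) / d
        fit = fit_moderation(s2, d)
        d0_est.append(fit.d0)
        s0_est.append(fit.s0_sq)
    assert 2.5 <= np.mean(d0_est) <= 6.5
    assert np.mean(s0_est) == pytest.approx(s0_true, rel=0.25)


def test_fit_moderation_equal_variances_give_infinite_d0():
    from scipy.special import digamma

    fit = fit_moderation(np.full(100, 0.25), residual_df=10)
    assert np.isinf(fit.d0)
    # s0^2 = exp(mean(e)): the observed variance after undoing the
    # log-chi-square bias, not the raw 0.25
    expected = 0.25 * np.exp(np.log(5) - digamma(5))
    assert fit.s0_sq == pytest.approx(expected, rel=1e-9)


def test_fit_moderation_needs_ten_variances():
    with pytest.raises(ValueError, match="10"):
        fit_moderation(np.full(5, 0.1), residual_df=10)


def test_fit_moderation_warns_on_zero_variances():
    v = np.concatenate([np.full(20, 0.1), [0.0]])
    with pytest.warns(UserWarning, match="excluding"):
        fit_moderation(v, residual_df=10)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _random_matrix(seed, genes=40, n1=5, n2=5):
    rng = np.random.default_rng(seed)
    vals = rng.normal(8, 1, (genes, n1 + n2)) * rng.uniform(0.5, 2, genes)[:, None]
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n1 + n2)],
            "group": ["schizophrenic"] * n1 + ["control"] * n2,
        }
    )
    return make_matrix(vals, samples=list(meta["sample_id"])), meta


def test_ordinary_equals_student_t():
    m, meta = _random_matrix(1)
    ours = moderated_t_test(m, meta, ordinary=True)
    case = m.values[:, :5]
    control = m.values[:, 5:]
    t_ref, p_ref = stats.ttest_ind(case, control, axis=1, equal_var=True)
    np.testing.assert_allclose(ours["t_stat"], t_ref, atol=1e-12)
    np.testing.assert_allclose(ours["p_value"], p_ref, atol=1e-12)


def test_infinite_d0_gives_constant_posterior_variance():
    m, meta = _random_matrix(2)
    fit = ModerationFit(d0=np.inf, s0_sq=0.5, residual_df=8)
    table = moderated_t_test(m, meta, fit=fit)
    # with s2_post constant, |t| must be proportional to |log2fc|
    se = np.sqrt(0.5 * (1 / 5 + 1 / 5))
    np.testing.assert_allclose(table["t_stat"], table["log2fc"] / se, atol=1e-12)


def test_zero_effect_gene_has_t_zero_p_one():
    vals = np.tile([1.0, 2.0, 1.0, 2.0], (3, 1))
    meta = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(4)],
         "group": ["schizophrenic", "schizophrenic", "control", "control"]}
    )
    m = make_matrix(vals, samples=list(meta["sample_id"]))
    table = moderated_t_test(m, meta, ordinary=True)
    assert table["log2fc"].eq(0).all()
    assert table["t_stat"].eq(0).all()
    assert table["p_value"].eq(1).all()


def test_group_smaller_than_two_rejected():
    vals = np.ones((12, 3))
    meta = pd.DataFrame(
        {"sample_id": ["a", "b", "c"],
         "group": ["schizophrenic", "control", "control"]}
    )
    with pytest.raises(ValueError, match=">= 2"):
        moderated_t_test(make_matrix(vals, samples=["a", "b", "c"]), meta)


def test_moderated_t_matches_limma(tmp_path):
    """Independent oracle: limma's lmFit + eBayes on the same matrix."""
    m, meta = _random_matrix(3, genes=60)
    df = m.data.copy()
    df.to_csv(tmp_path / "x.tsv", sep="\t")
    script = textwrap.dedent(
        """
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("x.tsv", row.names=1))
        grp <- factor(c(rep("case",5), rep("ctl",5)), levels=c("ctl","case"))
        fit <- eBayes(lmFit(x, model.matrix(~grp)))
        write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
                    "limma.tsv", sep="\t", quote=FALSE)
        """
    )
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    ours = moderated_t_test(m, meta)
    np.testing.assert_allclose(ours["t_stat"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(ours["p_value"], ref["p"], rtol=1e-5)


def test_null_data_respects_fdr_level():
    """Global null: the BH-adjusted rejection fraction at 0.05 stays near 0."""
    fractions = []
    for seed in range(100):
        m, meta = _random_matrix(seed + 1000, genes=100, n1=6, n2=6)
        table = moderated_t_test(m, meta)
        fractions.append((table["adj_p"] < 0.05).mean())
    assert np.mean(fractions) <= 0.05 + 0.01


def test_planted_effects_are_recovered_with_high_power():
    """Pure planted shifts of 1 log2 unit at noise 0.3, n = 25+25: nearly
    every planted gene is called at |log2FC| >= 0.5 and adj p < 0.001."""
    rng = np.random.default_rng(42)
    genes, n = 500, 50
    vals = rng.normal(8, 0.3, (genes, n))
    planted = rng.choice(genes, 50, replace=False)
    signs = rng.choice([-1.0, 1.0], 50)
    vals[planted, :25] += signs[:, None]
    meta = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)],
         "group": ["schizophrenic"] * 25 + ["control"] * 25}
    )
    table = call_degs(moderated_t_test(make_matrix(vals, samples=list(meta["sample_id"])), meta))
    called = (table.iloc[planted]["status"] != "not_de").mean()
    assert called >= 0.99


# ---------------------------------------------------------------------------
# DE calling and partitioning
# ---------------------------------------------------------------------------


def _table(rows):
    return pd.DataFrame(
        rows, columns=["log2fc", "adj_p"],
        index=pd.Index([f"g{i}" for i in range(len(rows))], name="symbol"),
    )


@pytest.mark.parametrize(
    "lfc,adj_p,strict,expected",
    [
        (0.6, 1e-4, False, "up"),
        (0.5, 1e-4, False, "up"),  # boundary under the >= comparator
        (0.5, 1e-4, True, "not_de"),  # boundary under strict >
        (-2.0, 0.001, False, "not_de"),  # FDR compared strictly
        (-0.7, 1e-5, False, "down"),
    ],
)
def test_call_degs_thresholds(lfc, adj_p, strict, expected):
    out = call_degs(_table([[lfc, adj_p]]), strict_lfc=strict)
    assert out["status"].iloc[0] == expected


def test_partition_by_symbol():
    table = call_degs(_table([[1.0, 1e-5], [1.0, 1e-5], [0.0, 0.9]]))
    table.index = ["PEG3-AS1", "EGR1", "OTHER"]
    delnc, demrna = partition_lnc_mrna(table, {"PEG3-AS1"})
    assert list(delnc.index) == ["PEG3-AS1"]
    assert list(demrna.index) == ["EGR1"]
    assert (delnc["biotype"] == "lncRNA").all()


def test_partition_empty_and_disjoint_lists():
    table = call_degs(_table([[1.0, 1e-5], [-1.0, 1e-5]]))
    delnc, demrna = partition_lnc_mrna(table, set())
    assert len(delnc) == 0 and len(demrna) == 2
    delnc, demrna = partition_lnc_mrna(table, {"XIST"})
    assert len(delnc) == 0 and len(demrna) == 2
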