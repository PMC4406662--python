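import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zrpage import (
    AnalysisConfig,
    ComparisonSpec,
    DegenerateInputError,
    SampleDesign,
    ValidationError,
    call_differential,
    filter_expressed,
    gene_significance,
    z_ratio,
)
from zrpage.diffexpr import anova_f

from conftest import random_zmatrix

CMP = ComparisonSpec("EXP", "CTRL")


def _zmat(exp_rows, ctrl_rows, genes=None):
    """Build a replicate Z matrix from per-gene replicate lists."""
    exp = np.atleast_2d(np.asarray(exp_rows, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl_rows, dtype=float))
    genes = genes or [f"G{i}" for i in range(exp.shape[0])]
    cols = [f"E_{j}" for j in range(exp.shape[1])] + [f"C_{j}" for j in range(ctrl.shape[1])]
    df = pd.DataFrame(np.hstack([exp, ctrl]), index=genes, columns=cols)
    design = SampleDesign({c: ("EXP" if c.startswith("E") else "CTRL") for c in cols})
    return df, design


def test_z_ratio_hand_computed_example():
    """d = [0.5, -0.5, 1.0, -1.0] has sd sqrt(2.5/3); ratios follow exactly."""
    z, design = _zmat(
        exp_rows=[[0.5, 0.5], [-0.5, -0.5], [1.0, 1.0], [-1.0, -1.0]],
        ctrl_rows=[[0.0, 0.0]] * 4,
    )
    zr = z_ratio(z, design, CMP)
    sd = np.sqrt(2.5 / 3)
    np.testing.assert_allclose(
        zr, np.array([0.5, -0.5, 1.0, -1.0]) / sd, atol=1e-12
    )
    np.testing.assert_allclose(zr.iloc[0], 0.5477, atol=5e-5)


def test_z_ratio_antisymmetric_under_group_swap():
    z, design = _zmat(np.random.default_rng(0).normal(size=(30, 3)),
                      np.random.default_rng(1).normal(size=(30, 3)))
    forward = z_ratio(z, design, CMP)
    backward = z_ratio(z, design, ComparisonSpec("CTRL", "EXP"))
    assert (forward == -backward).all()


def test_z_ratio_degenerate_when_all_differences_equal():
    z, design = _zmat([[1.0], [1.0], [1.0]], [[0.0], [0.0], [0.0]])
    with pytest.raises(DegenerateInputError):
        z_ratio(z, design, CMP)


@pytest.mark.parametrize("seed", range(10))
def test_z_ratio_matches_brute_force_oracle(seed):
    """Random 50-gene instances agree with a from-scratch recomputation."""
    rng = np.random.default_rng(seed)
    z, design = _zmat(rng.normal(size=(50, 3)), rng.normal(size=(50, 3)))
    zr = z_ratio(z, design, CMP)
    diffs = [
        np.mean([z.loc[g, c] for c in ("E_0", "E_1", "E_2")])
        - np.mean([z.loc[g, c] for c in ("C_0", "C_1", "C_2")])
        for g in z.index
    ]
    sd = np.std(diffs, ddof=1)
    np.testing.assert_allclose(zr.to_numpy(), np.array(diffs) / sd, atol=1e-12)


def test_welch_significance_frozen_example():
    """Replicates {1,2,3} vs {2,3,4}: t = -1.2247, df = 4, p = 0.2878."""
    z, design = _zmat([[1.0, 2.0, 3.0]], [[2.0, 3.0, 4.0]])
    p = gene_significance(z, design, CMP)
    t, df = -np.sqrt(1.5), 4.0
    expected = 2 * stats.t.sf(abs(t), df)
    assert p.iloc[0] == pytest.approx(expected, abs=1e-12)
    assert p.iloc[0] == pytest.approx(0.2879, abs=1e-3)


@pytest.mark.parametrize("seed", range(5))
def test_welch_matches_scipy_oracle(seed):
    rng = np.random.default_rng(seed)
    z, design = _zmat(rng.normal(size=(40, 3)), rng.normal(size=(40, 4)))
    p = gene_significance(z, design, CMP)
    a = z[["E_0", "E_1", "E_2"]].to_numpy()
    b = z[["C_0", "C_1", "C_2", "C_3"]].to_numpy()
    oracle = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    np.testing.assert_allclose(p.to_numpy(), oracle, atol=1e-12)


def test_welch_symmetry_and_degenerate_conventions():
    z, design = _zmat([[1.0, 2.0, 3.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
                      [[1.0, 2.0, 3.0], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
    p_fwd = gene_significance(z, design, CMP)
    p_bwd = gene_significance(z, design, ComparisonSpec("CTRL", "EXP"))
    np.testing.assert_allclose(p_fwd, p_bwd, atol=1e-15)
    assert p_fwd.iloc[0] == 1.0  # identical replicate sets
    assert p_fwd.iloc[1] == 1.0  # both constant, equal means
    assert p_fwd.iloc[2] == 0.0  # both constant, unequal means


@pytest.mark.parametrize(
    "zr, p, expected",
    [
        (1.6, 0.01, "up"),
        (-1.49, 0.001, "ns"),
        (2.0, 0.20, "ns"),
        (-2.5, 0.04, "down"),
        (1.5, 0.049, "up"),
    ],
)
def test_call_rule(zr, p, expected):
    assert call_differential(zr, p, AnalysisConfig()) == expected


def test_call_rejects_nan_and_vectorizes():
    with pytest.raises(ValidationError):
        call_differential(float("nan"), 0.01)
    zr = pd.Series([1.6, -1.49, 2.0], index=["A", "B", "C"])
    p = pd.Series([0.01, 0.001, 0.2], index=["A", "B", "C"])
    assert call_differential(zr, p).tolist() == ["up", "ns", "ns"]


def test_filter_expressed_trivial_cases():
    cols = [f"{g}_{r}" for g in ("A", "B", "C", "D") for r in (1, 2, 3)]
    design = SampleDesign({c: c.split("_")[0] for c in cols})
    flat = [0.5] * 12  # identical everywhere -> F = 0
    sep = [-2.0 + 1e-9 * i for i in range(3)] + [2.0] * 3 + [-2.0] * 3 + [2.0] * 3
    z = pd.DataFrame([flat, sep], index=["flat", "sep"], columns=cols)
    kept = filter_expressed(z, design, alpha=0.05)
    assert "flat" not in kept
    assert "sep" in kept


@pytest.mark.parametrize("seed", range(5))
def test_anova_matches_scipy_oracle(seed):
    cols = [f"{g}_{r}" for g in ("A", "B", "C", "D") for r in (1, 2, 3)]
    design = SampleDesign({c: c.split("_")[0] for c in cols})
    z = random_zmatrix(30, design, seed)
    res = anova_f(z, design)
    groups = [z[[c for c in cols if c.startswith(g)]].to_numpy() for g in "ABCD"]
    oracle = stats.f_oneway(*groups, axis=1)
    np.testing.assert_allclose(res["F"], oracle.statistic, atol=1e-10)
    np.testing.assert_allclose(res["p_value"], oracle.pvalue, atol=1e-10)


def test_group_with_single_replicate_rejected():
    z, design = _zmat([[1.0, 2.0]], [[3.0]])
    with pytest.raises(ValidationError, match="replicate"):
        gene_significance(z, design, CMP)


def test_universe_restriction_rescales_ratios():
    """The SD denominator is computed over the supplied gene universe."""
    rng = np.random.default_rng(4)
    z, design = _zmat(rng.normal(size=(50, 3)), rng.normal(size=(50, 3)))
    full = z_ratio(z, design, CMP)
    subset = z.index[:20]
    restricted = z_ratio(z, design, CMP, genes=pd.Index(subset))
    ratio = (full.loc[subset] / restricted).to_numpy()
    np.testing.assert_allclose(ratio, ratio[0], atol=1e-9)  # common rescale factor
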