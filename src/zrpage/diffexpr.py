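"""Per-gene Z-ratio differential expression for a named group pair.

The Z ratio for gene g between an experimental and a control group is the
difference of its group-mean Z scores divided by the sample SD of those
differences across all genes in the analysis universe:

    d_g       = meanZ_g(exp) - meanZ_g(ctrl)
    zratio_g  = d_g / sd_genes(d)        (denominator n-1)

A gene is called up when zratio >= +cutoff and its per-gene p-value is
below alpha, down when zratio <= -cutoff and p < alpha, otherwise ns
(default cutoff 1.5, alpha 0.05). The per-gene p-value is a Welch
two-sample t-test on the replicate Z scores; no multiple-testing
correction is applied, matching the raw P < 0.05 selection the Z-ratio
method uses.

An optional expression filter retains genes whose one-way ANOVA across
all design groups is significant, restricting the universe over which the
Z-ratio denominator is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .normalize import SD_DDOF, SampleDesign

GENE_RESULT_COLUMNS = ["mean_z_exp", "mean_z_ctrl", "z_ratio", "p_value", "call"]


@dataclass(frozen=True)
class ComparisonSpec:
    """An experimental-vs-control group pair, displayed as ``EXP-CTRL``.

    A positive Z ratio means higher expression in the experimental
    (first-named) group.
    """

    experimental: str
    control: str

    def __post_init__(self) -> None:
        if self.experimental == self.control:
            raise ValidationError(
                f"comparison groups must differ, got {self.experimental!r} twice"
            )

    @property
    def name(self) -> str:
        return f"{self.experimental}-{self.control}"

    @classmethod
    def parse(cls, text: str) -> "ComparisonSpec":
        """Parse an ``EXP-CTRL`` display name."""
        parts = text.split("-")
        if len(parts) != 2 or not all(parts):
            raise ValidationError(f"cannot parse comparison {text!r} as EXP-CTRL")
        return cls(parts[0], parts[1])

    def validate_against(self, design: SampleDesign) -> None:
        for g in (self.experimental, self.control):
            if g not in design.groups:
                raise ValidationError(f"comparison group {g!r} not in design groups")


@dataclass(frozen=True)
class AnalysisConfig:
    """Selection thresholds shared by the gene- and set-level calls."""

    z_ratio_cutoff: float = 1.5
    alpha: float = 0.05
    expression_filter_alpha: float = 0.05
    min_set_size: int = 5

    def __post_init__(self) -> None:
        if not (self.z_ratio_cutoff > 0):
            raise ValidationError(f"z_ratio_cutoff must be > 0, got {self.z_ratio_cutoff}")
        for name in ("alpha", "expression_filter_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.min_set_size < 0:
            raise ValidationError(f"min_set_size must be >= 0, got {self.min_set_size}")


def _group_arrays(z: pd.DataFrame, design: SampleDesign) -> list[np.ndarray]:
    return [z[design.samples_in(g)].to_numpy(dtype=float) for g in design.groups]


def anova_f(z: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Vectorized one-way ANOVA per gene across all design groups.

    Returns a DataFrame with columns ``F`` and ``p_value``. Genes with
    zero between- and within-group variance get F = 0, p = 1; zero
    within-group variance with distinct means gives F = inf, p = 0.
    """
    design.require_replicates(2)
    groups = _group_arrays(z, design)
    k = len(groups)
    if k < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, m in zip(groups, means.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0),
                     np.where(msb > 0, np.inf, 0.0))
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0.0, f),
                                              k - 1, n_total - k))
    return pd.DataFrame({"F": f, "p_value": p}, index=z.index)


def filter_expressed(
    z: pd.DataFrame, design: SampleDesign, alpha: float = 0.05
) -> pd.Index:
    """Genes whose replicate Z scores differ across groups (ANOVA p < alpha)."""
    res = anova_f(z, design)
    return res.index[res["p_value"] < alpha]


def z_ratio(
    z: pd.DataFrame,
    design: SampleDesign,
    cmp: ComparisonSpec,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Per-gene Z ratio for one comparison over the given gene universe.

    The SD in the denominator is computed over ``genes`` (all genes when
    None), so restricting the universe rescales every ratio.
    """
    cmp.validate_against(design)
    sub = z if genes is None else z.loc[genes]
    if sub.shape[0] < 2:
        raise ValidationError("z_ratio needs >= 2 genes")
    d = (
        sub[design.samples_in(cmp.experimental)].mean(axis=1)
        - sub[design.samples_in(cmp.control)].mean(axis=1)
    )
    sd = float(d.std(ddof=SD_DDOF))
    if sd == 0:
        raise DegenerateInputError(
            f"all group-mean differences identical for {cmp.name}; SD = 0"
        )
    return d / sd


def gene_significance(
    z: pd.DataFrame,
    design: SampleDesign,
    cmp: ComparisonSpec,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Welch two-sample t-test p-value per gene on replicate Z scores.

    Degenerate conventions: both groups constant with equal means -> p = 1;
    constant with unequal means -> p = 0.
    """
    cmp.validate_against(design)
    design.require_replicates(2)
    sub = z if genes is None else z.loc[genes]
    a = sub[design.samples_in(cmp.experimental)].to_numpy(dtype=float)
    b = sub[design.samples_in(cmp.control)].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return pd.Series(p, index=sub.index, name="p_value")


def call_differential(z_ratio, p, cfg: AnalysisConfig | None = None):
    """Joint cutoff call: up/down requires |z_ratio| >= cutoff AND p < alpha.

    Accepts scalars (returns a string) or aligned Series (returns a
    Series of calls). NaN inputs are rejected.
    """
    cfg = cfg or AnalysisConfig()
    if np.isscalar(z_ratio):
        if math.isnan(z_ratio) or math.isnan(p):
            raise ValidationError("NaN z_ratio or p-value")
        if not (0 <= p <= 1):
            raise ValidationError(f"p-value {p} outside [0, 1]")
        if z_ratio >= cfg.z_ratio_cutoff and p < cfg.alpha:
            return "up"
        if z_ratio <= -cfg.z_ratio_cutoff and p < cfg.alpha:
            return "down"
        return "ns"
    zr = np.asarray(z_ratio, dtype=float)
    pv = np.asarray(p, dtype=float)
    if np.isnan(zr).any() or np.isnan(pv).any():
        raise ValidationError("NaN z_ratio or p-value")
    calls = np.where(
        (zr >= cfg.z_ratio_cutoff) & (pv < cfg.alpha), "up",
        np.where((zr <= -cfg.z_ratio_cutoff) & (pv < cfg.alpha), "down", "ns"),
    )
    index = z_ratio.index if isinstance(z_ratio, pd.Series) else None
    return pd.Series(calls, index=index, name="call")


def differential_expression(
    z: pd.DataFrame,
    design: SampleDesign,
    cmp: ComparisonSpec,
    cfg: AnalysisConfig | None = None,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Full per-gene result table for one comparison.

    Columns: ``mean_z_exp, mean_z_ctrl, z_ratio, p_value, call``; index is
    the gene universe used (after optional filtering).
    """
    cfg = cfg or AnalysisConfig()
    sub = z if genes is None else z.loc[genes]
    zr = z_ratio(sub, design, cmp)
    pv = gene_significance(sub, design, cmp)
    return pd.DataFrame(
        {
            "mean_z_exp": sub[design.samples_in(cmp.experimental)].mean(axis=1),
            "mean_z_ctrl": sub[design.samples_in(cmp.control)].mean(axis=1),
            "z_ratio": zr,
            "p_value": pv,
            "call": call_differential(zr, pv, cfg),
        }
    )
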