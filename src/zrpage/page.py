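"""Parametric analysis of gene set enrichment (PAGE).

For a comparison summarized by per-gene Z ratios, a gene set S with m
measured members scores

    Z_S = (Sm - mu) * sqrt(m) / delta

where Sm is the mean member Z ratio and mu, delta are the mean and sample
SD (denominator n-1) of all Z ratios in the background. Under the null
that S is a random draw from the background, Z_S is approximately standard
normal, giving a two-sided p-value p = 2 * (1 - Phi(|Z_S|)).

A set is called up when Z_S >= cutoff and p < alpha, down when
Z_S <= -cutoff and p < alpha, otherwise ns; with the default cutoff 1.5
and alpha 0.05 the p criterion (|Z| > 1.96) is the binding one. Sets with
fewer measured members than ``min_set_size`` are reported as excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import AnalysisConfig
from .errors import DegenerateInputError, ValidationError
from .normalize import SD_DDOF

PAGE_COLUMNS = ["set_name", "m", "Sm", "mu", "delta", "z_score", "p_value", "call"]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with unique members."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"set {self.name!r} has duplicate members")


class GeneSetCollection:
    """Ordered collection of gene sets with unique names."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets = list(sets)
        names = [s.name for s in self._sets]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate set names: {dups[:5]}")
        self._by_name = {s.name: s for s in self._sets}

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._sets]


@dataclass(frozen=True)
class PageBackground:
    """Background distribution parameters of the Z ratios."""

    mu: float
    delta: float
    n: int


def page_background(z_ratios: pd.Series) -> PageBackground:
    """Mean and sample SD of the finite Z ratios forming the background."""
    vals = z_ratios.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValidationError("background needs >= 2 genes with finite Z ratios")
    delta = float(vals.std(ddof=SD_DDOF))
    if delta == 0:
        raise DegenerateInputError("background Z ratios have zero SD")
    return PageBackground(mu=float(vals.mean()), delta=delta, n=int(vals.size))


def page_pvalue(z: float) -> float:
    """Two-sided standard-normal tail probability 2*(1 - Phi(|z|))."""
    if not math.isfinite(z):
        raise ValidationError(f"z score must be finite, got {z}")
    return float(2.0 * stats.norm.sf(abs(z)))


def classify_gene_set(z: float, p: float, m: int, cfg: AnalysisConfig) -> str:
    """Joint call: up/down requires |Z| >= cutoff AND p < alpha; small sets excluded."""
    if m < 0:
        raise ValidationError(f"m must be >= 0, got {m}")
    if m < cfg.min_set_size:
        return "excluded"
    if math.isnan(z) or math.isnan(p):
        raise ValidationError("NaN z score or p-value")
    if z >= cfg.z_ratio_cutoff and p < cfg.alpha:
        return "up"
    if z <= -cfg.z_ratio_cutoff and p < cfg.alpha:
        return "down"
    return "ns"


def page_zscore(
    z_ratios: pd.Series,
    sets: GeneSetCollection,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Score every gene set against the Z-ratio background.

    Members absent from the background (or with non-finite Z ratio) are
    dropped before computing m and Sm; a set with no measured members is
    reported with m = 0 and call ``excluded``.

    Returns a DataFrame with columns ``set_name, m, Sm, mu, delta,
    z_score, p_value, call`` in collection order.
    """
    cfg = cfg or AnalysisConfig()
    finite = z_ratios[np.isfinite(z_ratios.to_numpy(dtype=float))]
    bg = page_background(finite)
    lookup = finite.to_dict()
    rows = []
    for gs in sets:
        member_vals = [lookup[g] for g in gs.members if g in lookup]
        m = len(member_vals)
        if m == 0:
            rows.append((gs.name, 0, np.nan, bg.mu, bg.delta, np.nan, np.nan, "excluded"))
            continue
        sm = float(np.mean(member_vals))
        z = (sm - bg.mu) * math.sqrt(m) / bg.delta
        p = page_pvalue(z)
        rows.append((gs.name, m, sm, bg.mu, bg.delta, z, p,
                     classify_gene_set(z, p, m, cfg)))
    return pd.DataFrame(rows, columns=PAGE_COLUMNS).set_index("set_name")
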