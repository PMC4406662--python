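"""File formats, pipeline orchestration and the run manifest.

All tabular artifacts are plain TSV with '.' decimal separator and fixed
column orders. Z ratios and gene-set Z scores are written with 4 decimal
places; other floats with 6 significant digits. Gene sets use the GMT
dialect (set name TAB description TAB member...). Every output is a pure
function of (inputs, config), so reruns are byte-identical; the manifest
records every convention needed to reproduce a run.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import compare as _compare
from .diffexpr import (
    AnalysisConfig,
    ComparisonSpec,
    differential_expression,
    filter_expressed,
)
from .errors import FormatError, ValidationError, ZrpageError
from .normalize import SD_DDOF, SampleDesign, zscore_normalize
from .page import GeneSet, GeneSetCollection, page_zscore
from .simdata import SimResult

logger = logging.getLogger("zrpage")

#: Columns rendered with 4 decimals (echoing Z-score precision like 5.0492).
_Z_COLUMNS = frozenset({"z_ratio", "z_score"})


def _fmt_cell(value, column: str) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return f"{value:.4f}" if column in _Z_COLUMNS else f"{value:.6g}"
    return str(value)


def write_table(df: pd.DataFrame, path: Path | str, index_label: str | None = None) -> None:
    """Write a DataFrame as deterministic TSV with the package's float rules."""
    path = Path(path)
    out = df.copy()
    for col in out.columns:
        out[col] = [_fmt_cell(v, col) for v in out[col]]
    out.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


# ---------------------------------------------------------------- expression


def write_expression(raw: pd.DataFrame, path: Path | str) -> None:
    # %.17g round-trips IEEE doubles exactly
    raw.to_csv(path, sep="\t", index_label=raw.index.name or "gene_id",
               float_format="%.17g")


def write_design(design: SampleDesign, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in design.assignments.items():
            fh.write(f"{sample}\t{group}\n")


def read_design(path: Path | str) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise FormatError(f"{path}: expected columns sample_id, group")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups[:5]}")
    return SampleDesign(assignments=dict(zip(df["sample_id"], df["group"])))


def read_expression(
    path: Path | str, design_path: Path | str
) -> tuple[pd.DataFrame, SampleDesign]:
    """Read an intensity matrix and its design table, cross-validated.

    Raises on duplicate gene ids, non-numeric cells (with coordinates),
    and design samples absent from the matrix header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dups[:5]}")
    # locate any malformed cell first, then convert with the exact parser
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {df.iloc[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    numeric = df.astype(float)
    design = read_design(design_path)
    missing = [s for s in design.sample_ids if s not in numeric.columns]
    if missing:
        raise ValidationError(
            f"{design_path}: design samples missing from matrix: {missing[:5]}"
        )
    numeric.index.name = "gene_id"
    out = numeric[list(design.sample_ids)]
    out.columns.name = "sample_id"
    return out, design


# ----------------------------------------------------------------------- GMT


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Parse a GMT file; duplicate members are dropped with a warning."""
    sets = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            if name in names:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: set %r has %d duplicate member(s); deduplicated",
                    path, lineno, name, len(members) - len(unique),
                )
            sets.append(GeneSet(name=name, description=description, members=tuple(unique)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: Path | str) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# --------------------------------------------------------------------- truth


def write_truth(result: SimResult, directory: Path | str) -> None:
    """Write ground truth as TSVs: per-gene effects/directions, coherent sets."""
    directory = Path(directory)
    truth = result.truth
    per_gene = pd.concat([truth.gene_effects, truth.expected_direction], axis=1)
    write_table(per_gene, directory / "truth_genes.tsv", index_label="gene_id")
    rows = pd.DataFrame(
        {"shift_sign": pd.Series(truth.coherent_sets, dtype=int)}
    )
    rows.index.name = "set_name"
    write_table(rows, directory / "truth_sets.tsv")


# ------------------------------------------------------------------ pipeline


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    expression: Path
    design: Path
    gene_sets: dict[str, Path]
    out_dir: Path
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    comparisons: list[str] = field(default_factory=list)
    cross_pairs: list[tuple[str, str]] = field(default_factory=list)
    expression_filter: bool = False
    log_base: float = 10.0
    top_k: int = 100
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    seed: int = 0

    def validate(self) -> None:
        for p in [self.expression, self.design, *self.gene_sets.values()]:
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")
        if not self.comparisons:
            raise ValidationError("comparisons: at least one EXP-CTRL pair required")
        for a, b in self.cross_pairs:
            for name in (a, b):
                if name not in self.comparisons:
                    raise ValidationError(
                        f"cross pair references unknown comparison {name!r}"
                    )


def load_pipeline_config(path: Path | str) -> PipelineConfig:
    """Load a TOML config file (see the README for the schema)."""
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    paths = data.get("paths", {})
    analysis = data.get("analysis", {})
    comparisons = data.get("comparisons", {})
    return PipelineConfig(
        expression=_resolve(paths["expression"]),
        design=_resolve(paths["design"]),
        gene_sets={k: _resolve(v) for k, v in paths.get("gene_sets", {}).items()},
        out_dir=_resolve(paths.get("out", "results")),
        analysis=AnalysisConfig(
            z_ratio_cutoff=analysis.get("z_ratio_cutoff", 1.5),
            alpha=analysis.get("alpha", 0.05),
            expression_filter_alpha=analysis.get("expression_filter_alpha", 0.05),
            min_set_size=analysis.get("min_set_size", 5),
        ),
        comparisons=list(comparisons.get("pairs", [])),
        cross_pairs=[tuple(p) for p in comparisons.get("cross", [])],
        expression_filter=analysis.get("expression_filter", False),
        log_base=analysis.get("log_base", 10.0),
        top_k=analysis.get("top_k", 100),
        cluster_metric=analysis.get("cluster_metric", "euclidean"),
        cluster_method=analysis.get("cluster_method", "average"),
        seed=data.get("seed", 0),
    )


def _write_manifest(cfg: PipelineConfig, path: Path) -> None:
    from . import __version__

    lines = {
        "zrpage_version": __version__,
        "log_base": f"{cfg.log_base:g}",
        "sd_denominator": f"n-{SD_DDOF}",
        "z_ratio_cutoff": f"{cfg.analysis.z_ratio_cutoff:g}",
        "alpha": f"{cfg.analysis.alpha:g}",
        "expression_filter": str(cfg.expression_filter),
        "expression_filter_alpha": f"{cfg.analysis.expression_filter_alpha:g}",
        "min_set_size": str(cfg.analysis.min_set_size),
        "top_k": str(cfg.top_k),
        "cluster_metric": cfg.cluster_metric,
        "cluster_method": cfg.cluster_method,
        "comparisons": ",".join(cfg.comparisons),
        "cross_pairs": ";".join(f"{a}~{b}" for a, b in cfg.cross_pairs),
        "seed": str(cfg.seed),
    }
    with open(path, "w") as fh:
        for k, v in lines.items():
            fh.write(f"{k}={v}\n")


def _write_cross(prefix: Path, calls_1: pd.Series, calls_2: pd.Series) -> None:
    cc = _compare.cross_classify(calls_1, calls_2)
    write_table(cc.table, prefix.with_suffix(".tsv"))
    ds = _compare.direction_stats(calls_1, calls_2)
    venn = _compare.venn_summary(calls_1, calls_2)
    summary = {
        **{f"n_{c}": str(n) for c, n in cc.counts.items()},
        "n_universe": str(cc.universe_size),
        "n_coincident": str(ds.n_coincident),
        "n_opposite": str(ds.n_opposite),
        "frac_opposite": f"{ds.fraction:.6g}" if ds.defined else "undefined",
        **{
            f"venn_{k}": str(getattr(venn, k))
            for k in ("first_only_up", "first_only_down", "second_only_up",
                      "second_only_down", "both_up", "both_down", "opposed")
        },
    }
    with open(prefix.parent / (prefix.name + "_summary.txt"), "w") as fh:
        for k, v in summary.items():
            fh.write(f"{k}={v}\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run normalization, per-comparison DE + PAGE, cross-comparisons,
    clustering and PCA; write all artifacts under ``cfg.out_dir``.

    Returns an in-memory bundle: per-comparison gene tables, per-collection
    PAGE tables, and the cluster/PCA results.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        raw, design = read_expression(cfg.expression, cfg.design)
        collections = {name: read_gmt(p) for name, p in cfg.gene_sets.items()}

        stage = "normalize"
        z = zscore_normalize(raw, log_base=cfg.log_base)

        stage = "expression filter"
        genes = None
        if cfg.expression_filter:
            genes = filter_expressed(z, design, cfg.analysis.expression_filter_alpha)
            logger.info("expression filter retained %d of %d genes",
                        len(genes), z.shape[0])

        stage = "differential expression"
        gene_results: dict[str, pd.DataFrame] = {}
        for name in cfg.comparisons:
            cmp = ComparisonSpec.parse(name)
            res = differential_expression(z, design, cmp, cfg.analysis, genes=genes)
            gene_results[name] = res
            write_table(res, out / f"genes_{name}.tsv", index_label="gene_id")

        stage = "gene-set enrichment"
        page_results: dict[str, dict[str, pd.DataFrame]] = {}
        for coll_name, coll in collections.items():
            page_results[coll_name] = {}
            for name in cfg.comparisons:
                pres = page_zscore(gene_results[name]["z_ratio"], coll, cfg.analysis)
                page_results[coll_name][name] = pres
                write_table(pres, out / f"page_{coll_name}_{name}.tsv")

        stage = "cross-comparisons"
        for a, b in cfg.cross_pairs:
            _write_cross(out / f"cross_genes_{a}_vs_{b}",
                         gene_results[a]["call"], gene_results[b]["call"])
            for coll_name in collections:
                _write_cross(
                    out / f"cross_page_{coll_name}_{a}_vs_{b}",
                    page_results[coll_name][a]["call"],
                    page_results[coll_name][b]["call"],
                )

        stage = "clustering"
        cluster_results = {}
        for coll_name in collections:
            table = pd.DataFrame(
                {name: page_results[coll_name][name]["z_score"]
                 for name in cfg.comparisons}
            ).dropna()
            if table.shape[0] >= 2:
                top = _cluster.select_top_sets(table, cfg.top_k)
                lo = _cluster.hcluster(top, metric=cfg.cluster_metric,
                                       method=cfg.cluster_method)
                cluster_results[coll_name] = (top, lo)
                write_table(top.loc[lo.order],
                            out / f"cluster_table_{coll_name}.tsv",
                            index_label="set_name")
                write_table(lo.merges, out / f"cluster_merges_{coll_name}.tsv",
                            index_label="step")

        stage = "pca"
        pca = _cluster.pca_groups(z, design)
        write_table(pca.coordinates, out / "pca_coordinates.tsv", index_label="group")
        write_table(pca.explained.to_frame("variance_fraction"),
                    out / "pca_explained.tsv", index_label="component")

        stage = "manifest"
        _write_manifest(cfg, out / "manifest.txt")
    except Exception as exc:
        raise ZrpageError(f"[stage: {stage}] {exc}") from exc

    return {
        "genes": gene_results,
        "page": page_results,
        "cluster": cluster_results,
        "pca": pca,
        "out_dir": out,
    }
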