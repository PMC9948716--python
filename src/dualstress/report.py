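"""Pipeline orchestration, run configuration and publication-style exports.

``run_pipeline`` executes normalize -> filter -> lfc/test/FDR -> DEG
summary -> trends -> RVD -> paralogue ratios and writes every result as a
TSV whose first line is a comment carrying the configuration hash, plus a
JSON manifest (configuration, input checksums, package version). Given
the same inputs and configuration the run is byte-identical.

The nine-column heatmap matrix mirrors the published layout: column 1 is
the log2 cross-strain control ratio, columns 2-4 and 5-7 the early/middle/
late lfc per strain, columns 8-9 the late-minus-early differences. The
identities col8 = col4 - col2 and col9 = col7 - col5 hold exactly; any
clamping of the color scale is a rendering concern only and stored values
are never clamped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    STRAINS,
    STRESS_TIMES,
    CountMatrix,
    DataValidationError,
    GeneSetCollection,
    ParalogueMap,
    SampleTable,
    write_counts,
)
from .normalize import (
    NormalizedMatrix,
    baseline_ratio_stats,
    compute_size_factors,
    filter_by_min_count,
    normalize,
    run_pca,
)
from .diffexpr import (
    classify_degs,
    compute_delta_lfc,
    differential_expression,
    select_trend_genes,
    summarize_degs,
)
from .rvd import RANK_SIGN_VARIANTS, compute_rvd_scores, rank_within_sample, select_extreme_genes
from .paralogue import compute_paralogue_ratios, flag_shifted_pairs

__all__ = ["RunConfig", "build_heatmap_matrix", "run_pipeline", "PipelineResult"]

HEATMAP_COLUMNS = (
    ["t0_log2_ratio"]
    + [f"{s}_{t}" for s in STRAINS for t in STRESS_TIMES]
    + [f"{s}_delta" for s in STRAINS]
)


@dataclass
class RunConfig:
    """Thresholds and knobs for one pipeline run."""

    min_count: float = 50.0
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    paralogue_fold: float = 2.5
    pseudocount: float = 0.5
    rvd_k: int = 200
    rank_sign_variant: str = "abs_sum"
    var_policy: str = "pooled"
    trend_threshold: float = 1.0
    baseline_low: float = 0.70
    baseline_high: float = 1.3
    pca_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataValidationError("alpha must lie in (0, 1)")
        for name in ("lfc_threshold", "trend_threshold", "pseudocount"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be non-negative")
        if self.min_count < 0:
            raise DataValidationError("min_count must be non-negative")
        if self.paralogue_fold <= 1:
            raise DataValidationError("paralogue_fold must be > 1")
        if self.rvd_k < 1:
            raise DataValidationError("rvd_k must be >= 1")
        if self.rank_sign_variant not in RANK_SIGN_VARIANTS:
            raise DataValidationError(
                f"rank_sign_variant must be one of {RANK_SIGN_VARIANTS}"
            )
        if self.var_policy not in ("pooled", "welch"):
            raise DataValidationError("var_policy must be 'pooled' or 'welch'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_heatmap_matrix(
    lfc_table: pd.DataFrame,
    baseline_log2: pd.Series,
    delta_table: pd.DataFrame,
    gene_order: list[str],
) -> pd.DataFrame:
    """Nine-column heatmap matrix for the supplied gene order."""
    lfc_wide = lfc_table["lfc"].unstack(level=["strain", "time"])
    delta_wide = delta_table["delta"].unstack(level="strain")
    for gene in gene_order:
        if gene not in lfc_wide.index:
            raise DataValidationError(f"gene {gene!r} missing from the lfc table")
        if gene not in baseline_log2.index:
            raise DataValidationError(f"gene {gene!r} missing from baseline ratios")
        if gene not in delta_wide.index:
            raise DataValidationError(f"gene {gene!r} missing from the delta table")
    out = pd.DataFrame(index=pd.Index(gene_order, name="gene"))
    out["t0_log2_ratio"] = baseline_log2.loc[gene_order].to_numpy()
    for strain in STRAINS:
        for time in STRESS_TIMES:
            out[f"{strain}_{time}"] = lfc_wide.loc[gene_order, (strain, time)].to_numpy()
    for strain in STRAINS:
        out[f"{strain}_delta"] = delta_wide.loc[gene_order, strain].to_numpy()
    return out[list(HEATMAP_COLUMNS)]


@dataclass
class PipelineResult:
    """In-memory results of one full pipeline run."""

    config: RunConfig
    size_factors: pd.Series
    filtered_counts: CountMatrix
    normalized: NormalizedMatrix
    baseline: object
    pca_coordinates: pd.DataFrame
    pca_variance_fractions: list[float]
    lfc_table: pd.DataFrame
    deg_calls: pd.DataFrame
    deg_summary: pd.DataFrame
    discordant: dict[str, int]
    delta_table: pd.DataFrame
    trend_genes: dict[str, list[str]]
    rvd_table: pd.DataFrame
    top_genes: list[str]
    bottom_genes: list[str]
    heatmap_top: pd.DataFrame
    heatmap_bottom: pd.DataFrame
    paralogue_ratios: pd.DataFrame | None = None
    paralogue_verdicts: pd.DataFrame | None = None
    unevaluable_pairs: list[str] = field(default_factory=list)


def _write_tsv(frame: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


def run_pipeline(
    config: RunConfig,
    counts: CountMatrix,
    samples: SampleTable,
    pairs: ParalogueMap | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis; optionally write all tables to out_dir."""
    samples.require_match(counts)
    stage = "size factors"
    try:
        sf = compute_size_factors(counts)
        stage = "min-count filter"
        filtered = filter_by_min_count(counts, samples, config.min_count)
        if filtered.data.empty:
            raise DataValidationError("no gene passes the min-count filter")
        stage = "normalization"
        norm = normalize(filtered, sf)
        stage = "baseline ratios"
        baseline = baseline_ratio_stats(
            norm, samples, config.baseline_low, config.baseline_high
        )
        stage = "PCA"
        k = min(config.pca_components, norm.data.shape[1])
        pca = run_pca(norm, samples, k)
        stage = "differential expression"
        lfc_table = differential_expression(
            norm, samples, config.pseudocount, config.var_policy
        )
        calls = classify_degs(lfc_table, config.lfc_threshold, config.alpha)
        summary = summarize_degs(calls, universe_size=len(filtered.data))
        stage = "trend analysis"
        delta = compute_delta_lfc(lfc_table)
        trend = select_trend_genes(delta, config.trend_threshold)
        stage = "RVD"
        ranks = rank_within_sample(lfc_table)
        rvd_table = compute_rvd_scores(ranks, config.rank_sign_variant)
        k_sel = min(config.rvd_k, len(rvd_table))
        top = select_extreme_genes(rvd_table, k_sel, "highest")
        bottom = select_extreme_genes(rvd_table, k_sel, "lowest")
        stage = "heatmap export"
        heat_top = build_heatmap_matrix(lfc_table, baseline.table["log2_ratio"], delta, top)
        heat_bottom = build_heatmap_matrix(
            lfc_table, baseline.table["log2_ratio"], delta, bottom
        )
        paralogue_ratios = None
        verdicts = None
        unevaluable: list[str] = []
        if pairs is not None and len(pairs):
            stage = "paralogue ratios"
            present = set(norm.gene_ids)
            mask = pairs.data["gene_a"].isin(present) & pairs.data["gene_b"].isin(present)
            unevaluable = [str(p) for p in pairs.data.loc[~mask, "protein_name"]]
            evaluable = pairs.data.loc[mask]
            if len(evaluable):
                sub_pairs = ParalogueMap(evaluable.reset_index(drop=True))
                paralogue_ratios = compute_paralogue_ratios(
                    norm, samples, sub_pairs, config.pseudocount
                )
                flags = flag_shifted_pairs(paralogue_ratios, config.paralogue_fold)
                paralogue_ratios = flags.table
                verdicts = flags.verdicts
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from err

    result = PipelineResult(
        config=config,
        size_factors=sf,
        filtered_counts=filtered,
        normalized=norm,
        baseline=baseline,
        pca_coordinates=pca.coordinates,
        pca_variance_fractions=[float(v) for v in pca.variance_fractions],
        lfc_table=lfc_table,
        deg_calls=calls,
        deg_summary=summary.table,
        discordant=summary.discordant,
        delta_table=delta,
        trend_genes=trend,
        rvd_table=rvd_table,
        top_genes=top,
        bottom_genes=bottom,
        heatmap_top=heat_top,
        heatmap_bottom=heat_bottom,
        paralogue_ratios=paralogue_ratios,
        paralogue_verdicts=verdicts,
        unevaluable_pairs=unevaluable,
    )
    if out_dir is not None:
        _export(result, counts, samples, pairs, Path(out_dir))
    return result


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _export(
    result: PipelineResult,
    counts: CountMatrix,
    samples: SampleTable,
    pairs: ParalogueMap | None,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    h = result.config.hash()
    _write_tsv(result.size_factors.to_frame(), out_dir / "size_factors.tsv", h)
    _write_tsv(result.normalized.data, out_dir / "normalized_filtered.tsv", h)
    _write_tsv(result.baseline.table, out_dir / "baseline_ratios.tsv", h)
    _write_tsv(result.pca_coordinates, out_dir / "pca_coordinates.tsv", h)
    _write_tsv(result.lfc_table, out_dir / "lfc.tsv", h)
    _write_tsv(result.deg_calls, out_dir / "deg_calls.tsv", h)
    _write_tsv(result.deg_summary, out_dir / "deg_summary.tsv", h)
    _write_tsv(result.delta_table, out_dir / "delta_lfc.tsv", h)
    trend = pd.DataFrame(
        [
            {"strain": strain, "gene": gene}
            for strain, genes in sorted(result.trend_genes.items())
            for gene in genes
        ],
        columns=["strain", "gene"],
    )
    _write_tsv(trend, out_dir / "trend_genes.tsv", h, index=False)
    rvd_sorted = result.rvd_table.sort_values(
        "abs_rank_sum", ascending=False, kind="mergesort"
    )
    _write_tsv(rvd_sorted, out_dir / "rvd_by_abs_rank_sum.tsv", h)
    _write_tsv(
        result.rvd_table.sort_values("rank_sign", ascending=False, kind="mergesort"),
        out_dir / "rvd_by_rank_sign.tsv",
        h,
    )
    _write_tsv(result.heatmap_top, out_dir / "heatmap_most_different.tsv", h)
    _write_tsv(result.heatmap_bottom, out_dir / "heatmap_most_similar.tsv", h)
    if result.paralogue_ratios is not None:
        _write_tsv(result.paralogue_ratios, out_dir / "paralogue_ratios.tsv", h)
        _write_tsv(result.paralogue_verdicts, out_dir / "paralogue_flags.tsv", h)
    manifest = {
        "package": "dualstress",
        "version": __version__,
        "config": asdict(result.config),
        "config_hash": h,
        "inputs": {
            "counts_sha256": _checksum(counts.data.to_csv(sep="\t")),
            "samples_sha256": _checksum(samples.data.to_csv(sep="\t", index=False)),
            "pairs_sha256": _checksum(pairs.data.to_csv(sep="\t", index=False))
            if pairs is not None
            else None,
        },
        "unevaluable_pairs": result.unevaluable_pairs,
        "discordant_genes": result.discordant,
        "n_genes_input": len(counts.data),
        "n_genes_filtered": len(result.filtered_counts.data),
        "pca_variance_fractions": result.pca_variance_fractions,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
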