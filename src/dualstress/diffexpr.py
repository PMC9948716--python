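"""Per-strain, per-time differential expression and DEG overlap summaries.

For each strain, every post-shift time class is contrasted against the
same-strain pre-shift control:

* ``lfc`` — log2 of (replicate-mean normalized count + pseudocount) at the
  time point over the same quantity in the control.
* ``p_value`` — a two-sample t test on log2(normalized + pseudocount)
  replicate values. The default is the pooled-variance (Student) test,
  which holds its nominal level at three replicates per group; the Welch
  unequal-variance variant is available via ``var_policy="welch"``.
* ``fdr`` — Benjamini-Hochberg adjustment, applied within each
  strain x time contrast (six testing families).

A gene is a DEG at a time point when its |lfc| >= 1 (inclusive) and its
FDR < 0.05 (strict). The overlap summary mirrors the published layout:
per time, counts of genes significant in strain A only / both strains /
strain B only, for all DEGs and for the up and down directions, each with
the percentage of the gene universe, plus a "persistent" row for genes
that are DEGs at all three times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import STRAINS, STRESS_TIMES, DataValidationError, SampleTable
from .normalize import NormalizedMatrix

__all__ = [
    "compute_lfc",
    "test_differential",
    "adjust_fdr",
    "differential_expression",
    "classify_degs",
    "overlap_row",
    "summarize_degs",
    "DegSummary",
    "compute_delta_lfc",
    "select_trend_genes",
]

_SMALLEST_P = np.nextafter(0.0, 1.0)


def _to_long(
    values_by_contrast: dict[tuple[str, str], np.ndarray], genes, name: str
) -> pd.DataFrame:
    """Stack per-contrast vectors into a (gene, strain, time)-indexed frame."""
    wide = pd.DataFrame(values_by_contrast, index=genes)
    wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["strain", "time"])
    long = wide.stack(level=["strain", "time"], future_stack=True)
    long.name = name
    out = long.to_frame()
    out.index.names = ["gene", "strain", "time"]
    return out


def compute_lfc(
    norm: NormalizedMatrix, samples: SampleTable, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Log2 fold change vs the same-strain control, from replicate means.

    Returns a long frame indexed by (gene, strain, time) with an ``lfc``
    column. With a positive pseudocount the value is always finite.
    """
    if pseudocount < 0:
        raise DataValidationError("pseudocount must be >= 0")
    means = norm.group_means(samples)
    rows = {}
    for strain in samples.strains:
        ctrl = means[(strain, "control")].to_numpy()
        for time in STRESS_TIMES:
            x = means[(strain, time)].to_numpy()
            rows[(strain, time)] = np.log2((x + pseudocount) / (ctrl + pseudocount))
    return _to_long(rows, norm.data.index, "lfc")


def _t_test(
    x: np.ndarray, y: np.ndarray, var_policy: str
) -> np.ndarray:
    """Vectorized two-sample t test on rows of x vs rows of y.

    Degenerate-variance guard: when both groups have zero variance, p = 1
    for equal means and the smallest positive float for unequal means.
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    p = np.empty(len(m1))
    degenerate = (v1 == 0) & (v2 == 0)
    p[degenerate] = np.where(m1[degenerate] == m2[degenerate], 1.0, _SMALLEST_P)
    ok = ~degenerate
    if var_policy == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full(len(m1), n1 + n2 - 2, dtype=float)
    elif var_policy == "welch":
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    else:
        raise DataValidationError(f"unknown var_policy {var_policy!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    pv = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[ok] = np.clip(pv, _SMALLEST_P, 1.0)
    return p


def test_differential(
    norm: NormalizedMatrix,
    samples: SampleTable,
    pseudocount: float = 0.5,
    var_policy: str = "pooled",
) -> pd.DataFrame:
    """Two-sided t test of each time group vs control on log2(norm + pc).

    Returns a long frame indexed by (gene, strain, time) with ``p_value``.
    Raises for any compared group with fewer than two replicates.
    """
    log_data = np.log2(norm.data.to_numpy() + pseudocount)
    frame = pd.DataFrame(log_data, index=norm.data.index, columns=norm.data.columns)
    cols = {}
    for strain in samples.strains:
        ctrl_ids = samples.samples_for(strain, "control")
        if len(ctrl_ids) < 2:
            raise DataValidationError(
                f"group ({strain}, control) has {len(ctrl_ids)} replicate(s); need >= 2"
            )
        ctrl = frame[ctrl_ids].to_numpy()
        for time in STRESS_TIMES:
            ids = samples.samples_for(strain, time)
            if len(ids) < 2:
                raise DataValidationError(
                    f"group ({strain}, {time}) has {len(ids)} replicate(s); need >= 2"
                )
            cols[(strain, time)] = _t_test(frame[ids].to_numpy(), ctrl, var_policy)
    return _to_long(cols, norm.data.index, "p_value")


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: NormalizedMatrix,
    samples: SampleTable,
    pseudocount: float = 0.5,
    var_policy: str = "pooled",
) -> pd.DataFrame:
    """Full lfc/p/FDR table, BH-adjusted within each strain x time contrast."""
    lfc = compute_lfc(norm, samples, pseudocount)
    pvals = test_differential(norm, samples, pseudocount, var_policy)
    table = lfc.join(pvals)
    fdr = np.empty(len(table))
    for (strain, time), idx in table.groupby(level=["strain", "time"]).indices.items():
        fdr[idx] = adjust_fdr(table["p_value"].to_numpy()[idx])
    table["fdr"] = fdr
    return table


def classify_degs(
    lfc_table: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Call up/down/none per (gene, strain, time).

    up: lfc >= threshold and FDR < alpha; down: lfc <= -threshold and
    FDR < alpha (|lfc| inclusive, FDR strict).
    """
    if "fdr" not in lfc_table.columns:
        raise DataValidationError("lfc table must carry an 'fdr' column")
    lfc = lfc_table["lfc"].to_numpy()
    fdr = lfc_table["fdr"].to_numpy()
    call = np.where(
        (fdr < alpha) & (lfc >= lfc_threshold),
        "up",
        np.where((fdr < alpha) & (lfc <= -lfc_threshold), "down", "none"),
    )
    return pd.DataFrame({"call": call}, index=lfc_table.index)


def overlap_row(
    n_a_only: int, n_both: int, n_b_only: int, universe_size: int
) -> dict[str, float]:
    """Union count and percentages for one summary row.

    The union is exactly a_only + both + b_only; percentages are
    100 * n / universe, reported to one decimal.
    """
    if universe_size <= 0:
        raise DataValidationError("universe_size must be positive")
    n_all = n_a_only + n_both + n_b_only
    out: dict[str, float] = {
        "n_a_only": n_a_only,
        "n_both": n_both,
        "n_b_only": n_b_only,
        "n_all": n_all,
    }
    for key, n in list(out.items()):
        out["f" + key[1:]] = round(100.0 * n / universe_size, 1)
    return out


@dataclass(frozen=True)
class DegSummary:
    """Overlap table plus the per-time count of direction-discordant genes.

    Discordant genes (up in one strain, down in the other at the same time)
    are counted in the "both" column of the total block but in neither the
    up-both nor down-both column; in the up/down strain-only columns they
    count per their direction in that strain. The ``discordant`` counts make
    that convention auditable.
    """

    table: pd.DataFrame
    discordant: dict[str, int]
    universe_size: int


def summarize_degs(calls: pd.DataFrame, universe_size: int) -> DegSummary:
    """Published-style overlap summary from per-(gene, strain, time) calls."""
    genes = calls.index.get_level_values("gene").unique()
    if universe_size < len(genes):
        raise DataValidationError(
            f"universe_size {universe_size} smaller than the {len(genes)} called genes"
        )
    wide = calls["call"].unstack(level=["strain", "time"])
    a, b = STRAINS
    for strain in (a, b):
        for time in STRESS_TIMES:
            if (strain, time) not in wide.columns:
                raise DataValidationError(
                    f"calls missing the ({strain}, {time}) contrast"
                )

    def sets_at(strain: str, time: str) -> dict[str, set]:
        col = wide[(strain, time)]
        return {
            "up": set(col.index[col == "up"]),
            "down": set(col.index[col == "down"]),
            "any": set(col.index[col != "none"]),
        }

    def persistent_sets(strain: str) -> dict[str, set]:
        per_time = [sets_at(strain, t) for t in STRESS_TIMES]
        return {
            key: set.intersection(*(s[key] for s in per_time))
            for key in ("up", "down", "any")
        }

    rows = []
    discordant: dict[str, int] = {}
    labels = list(STRESS_TIMES) + ["persistent"]
    for label in labels:
        if label == "persistent":
            sa, sb = persistent_sets(a), persistent_sets(b)
        else:
            sa, sb = sets_at(a, label), sets_at(b, label)
        disc = (sa["up"] & sb["down"]) | (sa["down"] & sb["up"])
        discordant[label] = len(disc)
        blocks = {
            "total": (sa["any"], sb["any"]),
            "up": (sa["up"], sb["up"]),
            "down": (sa["down"], sb["down"]),
        }
        for block, (set_a, set_b) in blocks.items():
            both = set_a & set_b
            row = overlap_row(
                len(set_a - set_b), len(both), len(set_b - set_a), universe_size
            )
            rows.append({"time": label, "block": block, **row})
    table = pd.DataFrame(rows).set_index(["time", "block"])
    return DegSummary(table=table, discordant=discordant, universe_size=universe_size)


def compute_delta_lfc(lfc_table: pd.DataFrame) -> pd.DataFrame:
    """Late minus early lfc per gene and strain (the trend column pair)."""
    wide = lfc_table["lfc"].unstack(level="time")
    for needed in ("early", "late"):
        if needed not in wide.columns:
            raise DataValidationError(f"lfc table lacks the {needed!r} time point")
    out = pd.DataFrame({"delta": wide["late"] - wide["early"]})
    return out


def select_trend_genes(
    delta_table: pd.DataFrame, threshold: float = 1.0
) -> dict[str, list[str]]:
    """Genes with |late - early lfc| >= threshold, per strain."""
    out: dict[str, list[str]] = {}
    for strain, sub in delta_table.groupby(level="strain"):
        mask = sub["delta"].abs() >= threshold
        out[str(strain)] = sorted(sub.index.get_level_values("gene")[mask])
    return out
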