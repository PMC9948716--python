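"""Over-representation of gene lists in user-supplied annotation sets,
and mRNA-mass fractions of gene classes.

Enrichment is the one-sided hypergeometric upper tail: with a universe of
N genes, a set of K, a query of n and an overlap of k, the p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n), and the fold enrichment is
(k/n)/(K/N). P-values are Benjamini-Hochberg adjusted across the tested
sets. Sets with fewer than three members after intersection with the
universe are reported but not tested (degenerate tails).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import DataValidationError, GeneSetCollection, SampleTable
from .diffexpr import adjust_fdr
from .normalize import NormalizedMatrix

__all__ = ["enrich", "class_mrna_fraction"]


def enrich(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Returns one row per set, sorted by p-value (untested sets last), with
    overlap, expected overlap, fold enrichment, p and BH FDR.
    """
    universe_set = set(universe)
    if len(universe_set) != len(universe):
        raise DataValidationError("universe contains duplicate gene ids")
    query_set = set(query)
    outside = sorted(query_set - universe_set)
    if outside:
        raise DataValidationError(f"query genes outside the universe: {outside}")
    big_n, n = len(universe_set), len(query_set)
    rows = []
    for name in sets.names():
        members = set(sets[name]) & universe_set
        k_set = len(members)
        overlap = len(members & query_set)
        tested = k_set >= min_set_size and n > 0
        expected = n * k_set / big_n if big_n else float("nan")
        fold = (overlap / n) / (k_set / big_n) if tested and k_set else float("nan")
        p = float(hypergeom.sf(overlap - 1, big_n, k_set, n)) if tested else float("nan")
        rows.append(
            {
                "set_name": name,
                "set_size": k_set,
                "overlap": overlap,
                "expected": expected,
                "fold_enrichment": fold,
                "p_value": p,
                "tested": tested,
            }
        )
    frame = pd.DataFrame(rows)
    frame["fdr"] = np.nan
    tested_mask = frame["tested"].to_numpy()
    if tested_mask.any():
        frame.loc[tested_mask, "fdr"] = adjust_fdr(
            frame.loc[tested_mask, "p_value"].to_numpy()
        )
    frame = frame.sort_values(
        ["tested", "p_value", "set_name"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def class_mrna_fraction(
    norm: NormalizedMatrix,
    samples: SampleTable,
    sets: GeneSetCollection,
    time: str = "control",
) -> pd.DataFrame:
    """Fraction of total mRNA mass carried by each gene set, per strain.

    The fraction is the sum of replicate-mean normalized counts over member
    genes divided by the sum over all genes, at the requested time class.
    Empty sets (after intersection with the matrix) yield 0 with a warning.
    """
    means = norm.group_means(samples)
    rows = []
    genes = set(norm.gene_ids)
    for strain in samples.strains:
        if (strain, time) not in means.columns:
            raise DataValidationError(f"no samples at ({strain}, {time})")
        col = means[(strain, time)]
        total = float(col.sum())
        for name in sets.names():
            members = [g for g in sets[name] if g in genes]
            if not members:
                warnings.warn(
                    f"gene set {name!r} has no members in the matrix; fraction 0",
                    stacklevel=2,
                )
                frac = 0.0
            else:
                frac = float(col.loc[members].sum() / total) if total else float("nan")
            rows.append({"set_name": name, "strain": strain, "fraction": frac})
    return pd.DataFrame(rows).set_index(["set_name", "strain"])
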