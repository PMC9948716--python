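"""Rank-value-difference (RVD) concordance scoring.

Within each strain x time contrast, genes are ranked by their log2 fold
change (ascending, average ranks for ties; log2 is monotone, so ranking
raw fold change gives the same result). The RVD of a gene at a time point
is its rank in the nucleolar-stress strain (stressA) minus its rank in the
translation-stress strain (stressB). Per gene, over the three stress time
points:

* ``abs_rank_sum`` = sum of |RVD|: high values mark genes whose expression
  changed most differently between the two stresses, low values most
  similarly.
* ``rank_sum`` = sum of signed RVDs.
* ``rank_sign`` = abs_rank_sum - rank_sum (default); it is zero iff no RVD
  is negative and is largest for genes whose relative rank flips between
  time points. An alternative algebraic reading, |rank_sum| - rank_sum, is
  available as ``rank_sign_variant="abs_of_sum"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import STRAINS, STRESS_TIMES, DataValidationError

__all__ = ["rank_within_sample", "compute_rvd_scores", "select_extreme_genes"]

RANK_SIGN_VARIANTS = ("abs_sum", "abs_of_sum")


def rank_within_sample(lfc_table: pd.DataFrame) -> pd.DataFrame:
    """Ascending average-tie rank of lfc within every strain x time vector.

    Rank 1 is the lowest lfc; ties share the average of their positions, so
    the ranks in each vector always sum to G(G+1)/2.
    """
    if lfc_table["lfc"].isna().any():
        missing = lfc_table.index[lfc_table["lfc"].isna()][:5]
        raise DataValidationError(f"missing lfc values, e.g. {list(missing)}")
    out = lfc_table[[]].copy()
    rank = np.empty(len(lfc_table))
    for _, idx in lfc_table.groupby(level=["strain", "time"]).indices.items():
        rank[idx] = rankdata(lfc_table["lfc"].to_numpy()[idx], method="average")
    out["rank"] = rank
    return out


def compute_rvd_scores(
    ranks: pd.DataFrame, rank_sign_variant: str = "abs_sum"
) -> pd.DataFrame:
    """Per-gene RVDs and their summary scores.

    Returns a frame indexed by gene with columns rvd_early, rvd_middle,
    rvd_late, abs_rank_sum, rank_sum and rank_sign.
    """
    if rank_sign_variant not in RANK_SIGN_VARIANTS:
        raise DataValidationError(
            f"rank_sign_variant must be one of {RANK_SIGN_VARIANTS}"
        )
    wide = ranks["rank"].unstack(level=["strain", "time"])
    a, b = STRAINS
    for strain in (a, b):
        for time in STRESS_TIMES:
            if (strain, time) not in wide.columns:
                raise DataValidationError(f"ranks missing ({strain}, {time})")
    if wide.isna().any().any():
        gene = wide.index[wide.isna().any(axis=1)][0]
        raise DataValidationError(f"gene {gene!r} lacks ranks in one strain")
    out = pd.DataFrame(index=wide.index)
    for time in STRESS_TIMES:
        out[f"rvd_{time}"] = wide[(a, time)] - wide[(b, time)]
    rvds = out[[f"rvd_{t}" for t in STRESS_TIMES]].to_numpy()
    out["abs_rank_sum"] = np.abs(rvds).sum(axis=1)
    out["rank_sum"] = rvds.sum(axis=1)
    if rank_sign_variant == "abs_sum":
        out["rank_sign"] = out["abs_rank_sum"] - out["rank_sum"]
    else:
        out["rank_sign"] = out["rank_sum"].abs() - out["rank_sum"]
    return out


def select_extreme_genes(
    rvd_table: pd.DataFrame, k: int = 200, end: str = "highest"
) -> list[str]:
    """The k genes with the highest (or lowest) abs_rank_sum.

    Ordered by score (descending for ``highest``, ascending for ``lowest``)
    with ties broken deterministically by gene id lexical order.
    """
    if end not in ("highest", "lowest"):
        raise DataValidationError("end must be 'highest' or 'lowest'")
    if k > len(rvd_table):
        raise DataValidationError(
            f"k={k} exceeds the number of genes ({len(rvd_table)})"
        )
    frame = rvd_table.reset_index()
    gene_col = frame.columns[0]
    frame = frame.sort_values(
        ["abs_rank_sum", gene_col], ascending=[end == "lowest", True], kind="mergesort"
    )
    return [str(g) for g in frame[gene_col].head(k)]
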