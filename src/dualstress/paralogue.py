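"""Control-normalized A/B paralogue mRNA-ratio trajectories.

For a paralogous pair (gene A, gene B) the statistic at each strain x time
is::

    log2_ratio = log2( (A_t / B_t) / (A_0 / B_0) )

computed from replicate-mean normalized counts with a pseudocount, where
t=0 is the same strain's control. Dividing by the control ratio removes
any allele-specific capture or mapping bias, so only *changes* in the A:B
ratio are interpretable — absolute A:B expression ratios are deliberately
out of scope. A pair is flagged as shifted when |log2_ratio| reaches
log2(fold_threshold) (2.5-fold by default, inclusive) at any strain x time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STRESS_TIMES, DataValidationError, ParalogueMap, SampleTable
from .normalize import NormalizedMatrix

__all__ = ["compute_paralogue_ratios", "flag_shifted_pairs", "ParalogueFlagResult"]


def compute_paralogue_ratios(
    norm: NormalizedMatrix,
    samples: SampleTable,
    pairs: ParalogueMap,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Long table of log2 control-normalized A/B ratios.

    Indexed by (protein, strain, time) for the three stress times; the
    control time is log2_ratio = 0 by construction and not emitted.
    Raises if a pair member is absent from the matrix.
    """
    genes = set(norm.gene_ids)
    for _, row in pairs.data.iterrows():
        for role in ("gene_a", "gene_b"):
            if row[role] not in genes:
                raise DataValidationError(
                    f"gene {row[role]!r} of pair {row['protein_name']!r} "
                    "is absent from the normalized matrix"
                )
    means = norm.group_means(samples)
    records = []
    for _, row in pairs.data.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        for strain in samples.strains:
            a0 = means.loc[a, (strain, "control")] + pseudocount
            b0 = means.loc[b, (strain, "control")] + pseudocount
            for time in STRESS_TIMES:
                at = means.loc[a, (strain, time)] + pseudocount
                bt = means.loc[b, (strain, time)] + pseudocount
                records.append(
                    {
                        "protein": row["protein_name"],
                        "strain": strain,
                        "time": time,
                        "log2_ratio": float(np.log2((at / bt) / (a0 / b0))),
                    }
                )
    return pd.DataFrame(records).set_index(["protein", "strain", "time"])


@dataclass(frozen=True)
class ParalogueFlagResult:
    """Flags per pair with the strain/time cells that triggered them."""

    table: pd.DataFrame  # ratio table plus a per-cell 'flag' column
    verdicts: pd.DataFrame  # per protein: flagged, max |log2_ratio|, triggers


def flag_shifted_pairs(
    ratio_table: pd.DataFrame, fold_threshold: float = 2.5
) -> ParalogueFlagResult:
    """Flag pairs whose ratio shifted by >= fold_threshold anywhere."""
    if fold_threshold <= 1:
        raise DataValidationError("fold_threshold must be > 1")
    cutoff = np.log2(fold_threshold)
    table = ratio_table.copy()
    table["flag"] = table["log2_ratio"].abs() >= cutoff
    verdicts = []
    for protein, sub in table.groupby(level="protein", sort=False):
        hits = sub[sub["flag"]]
        triggers = ";".join(
            f"{s}:{t}" for (_, s, t) in hits.index
        )
        verdicts.append(
            {
                "protein": protein,
                "flagged": bool(len(hits)),
                "max_abs_log2_ratio": float(sub["log2_ratio"].abs().max()),
                "triggers": triggers,
            }
        )
    verdict_frame = pd.DataFrame(verdicts).set_index("protein")
    return ParalogueFlagResult(table=table, verdicts=verdict_frame)
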