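"""Size-factor normalization, abundance filtering, baseline ratios and PCA.

Library-size correction uses the median-of-ratios size factor: each
sample's factor is the median, over genes with an all-positive geometric
mean across samples, of that sample's count divided by the gene's
geometric mean. Counts divided by the factor are comparable across
libraries. This is the standard normalization for bulk RNA-seq count
matrices and is implemented here directly so that it is fully specified
and unit-testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import STRAINS, STRESS_TIMES, TIMES, CountMatrix, DataValidationError, SampleTable

__all__ = [
    "NormalizedMatrix",
    "BaselineRatioStats",
    "PcaResult",
    "compute_size_factors",
    "normalize",
    "filter_by_min_count",
    "baseline_ratio_stats",
    "run_pca",
]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Counts divided by per-sample size factors (genes x samples, float)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise DataValidationError("normalized values must be finite")
        if values.size and np.any(values < 0):
            raise DataValidationError("normalized values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    def group_means(self, samples: SampleTable) -> pd.DataFrame:
        """Replicate-mean normalized count per gene for every strain x time.

        Returns a genes x (strain, time) column-MultiIndex frame.
        """
        cols = {}
        for strain in samples.strains:
            for time in TIMES:
                ids = samples.samples_for(strain, time)
                if not ids:
                    raise DataValidationError(f"no samples for ({strain}, {time})")
                cols[(strain, time)] = self.data[ids].mean(axis=1)
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["strain", "time"])
        return out


def compute_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those whose geometric mean across samples is
    positive, i.e. genes counted in every sample. Raises if no such gene
    exists.
    """
    mat = counts.data.to_numpy(dtype=float)
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        raise DataValidationError(
            "cannot compute size factors: no gene has positive counts in all samples"
        )
    ref = mat[positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.data.columns, name="size_factor")


def normalize(counts: CountMatrix, size_factors: pd.Series) -> NormalizedMatrix:
    """Divide each sample column by its size factor."""
    missing = [s for s in counts.sample_ids if s not in size_factors.index]
    if missing:
        raise DataValidationError(f"size factors missing for samples: {missing}")
    sf = size_factors.loc[counts.data.columns].to_numpy(dtype=float)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise DataValidationError("size factors must be positive and finite")
    return NormalizedMatrix(counts.data / sf)


def filter_by_min_count(
    counts: CountMatrix, samples: SampleTable, threshold: float = 50.0
) -> CountMatrix:
    """Keep genes whose replicate-mean raw count is >= threshold in every
    strain x time cell (the "at least 50 reads at all sampling times" rule,
    applied to the replicate mean)."""
    samples.require_match(counts)
    keep = np.ones(len(counts.data), dtype=bool)
    for strain in samples.strains:
        for time in TIMES:
            ids = samples.samples_for(strain, time)
            keep &= counts.data[ids].mean(axis=1).to_numpy() >= threshold
    return CountMatrix(counts.data.loc[keep])


@dataclass(frozen=True)
class BaselineRatioStats:
    """Per-gene cross-strain control (t=0) expression ratio.

    ``table`` has one row per gene with the stressA/stressB ratio of
    replicate-mean normalized control counts and its log2 (the first heatmap
    column); ``fraction_in_band`` is the share of defined ratios inside
    [low, high], the summary used to show that baseline expression is
    similar in the two strains before stress.
    """

    table: pd.DataFrame
    fraction_in_band: float
    low: float
    high: float


def baseline_ratio_stats(
    norm: NormalizedMatrix,
    samples: SampleTable,
    low: float = 0.70,
    high: float = 1.3,
) -> BaselineRatioStats:
    a_ids = samples.samples_for(STRAINS[0], "control")
    b_ids = samples.samples_for(STRAINS[1], "control")
    if not a_ids or not b_ids:
        raise DataValidationError("both strains need control samples")
    a = norm.data[a_ids].mean(axis=1).to_numpy()
    b = norm.data[b_ids].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
        log2_ratio = np.log2(ratio)
    table = pd.DataFrame(
        {"ratio": ratio, "log2_ratio": log2_ratio}, index=norm.data.index
    )
    defined = ~np.isnan(ratio)  # 0/0 -> nan is undefined; x/0 -> inf counts as defined
    n_defined = int(defined.sum())
    in_band = (ratio >= low) & (ratio <= high) & defined
    fraction = float(in_band.sum() / n_defined) if n_defined else float("nan")
    return BaselineRatioStats(table=table, fraction_in_band=fraction, low=low, high=high)


@dataclass(frozen=True)
class PcaResult:
    """Sample coordinates on the first K principal components."""

    coordinates: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fractions, dtype=float)
        if np.any(vf < -1e-12) or np.any(vf > 1 + 1e-12) or vf.sum() > 1 + 1e-9:
            raise DataValidationError("variance fractions must lie in [0,1] and sum <= 1")
        if np.any(np.diff(vf) > 1e-9):
            raise DataValidationError("variance fractions must be non-increasing")


def run_pca(norm: NormalizedMatrix, samples: SampleTable, k: int = 2) -> PcaResult:
    """PCA of samples in gene space on log2(normalized + 1), per-gene centered.

    The log transform keeps the most abundant transcripts from dominating
    the rotation; no per-gene scaling is applied. Deterministic up to
    component sign.
    """
    n_samples = norm.data.shape[1]
    if n_samples < 2:
        raise DataValidationError("PCA needs at least 2 samples")
    if k > n_samples:
        raise DataValidationError(f"k={k} exceeds the number of samples ({n_samples})")
    x = np.log2(norm.data.to_numpy().T + 1.0)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(
        coords,
        index=norm.data.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(coordinates=frame, variance_fractions=pca.explained_variance_ratio_)
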