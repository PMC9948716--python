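"""Seeded generator of two-strain, four-time-point replicated count data
with planted gene classes and a ground-truth table.

The generator emulates the statistical structure the analysis assumes:

* two strains x {control, early, middle, late} x 3 replicates, with an
  optional dropout of one strainB middle replicate (the 23-sample design
  in which one RNA sample failed quality control);
* gene-level negative-binomial counts, mean = baseline x 2^(true lfc) x
  per-sample library factor, fixed dispersion (variance = mu + mu^2/size);
* planted classes —

  - ``concordant_down``: repressed early in both strains and stable
    afterwards (the glucose-repression signature, e.g. mitochondrial
    genes after a galactose-to-glucose shift);
  - ``opposite_trend``: initially repressed then induced under the
    assembly block, initially induced (shift-up) then repressed under the
    function block — the r-protein-like signature;
  - ``flat``: no planted change (the auxiliary-factor-like class; differs
    from ``null`` only in the membership lists tests use);
  - ``null``: no planted change, used for error-rate estimates;
  - ``paralogue``: members of A/B pairs carved from the null allotment; a
    configurable fraction of pairs gains a +2 lfc on the A member at
    middle/late in stressA, a 4-fold A:B ratio shift.

All randomness derives from one seed via three independent child streams
(truth, library factors, counts), so toggling one component does not
reshuffle the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    STRAINS,
    STRESS_TIMES,
    TIMES,
    CountMatrix,
    DataValidationError,
    ParalogueMap,
    SampleTable,
)

__all__ = ["SimSpec", "generate_truth", "simulate_counts", "simulate", "paralogue_map_from_truth"]

CLASSES = ("concordant_down", "opposite_trend", "flat", "null", "paralogue")


def _default_proportions() -> dict[str, float]:
    return {"concordant_down": 0.15, "opposite_trend": 0.10, "flat": 0.10}


def _default_trajectories() -> dict[str, dict[str, tuple[float, float, float]]]:
    zero = (0.0, 0.0, 0.0)
    return {
        "concordant_down": {
            "stressA": (-1.5, -1.6, -1.6),
            "stressB": (-1.5, -1.6, -1.6),
        },
        "opposite_trend": {
            "stressA": (-0.5, 0.3, 1.0),
            "stressB": (0.5, -0.5, -1.5),
        },
        "flat": {"stressA": zero, "stressB": zero},
        "null": {"stressA": zero, "stressB": zero},
        "paralogue": {"stressA": zero, "stressB": zero},
    }


@dataclass
class SimSpec:
    """Study-design and distributional parameters for one simulation.

    Defaults encode the reference design: ~5,000 genes, triplicates with
    one strainB middle replicate dropped, log-normal baseline abundances
    tuned so ~95% of genes clear the 50-count filter, and NB dispersion
    size=80 (per-replicate CV ~ 0.12 at high counts), the order observed
    for tightly controlled yeast culture triplicates and large enough that
    a planted ~3-fold change is detectable with three replicates.
    """

    n_genes: int = 5000
    replicates: int = 3
    drop_one_middle_replicate_strainB: bool = True
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    n_paralogue_pairs: int = 60
    shifted_fraction: float = 0.15
    baseline_log_mean: float = math.log(400.0)
    baseline_log_sd: float = 1.2
    dispersion: float | None = 80.0
    library_log_sd: float = 0.15
    trajectories: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=_default_trajectories
    )
    paralogue_shift_lfc: float = 2.0
    #: Paralogue-pair genes get their own baseline distribution: r-protein
    #: mRNAs, the real analogue of the planted pairs, are abundant and span
    #: a much narrower dynamic range than the transcriptome at large.
    paralogue_log_mean: float = math.log(2000.0)
    paralogue_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = 0.0
        for name, p in self.class_proportions.items():
            if name not in CLASSES:
                raise DataValidationError(f"unknown class {name!r}")
            if not 0 <= p <= 1:
                raise DataValidationError(f"proportion for {name!r} outside [0,1]")
            total += p
        if total > 1 + 1e-12:
            raise DataValidationError(f"class proportions sum to {total} > 1")
        if self.dispersion is not None and not (
            math.isinf(self.dispersion) or self.dispersion > 0
        ):
            raise DataValidationError("dispersion must be positive, infinite or None")
        if self.replicates < 1:
            raise DataValidationError("replicates must be >= 1")
        if not 0 <= self.shifted_fraction <= 1:
            raise DataValidationError("shifted_fraction must lie in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        """Load a flat key-value YAML file; unknown keys are an error."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


def generate_truth(spec: SimSpec) -> pd.DataFrame:
    """Deterministic (per seed) truth table: one row per gene.

    Columns: class, baseline_mean, lfc_<strain>_<time> for the six
    stress contrasts, and pair_name / pair_role / pair_shifted for genes
    belonging to a paralogue pair.
    """
    rng = spec.streams()[0]
    n = spec.n_genes
    counts = {
        name: int(round(spec.class_proportions.get(name, 0.0) * n))
        for name in ("concordant_down", "opposite_trend", "flat")
    }
    n_pair_genes = 2 * spec.n_paralogue_pairs
    n_planted = sum(counts.values())
    n_null = n - n_planted - n_pair_genes
    if n_null < 0:
        raise DataValidationError(
            "class proportions plus paralogue pairs exceed the gene count"
        )
    width = max(5, len(str(n)))
    genes = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    classes = (
        ["concordant_down"] * counts["concordant_down"]
        + ["opposite_trend"] * counts["opposite_trend"]
        + ["flat"] * counts["flat"]
        + ["null"] * n_null
        + ["paralogue"] * n_pair_genes
    )
    truth = pd.DataFrame({"class": classes}, index=pd.Index(genes, name="gene_id"))
    truth["baseline_mean"] = rng.lognormal(
        spec.baseline_log_mean, spec.baseline_log_sd, n
    )
    if n_pair_genes:
        pair_mask = truth["class"].to_numpy() == "paralogue"
        truth.loc[pair_mask, "baseline_mean"] = rng.lognormal(
            spec.paralogue_log_mean, spec.paralogue_log_sd, n_pair_genes
        )
    for strain in STRAINS:
        for j, time in enumerate(STRESS_TIMES):
            truth[f"lfc_{strain}_{time}"] = [
                float(spec.trajectories[c][strain][j]) for c in classes
            ]
    truth["pair_name"] = ""
    truth["pair_role"] = ""
    truth["pair_shifted"] = False
    n_shifted = int(round(spec.shifted_fraction * spec.n_paralogue_pairs))
    pair_genes = genes[n - n_pair_genes :]
    for i in range(spec.n_paralogue_pairs):
        name = f"pair{i + 1:03d}"
        ga, gb = pair_genes[2 * i], pair_genes[2 * i + 1]
        shifted = i < n_shifted
        truth.loc[[ga, gb], "pair_name"] = name
        truth.loc[ga, "pair_role"] = "A"
        truth.loc[gb, "pair_role"] = "B"
        truth.loc[[ga, gb], "pair_shifted"] = shifted
        if shifted:
            # 4-fold A:B ratio shift at middle/late under nucleolar stress
            truth.loc[ga, "lfc_stressA_middle"] += spec.paralogue_shift_lfc
            truth.loc[ga, "lfc_stressA_late"] += spec.paralogue_shift_lfc
    return truth


def _sample_design(spec: SimSpec) -> pd.DataFrame:
    rows = []
    for strain in STRAINS:
        for time in TIMES:
            reps = spec.replicates
            if (
                spec.drop_one_middle_replicate_strainB
                and strain == "stressB"
                and time == "middle"
            ):
                reps -= 1
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{time}_r{r}",
                        "strain": strain,
                        "time": time,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(
    truth: pd.DataFrame, spec: SimSpec
) -> tuple[CountMatrix, SampleTable]:
    """Draw the count matrix implied by a truth table.

    Counts are negative binomial with mean = baseline x 2^lfc x library
    factor and the spec's dispersion; an infinite/None dispersion falls
    back to Poisson draws.
    """
    _, lib_rng, count_rng = spec.streams()
    design = _sample_design(spec)
    samples = SampleTable(design)
    lib = np.exp(lib_rng.normal(0.0, spec.library_log_sd, len(design)))
    baseline = truth["baseline_mean"].to_numpy()
    mean = np.empty((len(truth), len(design)))
    for j, row in design.iterrows():
        if row["time"] == "control":
            lfc = 0.0
        else:
            lfc = truth[f"lfc_{row['strain']}_{row['time']}"].to_numpy()
        mean[:, j] = baseline * 2.0**lfc * lib[j]
    size = spec.dispersion
    if size is None or math.isinf(size):
        counts = count_rng.poisson(mean)
    else:
        counts = count_rng.negative_binomial(size, size / (size + mean))
    matrix = CountMatrix(
        pd.DataFrame(counts, index=truth.index, columns=design["sample_id"])
    )
    return matrix, samples


def paralogue_map_from_truth(truth: pd.DataFrame) -> ParalogueMap:
    """Extract the planted A/B pairs as a ParalogueMap."""
    paired = truth[truth["pair_name"] != ""]
    rows = []
    for name, sub in paired.groupby("pair_name", sort=True):
        a = sub.index[sub["pair_role"] == "A"][0]
        b = sub.index[sub["pair_role"] == "B"][0]
        rows.append({"protein_name": name, "gene_a": a, "gene_b": b})
    frame = pd.DataFrame(rows, columns=["protein_name", "gene_a", "gene_b"])
    return ParalogueMap(frame)


def simulate(
    spec: SimSpec,
) -> tuple[CountMatrix, SampleTable, ParalogueMap, pd.DataFrame]:
    """Convenience wrapper: truth -> counts + samples + paralogue map."""
    truth = generate_truth(spec)
    counts, samples = simulate_counts(truth, spec)
    return counts, samples, paralogue_map_from_truth(truth), truth
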