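import numpy as np
import pandas as pd
import pytest

from dualstress import CountMatrix, SampleTable, SimSpec, simulate
from dualstress.normalize import NormalizedMatrix


def make_sample_table(replicates: int = 2, drop_middle_b: bool = False) -> SampleTable:
    rows = []
    for strain in ("stressA", "stressB"):
        for time in ("control", "early", "middle", "late"):
            n = replicates
            if drop_middle_b and strain == "stressB" and time == "middle":
                n -= 1
            for r in range(1, n + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{time}_r{r}",
                        "strain": strain,
                        "time": time,
                        "replicate": r,
                    }
                )
    return SampleTable(pd.DataFrame(rows))


def matrix_from_group_means(
    means: dict[tuple[str, str], np.ndarray],
    genes: list[str],
    replicates: int = 2,
) -> NormalizedMatrix:
    """Constant-replicate normalized matrix with the given group means."""
    samples = make_sample_table(replicates)
    data = {}
    for _, row in samples.data.iterrows():
        data[row["sample_id"]] = means[(row["strain"], row["time"])]
    return NormalizedMatrix(pd.DataFrame(data, index=genes, dtype=float))


@pytest.fixture
def toy_samples() -> SampleTable:
    return make_sample_table(replicates=2)


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-class simulation shared across tests."""
    spec = SimSpec(n_genes=400, n_paralogue_pairs=10, seed=123)
    counts, samples, pairs, truth = simulate(spec)
    return spec, counts, samples, pairs, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default-parameter fixture used for end-to-end recovery checks."""
    spec = SimSpec()
    counts, samples, pairs, truth = simulate(spec)
    return spec, counts, samples, pairs, truth


def counts_from_array(arr, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))
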