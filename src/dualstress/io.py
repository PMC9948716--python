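"""Data model and TSV readers/writers.

The canonical interchange format is tab-separated text with a header row.
Gene and sample identifiers are case-sensitive strings matched exactly.

Containers are thin, validated wrappers around :class:`pandas.DataFrame`:

* :class:`CountMatrix` — integer read counts, genes x samples.
* :class:`SampleTable` — sample metadata (strain, time, replicate).
* :class:`ParalogueMap` — A/B gene pairs encoding the same protein.
* :class:`GeneSetCollection` — named gene sets (GMT-style or two-column TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRAINS",
    "TIMES",
    "STRESS_TIMES",
    "CountMatrix",
    "SampleTable",
    "ParalogueMap",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_sample_table",
    "write_sample_table",
    "read_paralogue_map",
    "read_gene_sets",
]

#: The two stress strains: stressA models the ribosome-assembly block
#: (nucleolar stress), stressB the ribosome-function block (translation
#: stress).
STRAINS = ("stressA", "stressB")

#: Sampling schedule: a pre-shift control culture plus three post-shift
#: time classes chosen at matched growth rates.
TIMES = ("control", "early", "middle", "late")

#: The three post-shift time points (contrasts are always vs control).
STRESS_TIMES = ("early", "middle", "late")


class DataValidationError(ValueError):
    """An input table violates a structural invariant."""


def _check_unique(values: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    dups = sorted(v for v, n in seen.items() if n > 1)
    if dups:
        raise DataValidationError(f"duplicate {what}: {', '.join(dups)}")


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes (rows) x samples (columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique([str(g) for g in df.index], "gene id")
        _check_unique([str(s) for s in df.columns], "sample id")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise DataValidationError("counts must be numeric")
            if np.any(values < 0):
                g, s = np.argwhere(values < 0)[0]
                raise DataValidationError(
                    f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
            if not np.all(np.equal(np.mod(values, 1), 0)):
                g, s = np.argwhere(np.mod(values, 1) != 0)[0]
                raise DataValidationError(
                    f"non-integer count {values[g, s]!r} at gene {df.index[g]!r}, "
                    f"sample {df.columns[s]!r}"
                )
        if not np.issubdtype(values.dtype, np.integer):
            object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(genes)])


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: strain, time class and replicate number.

    Every (strain, time) combination must contain at least one sample and
    each strain must have a control, because every downstream contrast is
    computed against the same-strain control.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = {"sample_id", "strain", "time", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"sample table missing columns: {sorted(missing)}")
        _check_unique([str(s) for s in df["sample_id"]], "sample_id")
        bad_strain = sorted(set(df["strain"]) - set(STRAINS))
        if bad_strain:
            raise DataValidationError(
                f"unknown strain(s) {bad_strain}; allowed: {list(STRAINS)}"
            )
        bad_time = sorted(set(df["time"]) - set(TIMES))
        if bad_time:
            raise DataValidationError(
                f"unknown time label(s) {bad_time}; allowed: {list(TIMES)}"
            )
        reps = pd.to_numeric(df["replicate"], errors="raise")
        if np.any(reps.to_numpy() < 1) or np.any(np.mod(reps.to_numpy(), 1) != 0):
            raise DataValidationError("replicate must be a positive integer")
        for strain in sorted(set(df["strain"])):
            sub = df[df["strain"] == strain]
            if "control" not in set(sub["time"]):
                raise DataValidationError(f"strain {strain!r} has no control samples")
            for time in TIMES:
                if not np.any(sub["time"] == time):
                    raise DataValidationError(
                        f"no sample for strain {strain!r} at time {time!r}"
                    )
        df = df.assign(replicate=reps.astype(int))
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data["sample_id"]]

    @property
    def strains(self) -> list[str]:
        return sorted(set(self.data["strain"]))

    def samples_for(self, strain: str, time: str) -> list[str]:
        df = self.data
        mask = (df["strain"] == strain) & (df["time"] == time)
        return [str(s) for s in df.loc[mask, "sample_id"]]

    def require_match(self, counts: CountMatrix) -> None:
        """Counts columns and sample table must describe the same samples.

        Samples present in the counts file but absent from the table are a
        hard error: discarding a sample must be explicit, never silent.
        """
        table = set(self.sample_ids)
        matrix = set(counts.sample_ids)
        extra = sorted(matrix - table)
        if extra:
            raise DataValidationError(
                f"samples in counts but not in sample table: {extra}"
            )
        missing = sorted(table - matrix)
        if missing:
            raise DataValidationError(
                f"samples in sample table but not in counts: {missing}"
            )


@dataclass(frozen=True)
class ParalogueMap:
    """A/B paralogous gene pairs, one per encoded protein."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = {"protein_name", "gene_a", "gene_b"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"paralogue map missing columns: {sorted(missing)}")
        same = df["gene_a"] == df["gene_b"]
        if same.any():
            name = df.loc[same, "protein_name"].iloc[0]
            raise DataValidationError(f"pair {name!r} lists the same gene twice")
        all_genes = list(df["gene_a"]) + list(df["gene_b"])
        _check_unique(all_genes, "paralogue gene (a gene may appear in only one pair)")
        _check_unique(list(df["protein_name"]), "protein_name")
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def proteins(self) -> list[str]:
        return [str(p) for p in self.data["protein_name"]]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (stand-in for external functional annotations)."""

    sets: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            _check_unique(list(members), f"gene in set {name!r}")
            clean[str(name)] = [str(m) for m in members]
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# Readers / writers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV (first column gene id, header row).

    Raises :class:`DataValidationError` naming the offending gene for
    duplicated ids and citing row/column coordinates for negative or
    non-integer cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(list(df.index), "gene id")
    _check_unique([str(c) for c in df.columns], "sample id")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric count {df.iat[g, s]!r} at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataValidationError(
            f"missing count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(numeric)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str, "time": str})
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


def read_paralogue_map(path: str | Path) -> ParalogueMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ParalogueMap(df)


def write_paralogue_map(pairs: ParalogueMap, path: str | Path) -> None:
    pairs.data.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a two-column TSV (set_name, gene_id) or GMT lines.

    GMT lines carry ``name<TAB>description<TAB>gene1<TAB>gene2...``; a file
    in which every line has exactly two fields is read as the two-column
    format instead.
    """
    lines = [
        ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    rows = [ln.split("\t") for ln in lines]
    sets: dict[str, list[str]] = {}
    if all(len(r) == 2 for r in rows):
        start = 1 if rows and rows[0] == ["set_name", "gene_id"] else 0
        for name, gene in rows[start:]:
            sets.setdefault(name, [])
            if gene not in sets[name]:
                sets[name].append(gene)
    else:
        for r in rows:
            if len(r) < 3:
                raise DataValidationError(
                    f"GMT line needs name, description and >=1 gene: {r!r}"
                )
            name, _desc, *genes = r
            members: list[str] = []
            for g in genes:
                if g and g not in members:
                    members.append(g)
            sets[name] = members
    return GeneSetCollection(sets)
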