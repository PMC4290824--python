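"""Reading and writing count tables, designs, GMT gene sets and result tables.

The count-table dialect is the de-facto standard for pooled screen read
counts: a tab-separated file whose header names the columns, the first two
columns holding the sgRNA identifier and the gene it targets, and every
remaining column holding non-negative integer read counts for one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CountTableFormatError, DesignError, GMTFormatError

__all__ = [
    "CountTable",
    "DesignSpec",
    "PathwayDB",
    "read_count_table",
    "write_count_table",
    "read_gmt",
    "write_results",
]


@dataclass
class CountTable:
    """sgRNA-by-sample matrix of read counts with the sgRNA-to-gene mapping.

    Rows are sgRNAs (M of them), columns are samples/screening experiments
    (N of them).  Each sgRNA targets exactly one gene; a gene is usually
    targeted by several sgRNAs.
    """

    sgrna_ids: list[str]
    gene_ids: list[str]
    sample_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountTableFormatError("counts must be a 2-D matrix")
        m, n = self.counts.shape
        if len(self.sgrna_ids) != m or len(self.gene_ids) != m:
            raise CountTableFormatError(
                "sgrna_ids and gene_ids must have one entry per count row"
            )
        if len(self.sample_names) != n:
            raise CountTableFormatError("sample_names must match count columns")
        if n < 1:
            raise CountTableFormatError("need at least one sample column")
        dupes = _duplicates(self.sgrna_ids)
        if dupes:
            raise CountTableFormatError(f"duplicate sgRNA id {dupes[0]!r}")
        if len(set(self.sample_names)) != n:
            raise CountTableFormatError("duplicate sample names")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = self.counts.astype(float)
            rounded = np.rint(as_float)
            if not np.array_equal(as_float, rounded):
                i, j = np.argwhere(as_float != rounded)[0]
                raise CountTableFormatError(
                    f"non-integer count at sgRNA {self.sgrna_ids[i]!r}, "
                    f"sample {self.sample_names[j]!r}"
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise CountTableFormatError(
                f"negative count at sgRNA {self.sgrna_ids[i]!r}, "
                f"sample {self.sample_names[j]!r}"
            )

    @property
    def n_sgrnas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def all_zero(self) -> np.ndarray:
        """Boolean mask of sgRNAs with zero reads in every sample.

        Such sgRNAs stay in the table (removing them would change every
        rank percentile downstream); consumers decide how to treat them.
        """
        return (self.counts == 0).all(axis=1)

    def sample_index(self, names: list[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_names)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise DesignError(f"unknown sample(s): {', '.join(missing)}")
        return np.array([pos[s] for s in names], dtype=int)

    def gene_groups(self) -> dict[str, np.ndarray]:
        """Row indices per gene, genes in first-appearance order."""
        groups: dict[str, list[int]] = {}
        for i, g in enumerate(self.gene_ids):
            groups.setdefault(g, []).append(i)
        return {g: np.array(ix, dtype=int) for g, ix in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_names)
        df.insert(0, "gene", self.gene_ids)
        df.insert(0, "sgRNA", self.sgrna_ids)
        return df


@dataclass(frozen=True)
class DesignSpec:
    """Which samples are controls (condition A) and treatments (condition B)."""

    control_samples: tuple[str, ...]
    treatment_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        ctrl, trt = set(self.control_samples), set(self.treatment_samples)
        if not ctrl or not trt:
            raise DesignError("control and treatment sample sets must be non-empty")
        if ctrl & trt:
            raise DesignError(
                f"samples in both conditions: {', '.join(sorted(ctrl & trt))}"
            )

    def validate(self, table: CountTable) -> None:
        table.sample_index(list(self.control_samples))
        table.sample_index(list(self.treatment_samples))


@dataclass
class PathwayDB:
    """Named gene sets, e.g. KEGG or REACTOME exports in GMT format."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise GMTFormatError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen:
            dupes.append(x)
        seen.add(x)
    return dupes


def read_count_table(path) -> CountTable:
    """Parse a tab-separated count file: header, sgRNA, gene, sample columns."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise CountTableFormatError(
            f"{path}: need sgRNA, gene and at least one sample column"
        )
    sgrna_ids = df.iloc[:, 0].tolist()
    gene_ids = df.iloc[:, 1].tolist()
    sample_names = [str(c) for c in df.columns[2:]]
    raw = df.iloc[:, 2:]
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        try:
            vals = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise CountTableFormatError(
                f"{path}: non-numeric value in sample column {col!r}"
            ) from exc
        fv = np.asarray(vals, dtype=float)
        if np.isnan(fv).any():
            i = int(np.argmax(np.isnan(fv)))
            raise CountTableFormatError(
                f"{path}: missing count at row {i + 1}, sample {col!r}"
            )
        if not np.array_equal(fv, np.rint(fv)):
            i = int(np.argmax(fv != np.rint(fv)))
            raise CountTableFormatError(
                f"{path}: non-integer count at row {i + 1}, sample {col!r}"
            )
        counts[:, j] = fv.astype(np.int64)
    return CountTable(sgrna_ids, gene_ids, sample_names, counts)


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path, case_fold: bool = False) -> PathwayDB:
    """Parse an MSigDB-style GMT file: name, description, member genes.

    Gene symbols are matched case-sensitively by default; ``case_fold``
    upper-cases them, which hides annotation/source case mismatches and is
    therefore opt-in.
    """
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >=3"
                )
            name, desc = fields[0], fields[1]
            if name in pathways:
                raise GMTFormatError(f"{path}: duplicate pathway {name!r} at line {lineno}")
            genes = [g for g in fields[2:] if g]
            if case_fold:
                genes = [g.upper() for g in genes]
            pathways[name] = frozenset(genes)
            descriptions[name] = desc
    return PathwayDB(pathways, descriptions)


def write_results(results: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a result table as TSV, deterministically ordered.

    Rows are sorted by the first ``rank*`` column when one exists (the
    negative-selection rank for bi-directional summaries), otherwise left
    in input order; floats use at least six significant digits.
    """
    df = results.copy()
    rank_cols = [c for c in df.columns if c.startswith("rank")]
    if rank_cols and len(df):
        df = df.sort_values(rank_cols[0], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
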