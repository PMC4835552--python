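"""Tabular input/output and validation for expression artifacts.

Everything downstream speaks in terms of a small set of validated containers:
an :class:`ExpressionMatrix` (gene x sample abundances), a
:class:`ReferenceTimecourse` (an expression matrix whose columns are ordered
developmental stages with times in minutes after egg deposition, AED), a
:class:`GeneClass` labelling (maternal / zygotic / unclassified) and a
:class:`HalfLifeTable` of per-gene mRNA half-lives in minutes.

All on-disk formats are plain tab-separated text so fixtures stay diffable:

* expression matrix -- header row of sample ids, first column gene ids;
* gene list -- one id per line, ``#`` comments allowed;
* half-life table -- ``gene<TAB>minutes``;
* stage table -- ``label<TAB>minutes``, rows in developmental order.

Gene identifiers are matched by exact string equality after stripping
surrounding whitespace; no symbol aliasing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_CLASS_LABELS = ("maternal", "zygotic", "unclassified")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample abundance table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Values are
        RPKM-like abundances (or simulated equivalents); never negative.
    unit_tag
        One of ``rpkm``, ``abundance``, ``counts``.
    """

    values: pd.DataFrame
    unit_tag: str = "abundance"

    def __post_init__(self) -> None:
        if self.unit_tag not in ("rpkm", "abundance", "counts"):
            raise ValidationError(f"unknown unit_tag {self.unit_tag!r}")
        df = self.values
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("expression matrix needs >=1 gene and >=1 sample")
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        dup_g = df.index[df.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {dup_g[:5]}")
        dup_s = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s[:5]}")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value for gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value {arr[gi, si]} for gene {df.index[gi]!r}, "
                f"sample {df.columns[si]!r}"
            )
        df = df.astype(float)
        df.index.name = "gene_id"
        df.columns.name = None
        self.values = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.unit_tag)

    def mean_profile(self) -> pd.Series:
        """Replicate-pooled mean abundance per gene."""
        return self.values.mean(axis=1)


@dataclass
class ReferenceTimecourse:
    """Expression matrix whose samples are ordered developmental stages.

    ``stage_times`` are minutes AED, strictly increasing, one per column of
    ``matrix`` in column order.
    """

    matrix: ExpressionMatrix
    stage_labels: tuple[str, ...]
    stage_times: np.ndarray

    def __post_init__(self) -> None:
        self.stage_labels = tuple(str(s).strip() for s in self.stage_labels)
        self.stage_times = np.asarray(self.stage_times, dtype=float)
        ncol = self.matrix.values.shape[1]
        if len(self.stage_labels) != ncol:
            raise ValidationError(
                f"{len(self.stage_labels)} stage labels for {ncol} reference columns"
            )
        if len(self.stage_times) != ncol:
            raise ValidationError(
                f"{len(self.stage_times)} stage times for {ncol} reference columns"
            )
        if tuple(self.matrix.sample_ids) != self.stage_labels:
            raise ValidationError("stage labels must match matrix columns in order")
        if not np.all(np.diff(self.stage_times) > 0):
            raise ValidationError("stage times must be strictly increasing")

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.gene_ids

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def subset_genes(self, genes: Sequence[str]) -> "ReferenceTimecourse":
        return ReferenceTimecourse(
            self.matrix.subset_genes(genes), self.stage_labels, self.stage_times.copy()
        )


@dataclass
class GeneClass:
    """Per-gene label in ``{maternal, zygotic, unclassified}``."""

    labels: pd.Series
    source_tag: str = ""

    def __post_init__(self) -> None:
        s = self.labels
        s.index = s.index.astype(str).str.strip()
        if s.index.duplicated().any():
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in class table: {dups[:5]}")
        bad = sorted(set(s.astype(str)) - set(GENE_CLASS_LABELS))
        if bad:
            raise ValidationError(f"unknown class labels: {bad}")
        self.labels = s.astype(str)

    @property
    def gene_ids(self) -> pd.Index:
        return self.labels.index

    def genes_of(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def subset_genes(self, genes: Sequence[str]) -> "GeneClass":
        return GeneClass(self.labels.loc[list(genes)].copy(), self.source_tag)


@dataclass
class HalfLifeTable:
    """Gene id -> mRNA half-life in minutes (finite, positive)."""

    halflives: pd.Series

    def __post_init__(self) -> None:
        s = self.halflives.astype(float)
        s.index = s.index.astype(str).str.strip()
        if s.index.duplicated().any():
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in half-life table: {dups[:5]}")
        bad = s.index[~np.isfinite(s.to_numpy()) | (s.to_numpy() <= 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive or non-finite half-life for gene(s) {list(bad[:5])}"
            )
        self.halflives = s

    @property
    def gene_ids(self) -> pd.Index:
        return self.halflives.index

    def subset_genes(self, genes: Sequence[str]) -> "HalfLifeTable":
        return HalfLifeTable(self.halflives.loc[list(genes)].copy())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, unit_tag: str = "abundance") -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The first column holds gene ids and the header row sample ids. Ragged
    rows, duplicate ids, negative or non-numeric values raise
    :class:`ValidationError` naming the offending row where possible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed table ({exc})") from exc
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for row_no, (gene, row) in enumerate(df.iterrows(), start=2):
            try:
                row.astype(float)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: non-numeric value at row {row_no} (gene {gene!r})"
                ) from exc
        raise
    try:
        return ExpressionMatrix(df, unit_tag)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; ``#`` starts a comment; blank lines ignored."""
    genes: list[str] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        if "\t" in entry or " " in entry:
            raise ValidationError(f"{path}: line {line_no}: expected a single gene id")
        genes.append(entry)
    seen = set()
    for g in genes:
        if g in seen:
            raise ValidationError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path, header: str = "") -> None:
    lines = [f"# {h}" for h in header.splitlines() if h] if header else []
    lines += [str(g) for g in genes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_class(
    maternal: str | Path | None = None,
    zygotic: str | Path | None = None,
    source_tag: str = "",
) -> GeneClass:
    """Build a :class:`GeneClass` from per-label gene-list files.

    A gene listed in both the maternal and the zygotic file is an error.
    """
    mat = read_gene_list(maternal) if maternal is not None else []
    zyg = read_gene_list(zygotic) if zygotic is not None else []
    overlap = sorted(set(mat) & set(zyg))
    if overlap:
        raise ValidationError(
            f"gene(s) listed as both maternal and zygotic: {overlap[:5]}"
        )
    labels = pd.Series(
        ["maternal"] * len(mat) + ["zygotic"] * len(zyg), index=mat + zyg, dtype=str
    )
    if labels.empty:
        raise ValidationError("no genes in gene-class input")
    return GeneClass(labels, source_tag)


def read_halflife_table(path: str | Path) -> HalfLifeTable:
    """Read a ``gene<TAB>half-life-minutes`` table (no header required)."""
    rows: list[tuple[str, float]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        parts = entry.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path}: line {line_no}: expected gene<TAB>minutes, got {entry!r}"
            )
        gene, value = parts[0].strip(), parts[1].strip()
        if line_no == 1 and gene.lower() in ("gene", "gene_id"):
            continue
        try:
            hl = float(value)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: line {line_no}: non-numeric half-life {value!r}"
            ) from exc
        rows.append((gene, hl))
    if not rows:
        raise ValidationError(f"{path}: empty half-life table")
    series = pd.Series({g: h for g, h in rows})
    if len(series) != len(rows):
        raise ValidationError(f"{path}: duplicate gene ids")
    try:
        return HalfLifeTable(series)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_halflife_table(table: HalfLifeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\thalflife_min\n")
        for gene, hl in table.halflives.items():
            fh.write(f"{gene}\t{hl:.17g}\n")


def read_stage_table(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read ``label<TAB>minutes`` rows in developmental order."""
    labels: list[str] = []
    times: list[float] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        parts = entry.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path}: line {line_no}: expected label<TAB>minutes"
            )
        if line_no == 1 and parts[0].strip().lower() in ("stage", "label"):
            continue
        labels.append(parts[0].strip())
        times.append(float(parts[1]))
    if not labels:
        raise ValidationError(f"{path}: empty stage table")
    return tuple(labels), np.asarray(times, dtype=float)


def write_stage_table(
    labels: Sequence[str], times: Sequence[float], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("stage\ttime_min\n")
        for lab, t in zip(labels, times):
            fh.write(f"{lab}\t{t:.10g}\n")


def read_reference(
    matrix_path: str | Path, stage_table_path: str | Path, unit_tag: str = "abundance"
) -> ReferenceTimecourse:
    matrix = read_matrix(matrix_path, unit_tag)
    labels, times = read_stage_table(stage_table_path)
    return ReferenceTimecourse(matrix, labels, times)


def write_reference(
    reference: ReferenceTimecourse,
    matrix_path: str | Path,
    stage_table_path: str | Path,
) -> None:
    write_matrix(reference.matrix, matrix_path)
    write_stage_table(reference.stage_labels, reference.stage_times, stage_table_path)


# ---------------------------------------------------------------------------
# Gene-universe intersection
# ---------------------------------------------------------------------------

GeneCarrier = ExpressionMatrix | ReferenceTimecourse | GeneClass | HalfLifeTable


def intersect_genes(*objects: GeneCarrier) -> tuple[list[GeneCarrier], pd.DataFrame]:
    """Restrict two or more gene-indexed objects to their common gene set.

    Returns the restricted objects (gene order taken from the first object)
    and a per-input report of retained/dropped counts. An empty intersection
    is an error.
    """
    if len(objects) < 2:
        raise ValueError("intersect_genes needs at least two objects")
    common = set(objects[0].gene_ids)
    for obj in objects[1:]:
        common &= set(obj.gene_ids)
    if not common:
        raise ValidationError("empty gene intersection across inputs")
    order = [g for g in objects[0].gene_ids if g in common]
    restricted = [obj.subset_genes(order) for obj in objects]
    report = pd.DataFrame(
        {
            "input": list(range(len(objects))),
            "type": [type(o).__name__ for o in objects],
            "n_genes": [len(o.gene_ids) for o in objects],
            "n_kept": [len(order)] * len(objects),
            "n_dropped": [len(o.gene_ids) - len(order) for o in objects],
        }
    )
    return restricted, report
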