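"""Readers and writers for the pipeline's file formats.

Dialects
--------
Expression matrix
    Tab-separated text, one file per cancer-type cohort. First header cell is
    ``gene``, remaining header cells are sample IDs. Each subsequent row is a
    gene symbol followed by one value per sample. Missing values are accepted
    on read as ``NA``, ``NaN`` or the empty string and always written as
    ``NA``. Values are written with full (round-trip) precision.
GMT
    One gene set per line: name, description, then one or more member gene
    symbols, tab-separated. Duplicate members within a set are de-duplicated
    (order preserving).
RNK
    Two tab-separated columns (gene symbol, score), sorted descending by
    score, full float precision. This is the input format of preranked
    gene-set enrichment.
Gene list
    One symbol per line; blank lines and lines starting with ``#`` ignored.
Responder cohort
    Tab-separated with header ``sample_id  response  CD3E_TPM  PDCD1_TPM``;
    response labels are ``responder`` or ``nonresponder``.

Gene symbols are case-sensitive everywhere and matched exactly; no aliasing
is attempted. All writers are deterministic byte-for-byte given identical
inputs; all readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ResponderCohort",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "write_rnk",
    "read_rnk",
    "read_gene_list",
    "read_responder_table",
    "write_responder_table",
    "load_panel_genes",
    "load_printed_coexpression_table",
]

#: Tokens recognised as missing on input. Output always uses "NA".
MISSING_TOKENS = frozenset({"NA", "NaN", ""})

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
_RESPONSE_LABELS = frozenset({RESPONDER, NONRESPONDER})


def _fmt(value: float) -> str:
    """Full-precision, round-trippable text form of a float ('NA' if missing)."""
    if np.isnan(value):
        return "NA"
    return repr(float(value))


@dataclass
class ExpressionMatrix:
    """One cancer-type cohort: genes x samples with missing-value support.

    Parameters
    ----------
    cancer_type
        Cohort label (e.g. a TCGA study abbreviation such as ``SKCM``).
    data
        ``pandas.DataFrame`` with gene symbols as the index, sample IDs as
        the columns and float values; ``NaN`` marks a missing measurement.
    """

    cancer_type: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(
                f"duplicate gene symbol(s) in cohort {self.cancer_type!r}: "
                + ", ".join(map(repr, dupes))
            )
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValueError(
                f"duplicate sample ID(s) in cohort {self.cancer_type!r}: "
                + ", ".join(map(repr, dupes))
            )
        self.data = self.data.astype(float)
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy()).any():
                raise ValueError("expression values must be finite or missing")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.cancer_type == other.cancer_type and self.data.equals(other.data)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT contents)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene set name: {dup!r}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class ResponderCohort:
    """Paired marker/checkpoint expression with therapy-response labels.

    ``data`` columns: ``sample_id`` (index), ``response``, ``CD3E_TPM``,
    ``PDCD1_TPM``. ``outlier_id`` optionally records the sample planted (or
    identified) as the very-high-expression outlier.
    """

    data: pd.DataFrame
    outlier_id: str | None = None

    def __post_init__(self) -> None:
        required = {"response", "CD3E_TPM", "PDCD1_TPM"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"responder table missing column(s): {sorted(missing)}")
        bad = set(self.data["response"]) - _RESPONSE_LABELS
        if bad:
            raise ValueError(f"unknown response label(s): {sorted(bad)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs in responder cohort")
        if (self.data[["CD3E_TPM", "PDCD1_TPM"]].to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative (TPM)")

    def group(self, label: str) -> pd.DataFrame:
        if label not in _RESPONSE_LABELS:
            raise ValueError(f"unknown response label {label!r}")
        return self.data[self.data["response"] == label]

    @property
    def n_responders(self) -> int:
        return int((self.data["response"] == RESPONDER).sum())

    @property
    def n_nonresponders(self) -> int:
        return int((self.data["response"] == NONRESPONDER).sum())


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(path: str | Path, cancer_type: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The cohort label defaults to the file stem. Raises ``ValueError`` on
    ragged rows (with the line number), duplicate gene symbols (naming the
    symbol) and non-numeric cells.
    """
    path = Path(path)
    label = cancer_type if cancer_type is not None else path.stem
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 1:
            raise ValueError(f"{path}: malformed header")
        sample_ids = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            symbol = row[0]
            if symbol in seen:
                raise ValueError(f"{path}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            genes.append(symbol)
            values = []
            for cell in row[1:]:
                if cell in MISSING_TOKENS:
                    values.append(np.nan)
                else:
                    try:
                        values.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: non-numeric cell {cell!r}"
                        ) from None
            rows.append(values)
    data = pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)
    return ExpressionMatrix(cancer_type=label, data=data)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the expression TSV dialect (full float precision)."""
    path = Path(path)
    values = matrix.data.to_numpy()
    with open(path, "w", newline="") as fh:
        fh.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for gene, row in zip(matrix.genes, values):
            fh.write(gene + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection; order-preserving, members de-duplicated."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} field(s))"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if not uniq:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, description=description, genes=tuple(uniq)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join((s.name, s.description, *s.genes)) + "\n")


# ---------------------------------------------------------------------------
# rankings


def write_rnk(table, path: str | Path) -> None:
    """Write a RankedGeneTable (or (gene, score) Series) as an RNK file.

    Two tab-separated columns, sorted descending by score (ties by ascending
    symbol), full float precision, genes with missing scores omitted.
    """
    if hasattr(table, "medians"):
        series = table.medians
    elif isinstance(table, pd.Series):
        series = table
    else:
        raise TypeError("expected RankedGeneTable or pandas Series")
    series = series.dropna()
    order = sorted(series.index, key=lambda g: (-series[g], g))
    with open(Path(path), "w") as fh:
        for gene in order:
            fh.write(f"{gene}\t{_fmt(series[gene])}\n")


def read_rnk(path: str | Path) -> pd.Series:
    """Read an RNK file into a gene -> score Series (input order preserved)."""
    genes: list[str] = []
    scores: list[float] = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields")
            genes.append(fields[0])
            scores.append(float(fields[1]))
    if len(genes) != len(set(genes)):
        raise ValueError(f"{path}: duplicate gene symbols in RNK file")
    return pd.Series(scores, index=genes, dtype=float)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list ('#' comment lines allowed)."""
    symbols: list[str] = []
    seen: set[str] = set()
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line in seen:
                raise ValueError(f"{path}: duplicate gene symbol {line!r}")
            seen.add(line)
            symbols.append(line)
    return symbols


# ---------------------------------------------------------------------------
# responder cohorts


def read_responder_table(path: str | Path) -> ResponderCohort:
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return ResponderCohort(data=df)


def write_responder_table(cohort: ResponderCohort, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("sample_id\tresponse\tCD3E_TPM\tPDCD1_TPM\n")
        for sample_id, row in cohort.data.iterrows():
            fh.write(
                f"{sample_id}\t{row['response']}\t"
                f"{_fmt(row['CD3E_TPM'])}\t{_fmt(row['PDCD1_TPM'])}\n"
            )


# ---------------------------------------------------------------------------
# shipped fixtures


def load_panel_genes() -> list[str]:
    """The 40-gene candidate immune-regulator panel shipped with the package."""
    ref = resources.files("tmetargets.data") / "tcell_panel_40.txt"
    with resources.as_file(ref) as p:
        return read_gene_list(p)


def load_printed_coexpression_table() -> pd.DataFrame:
    """Published top CD3E co-expression ranking (printed medians, 3 decimals).

    Columns: ``rank`` (published), ``symbol``, ``median_r``, ``panel`` (bool).
    Contains the printed top-55 rows plus CTLA4 (published rank 103).
    """
    ref = resources.files("tmetargets.data") / "cd3e_top_coexpression.tsv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    df["panel"] = df["panel"].astype(bool)
    return df
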