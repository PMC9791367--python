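"""Readers and writers for the deleteome-style expression compendium and
deletion-fitness tables.

The expression compendium is a wide tab-separated table: one row per gene
measured on the array, and for every deletion strain a pair of columns
holding the log2 fold-change versus wild type (M) and the FDR-adjusted
p-value of that change. Strain headers encode the deleted gene and,
optionally, a growth-media label. The exact layout is *dialect-driven*: a
small declarative config maps column labels and the strain-header pattern,
so format drift in the source file never touches analysis code. P-values
are consumed exactly as stored (they are already FDR-adjusted upstream);
missing cells are kept as NaN and excluded downstream, never dropped
silently.
"""

from __future__ import annotations

import io as _io
import logging
import math
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError, ConfigError

logger = logging.getLogger(__name__)

#: Strain headers look like "yfr034c-del vs. wt" with an optional
#: parenthesised media label, e.g. "yfr034c-del vs. wt (gal)".
DELETEOME_STRAIN_PATTERN = (
    r"^(?P<gene>\S+)-del vs\. wt(?: \((?P<media>[^)]+)\))?$"
)


@dataclass(frozen=True)
class ExpressionDialect:
    """Column-mapping config for an expression compendium file.

    Two header rows are expected: the first repeats the strain header over
    that strain's sub-columns, the second labels each sub-column as M or p.
    One M and one p column per strain is assumed.
    """

    gene_column: str = "gene"
    m_label: str = "M"
    p_label: str = "p_value"
    strain_pattern: str = DELETEOME_STRAIN_PATTERN
    default_media: str = "ypd"
    sep: str = "\t"
    na_rep: str = "NA"

    def strain_header(self, deleted_gene: str, media: str) -> str:
        """Render the header string for a strain in this dialect."""
        base = f"{deleted_gene}-del vs. wt"
        if media != self.default_media:
            base += f" ({media})"
        return base

    def parse_strain_header(self, header: str) -> tuple[str, str]:
        m = re.match(self.strain_pattern, header)
        if m is None:
            raise ParseError(
                f"strain header {header!r} does not match the dialect "
                f"pattern {self.strain_pattern!r}"
            )
        media = m.groupdict().get("media") or self.default_media
        return m.group("gene"), media

    @classmethod
    def from_yaml(cls, path) -> "ExpressionDialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class FitnessDialect:
    """Column mapping for the per-deletion competitive-fitness table."""

    gene_column: str = "gene"
    fitness_column: str = "fitness"
    sep: str = "\t"


@dataclass
class ExpressionCompendium:
    """Per-(strain, gene) M and adjusted-p matrices plus strain metadata.

    ``strains`` has one row per deletion strain with columns
    ``strain_id`` (the file header string), ``deleted_gene`` and ``media``.
    ``M`` and ``P`` are indexed by ``strain_id`` with one column per gene,
    in file order. NaN marks a missing measurement.
    """

    strains: pd.DataFrame
    M: pd.DataFrame
    P: pd.DataFrame

    def __post_init__(self):
        self.validate()
        self._strain_by_gene: Optional[dict] = None

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if not self.M.index.equals(self.P.index) or not self.M.columns.equals(
            self.P.columns
        ):
            raise ValidationError("M and P must share (strain, gene) indexes")
        if self.M.index.has_duplicates:
            raise ValidationError("duplicate strain identifiers")
        if self.M.columns.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        if not self.M.index.equals(pd.Index(self.strains["strain_id"])):
            raise ValidationError("strain metadata and matrices disagree")
        p = self.P.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((p < 0) | (p > 1))
        if bad:
            raise ValidationError(f"{int(bad)} p-values outside [0, 1]")

    # -- conveniences -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.M.columns

    @property
    def n_strains(self) -> int:
        return len(self.M)

    @property
    def n_genes(self) -> int:
        return self.M.shape[1]

    def deletion_measured(self, deleted_gene: str) -> bool:
        return deleted_gene in self.genes

    def strain_for_deletion(self, deleted_gene: str) -> str:
        if self._strain_by_gene is None:
            counts = self.strains["deleted_gene"].value_counts()
            dupes = counts[counts > 1]
            mapping = dict(
                zip(self.strains["deleted_gene"], self.strains["strain_id"])
            )
            for g in dupes.index:
                mapping.pop(g, None)
            self._strain_by_gene = mapping
            self._duplicated_deletions = set(dupes.index)
        if deleted_gene in getattr(self, "_duplicated_deletions", ()):
            raise ValidationError(
                f"gene {deleted_gene!r} is deleted by multiple strains"
            )
        try:
            return self._strain_by_gene[deleted_gene]
        except KeyError:
            raise ValidationError(f"no strain deletes gene {deleted_gene!r}")

    def m_row(self, deleted_gene: str) -> pd.Series:
        """M values (log2 fold-change) of the strain deleting a gene."""
        return self.M.loc[self.strain_for_deletion(deleted_gene)]

    def p_row(self, deleted_gene: str) -> pd.Series:
        return self.P.loc[self.strain_for_deletion(deleted_gene)]

    def equals(self, other: "ExpressionCompendium", atol: float = 0.0) -> bool:
        if not self.strains.reset_index(drop=True).equals(
            other.strains.reset_index(drop=True)
        ):
            return False
        for a, b in ((self.M, other.M), (self.P, other.P)):
            if not a.index.equals(b.index) or not a.columns.equals(b.columns):
                return False
            x, y = a.to_numpy(float), b.to_numpy(float)
            both_nan = np.isnan(x) & np.isnan(y)
            close = np.isclose(x, y, rtol=0.0, atol=atol, equal_nan=False)
            if not np.all(both_nan | close):
                return False
        return True


@dataclass
class FitnessTable:
    """Competitive fitness of each deletion relative to a reference (=1)."""

    values: pd.Series  # index: deleted gene, value: relative fitness

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in fitness table")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("fitness values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    def fitness(self, gene: str) -> float:
        return float(self.values.loc[gene])

    def cost(self, gene: str) -> float:
        """Fitness cost = 1 - relative fitness (negative if beneficial)."""
        return 1.0 - self.fitness(gene)


# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

def read_expression_compendium(
    path,
    dialect: Optional[ExpressionDialect] = None,
    drop_nonstandard_media: bool = False,
) -> ExpressionCompendium:
    """Read a compendium file, validating headers and every numeric cell.

    With ``drop_nonstandard_media`` strains whose media label differs from
    the dialect's default rich-media label are removed (the source data
    include a handful of alternative-media experiments that the analysis
    excludes).
    """
    dialect = dialect or ExpressionDialect()
    path = Path(path)
    with open(path) as fh:
        line1 = fh.readline().rstrip("\n")
        line2 = fh.readline().rstrip("\n")
    if not line1:
        raise ParseError(f"{path}: empty file, no header rows")
    header1 = line1.split(dialect.sep)
    header2 = line2.split(dialect.sep) if line2 else [""]
    if header1[0] != dialect.gene_column:
        raise ParseError(
            f"{path}: first column is {header1[0]!r}, expected "
            f"{dialect.gene_column!r}"
        )
    if len(header2) != len(header1):
        # a header-only file with zero strains has a single gene column
        if len(header1) == 1 and header2 == [""]:
            header2 = [header1[0]]
        else:
            raise ParseError(
                f"{path}: header rows have {len(header1)} vs {len(header2)} fields"
            )

    # group data columns by strain header, preserving first-appearance order
    strain_order: list[str] = []
    columns: dict[str, dict[str, int]] = {}
    for idx in range(1, len(header1)):
        strain_id, sub = header1[idx], header2[idx]
        if sub not in (dialect.m_label, dialect.p_label):
            raise ParseError(
                f"{path}: column {idx + 1} has sub-label {sub!r}; expected "
                f"{dialect.m_label!r} or {dialect.p_label!r}"
            )
        if strain_id not in columns:
            columns[strain_id] = {}
            strain_order.append(strain_id)
        if sub in columns[strain_id]:
            raise ParseError(
                f"{path}: strain {strain_id!r} has duplicate {sub!r} columns"
            )
        columns[strain_id][sub] = idx
    for strain_id, subs in columns.items():
        missing = {dialect.m_label, dialect.p_label} - set(subs)
        if missing:
            raise ParseError(
                f"{path}: strain {strain_id!r} lacks column(s) {sorted(missing)}"
            )

    records = []
    for strain_id in strain_order:
        gene, media = dialect.parse_strain_header(strain_id)
        records.append({"strain_id": strain_id, "deleted_gene": gene, "media": media})
    strains = pd.DataFrame(records, columns=["strain_id", "deleted_gene", "media"])

    # data block: read as strings so bad cells can be reported by coordinate
    try:
        raw = pd.read_csv(
            path,
            sep=dialect.sep,
            skiprows=2,
            header=None,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(len(header1)))
    if len(raw) and raw.shape[1] != len(header1):
        raise ParseError(
            f"{path}: data rows have {raw.shape[1]} fields, header has "
            f"{len(header1)}"
        )
    genes = pd.Index(raw[0].astype(str)) if len(raw) else pd.Index([], dtype=object)
    if genes.has_duplicates:
        dupes = genes[genes.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene identifiers {dupes[:5]}")

    def numeric(col_idx: int, label: str) -> np.ndarray:
        if not len(raw):
            return np.empty(0, dtype=float)
        col = raw[col_idx].replace(dialect.na_rep, np.nan).replace("", np.nan)
        check = pd.to_numeric(col, errors="coerce")
        bad = check.isna() & col.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {col.iloc[row]!r} at data row "
                f"{row + 1}, column {label!r}"
            )
        # numpy's string->float conversion is correctly rounded, so 17-digit
        # output from the writer round-trips bit for bit
        return np.array(col.fillna("nan"), dtype=float)

    m_cols, p_cols = {}, {}
    for strain_id in strain_order:
        m_cols[strain_id] = numeric(columns[strain_id][dialect.m_label], strain_id + "/M")
        p_vals = numeric(columns[strain_id][dialect.p_label], strain_id + "/p")
        with np.errstate(invalid="ignore"):
            out_of_range = np.nansum((p_vals < 0) | (p_vals > 1))
        if out_of_range:
            raise ValidationError(
                f"{path}: strain {strain_id!r} has {int(out_of_range)} "
                "p-values outside [0, 1]"
            )
        p_cols[strain_id] = p_vals

    M = pd.DataFrame(m_cols, index=genes).T
    P = pd.DataFrame(p_cols, index=genes).T
    M = M.reindex(strain_order)
    P = P.reindex(strain_order)
    M.columns = genes
    P.columns = genes

    if drop_nonstandard_media:
        keep = strains["media"] == dialect.default_media
        n_dropped = int((~keep).sum())
        strains = strains.loc[keep].reset_index(drop=True)
        M = M.loc[strains["strain_id"]]
        P = P.loc[strains["strain_id"]]
        logger.info(
            "read %s: retained %d strains (%d dropped for non-%s media), %d genes",
            path.name, len(strains), n_dropped, dialect.default_media, len(genes),
        )
    else:
        logger.info(
            "read %s: %d strains, %d genes", path.name, len(strains), len(genes)
        )
    return ExpressionCompendium(strains=strains, M=M, P=P)


def write_expression_compendium(
    compendium: ExpressionCompendium,
    path,
    dialect: Optional[ExpressionDialect] = None,
):
    """Write a compendium in the dialect consumed by the reader.

    Floats are rendered with 17 significant digits so values round-trip
    exactly through text.
    """
    dialect = dialect or ExpressionDialect()
    path = Path(path)
    sep = dialect.sep

    def fmt(v: float) -> str:
        return dialect.na_rep if (v is None or math.isnan(v)) else f"{v:.17g}"

    buf = _io.StringIO()
    strain_ids = list(compendium.M.index)
    head1 = [dialect.gene_column]
    head2 = [""]
    for sid in strain_ids:
        head1 += [sid, sid]
        head2 += [dialect.m_label, dialect.p_label]
    buf.write(sep.join(head1) + "\n")
    buf.write(sep.join(head2) + "\n")
    Mv = compendium.M.to_numpy(dtype=float)
    Pv = compendium.P.to_numpy(dtype=float)
    for j, gene in enumerate(compendium.genes):
        fields = [str(gene)]
        for i in range(len(strain_ids)):
            fields.append(fmt(Mv[i, j]))
            fields.append(fmt(Pv[i, j]))
        buf.write(sep.join(fields) + "\n")
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# fitness table
# ---------------------------------------------------------------------------

def read_fitness_table(path, dialect: Optional[FitnessDialect] = None) -> FitnessTable:
    dialect = dialect or FitnessDialect()
    path = Path(path)
    table = pd.read_csv(path, sep=dialect.sep, dtype={0: str})
    for col in (dialect.gene_column, dialect.fitness_column):
        if col not in table.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    genes = table[dialect.gene_column].astype(str)
    if genes.duplicated().any():
        dupes = genes[genes.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene identifiers {dupes[:5]}")
    fitness = pd.to_numeric(table[dialect.fitness_column], errors="coerce")
    if fitness.isna().any():
        row = int(np.flatnonzero(fitness.isna().to_numpy())[0])
        raise ParseError(f"{path}: non-numeric fitness at data row {row + 1}")
    values = pd.Series(fitness.to_numpy(dtype=float), index=pd.Index(genes, name="gene"))
    return FitnessTable(values=values)


def write_fitness_table(
    table: FitnessTable, path, dialect: Optional[FitnessDialect] = None
):
    dialect = dialect or FitnessDialect()
    path = Path(path)
    frame = pd.DataFrame(
        {
            dialect.gene_column: table.values.index,
            dialect.fitness_column: [f"{v:.17g}" for v in table.values.to_numpy()],
        }
    )
    frame.to_csv(path, sep=dialect.sep, index=False)
    return path
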