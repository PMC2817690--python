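"""Domain types and tabular I/O for the transcriptome-map pipeline.

Everything downstream (map building, region calling, feature tracks,
synteny analysis) consumes the types defined here.  All coordinates are
held internally as 0-based half-open intervals; readers normalise from
the dialect's native convention on the way in and writers convert back
on the way out, so a write/read round trip is the identity.

Supported dialects for gene tables:

``tsv``
    The package's own tab-separated layout (1-based inclusive
    coordinates, the Ensembl/BioMart convention), columns
    ``gene_id  chrom  start  end  strand  gc_fraction  intron_lengths``.
    ``gc_fraction`` and ``intron_lengths`` may be empty.  Intron lengths
    are semicolon-separated per transcript and comma-separated within a
    transcript, e.g. ``100,200;300`` is two transcripts.
``bed``
    BED6 (0-based half-open, passed through): ``chrom start end name
    score strand``.  GC and intron annotation are not representable.
``gff-lite``
    Nine GFF columns (1-based inclusive); the record id is taken from an
    ``ID=`` key in the attributes column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "RecordValidationError",
    "GeneRecord",
    "ExpressionTable",
    "SyntenyBlock",
    "HomologPair",
    "ProbeCollapseReport",
    "read_gene_table",
    "write_gene_table",
    "read_expression",
    "write_expression",
    "collapse_probes",
    "read_synteny",
    "write_synteny",
    "read_homologs",
    "write_homologs",
]


class TableFormatError(ValueError):
    """A file does not match the expected tabular layout (e.g. a missing column)."""


class RecordValidationError(ValueError):
    """A single record violates a domain invariant (reported with its line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class GeneRecord:
    """One gene's genomic location, strand and optional sequence features.

    Coordinates are 0-based half-open.  ``transcript_intron_lengths``
    holds one inner list of intron lengths (bp) per annotated transcript.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gc_fraction: float | None = None
    transcript_intron_lengths: list[list[int]] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RecordValidationError(
                f"gene {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise RecordValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise RecordValidationError(
                f"gene {self.gene_id!r}: gc_fraction {self.gc_fraction} outside [0, 1]"
            )
        if self.transcript_intron_lengths is not None:
            for tx in self.transcript_intron_lengths:
                if any(length <= 0 for length in tx):
                    raise RecordValidationError(
                        f"gene {self.gene_id!r}: intron lengths must be positive"
                    )

    @property
    def midpoint(self) -> int:
        """Integer gene midpoint, ``floor((start + end) / 2)``; the ordering key for maps."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionTable:
    """A genes x tissues matrix of log2 expression values.

    ``summary`` is the per-gene median across tissues, the value the
    combined transcriptome map smooths.
    """

    gene_ids: list[str]
    tissue_names: list[str]
    values: np.ndarray
    summary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_names)):
            raise RecordValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tissue_names)} tissues"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise RecordValidationError(f"duplicate gene id {dup!r} in expression table")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise RecordValidationError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"tissue {self.tissue_names[j]!r}"
            )
        self.summary = np.median(self.values, axis=1)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def summary_by_gene(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.summary.tolist()))

    def value_by_gene(self, tissue: str) -> dict[str, float]:
        try:
            j = self.tissue_names.index(tissue)
        except ValueError:
            raise KeyError(f"unknown tissue {tissue!r}") from None
        return dict(zip(self.gene_ids, self.values[:, j].tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.tissue_names)

    def rename_genes(self, mapping: dict[str, str]) -> "ExpressionTable":
        """A copy with gene ids translated through ``mapping`` (used for homolog genomes)."""
        return ExpressionTable(
            gene_ids=[mapping.get(g, g) for g in self.gene_ids],
            tissue_names=list(self.tissue_names),
            values=self.values.copy(),
        )


@dataclass(slots=True)
class SyntenyBlock:
    """A conserved synteny block: one span in each of two genomes.

    Orientation ``-`` means the block is inverted between the genomes,
    so the left end in genome A corresponds to the right end in genome B.
    """

    block_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str

    def __post_init__(self) -> None:
        if self.start_a >= self.end_a:
            raise RecordValidationError(
                f"block {self.block_id!r}: start_a must be < end_a"
            )
        if self.start_b >= self.end_b:
            raise RecordValidationError(
                f"block {self.block_id!r}: start_b must be < end_b"
            )
        if self.orientation not in ("+", "-"):
            raise RecordValidationError(
                f"block {self.block_id!r}: orientation must be '+' or '-'"
            )


@dataclass(slots=True, frozen=True)
class HomologPair:
    """A 1-to-1 ortholog pair between genome A and genome B."""

    gene_id_a: str
    gene_id_b: str


def validate_homolog_pairs(pairs: Sequence[HomologPair]) -> None:
    """Enforce 1-to-1: no gene id may occur in more than one pair."""
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for p in pairs:
        if p.gene_id_a in seen_a:
            raise RecordValidationError(f"gene {p.gene_id_a!r} occurs in multiple homolog pairs")
        if p.gene_id_b in seen_b:
            raise RecordValidationError(f"gene {p.gene_id_b!r} occurs in multiple homolog pairs")
        seen_a.add(p.gene_id_a)
        seen_b.add(p.gene_id_b)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "gc_fraction", "intron_lengths"]


def _parse_introns(cell: str) -> list[list[int]] | None:
    cell = cell.strip()
    if not cell:
        return None
    return [[int(x) for x in tx.split(",") if x] for tx in cell.split(";") if tx]


def _format_introns(introns: list[list[int]] | None) -> str:
    if introns is None:
        return ""
    return ";".join(",".join(str(x) for x in tx) for tx in introns)


def read_gene_table(path: str | Path, dialect: str = "tsv") -> list[GeneRecord]:
    """Read a gene annotation table and normalise to internal coordinates.

    ``tsv`` and ``gff-lite`` inputs are 1-based inclusive and are shifted
    to 0-based half-open on read; ``bed`` is already 0-based half-open.
    Records are returned sorted by (chrom, start, gene_id).
    """
    if dialect not in ("tsv", "bed", "gff-lite"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[GeneRecord] = []
    with path.open() as fh:
        header_checked = dialect != "tsv"
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_checked:
                missing = [c for c in _GENE_TSV_COLUMNS[:5] if c not in fields]
                if missing:
                    raise TableFormatError(
                        f"{path}: gene table header is missing column(s) {missing}"
                    )
                header = fields
                col = {name: header.index(name) for name in header}
                header_checked = True
                continue
            try:
                if dialect == "tsv":
                    gene_id = fields[col["gene_id"]]
                    chrom = fields[col["chrom"]]
                    raw_start, raw_end = int(fields[col["start"]]), int(fields[col["end"]])
                    if raw_start >= raw_end:
                        raise RecordValidationError(
                            f"{path}:{lineno}: gene {gene_id!r}: start ({raw_start}) "
                            f"must be < end ({raw_end})"
                        )
                    start = raw_start - 1  # 1-based inclusive -> half-open
                    end = raw_end
                    strand = fields[col["strand"]]
                    gc_cell = fields[col["gc_fraction"]] if "gc_fraction" in col and col["gc_fraction"] < len(fields) else ""
                    gc = float(gc_cell) if gc_cell.strip() else None
                    intron_cell = fields[col["intron_lengths"]] if "intron_lengths" in col and col["intron_lengths"] < len(fields) else ""
                    introns = _parse_introns(intron_cell)
                elif dialect == "bed":
                    if len(fields) < 6:
                        raise TableFormatError(
                            f"{path}:{lineno}: BED6 requires 6 columns, found {len(fields)}"
                        )
                    chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
                    start, end = int(start_s), int(end_s)
                    gc, introns = None, None
                else:  # gff-lite
                    if len(fields) < 9:
                        raise TableFormatError(
                            f"{path}:{lineno}: GFF requires 9 columns, found {len(fields)}"
                        )
                    chrom, _src, _type, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
                    start, end = int(start_s) - 1, int(end_s)
                    gene_id = ""
                    for kv in attrs.split(";"):
                        k, _, v = kv.strip().partition("=")
                        if k == "ID":
                            gene_id = v
                    if not gene_id:
                        raise TableFormatError(
                            f"{path}:{lineno}: GFF attributes lack an ID= key"
                        )
                    gc, introns = None, None
            except (IndexError, ValueError) as exc:
                if isinstance(exc, (TableFormatError, RecordValidationError)):
                    raise
                raise TableFormatError(f"{path}:{lineno}: cannot parse gene row: {exc}") from exc
            try:
                records.append(
                    GeneRecord(gene_id, chrom, start, end, strand, gc, introns)
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{lineno}: {exc}") from exc
    records.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return records


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write the package's TSV gene-table dialect (1-based inclusive)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_GENE_TSV_COLUMNS) + "\n")
        for g in genes:
            gc = "" if g.gc_fraction is None else repr(g.gc_fraction)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start + 1}\t{g.end}\t{g.strand}\t"
                f"{gc}\t{_format_introns(g.transcript_intron_lengths)}\n"
            )


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a gene x tissue TSV (header = tissue names, first column = gene id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: expression table has no tissue columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise RecordValidationError(f"{path}: duplicate gene id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise TableFormatError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"tissue {df.columns[j]!r}"
        )
    return ExpressionTable(
        gene_ids=[str(g) for g in df.index],
        tissue_names=[str(t) for t in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(Path(path), sep="\t", index_label="gene_id")


@dataclass(slots=True)
class ProbeCollapseReport:
    """Bookkeeping from probe-to-gene collapsing."""

    n_probes_in: int
    n_probes_used: int
    n_dropped_unmapped: int
    n_dropped_ambiguous: int
    gene_probe_variance: pd.Series  # mean across-tissue variance among a gene's probes


def collapse_probes(
    probe_values: pd.DataFrame, probe_map: pd.DataFrame
) -> tuple[ExpressionTable, ProbeCollapseReport]:
    """Average probe-level expression into one row per gene.

    ``probe_values`` is probes x tissues; ``probe_map`` has columns
    ``probe_id`` and ``gene_id``.  Probes absent from the map are dropped
    (unmapped); probes mapped to more than one distinct gene are dropped
    (ambiguous); an exactly duplicated (probe, gene) row is an error.
    Per gene and tissue, the retained probes' values are averaged.
    """
    for c in ("probe_id", "gene_id"):
        if c not in probe_map.columns:
            raise TableFormatError(f"probe map is missing column {c!r}")
    pm = probe_map[["probe_id", "gene_id"]].astype(str)
    if pm.duplicated().any():
        row = pm[pm.duplicated()].iloc[0]
        raise RecordValidationError(
            f"duplicate probe-map row probe {row.probe_id!r} -> gene {row.gene_id!r}"
        )
    counts = pm.groupby("probe_id")["gene_id"].nunique()
    ambiguous = set(counts.index[counts > 1])
    mapping = {
        p: g for p, g in zip(pm.probe_id, pm.gene_id) if p not in ambiguous
    }
    probes = [str(p) for p in probe_values.index]
    used = [p for p in probes if p in mapping]
    n_unmapped = sum(1 for p in probes if p not in mapping and p not in ambiguous)
    n_ambiguous = sum(1 for p in probes if p in ambiguous)
    if not used:
        raise TableFormatError("no probe in the expression matrix maps to a gene")
    sub = probe_values.loc[used].astype(float)
    gene_of = pd.Series([mapping[p] for p in used], index=sub.index, name="gene_id")
    grouped = sub.groupby(gene_of)
    means = grouped.mean()
    variance = grouped.var(ddof=1).mean(axis=1)  # NaN for single-probe genes
    table = ExpressionTable(
        gene_ids=[str(g) for g in means.index],
        tissue_names=[str(t) for t in means.columns],
        values=means.to_numpy(dtype=float),
    )
    report = ProbeCollapseReport(
        n_probes_in=len(probes),
        n_probes_used=len(used),
        n_dropped_unmapped=n_unmapped,
        n_dropped_ambiguous=n_ambiguous,
        gene_probe_variance=variance,
    )
    return table, report


# ---------------------------------------------------------------------------
# synteny blocks and homolog pairs
# ---------------------------------------------------------------------------

_SYNTENY_COLUMNS = [
    "block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "orientation",
]


def read_synteny(path: str | Path) -> list[SyntenyBlock]:
    """Read a synteny-block TSV (1-based inclusive spans on both genomes)."""
    path = Path(path)
    blocks: list[SyntenyBlock] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _SYNTENY_COLUMNS if c not in header]
        if missing:
            raise TableFormatError(f"{path}: synteny table missing column(s) {missing}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                blocks.append(
                    SyntenyBlock(
                        block_id=f[col["block_id"]],
                        chrom_a=f[col["chrom_a"]],
                        start_a=int(f[col["start_a"]]) - 1,
                        end_a=int(f[col["end_a"]]),
                        chrom_b=f[col["chrom_b"]],
                        start_b=int(f[col["start_b"]]) - 1,
                        end_b=int(f[col["end_b"]]),
                        orientation=f[col["orientation"]],
                    )
                )
            except (IndexError, ValueError) as exc:
                raise TableFormatError(f"{path}:{lineno}: cannot parse synteny row: {exc}") from exc
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{lineno}: {exc}") from exc
    return blocks


def write_synteny(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_SYNTENY_COLUMNS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.chrom_a}\t{b.start_a + 1}\t{b.end_a}\t"
                f"{b.chrom_b}\t{b.start_b + 1}\t{b.end_b}\t{b.orientation}\n"
            )


def read_homologs(path: str | Path) -> list[HomologPair]:
    path = Path(path)
    pairs: list[HomologPair] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id_a", "gene_id_b"]:
            raise TableFormatError(
                f"{path}: homolog table must start with columns gene_id_a, gene_id_b"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")[:2]
            pairs.append(HomologPair(a, b))
    validate_homolog_pairs(pairs)
    return pairs


def write_homologs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id_a\tgene_id_b\n")
        for p in pairs:
            fh.write(f"{p.gene_id_a}\t{p.gene_id_b}\n")
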