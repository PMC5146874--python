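"""Readers and writers for the standard formats the pipeline touches.

Coordinates are normalized on read to the GFF3 convention: 1-based, inclusive
on both ends. BED input (0-based, half-open) is converted; the two encodings
of the same interval therefore yield identical :class:`GeneRecord` objects.
The transcriptional start site (TSS) is derived from the strand: the 5' end
of the gene feature (``start`` on +, ``end`` on −).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "DEGeneTable",
    "ParseError",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_de_table",
    "write_de_table",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: location plus the derived TSS.

    ``start``/``end`` are 1-based inclusive; ``tss`` equals ``start`` on the
    + strand and ``end`` on the − strand.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1")

    @property
    def tss(self) -> int:
        """1-based position of the transcriptional start site."""
        return self.start if self.strand == "+" else self.end


@dataclass
class DEGeneTable:
    """A differential-expression gene list filtered at an FDR threshold.

    ``data`` holds one row per retained gene with columns
    ``gene_id, log2fc, fdr``; every retained row satisfies
    ``fdr <= threshold``.
    """

    data: pd.DataFrame
    tissue_label: str = ""
    threshold: float = 1e-4
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "fdr"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if self.data["gene_id"].duplicated().any():
            dups = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene_ids in DE table: {list(dups[:5])}")
        if len(self.data) and (self.data["fdr"] > self.threshold).any():
            raise ValueError("DE table contains rows above the FDR threshold")

    @property
    def gene_ids(self) -> list[str]:
        return self.data["gene_id"].tolist()

    @property
    def directions(self) -> dict[str, int]:
        """gene_id -> sign of log2fc (+1, −1, or 0)."""
        import numpy as np

        return dict(
            zip(self.data["gene_id"], np.sign(self.data["log2fc"]).astype(int))
        )

    def __len__(self) -> int:
        return len(self.data)


def _records_from_gff3(path: Path, feature_type: str) -> list[GeneRecord]:
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted types for bad lines
        raise ParseError(f"{path}: failed to parse as GFF3: {exc}") from exc
    records = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        if feat.strand not in ("+", "-"):
            logger.warning(
                "skipping %s: unknown strand %r", feat.id, feat.strand
            )
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        records.append(
            GeneRecord(gene_id, feat.seqid, feat.strand, feat.start, feat.end)
        )
    return records


def _records_from_bed(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}"
                )
            contig, start0, end0, name, _score, strand = fields[:6]
            try:
                start0, end0 = int(start0), int(end0)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: skipping %s, unknown strand %r",
                    path, lineno, name, strand,
                )
                continue
            # BED 0-based half-open -> 1-based inclusive
            records.append(GeneRecord(name, contig, strand, start0 + 1, end0))
    return records


def read_gene_annotation(
    annotation_file: str | Path, feature_type: str = "gene"
) -> list[GeneRecord]:
    """Read gene features from GFF3 or BED6 into :class:`GeneRecord` objects.

    The format is chosen by extension (``.bed`` for BED; anything else is
    treated as GFF3). Features with strand "." are skipped with a warning.
    Duplicate gene_ids raise, since gene_id keys every downstream table.
    """
    path = Path(annotation_file)
    if path.suffix.lower() == ".bed":
        records = _records_from_bed(path)
    else:
        records = _records_from_gff3(path, feature_type)
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1
    dups = [g for g, c in seen.items() if c > 1]
    if dups:
        raise ValueError(f"duplicate gene_ids in {path}: {dups[:5]}")
    return records


def write_gene_annotation(
    records: list[GeneRecord], out_file: str | Path, feature_type: str = "gene"
) -> None:
    """Write GeneRecords as a minimal GFF3 file (round-trips through
    :func:`read_gene_annotation`)."""
    with open(out_file, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                f"{rec.contig}\t.\t{feature_type}\t{rec.start}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\tID={rec.gene_id}\n"
            )


def read_de_table(
    tsv_file: str | Path,
    fdr_threshold: float = 1e-4,
    tissue_label: str = "",
) -> DEGeneTable:
    """Read a DE gene table (TSV: gene_id, log2fc, fdr), keeping rows with
    ``fdr <= fdr_threshold`` and logging the number dropped."""
    df = pd.read_csv(tsv_file, sep="\t", comment="#", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{tsv_file}: missing columns {sorted(missing)}")
    for col in ("log2fc", "fdr"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() and len(df):
            bad = df.loc[numeric.isna()].index[0]
            raise ParseError(f"{tsv_file}: non-numeric {col} at data row {bad}")
        df[col] = numeric
    if len(df) and ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ParseError(f"{tsv_file}: fdr outside [0, 1]")
    kept = df[df["fdr"] <= fdr_threshold].reset_index(drop=True)
    n_dropped = len(df) - len(kept)
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d rows above FDR %.3g",
            tsv_file, n_dropped, len(df), fdr_threshold,
        )
    if not len(kept):
        logger.warning("%s: no rows pass FDR %.3g", tsv_file, fdr_threshold)
    return DEGeneTable(
        data=kept,
        tissue_label=tissue_label,
        threshold=fdr_threshold,
        n_dropped=n_dropped,
    )


def write_de_table(table: DEGeneTable, out_file: str | Path) -> None:
    table.data.to_csv(out_file, sep="\t", index=False)


# Motif files are read into MotifSet objects; the parser lives next to the
# motif model but is part of this module's IO surface.
from .motifs import read_motif_file, write_motif_file  # noqa: E402

__all__ += ["read_motif_file", "write_motif_file"]
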