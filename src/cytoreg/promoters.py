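"""Strand-aware extraction of upstream promoter windows.

The promoter of a gene is the window of ``window`` bp strictly upstream of
its transcriptional start site (the TSS base itself is excluded): genomic
positions [tss−window, tss−1] on the + strand, and [tss+1, tss+window]
reverse-complemented on the − strand, so the returned sequence always reads
5'→3' toward the TSS on the gene's own strand. Windows are truncated at
contig boundaries and flagged, never silently dropped; soft-masked bases are
uppercased and N is retained (it never matches a k-mer).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from pyfaidx import Fasta

from .io_genomics import GeneRecord
from .motifs import revcomp

__all__ = ["PromoterSet", "extract_promoters", "write_promoter_fasta", "read_promoter_fasta"]


@dataclass
class PromoterSet:
    """Promoter sequences keyed by gene_id, with truncation flags."""

    sequences: dict[str, str]
    truncated: dict[str, bool]
    window: int

    def __post_init__(self) -> None:
        for gene_id, seq in self.sequences.items():
            if len(seq) > self.window:
                raise ValueError(
                    f"{gene_id}: promoter longer than window {self.window}"
                )
            if self.truncated[gene_id] != (len(seq) < self.window):
                raise ValueError(f"{gene_id}: inconsistent truncation flag")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


def extract_promoters(
    genome_fasta: str | Path,
    genes: list[GeneRecord],
    window: int = 1000,
    drop_truncated: bool = False,
) -> PromoterSet:
    """Extract upstream promoter windows for each gene from an indexed FASTA.

    Parameters
    ----------
    genome_fasta : path to the genome FASTA (a .fai index is created).
    genes : gene records whose contigs must all be present in the FASTA.
    window : promoter length in bp (default 1000 — the 1 kb region upstream
        of the TSS conventionally searched for regulatory motifs).
    drop_truncated : drop genes whose window hits a contig boundary instead
        of keeping the truncated sequence (default: keep).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    missing = sorted({g.gene_id for g in genes if g.contig not in fasta})
    if missing:
        raise ValueError(f"contigs missing from genome for genes: {missing[:10]}")

    sequences: dict[str, str] = {}
    truncated: dict[str, bool] = {}
    for gene in genes:
        contig_len = len(fasta[gene.contig])
        tss = gene.tss
        if not 1 <= tss <= contig_len:
            raise ValueError(
                f"{gene.gene_id}: TSS {tss} outside contig "
                f"{gene.contig} (length {contig_len})"
            )
        if gene.strand == "+":
            lo = max(1, tss - window)
            hi = tss - 1
            seq = str(fasta[gene.contig][lo - 1 : hi]) if hi >= lo else ""
        else:
            lo = tss + 1
            hi = min(contig_len, tss + window)
            seq = revcomp(str(fasta[gene.contig][lo - 1 : hi])) if hi >= lo else ""
        is_trunc = len(seq) < window
        if is_trunc and drop_truncated:
            continue
        sequences[gene.gene_id] = seq
        truncated[gene.gene_id] = is_trunc
    return PromoterSet(sequences=sequences, truncated=truncated, window=window)


def write_promoter_fasta(promoters: PromoterSet, out_file: str | Path) -> None:
    """Write promoters as FASTA with headers ``gene_id|window|truncated``."""
    with open(out_file, "w") as fh:
        for gene_id, seq in promoters.sequences.items():
            trunc = str(promoters.truncated[gene_id]).lower()
            fh.write(f">{gene_id}|{promoters.window}|{trunc}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_promoter_fasta(fasta_file: str | Path) -> PromoterSet:
    """Read a promoter FASTA written by :func:`write_promoter_fasta`."""
    sequences: dict[str, str] = {}
    truncated: dict[str, bool] = {}
    window = None
    gene_id = None
    chunks: list[str] = []
    with open(fasta_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if gene_id is not None:
                    sequences[gene_id] = "".join(chunks)
                gene_id, win, trunc = line[1:].split("|")
                window = int(win)
                truncated[gene_id] = trunc == "true"
                chunks = []
            else:
                chunks.append(line)
    if gene_id is not None:
        sequences[gene_id] = "".join(chunks)
    if window is None:
        raise ValueError(f"{fasta_file}: empty promoter FASTA")
    return PromoterSet(sequences=sequences, truncated=truncated, window=window)
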