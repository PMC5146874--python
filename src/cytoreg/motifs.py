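"""Fixed-length motif sets and exact-match promoter scanning.

A :class:`MotifSet` is a set of equal-length DNA words (k-mers), optionally
carrying binding scores such as protein-binding-microarray E-scores.
Scanning is exact substring matching — a promoter "has" the motif set when
any window of length k equals one of the k-mers (or, by default, the reverse
complement of one, since double-stranded binding assays do not fix an
orientation). Windows containing N never match.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "MotifSet",
    "MotifHitTable",
    "expand_degenerate",
    "revcomp",
    "scan_sequence",
    "scan_promoters",
    "build_pfm",
    "read_motif_file",
    "write_motif_file",
    "read_hit_table",
    "write_hit_table",
]

_BASES = "ACGT"


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return str(Seq(sequence).reverse_complement())


def expand_degenerate(pattern: str) -> set[str]:
    """Expand a bracket-degenerate pattern like ``AAGAT[T/C]TT`` into the
    Cartesian set of plain ACGT k-mers.

    Bracket groups list alternative single bases separated by ``/``.
    Nested or empty brackets, and symbols outside ACGT, raise ValueError.
    """
    choices: list[str] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            end = pattern.find("]", i)
            if end == -1:
                raise ValueError(f"unclosed bracket in {pattern!r}")
            group = pattern[i + 1 : end]
            if "[" in group:
                raise ValueError(f"nested brackets in {pattern!r}")
            alts = group.split("/")
            if not group or any(len(a) != 1 or a not in _BASES for a in alts):
                raise ValueError(f"bad bracket group [{group}] in {pattern!r}")
            choices.append(group.replace("/", ""))
            i = end + 1
        elif ch in _BASES:
            choices.append(ch)
            i += 1
        else:
            raise ValueError(f"non-ACGT symbol {ch!r} in {pattern!r}")
    if not choices:
        raise ValueError("empty pattern")
    return {"".join(p) for p in itertools.product(*choices)}


@dataclass
class MotifSet:
    """A named set of length-k DNA words with optional per-word scores."""

    name: str
    kmers: frozenset[str]
    scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.kmers = frozenset(self.kmers)
        lengths = {len(km) for km in self.kmers}
        if len(lengths) > 1:
            raise ValueError(f"mixed k-mer lengths {sorted(lengths)}")
        for km in self.kmers:
            if any(b not in _BASES for b in km):
                raise ValueError(f"non-ACGT k-mer {km!r}")
        if self.scores is not None:
            missing = self.kmers - set(self.scores)
            if missing:
                raise ValueError(f"scores missing for {sorted(missing)[:3]}")

    @property
    def k(self) -> int:
        if not self.kmers:
            return 0
        return len(next(iter(self.kmers)))

    def __len__(self) -> int:
        return len(self.kmers)

    def with_reverse_complements(self) -> frozenset[str]:
        """The k-mers unioned with their reverse complements."""
        return self.kmers | {revcomp(km) for km in self.kmers}


@dataclass
class MotifHitTable:
    """Per-gene motif occurrence counts; ``has_hit`` ⇔ count ≥ 1."""

    counts: dict[str, int]

    def has_hit(self, gene_id: str) -> bool:
        return self.counts[gene_id] >= 1

    @property
    def hit_genes(self) -> set[str]:
        return {g for g, c in self.counts.items() if c >= 1}

    def __len__(self) -> int:
        return len(self.counts)


def scan_sequence(
    sequence: str, motifset: MotifSet, both_strands: bool = True
) -> int:
    """Count (possibly overlapping) exact occurrences of the motif set.

    With ``both_strands`` a window also matches when it equals the reverse
    complement of a k-mer; a palindromic match is counted once per position.
    Empty sequences, empty sets, or k > len(sequence) give 0.
    """
    k = motifset.k
    if k == 0 or len(sequence) < k:
        return 0
    words = (
        motifset.with_reverse_complements() if both_strands else motifset.kmers
    )
    seq = sequence.upper()
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in words)


def scan_promoters(
    promoters, motifset: MotifSet, both_strands: bool = True
) -> MotifHitTable:
    """Scan every promoter in a PromoterSet (or gene_id → sequence mapping)."""
    if hasattr(promoters, "sequences"):
        items = promoters.sequences.items()
    else:
        items = promoters.items()
    counts = {
        gene_id: scan_sequence(seq, motifset, both_strands)
        for gene_id, seq in items
    }
    if not counts:
        raise ValueError("no promoters to scan")
    return MotifHitTable(counts)


def build_pfm(
    kmers,
    weights: dict[str, float] | None = None,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Position frequency matrix (4 rows A,C,G,T × k columns; columns sum
    to 1) from equal-length k-mers with optional nonnegative weights."""
    kmers = sorted(set(kmers))
    if not kmers:
        raise ValueError("no k-mers")
    k = len(kmers[0])
    if any(len(km) != k for km in kmers):
        raise ValueError("mixed k-mer lengths")
    if weights is None:
        weights = {km: 1.0 for km in kmers}
    w = np.array([weights[km] for km in kmers], dtype=float)
    if (w < 0).any():
        raise ValueError("negative weights")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weights")
    pfm = np.full((4, k), pseudocount, dtype=float)
    for km, wi in zip(kmers, w):
        for j, base in enumerate(km):
            pfm[_BASES.index(base), j] += wi
    return pfm / (4 * pseudocount + total)


def read_motif_file(text_file: str | Path, name: str | None = None) -> MotifSet:
    """Read a motif file: one k-mer or degenerate pattern per line, with an
    optional tab-separated score. Degenerate patterns are expanded; a score
    on a degenerate line applies to every expansion."""
    path = Path(text_file)
    kmers: set[str] = set()
    scores: dict[str, float] = {}
    any_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            pattern = parts[0].strip().upper()
            try:
                expanded = expand_degenerate(pattern)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            kmers |= expanded
            if len(parts) > 1 and parts[1].strip():
                any_score = True
                score = float(parts[1])
                for km in expanded:
                    scores[km] = score
    if not kmers:
        raise ValueError(f"{path}: no k-mers")
    lengths = {len(km) for km in kmers}
    if len(lengths) > 1:
        raise ValueError(f"{path}: mixed k-mer lengths {sorted(lengths)}")
    return MotifSet(
        name=name or path.stem,
        kmers=frozenset(kmers),
        scores=scores if any_score else None,
    )


def write_motif_file(motifset: MotifSet, out_file: str | Path) -> None:
    with open(out_file, "w") as fh:
        for km in sorted(motifset.kmers):
            if motifset.scores is not None:
                fh.write(f"{km}\t{motifset.scores[km]}\n")
            else:
                fh.write(f"{km}\n")


def read_hit_table(tsv_file: str | Path) -> MotifHitTable:
    counts: dict[str, int] = {}
    with open(tsv_file) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, count, _has_hit = line.rstrip("\n").split("\t")
            counts[gene_id] = int(count)
    if not counts:
        raise ValueError(f"{tsv_file}: empty hit table")
    return MotifHitTable(counts)


def write_hit_table(table: MotifHitTable, out_file: str | Path) -> None:
    with open(out_file, "w") as fh:
        fh.write("gene_id\tcount\thas_hit\n")
        for gene_id in sorted(table.counts):
            c = table.counts[gene_id]
            fh.write(f"{gene_id}\t{c}\t{str(c >= 1).lower()}\n")
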