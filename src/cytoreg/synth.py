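"""Synthetic inputs with known ground truth for every pipeline stage.

Everything here is a pure function of its parameters and a seed, so any
downstream result can be checked against the planted truth:

* toy genomes (FASTA + GFF3) with genes laid out so each has a full,
  non-overlapping upstream promoter window;
* promoters rewritten to carry a motif with exact per-gene probabilities —
  background promoter sequence is rejection-sampled until it is motif-free
  on both strands, so the planting probability is exact, not approximate;
* a sequence-free variant that plants per-gene hit booleans directly, for
  large-scale statistical checks of the resampling test;
* nCounter panels with additive nonspecific background, known per-lane
  scale factors, a positive-control concentration ladder, and multiplicative
  log-normal noise;
* paired log2 fold-change vectors with a target correlation.

Default design parameters mirror the study the pipeline targets: a
6-positive / 8-negative / 3-reference control layout with three treated and
three control lanes, a 1 kb promoter window, and motif-presence
probabilities of 0.22 (background) vs 0.278 (focal set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneUniverse
from .io_genomics import GeneRecord
from .motifs import MotifSet, revcomp, scan_sequence
from .nanostring import NanoStringPanel

__all__ = [
    "make_toy_genome",
    "write_genome_fasta",
    "plant_motifs",
    "simulate_hit_universe",
    "simulate_nanostring_panel",
    "simulate_paired_foldchanges",
    "PANEL_POSITIVE_LADDER",
]

_BASES = np.array(list("ACGT"))

# Known input amounts (fM) of the six positive-control spike-ins, the
# standard four-fold dilution ladder.
PANEL_POSITIVE_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_toy_genome(
    n_genes: int,
    n_contigs: int = 2,
    window: int = 1000,
    gene_length: int = 120,
    spacer: int = 30,
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneRecord]]:
    """Random ACGT contigs with genes on alternating strands, each with a
    full ``window`` bp of upstream clearance and non-overlapping promoters.

    Returns (contig_id → sequence, GeneRecords). Deterministic given seed.
    """
    if n_contigs < 1:
        raise ValueError("need >= 1 contig")
    rng = np.random.default_rng(seed)
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1
    slot = window + gene_length + spacer
    contigs: dict[str, str] = {}
    records: list[GeneRecord] = []
    gene_no = 0
    for ci, count in enumerate(per_contig):
        contig_id = f"contig{ci + 1}"
        length = max(slot * count + spacer, window + 1)
        contigs[contig_id] = _random_dna(rng, length)
        for gi in range(count):
            strand = "+" if gene_no % 2 == 0 else "-"
            base = gi * slot + spacer
            if strand == "+":
                # promoter occupies [base+1, base+window]; gene follows
                start = base + window + 1
                end = start + gene_length - 1
            else:
                # gene first, promoter downstream in genomic coordinates
                start = base + 1
                end = start + gene_length - 1
            records.append(
                GeneRecord(f"g{gene_no + 1:05d}", contig_id, strand, start, end)
            )
            gene_no += 1
    return contigs, records


def write_genome_fasta(contigs: dict[str, str], out_file: str | Path) -> None:
    with open(out_file, "w") as fh:
        for contig_id, seq in contigs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _motif_free_window(
    rng: np.random.Generator,
    length: int,
    motifset: MotifSet,
    max_tries: int = 1000,
) -> str:
    for _ in range(max_tries):
        seq = _random_dna(rng, length)
        if scan_sequence(seq, motifset, both_strands=True) == 0:
            return seq
    raise RuntimeError(
        "could not sample a motif-free promoter window; the motif set covers "
        "too much of sequence space for this window length"
    )


def plant_motifs(
    contigs: dict[str, str],
    genes: list[GeneRecord],
    motifset: MotifSet,
    focal_set: set[str],
    p0: float = 0.22,
    p1: float = 0.278,
    window: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Rewrite each gene's promoter window so it carries >= 1 motif
    occurrence with probability ``p1`` (focal genes) or ``p0`` (background).

    Every promoter is first replaced by rejection-sampled motif-free
    sequence, making the planting probabilities exact; planted occurrences
    go at a uniform position on a uniform strand. Returns the modified
    contigs and a truth table (gene_id, focal, has_hit).
    """
    if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
        raise ValueError("p0 and p1 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = motifset.k
    if k == 0 or k > window:
        raise ValueError("motif length must be in [1, window]")
    kmers = sorted(motifset.kmers)
    arrays = {cid: list(seq) for cid, seq in contigs.items()}
    truth_rows = []
    for gene in genes:
        focal = gene.gene_id in focal_set
        p = p1 if focal else p0
        promoter = _motif_free_window(rng, window, motifset)
        has_hit = bool(rng.random() < p)
        if has_hit:
            pos = int(rng.integers(0, window - k + 1))
            kmer = kmers[rng.integers(0, len(kmers))]
            if rng.random() < 0.5:
                kmer = revcomp(kmer)
            promoter = promoter[:pos] + kmer + promoter[pos + k :]
        # write the promoter back in genomic orientation
        tss = gene.tss
        if gene.strand == "+":
            lo, hi = tss - window, tss - 1  # 1-based inclusive
            genomic = promoter
        else:
            lo, hi = tss + 1, tss + window
            genomic = revcomp(promoter)
        if lo < 1 or hi > len(arrays[gene.contig]):
            raise ValueError(
                f"{gene.gene_id}: promoter window outside contig; "
                "use a layout with upstream clearance"
            )
        arrays[gene.contig][lo - 1 : hi] = list(genomic)
        truth_rows.append((gene.gene_id, focal, has_hit))
    new_contigs = {cid: "".join(chars) for cid, chars in arrays.items()}
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "focal", "has_hit"])
    return new_contigs, truth


def simulate_hit_universe(
    n_genes: int,
    n_focal: int,
    p0: float = 0.22,
    p1: float = 0.278,
    seed: int = 0,
) -> tuple[GeneUniverse, list[str]]:
    """Sequence-free planting: per-gene has_hit booleans drawn directly
    (Bernoulli p1 for the first ``n_focal`` genes, p0 otherwise).

    Statistically identical to scanning promoters planted by
    :func:`plant_motifs`; used where the sequence layer would only add cost.
    Returns (universe, focal gene_ids).
    """
    if n_focal > n_genes:
        raise ValueError("n_focal > n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    probs = np.full(n_genes, p0)
    probs[:n_focal] = p1
    has_hit = rng.random(n_genes) < probs
    return GeneUniverse(gene_ids=gene_ids, has_hit=has_hit), gene_ids[:n_focal]


def simulate_nanostring_panel(
    n_endogenous: int = 30,
    n_replicates: int = 3,
    true_log2fc: np.ndarray | None = None,
    lane_factors: np.ndarray | None = None,
    sigma: float = 0.1,
    background_level: float = 4.0,
    reference_level: float = 800.0,
    baseline_range: tuple[float, float] = (500.0, 4000.0),
    positive_unit: float = 30.0,
    seed: int = 0,
) -> tuple[NanoStringPanel, dict]:
    """Simulate a raw nCounter panel with known truth.

    The count model for probe p in lane l is
    ``round(lane_factor_l * (background + signal_p,l * noise))`` with
    log-normal(0, sigma) noise per cell; the additive background term is
    what the negative controls measure. Endogenous signal is a per-gene
    baseline times ``2**true_log2fc`` in treated lanes; a true_log2fc of
    ``-inf`` (or a zero baseline) yields background-only counts, exercising
    the not-detected path. Positive controls follow the six-point
    concentration ladder; reference probes are condition-independent.

    Returns (panel, truth) where truth carries ``log2fc`` (per endogenous
    gene), ``lane_factors``, and ``baseline``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n_lanes = 2 * n_replicates
    lanes = [f"T{r + 1}" for r in range(n_replicates)] + [
        f"C{r + 1}" for r in range(n_replicates)
    ]
    condition = {l: ("treated" if l.startswith("T") else "control") for l in lanes}
    if lane_factors is None:
        lane_factors = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=n_lanes))
    lane_factors = np.asarray(lane_factors, dtype=float)
    if (lane_factors <= 0).any():
        raise ValueError("lane factors must be positive")
    if len(lane_factors) != n_lanes:
        raise ValueError("need one lane factor per lane")
    if true_log2fc is None:
        true_log2fc = rng.normal(0.0, 1.5, size=n_endogenous)
    true_log2fc = np.asarray(true_log2fc, dtype=float)
    if len(true_log2fc) != n_endogenous:
        raise ValueError("need one true log2fc per endogenous gene")

    baseline = np.exp(
        rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]),
                    size=n_endogenous)
    )

    def noise(shape) -> np.ndarray:
        if sigma == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, sigma, size=shape))

    probes, classes, rows = [], [], []

    endo_ids = [f"gene{i + 1:03d}" for i in range(n_endogenous)]
    effect = np.power(2.0, true_log2fc)  # -inf log2fc -> 0 signal
    for i, probe in enumerate(endo_ids):
        signal = np.array(
            [baseline[i] * (effect[i] if condition[l] == "treated" else 1.0)
             for l in lanes]
        )
        counts = lane_factors * (background_level * noise(n_lanes)
                                 + signal * noise(n_lanes))
        probes.append(probe)
        classes.append("endogenous")
        rows.append(counts)

    pos_ids = [f"POS_{chr(65 + i)}" for i in range(len(PANEL_POSITIVE_LADDER))]
    for probe, conc in zip(pos_ids, PANEL_POSITIVE_LADDER):
        counts = lane_factors * (background_level * noise(n_lanes)
                                 + positive_unit * conc * noise(n_lanes))
        probes.append(probe)
        classes.append("positive")
        rows.append(counts)

    for i in range(8):
        counts = lane_factors * background_level * noise(n_lanes)
        probes.append(f"NEG_{chr(65 + i)}")
        classes.append("negative")
        rows.append(counts)

    for i in range(3):
        counts = lane_factors * (background_level * noise(n_lanes)
                                 + reference_level * noise(n_lanes))
        probes.append(f"REF_{i + 1}")
        classes.append("reference")
        rows.append(counts)

    counts_df = pd.DataFrame(
        np.round(np.vstack(rows)).astype(np.int64), index=probes, columns=lanes
    )
    panel = NanoStringPanel(
        counts=counts_df,
        probe_class=pd.Series(classes, index=probes),
        lane_condition=condition,
        positive_conc=pd.Series(list(PANEL_POSITIVE_LADDER), index=pos_ids),
        lane_replicate={l: int(l[1:]) for l in lanes},
    )
    truth = {
        "log2fc": pd.Series(true_log2fc, index=endo_ids),
        "lane_factors": pd.Series(lane_factors, index=lanes),
        "baseline": pd.Series(baseline, index=endo_ids),
    }
    return panel, truth


def simulate_paired_foldchanges(
    n: int, rho: float, seed: int = 0, scale: float = 1.0
) -> pd.DataFrame:
    """Paired log2 fold changes from a bivariate normal with unit variances
    and correlation ``rho`` (optionally scaled)."""
    if not -1 <= rho <= 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    if abs(rho) == 1.0:  # singular covariance: perfectly (anti)correlated
        z = rng.standard_normal(n)
        draws = np.column_stack([z, math.copysign(1.0, rho) * z]) * scale
    else:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        draws = rng.multivariate_normal(
            [0.0, 0.0], cov, size=n, method="cholesky"
        ) * scale
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(n)],
            "log2fc_platform1": draws[:, 0],
            "log2fc_platform2": draws[:, 1],
        }
    )
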