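"""Monte-Carlo resampling test for motif presence in gene sets.

The question: is the fraction of genes in a focal set (say, the genes
up-regulated by a hormone) whose promoter contains a binding motif unusually
high or low? The test draws N random gene samples of the same size, without
replacement, from a universe of genes with a fixed per-gene "has the motif"
attribute, and reports the fraction of samples whose presence fraction is
strictly higher (enrichment) or strictly lower (depletion) than the observed
one; ties are tallied separately.

Because the per-gene attribute is fixed and sampling is without replacement,
the null number of motif-carrying genes in a sample is exactly
Hypergeometric(M, K, n); the closed-form tail probabilities are reported
alongside the Monte-Carlo estimates as a cross-check. The Monte-Carlo route
draws explicit index samples and never uses hypergeometric variates, so the
two routes are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .motifs import MotifHitTable

__all__ = [
    "GeneUniverse",
    "EnrichmentResult",
    "presence_fraction",
    "sample_null_hit_counts",
    "resampling_test",
    "enrichment_report",
    "write_enrichment_tsv",
    "write_histogram_tsv",
]


@dataclass
class GeneUniverse:
    """The sampling frame: an ordered gene list with per-gene hit booleans."""

    gene_ids: list[str]
    has_hit: np.ndarray  # bool, same length

    def __post_init__(self) -> None:
        self.has_hit = np.asarray(self.has_hit, dtype=bool)
        if len(self.gene_ids) != len(self.has_hit):
            raise ValueError("gene_ids and has_hit lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in universe")

    @classmethod
    def from_hit_table(cls, hit_table: MotifHitTable) -> "GeneUniverse":
        gene_ids = sorted(hit_table.counts)
        hits = np.array([hit_table.counts[g] >= 1 for g in gene_ids])
        return cls(gene_ids=gene_ids, has_hit=hits)

    @property
    def M(self) -> int:
        return len(self.gene_ids)

    @property
    def K(self) -> int:
        return int(self.has_hit.sum())


@dataclass
class EnrichmentResult:
    """Observed presence fraction plus the Monte-Carlo null summary.

    ``p_enriched`` (``p_depleted``) is the fraction of the N resamples whose
    presence fraction strictly exceeds (falls below) ``f_obs``; the
    conservative variants add one pseudo-sample: (r+1)/(N+1).
    ``p_exact_*`` are the matching hypergeometric tail probabilities.
    """

    set_label: str
    n: int
    f_obs: float
    N: int
    n_higher: int
    n_lower: int
    n_tied: int
    p_enriched: float
    p_depleted: float
    p_exact_enriched: float
    p_exact_depleted: float
    seed: int
    p_enriched_conservative: float = 0.0
    p_depleted_conservative: float = 0.0
    p_enriched_bh: float | None = None
    null_hit_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_higher + self.n_lower + self.n_tied != self.N:
            raise ValueError("n_higher + n_lower + n_tied must equal N")


def presence_fraction(gene_set, hit_table: MotifHitTable) -> float:
    """Fraction of the gene set whose promoter carries >= 1 motif."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    unknown = [g for g in genes if g not in hit_table.counts]
    if unknown:
        raise KeyError(f"genes missing from hit table: {unknown[:10]}")
    n_hit = sum(1 for g in genes if hit_table.counts[g] >= 1)
    return n_hit / len(genes)


def sample_null_hit_counts(
    has_hit: np.ndarray,
    n: int,
    N: int,
    rng: np.random.Generator,
    chunk_size: int = 256,
) -> np.ndarray:
    """Draw N without-replacement samples of n genes and count hits in each.

    Each sample is realized as the n smallest of M iid uniform keys
    (equivalent to a uniform random subset), in chunks to bound memory.
    """
    has_hit = np.asarray(has_hit, dtype=bool)
    M = len(has_hit)
    if not 1 <= n <= M:
        raise ValueError(f"need 1 <= n <= M, got n={n}, M={M}")
    if n == M:
        return np.full(N, has_hit.sum(), dtype=np.int64)
    hit_f = has_hit.astype(np.float64)
    out = np.empty(N, dtype=np.int64)
    done = 0
    while done < N:
        m = min(chunk_size, N - done)
        keys = rng.random((m, M))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        out[done : done + m] = hit_f[idx].sum(axis=1).round().astype(np.int64)
        done += m
    return out


def resampling_test(
    universe: GeneUniverse,
    n: int,
    f_obs: float,
    N: int = 1000,
    seed: int | None = None,
    set_label: str = "",
    keep_null: bool = True,
) -> EnrichmentResult:
    """Monte-Carlo enrichment/depletion test against equal-size resamples.

    Draws N samples of n genes without replacement from the full universe
    (focal genes are not excluded) and compares each sample's presence
    fraction to ``f_obs`` with strict inequalities. Closed-form
    hypergeometric tails are attached as a cross-check: with X ~
    Hypergeometric(M, K, n), ``p_exact_enriched`` = P(X > n·f_obs) and
    ``p_exact_depleted`` = P(X < n·f_obs).
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    M, K = universe.M, universe.K
    if not 1 <= n <= M:
        raise ValueError(f"need 1 <= n <= M, got n={n}, M={M}")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    rng = np.random.default_rng(seed)

    null_counts = sample_null_hit_counts(universe.has_hit, n, N, rng)
    # Compare in hit-count units to avoid float-division tie ambiguity.
    obs_count = f_obs * n
    n_higher = int((null_counts > obs_count + 1e-9).sum())
    n_lower = int((null_counts < obs_count - 1e-9).sum())
    n_tied = N - n_higher - n_lower

    k_obs = int(round(obs_count))
    if abs(obs_count - k_obs) < 1e-9:
        p_exact_enr = float(hypergeom.sf(k_obs, M, K, n))
        p_exact_dep = float(hypergeom.cdf(k_obs - 1, M, K, n))
    else:  # f_obs not attainable as a count of n: no ties possible
        p_exact_enr = float(hypergeom.sf(np.floor(obs_count), M, K, n))
        p_exact_dep = float(hypergeom.cdf(np.ceil(obs_count) - 1, M, K, n))

    return EnrichmentResult(
        set_label=set_label,
        n=n,
        f_obs=f_obs,
        N=N,
        n_higher=n_higher,
        n_lower=n_lower,
        n_tied=n_tied,
        p_enriched=n_higher / N,
        p_depleted=n_lower / N,
        p_exact_enriched=p_exact_enr,
        p_exact_depleted=p_exact_dep,
        seed=seed,
        p_enriched_conservative=(n_higher + 1) / (N + 1),
        p_depleted_conservative=(n_lower + 1) / (N + 1),
        null_hit_counts=null_counts if keep_null else None,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrichment_report(
    universe: GeneUniverse,
    hit_table: MotifHitTable,
    de_tables,
    N: int = 1000,
    seed: int | None = None,
    split_by_direction: bool = True,
) -> list[EnrichmentResult]:
    """Run the resampling test for each DE gene set (split up/down when the
    table carries directions) and append BH-adjusted enrichment p-values.

    Raw empirical p-values remain the primary output; the adjusted column
    only matters when many motif-set × gene-set combinations are tested at
    once.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    universe_set = set(universe.gene_ids)
    gene_sets: list[tuple[str, list[str]]] = []
    for table in de_tables:
        label = table.tissue_label or "de"
        if split_by_direction:
            dirs = table.directions
            up = [g for g, s in dirs.items() if s > 0]
            down = [g for g, s in dirs.items() if s < 0]
            if up:
                gene_sets.append((f"{label}:up", up))
            if down:
                gene_sets.append((f"{label}:down", down))
        else:
            gene_sets.append((label, table.gene_ids))

    results = []
    for i, (label, genes) in enumerate(gene_sets):
        outside = [g for g in genes if g not in universe_set]
        if outside:
            raise KeyError(
                f"{label}: genes not in universe: {outside[:10]}"
            )
        f_obs = presence_fraction(genes, hit_table)
        results.append(
            resampling_test(
                universe, len(genes), f_obs, N=N, seed=seed + i,
                set_label=label,
            )
        )
    if results:
        adjusted = _bh_adjust(np.array([r.p_enriched for r in results]))
        for res, adj in zip(results, adjusted):
            res.p_enriched_bh = float(adj)
    return results


_TSV_COLUMNS = [
    "set_label", "n", "f_obs", "N", "n_higher", "n_lower", "n_tied",
    "p_enriched", "p_depleted", "p_exact_enriched", "p_exact_depleted",
    "p_enriched_conservative", "p_depleted_conservative", "p_enriched_bh",
    "seed",
]


def write_enrichment_tsv(
    results: list[EnrichmentResult], out_file: str | Path, header_comment: str = ""
) -> None:
    with open(out_file, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in results:
            row = [getattr(r, c) for c in _TSV_COLUMNS]
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_histogram_tsv(
    result: EnrichmentResult, out_file: str | Path, n_bins: int = 30
) -> None:
    """Null presence-fraction histogram (bin_left, bin_right, count) for the
    enrichment figure; requires the result to retain its null samples."""
    if result.null_hit_counts is None:
        raise ValueError("result does not retain null samples")
    fracs = result.null_hit_counts / result.n
    counts, edges = np.histogram(fracs, bins=n_bins)
    with open(out_file, "w") as fh:
        fh.write(f"# set_label={result.set_label} f_obs={result.f_obs} "
                 f"N={result.N} seed={result.seed}\n")
        fh.write("bin_left\tbin_right\tcount\n")
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{left:.6g}\t{right:.6g}\t{count}\n")
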