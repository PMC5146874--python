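"""Cross-platform fold-change concordance and gene-set overlap analyses.

`platform_concordance` quantifies how well two expression platforms (e.g.
RNA-Seq and an nCounter validation panel) agree on per-gene log2 fold
changes: Pearson r, the least-squares line, R², and the fraction of pairs
with matching sign. `set_overlap` intersects two directional DE gene sets
and splits the intersection into same-direction and opposite-direction
genes. `ortholog_concordance` carries a direction comparison across species
through a (possibly many-to-many) ortholog map.

The package ships a small published validation dataset —
``data/nanostring_rnaseq_log2fc.tsv``, per-gene log2 fold changes for a rice
cytokinin-response panel measured by both RNA-Seq and NanoString nCounter in
roots and shoots, with "nd"/"ND" marking probes below the detection
background and "-" marking genes not significant on the RNA-Seq side —
loadable via :func:`load_validation_table` as a desk-check input.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceReport",
    "OverlapReport",
    "platform_concordance",
    "set_overlap",
    "ortholog_concordance",
    "load_validation_table",
    "read_paired_table",
]

ND_CODES = {"nd", "ND", "nd-treated", "nd-control"}


@dataclass
class ConcordanceReport:
    n_pairs: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    sign_concordance: float
    excluded_nd: int

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need >= 2 pairs")


@dataclass
class OverlapReport:
    size_a: int
    size_b: int
    n_intersection: int
    n_same_direction: int
    n_opposite: int
    p_hypergeom: float | None = None

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.size_a, self.size_b):
            raise ValueError("intersection larger than a set")


def _coerce_pair_columns(
    paired: pd.DataFrame, col_a: str, col_b: str, nd_policy: str
) -> tuple[np.ndarray, np.ndarray, int]:
    a = pd.to_numeric(paired[col_a], errors="coerce")
    b = pd.to_numeric(paired[col_b], errors="coerce")
    is_nd_a = paired[col_a].astype(str).isin(ND_CODES)
    is_nd_b = paired[col_b].astype(str).isin(ND_CODES)
    if nd_policy == "zero":
        a = a.where(~is_nd_a, 0.0)
        b = b.where(~is_nd_b, 0.0)
        excluded_nd = 0
    elif nd_policy == "exclude":
        excluded_nd = int(((is_nd_a | is_nd_b) & ~(a.isna() & ~is_nd_a)
                           & ~(b.isna() & ~is_nd_b)).sum())
    else:
        raise ValueError(f"nd_policy must be 'exclude' or 'zero', got {nd_policy!r}")
    keep = a.notna() & b.notna()
    return a[keep].to_numpy(float), b[keep].to_numpy(float), excluded_nd


def platform_concordance(
    paired: pd.DataFrame,
    col_a: str = "log2fc_platform1",
    col_b: str = "log2fc_platform2",
    nd_policy: str = "exclude",
) -> ConcordanceReport:
    """Concordance statistics between two log2 fold-change columns.

    ``nd_policy`` governs not-detected codes ("nd"/"ND") in either column:
    ``exclude`` drops the pair (default), ``zero`` treats the code as a
    fold change of 0. Non-significant markers ("-", blank) always drop the
    pair.
    """
    x, y, excluded_nd = _coerce_pair_columns(paired, col_a, col_b, nd_policy)
    if len(x) < 2:
        raise ValueError(f"need >= 2 complete pairs, got {len(x)}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a fold-change vector")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    signs = np.sign(x) * np.sign(y)
    nonzero = signs != 0
    sign_concordance = float((signs[nonzero] > 0).mean()) if nonzero.any() else 0.0
    return ConcordanceReport(
        n_pairs=len(x),
        pearson_r=r,
        r_squared=r * r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        sign_concordance=sign_concordance,
        excluded_nd=excluded_nd,
    )


def set_overlap(
    directions_a: dict[str, int],
    directions_b: dict[str, int],
    universe_size: int | None = None,
) -> OverlapReport:
    """Intersect two directional gene sets (gene_id → sign of log2FC).

    Genes with direction 0 participate in the intersection but in neither
    the same- nor opposite-direction count. With ``universe_size`` a
    hypergeometric upper-tail p-value for the intersection size is attached.
    """
    inter = set(directions_a) & set(directions_b)
    same = sum(
        1 for g in inter
        if directions_a[g] != 0 and directions_a[g] == directions_b[g]
    )
    opposite = sum(
        1 for g in inter
        if directions_a[g] != 0 and directions_b[g] != 0
        and directions_a[g] != directions_b[g]
    )
    p = None
    if universe_size is not None:
        if universe_size < max(len(directions_a), len(directions_b)):
            raise ValueError("universe smaller than a gene set")
        p = float(
            stats.hypergeom.sf(
                len(inter) - 1, universe_size, len(directions_a), len(directions_b)
            )
        )
    return OverlapReport(
        size_a=len(directions_a),
        size_b=len(directions_b),
        n_intersection=len(inter),
        n_same_direction=same,
        n_opposite=opposite,
        p_hypergeom=p,
    )


def ortholog_concordance(
    ortholog_map: dict[str, list[str]] | pd.DataFrame,
    directions_source: dict[str, int],
    directions_target: dict[str, int],
) -> dict[str, float]:
    """Direction concordance of a source-species DE list carried through an
    ortholog map into a target-species DE list.

    The denominator is source genes with at least one mapped ortholog. A
    source gene is *same-direction* if any ortholog is DE with matching
    sign; else *opposite* if any ortholog is DE with opposing sign; else
    *not-DE* (precedence: same > opposite > not-DE). Source genes absent
    from ``directions_source`` or with direction 0 cannot match a sign and
    fall into not-DE.
    """
    if isinstance(ortholog_map, pd.DataFrame):
        grouped: dict[str, list[str]] = {}
        for a, b in ortholog_map.itertuples(index=False):
            grouped.setdefault(str(a), []).append(str(b))
        ortholog_map = grouped
    if not ortholog_map:
        raise ValueError("empty ortholog map")

    n_with, n_same, n_opp, n_not = 0, 0, 0, 0
    for source, targets in ortholog_map.items():
        if not targets:
            continue
        n_with += 1
        src_dir = directions_source.get(source, 0)
        target_dirs = [
            directions_target[t] for t in targets if t in directions_target
        ]
        if src_dir != 0 and any(d == src_dir for d in target_dirs):
            n_same += 1
        elif src_dir != 0 and any(d == -src_dir for d in target_dirs if d != 0):
            n_opp += 1
        else:
            n_not += 1
    if n_with == 0:
        raise ValueError("no source gene has a mapped ortholog")
    return {
        "n_source": len(ortholog_map),
        "n_with_ortholog": n_with,
        "frac_with_ortholog": n_with / len(ortholog_map),
        "frac_same_direction": n_same / n_with,
        "frac_opposite_direction": n_opp / n_with,
        "frac_not_de": n_not / n_with,
    }


def read_paired_table(tsv_file: str | Path) -> pd.DataFrame:
    """Read a paired fold-change TSV (gene_id, log2fc_platform1,
    log2fc_platform2[, tissue]) keeping nd codes as strings."""
    return pd.read_csv(tsv_file, sep="\t", comment="#", dtype=str)


def load_validation_table() -> pd.DataFrame:
    """The bundled published RNA-Seq vs nCounter validation fold changes.

    Columns: gene_id, description, root_rnaseq, root_nano, shoot_rnaseq,
    shoot_nano. Values are log2 fold changes as printed; "-" means not
    significant by RNA-Seq in that tissue, "nd"/"ND" mark nCounter probes
    below the detection background in the treated sample / in both samples.
    """
    ref = resources.files("cytoreg.data") / "nanostring_rnaseq_log2fc.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
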