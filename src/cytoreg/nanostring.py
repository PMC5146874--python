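"""nCounter digital-count normalization and fold-change computation.

The normalization chain, per lane (one hybridization reaction):

1. **Background**: threshold B = mean + 2·SD (sample SD, n−1) of the eight
   negative-control probes; raw counts at or below B become *not detected*
   (no flooring to small positive values).
2. **Positive-control (standard-curve) scaling**: each lane is scaled by
   s_pos = (across-lane mean of per-lane positive-control geometric means) /
   (this lane's geometric mean), equalizing assay efficiency. A per-lane
   linear fit of log2 counts against log2 known input amounts is reported as
   QC (slope, R²) but not used for scaling.
3. **Reference-gene scaling**: the same geometric-mean construction over the
   housekeeping (reference) probes, applied after positive scaling, absorbs
   RNA-input differences.

A normalized value is ((raw − B) · s_pos · s_ref) when raw > B, else the
cell is flagged not detected. Per-gene log2 fold changes between conditions
use detected replicates only; genes with no detected replicate in the
treated condition are coded ``nd-treated``, in the control condition
``nd-control``, and in both ``ND``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "NanoStringPanel",
    "NormalizedPanel",
    "background_threshold",
    "subtract_background",
    "positive_control_scale",
    "reference_gene_scale",
    "normalize_panel",
    "nanostring_log2fc",
    "read_panel",
    "write_normalized_tsv",
    "write_qc_tsv",
]

PROBE_CLASSES = ("endogenous", "positive", "negative", "reference")


@dataclass
class NanoStringPanel:
    """Raw probe × lane counts with probe-class and lane metadata."""

    counts: pd.DataFrame                 # probes × lanes, nonnegative
    probe_class: pd.Series               # probe -> class
    lane_condition: dict[str, str]       # lane -> {"treated", "control"}
    positive_conc: pd.Series | None = None   # positive probe -> known amount
    lane_replicate: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        missing = set(self.counts.index) - set(self.probe_class.index)
        if missing:
            raise ValueError(f"probes without class: {sorted(missing)[:5]}")
        if len(self.probes_of("negative")) < 2:
            raise ValueError("need >= 2 negative-control probes")
        if len(self.probes_of("positive")) < 1:
            raise ValueError("need >= 1 positive-control probe")
        if len(self.probes_of("reference")) < 1:
            raise ValueError("need >= 1 reference probe")
        extra = set(self.counts.columns) - set(self.lane_condition)
        if extra:
            raise ValueError(f"lanes without condition: {sorted(extra)}")

    def probes_of(self, probe_class: str) -> list[str]:
        return [p for p in self.counts.index if self.probe_class[p] == probe_class]

    def lanes_of(self, condition: str) -> list[str]:
        return [l for l in self.counts.columns if self.lane_condition[l] == condition]


@dataclass
class NormalizedPanel:
    """Endogenous probe × lane normalized values (NaN = not detected) with
    the per-lane normalization parameters and standard-curve QC."""

    values: pd.DataFrame
    detected: pd.DataFrame
    background: pd.Series     # B per lane
    s_pos: pd.Series
    s_ref: pd.Series
    qc: pd.DataFrame          # per-lane standard-curve slope / r_squared
    lane_condition: dict[str, str]


def _geomean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.log(values).mean()))


def background_threshold(panel: NanoStringPanel, lane: str) -> float:
    """Detection threshold for one lane: mean + 2·sample-SD of negatives."""
    neg = panel.counts.loc[panel.probes_of("negative"), lane].to_numpy(float)
    if len(neg) < 2:
        raise ValueError("need >= 2 negative probes for a background SD")
    return float(neg.mean() + 2.0 * neg.std(ddof=1))


def subtract_background(
    panel: NanoStringPanel,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Background-corrected counts (NaN where raw <= B) for all probes.

    Returns (corrected, detected mask, per-lane B).
    """
    B = pd.Series(
        {lane: background_threshold(panel, lane) for lane in panel.counts.columns}
    )
    raw = panel.counts.astype(float)
    detected = raw.gt(B, axis=1)
    corrected = (raw.sub(B, axis=1)).where(detected)
    return corrected, detected, B


def positive_control_scale(panel: NanoStringPanel) -> pd.Series:
    """Per-lane scale factor from the positive-control geometric means."""
    pos = panel.counts.loc[panel.probes_of("positive")].astype(float)
    if (pos.values <= 0).any():
        raise ValueError("zero/negative positive-control count")
    lane_gm = pos.apply(lambda col: _geomean(col.to_numpy()), axis=0)
    return lane_gm.mean() / lane_gm


def reference_gene_scale(
    corrected: pd.DataFrame,
    s_pos: pd.Series,
    panel: NanoStringPanel,
) -> pd.Series:
    """Per-lane reference scale from background-corrected, positive-scaled
    reference probes; every reference probe must be detected in every lane."""
    ref = corrected.loc[panel.probes_of("reference")]
    if ref.isna().any().any():
        bad = [
            (probe, lane)
            for probe in ref.index
            for lane in ref.columns
            if pd.isna(ref.at[probe, lane])
        ]
        raise ValueError(f"reference probe(s) not detected: {bad[:5]}")
    scaled = ref.mul(s_pos, axis=1)
    lane_gm = scaled.apply(lambda col: _geomean(col.to_numpy()), axis=0)
    return lane_gm.mean() / lane_gm


def _standard_curve_qc(panel: NanoStringPanel) -> pd.DataFrame:
    """Per-lane linear fit of log2 positive counts vs log2 known amounts."""
    pos_probes = panel.probes_of("positive")
    rows = {}
    if panel.positive_conc is None or len(pos_probes) < 2:
        for lane in panel.counts.columns:
            rows[lane] = {"slope": np.nan, "r_squared": np.nan}
        return pd.DataFrame.from_dict(rows, orient="index")
    x = np.log2(panel.positive_conc.loc[pos_probes].to_numpy(float))
    for lane in panel.counts.columns:
        y = np.log2(panel.counts.loc[pos_probes, lane].to_numpy(float))
        fit = linregress(x, y)
        rows[lane] = {"slope": fit.slope, "r_squared": fit.rvalue**2}
    return pd.DataFrame.from_dict(rows, orient="index")


def normalize_panel(panel: NanoStringPanel) -> NormalizedPanel:
    """Run the full chain: background → positive scaling → reference scaling.

    Only endogenous probes appear in the output values; controls inform the
    per-lane parameters.
    """
    corrected, detected, B = subtract_background(panel)
    s_pos = positive_control_scale(panel)
    s_ref = reference_gene_scale(corrected, s_pos, panel)
    endo = panel.probes_of("endogenous")
    values = corrected.loc[endo].mul(s_pos * s_ref, axis=1)
    return NormalizedPanel(
        values=values,
        detected=detected.loc[endo],
        background=B,
        s_pos=s_pos,
        s_ref=s_ref,
        qc=_standard_curve_qc(panel),
        lane_condition=dict(panel.lane_condition),
    )


def nanostring_log2fc(
    normalized: NormalizedPanel,
    treated_lanes: list[str] | None = None,
    control_lanes: list[str] | None = None,
    mean_of_ratios: bool = False,
) -> pd.DataFrame:
    """Per-gene log2 fold change (treated vs control) from detected replicates.

    Default is log2 of the ratio of condition means of detected values;
    ``mean_of_ratios`` instead averages per-replicate log2 values and
    differences the condition averages (only defined when both conditions
    have detected replicates). Output columns: ``log2fc`` (NaN when coded)
    and ``code`` in {"ok", "nd-treated", "nd-control", "ND"}.
    """
    lanes = list(normalized.values.columns)
    if treated_lanes is None:
        treated_lanes = [l for l in lanes if normalized.lane_condition[l] == "treated"]
    if control_lanes is None:
        control_lanes = [l for l in lanes if normalized.lane_condition[l] == "control"]
    if not treated_lanes or not control_lanes:
        raise ValueError("both conditions need at least one lane")

    rows = []
    for gene in normalized.values.index:
        t = normalized.values.loc[gene, treated_lanes].dropna()
        c = normalized.values.loc[gene, control_lanes].dropna()
        if t.empty and c.empty:
            rows.append((gene, np.nan, "ND"))
        elif t.empty:
            rows.append((gene, np.nan, "nd-treated"))
        elif c.empty:
            rows.append((gene, np.nan, "nd-control"))
        elif mean_of_ratios:
            fc = np.log2(t.to_numpy(float)).mean() - np.log2(c.to_numpy(float)).mean()
            rows.append((gene, float(fc), "ok"))
        else:
            fc = np.log2(t.mean() / c.mean())
            rows.append((gene, float(fc), "ok"))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "code"]).set_index(
        "gene_id"
    )


def read_panel(
    counts_tsv: str | Path,
    probe_meta_tsv: str | Path,
    lane_meta_tsv: str | Path,
) -> NanoStringPanel:
    """Assemble a panel from a counts TSV (probe_id + one column per lane),
    a probe-metadata TSV (probe_id, class, known_conc) and a lane-metadata
    TSV (lane_id, condition, replicate)."""
    counts = pd.read_csv(counts_tsv, sep="\t", comment="#").set_index("probe_id")
    probe_meta = pd.read_csv(probe_meta_tsv, sep="\t", comment="#").set_index(
        "probe_id"
    )
    lane_meta = pd.read_csv(lane_meta_tsv, sep="\t", comment="#").set_index(
        "lane_id"
    )
    positive_conc = None
    if "known_conc" in probe_meta.columns:
        pos = probe_meta[probe_meta["class"] == "positive"]
        if pos["known_conc"].notna().all():
            positive_conc = pos["known_conc"].astype(float)
    return NanoStringPanel(
        counts=counts,
        probe_class=probe_meta["class"],
        lane_condition=lane_meta["condition"].to_dict(),
        positive_conc=positive_conc,
        lane_replicate=(
            lane_meta["replicate"].astype(int).to_dict()
            if "replicate" in lane_meta.columns
            else None
        ),
    )


def write_normalized_tsv(normalized: NormalizedPanel, out_file: str | Path) -> None:
    """Normalized endogenous values with 'nd' in undetected cells."""
    out = normalized.values.round(6).astype(object).where(
        normalized.values.notna(), "nd"
    )
    out.index.name = "probe_id"
    out.to_csv(out_file, sep="\t")


def write_qc_tsv(normalized: NormalizedPanel, out_file: str | Path) -> None:
    qc = pd.DataFrame(
        {
            "background": normalized.background,
            "s_pos": normalized.s_pos,
            "s_ref": normalized.s_ref,
            "curve_slope": normalized.qc["slope"],
            "curve_r_squared": normalized.qc["r_squared"],
        }
    )
    qc.index.name = "lane_id"
    qc.to_csv(out_file, sep="\t")
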