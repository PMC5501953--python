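"""Barnyard (species-mixing) analysis.

In a one-to-one mixture of human and mouse cells, reads are mapped
independently to both genomes and reads mapping to both with <=3
mismatches are excluded as ambiguous. Per-cell species cutoffs are set
robustly: the human cutoff is the median plus five times the
inter-quartile range of human transcript counts among mouse-dominated
cells (and symmetrically for mouse). A cell exceeding both cutoffs is a
cross-species multiplet; exceeding neither leaves it unclassified. Since
same-species multiplets are invisible in this design but occur at a
similar rate in a balanced mixture, the overall multiplet rate is
estimated as twice the cross-species rate. Single-cell purity is the
median own-species transcript fraction among classified cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesConfig",
    "exclude_ambiguous",
    "compute_cutoffs",
    "classify",
    "multiplet_rate",
    "purity",
    "analyze_barnyard",
]


@dataclass
class SpeciesConfig:
    """Thresholds of the barnyard analysis."""

    ambiguity_max_mismatch: int = 3
    iqr_multiplier: float = 5.0
    labels: tuple[str, str] = ("human", "mouse")

    def __post_init__(self) -> None:
        if self.ambiguity_max_mismatch < 0:
            raise ValueError("ambiguity_max_mismatch must be >= 0")


def exclude_ambiguous(
    mismatch_h: pd.Series,
    mismatch_m: pd.Series,
    config: SpeciesConfig | None = None,
) -> pd.Series:
    """Assign each read to a species or exclude it as ambiguous.

    Inputs are per-read best mismatch counts against each genome (NaN =
    unmapped). A read is excluded iff it maps to both genomes with at
    most ``ambiguity_max_mismatch`` mismatches each; otherwise it goes to
    the genome where it maps within the threshold. Reads mapping to
    neither genome within the threshold are unassigned.

    Returns a Series over reads with values in
    {human, mouse, ambiguous, unassigned} (using the configured labels).
    """
    config = config or SpeciesConfig()
    t = config.ambiguity_max_mismatch
    h_ok = mismatch_h.notna() & (mismatch_h <= t)
    m_ok = mismatch_m.notna() & (mismatch_m <= t)
    out = pd.Series("unassigned", index=mismatch_h.index, dtype=object)
    out[h_ok & m_ok] = "ambiguous"
    out[h_ok & ~m_ok] = config.labels[0]
    out[m_ok & ~h_ok] = config.labels[1]
    return out


def compute_cutoffs(
    counts: pd.DataFrame,
    config: SpeciesConfig | None = None,
) -> tuple[float, float]:
    """Robust per-species classification cutoffs.

    ``counts`` has per-cell columns ``transcripts_h`` and
    ``transcripts_m``. cutoff_h = median + iqr_multiplier * IQR of
    transcripts_h among mouse-dominated cells (transcripts_m >
    transcripts_h), and symmetrically for cutoff_m. Quantiles use linear
    interpolation (type 7).
    """
    config = config or SpeciesConfig()
    th = counts["transcripts_h"].to_numpy(float)
    tm = counts["transcripts_m"].to_numpy(float)
    mouse_dom = tm > th
    human_dom = th > tm
    if mouse_dom.sum() < 2 or human_dom.sum() < 2:
        raise ValueError(
            "need at least two cells on each side of the dominance split "
            f"(got {int(human_dom.sum())} human-dominated, {int(mouse_dom.sum())} mouse-dominated)"
        )

    def cutoff(values: np.ndarray) -> float:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return float(med + config.iqr_multiplier * (q3 - q1))

    return cutoff(th[mouse_dom]), cutoff(tm[human_dom])


def classify(
    counts: pd.DataFrame,
    cutoffs: tuple[float, float],
    config: SpeciesConfig | None = None,
) -> pd.Series:
    """Label each cell given the cutoffs.

    Strictly more own-species transcripts than the cutoff classifies a
    cell on that side; exceeding both cutoffs makes it a multiplet;
    neither leaves it unclassified. Every cell receives exactly one of
    the four labels.
    """
    config = config or SpeciesConfig()
    cutoff_h, cutoff_m = cutoffs
    is_h = counts["transcripts_h"] > cutoff_h
    is_m = counts["transcripts_m"] > cutoff_m
    out = pd.Series("unclassified", index=counts.index, dtype=object)
    out[is_h & ~is_m] = config.labels[0]
    out[is_m & ~is_h] = config.labels[1]
    out[is_h & is_m] = "multiplet"
    return out


def multiplet_rate(labels: pd.Series) -> tuple[float, float]:
    """Cross-species multiplet percentage and doubled overall estimate.

    The cross-species percentage uses all mixture cells as denominator.
    In a one-to-one mixture, half of all multiplets pair cells of the
    same species and go undetected, so the overall multiplet rate is
    estimated as twice the observed cross-species rate.
    """
    n = len(labels)
    if n == 0:
        return 0.0, 0.0
    cross = float((labels == "multiplet").sum()) / n * 100.0
    return cross, 2.0 * cross


def purity(
    counts: pd.DataFrame,
    labels: pd.Series,
    config: SpeciesConfig | None = None,
) -> dict[str, float]:
    """Median own-species transcript fraction per classified species."""
    config = config or SpeciesConfig()
    out = {}
    for label, own, other in (
        (config.labels[0], "transcripts_h", "transcripts_m"),
        (config.labels[1], "transcripts_m", "transcripts_h"),
    ):
        sub = counts[labels == label]
        if len(sub) == 0:
            raise ValueError(f"no cells classified as {label}")
        frac = sub[own] / (sub[own] + sub[other])
        out[label] = float(frac.median())
    return out


def analyze_barnyard(
    counts: pd.DataFrame,
    config: SpeciesConfig | None = None,
) -> dict:
    """Run the full barnyard analysis on per-cell dual-genome counts.

    Returns a dict with cutoffs, per-cell labels, label counts, the
    cross-species and overall multiplet rates, and per-species purity.
    """
    config = config or SpeciesConfig()
    cutoffs = compute_cutoffs(counts, config)
    labels = classify(counts, cutoffs, config)
    cross, overall = multiplet_rate(labels)
    return {
        "cutoff_h": cutoffs[0],
        "cutoff_m": cutoffs[1],
        "labels": labels,
        "label_counts": labels.value_counts().to_dict(),
        "cross_species_pct": cross,
        "overall_multiplet_pct": overall,
        "purity": purity(counts, labels, config),
    }
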