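"""Checkerboard dispenser quality control.

The checkerboard assay quantifies dispense-tip misalignment: one half of
the chip holds no-template negative controls (NTC), the other half
alternates lambda-DNA Positive wells with negative Test wells. A
misaligned tip deposits template into Test wells, producing qPCR signal
there. A melt-curve filter removes off-target products (Test/NTC wells
whose melting temperature falls more than 3 SD from the Positive-well
mean), and the misalignment statistic is the difference

    % misalignment = % Test wells with signal - % NTC wells with signal

so background signal that hits Test and NTC wells equally cancels. The
value may be negative and is reported as computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalRule", "melt_filter", "misalignment", "summarize_checkerboard"]


@dataclass
class SignalRule:
    """A well 'shows signal' when it has a Ct at or below ``max_ct``."""

    max_ct: float = 35.0

    def __call__(self, ct: pd.Series) -> pd.Series:
        return ct.notna() & (ct <= self.max_ct)


def melt_filter(wells: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Exclude Test/NTC signal with off-window melting temperature.

    The window is mean +/- ``n_sd`` * SD (sample SD, n-1 denominator) of
    the Positive wells' Tm. Test and NTC wells showing signal whose Tm
    falls outside the window get ``melt_excluded=True``; wells without
    signal are unaffected. Positive wells are never excluded.
    """
    pos_tm = wells.loc[(wells["well_class"] == "Positive") & wells["tm"].notna(), "tm"]
    if len(pos_tm) < 2:
        raise ValueError("need at least two Positive wells with a melting temperature")
    mean = float(pos_tm.mean())
    sd = float(pos_tm.std(ddof=1))
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    out = wells.copy()
    has_tm = out["tm"].notna()
    nonpos = out["well_class"] != "Positive"
    out["melt_excluded"] = nonpos & has_tm & ((out["tm"] < lo) | (out["tm"] > hi))
    out.attrs["tm_window"] = (lo, hi)
    return out


def misalignment(
    wells: pd.DataFrame,
    signal_rule: SignalRule | None = None,
) -> dict:
    """Misalignment percentage after melt filtering.

    Wells flagged ``melt_excluded`` do not count as showing signal. The
    percentages are over all wells of each class.
    """
    signal_rule = signal_rule or SignalRule()
    excluded = wells["melt_excluded"] if "melt_excluded" in wells.columns else \
        pd.Series(False, index=wells.index)
    signal = signal_rule(wells["ct"]) & ~excluded
    out = {}
    for cls in ("Test", "NTC"):
        mask = wells["well_class"] == cls
        n = int(mask.sum())
        k = int((signal & mask).sum())
        if n == 0:
            raise ValueError(f"no {cls} wells present")
        out[f"n_{cls.lower()}"] = n
        out[f"signal_{cls.lower()}"] = k
        out[f"pct_{cls.lower()}"] = 100.0 * k / n
    out["misalignment_pct"] = out["pct_test"] - out["pct_ntc"]
    return out


def summarize_checkerboard(
    wells: pd.DataFrame,
    signal_rule: SignalRule | None = None,
    n_sd: float = 3.0,
    summary_path: str | Path | None = None,
) -> dict:
    """Melt-filter a checkerboard table and compute the misalignment stats."""
    filtered = melt_filter(wells, n_sd=n_sd)
    stats = misalignment(filtered, signal_rule)
    stats["n_melt_excluded"] = int(filtered["melt_excluded"].sum())
    lo, hi = filtered.attrs["tm_window"]
    stats["tm_window"] = [float(lo), float(hi)]
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(stats, fh, indent=2)
    return stats
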