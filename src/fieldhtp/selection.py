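"""Breeding-selection helpers on QC'd plot means.

Works on a *line summary* table -- one record per breeding line x
collection date x trait, aggregated over that line's plots.  Supports
rank-and-select by a trait (e.g. the k lines with the lowest canopy
temperature) and flagging lines whose mean height declined between two
dates (lodging / storm intolerance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


def line_summaries(plot_means: pd.DataFrame, plot_lines: pd.DataFrame,
                   date: str, weighted: bool = False) -> pd.DataFrame:
    """Aggregate plot means to line-level values for one date.

    ``plot_lines`` maps plot_id -> line_id (a plot-map attribute
    table).  By default each of a line's plots contributes equally
    (unweighted mean of plot means); ``weighted=True`` weights plots by
    their observation counts instead.  Ranks (1 = smallest value) are
    assigned per trait within the date.
    """
    df = plot_means.merge(plot_lines[["plot_id", "line_id"]], on="plot_id",
                          how="left")
    df = df[df["line_id"].notna() & df["mean"].notna()]
    rows = []
    for (line, trait), sub in df.groupby(["line_id", "trait"], sort=True):
        if weighted:
            w = sub["n"].to_numpy(dtype=float)
            value = float(np.average(sub["mean"], weights=w)) if w.sum() else np.nan
        else:
            value = float(sub["mean"].mean())
        rows.append({"line_id": line, "date": date, "trait": trait,
                     "value": value, "n_plots": int(len(sub))})
    out = pd.DataFrame(rows)
    if len(out):
        out["rank"] = (out.groupby("trait")["value"]
                       .rank(method="first", ascending=True).astype(int))
    return out


def select_lines(summaries: pd.DataFrame, trait: str, date: str, k: int,
                 direction: str = "asc") -> pd.DataFrame:
    """Top-k lines by a trait on a date.

    ``direction='asc'`` selects the smallest values (e.g. coolest
    canopies), ``'desc'`` the largest.  Ties break lexicographically by
    line id, so the ordering is reproducible.
    """
    if direction not in ("asc", "desc"):
        raise SelectionError("direction must be 'asc' or 'desc'")
    sub = summaries[(summaries["trait"] == trait) & (summaries["date"] == date)]
    if not len(sub):
        raise SelectionError(f"no records for trait {trait!r} on date {date!r}")
    if k > len(sub):
        raise SelectionError(f"k={k} exceeds the {len(sub)} available lines")
    sub = sub.sort_values(["value", "line_id"],
                          ascending=[direction == "asc", True], kind="stable")
    return sub.head(k)[["line_id", "date", "trait", "value"]].reset_index(drop=True)


def height_decline(summaries: pd.DataFrame, date1: str, date2: str,
                   min_drop: float = 0.10, trait: str = "height") -> pd.DataFrame:
    """Lines whose mean height dropped by >= ``min_drop`` metres
    between two dates (inclusive bound) -- the lodging signature after
    storms.  The default 0.10 m is a height loss no growth plateau
    explains in-season.
    """
    a = summaries[(summaries["trait"] == trait) & (summaries["date"] == date1)]
    b = summaries[(summaries["trait"] == trait) & (summaries["date"] == date2)]
    if not len(a) or not len(b):
        raise SelectionError(f"missing {trait!r} summaries for {date1!r}/{date2!r}")
    merged = a[["line_id", "value"]].merge(
        b[["line_id", "value"]], on="line_id", suffixes=("_1", "_2"))
    merged["drop_m"] = merged["value_1"] - merged["value_2"]
    # inclusive bound, robust to binary rounding of decimal heights
    merged["flagged"] = merged["drop_m"] >= min_drop - 1e-9
    out = merged[merged["flagged"]].sort_values(
        "drop_m", ascending=False, kind="stable")
    return out[["line_id", "value_1", "value_2", "drop_m"]].reset_index(drop=True)
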