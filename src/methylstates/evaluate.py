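"""Validation machinery: region-set coincidence, cross-platform
correlation, and region-width summaries.

The coincidence between two labeled region sets (e.g. an array-based
segmentation vs. a WGBS-based one) is measured as base-pair-weighted
overlap: for every pair of labels the intersected bp are counted, and
each row is normalized by the total bp of that label in the first set.
A count-weighted variant (each region of set A votes with weight 1 for
the label of set B covering most of it) is available via
``weight="count"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ValidationError
from .profiles import MethylationProfile, chrom_sort_key, merge_intervals
from .regions import Region


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Region list -> BED-convention frame (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "state": [r.state for r in regions],
        }
    )


def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        df = obj.loc[:, ["chrom", "start", "end", "state"]].copy()
    else:
        df = regions_to_frame(list(obj))
    if ((df["end"] - df["start"]) <= 0).any():
        raise ValidationError("malformed interval (end <= start)")
    return df


def _label_intervals(df: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """(label, chrom) -> merged sorted [start, end) interval array."""
    out = {}
    for (label, chrom), sub in df.groupby(["state", "chrom"], sort=False):
        out[(str(label), str(chrom))] = merge_intervals(
            sub[["start", "end"]].to_numpy(dtype=np.int64)
        )
    return out


def _pair_overlap_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Total intersection bp of two sorted disjoint interval arrays."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


@dataclass
class OverlapMatrix:
    """State-wise coincidence between two labeled region sets.

    ``basepair_overlap[i, j]`` is the bp shared by row-label i of set A
    and column-label j of set B; ``row_fractions`` normalizes each row
    by the total bp of that label in set A, so a row sums to at most 1
    (the remainder is bp of A overlapping no region of B).
    """

    row_labels: list[str]
    col_labels: list[str]
    basepair_overlap: pd.DataFrame
    row_fractions: pd.DataFrame
    row_total_bp: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return self.row_fractions


def overlap_matrix(set_a, set_b, weight: str = "bp") -> OverlapMatrix:
    """Base-pair (or region-count) overlap matrix between two region sets.

    Inputs are sequences of :class:`Region` or frames with columns
    chrom/start/end/state in BED convention.  Same-label intervals are
    merged before counting (the mandatory validation merge).
    """
    if weight not in ("bp", "count"):
        raise ValidationError("weight must be 'bp' or 'count'")
    fa, fb = _as_frame(set_a), _as_frame(set_b)
    ia, ib = _label_intervals(fa), _label_intervals(fb)
    row_labels = sorted({lab for lab, _ in ia})
    col_labels = sorted({lab for lab, _ in ib})
    chroms = sorted(
        {c for _, c in ia} | {c for _, c in ib}, key=chrom_sort_key
    )
    bp = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=np.int64)
    totals = pd.Series(0, index=row_labels, dtype=np.int64)
    for la in row_labels:
        for chrom in chroms:
            a = ia.get((la, chrom))
            if a is None:
                continue
            totals[la] += int((a[:, 1] - a[:, 0]).sum())
            for lb in col_labels:
                b = ib.get((lb, chrom))
                if b is not None:
                    bp.loc[la, lb] += _pair_overlap_bp(a, b)

    if weight == "bp":
        frac = bp.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    else:
        # each region of A votes for the B label covering most of it
        votes = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=np.int64)
        counts = pd.Series(0, index=row_labels, dtype=np.int64)
        for _, row in fa.iterrows():
            la = str(row["state"])
            counts[la] += 1
            iv = np.array([[row["start"], row["end"]]], dtype=np.int64)
            cover = {
                lb: _pair_overlap_bp(iv, ib[(lb, str(row["chrom"]))])
                for lb in col_labels
                if (lb, str(row["chrom"])) in ib
            }
            if cover and max(cover.values()) > 0:
                votes.loc[la, max(cover, key=cover.get)] += 1
        frac = votes.div(counts.replace(0, np.nan), axis=0).fillna(0.0)
    return OverlapMatrix(
        row_labels=row_labels,
        col_labels=col_labels,
        basepair_overlap=bp,
        row_fractions=frac,
        row_total_bp=totals,
    )


def common_site_correlation(
    profile_a: MethylationProfile, profile_b: MethylationProfile
) -> tuple[float, int]:
    """Pearson r of beta-values at the common (chrom, pos) sites."""
    a = profile_a.records[["chrom", "pos", "beta"]]
    b = profile_b.records[["chrom", "pos", "beta"]]
    m = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(m) < 3:
        raise ValidationError(
            f"only {len(m)} common sites; need at least 3 for a correlation"
        )
    r = pearsonr(m["beta_a"], m["beta_b"]).statistic
    return float(r), int(len(m))


def width_summary(regions: Sequence[Region]) -> pd.DataFrame:
    """Five-number summary (bp) of region widths per state.

    Width is the 1-based inclusive span (end - start + 1); quartiles use
    linear interpolation.  States absent from the input are omitted.
    """
    rows = {}
    by_state: dict[str, list[int]] = {}
    for r in regions:
        by_state.setdefault(r.state, []).append(r.width)
    for state in sorted(by_state):
        w = np.asarray(by_state[state], dtype=float)
        q = np.percentile(w, [0, 25, 50, 75, 100])
        rows[state] = {
            "n": len(w),
            "min": q[0],
            "q1": q[1],
            "median": q[2],
            "q3": q[3],
            "max": q[4],
        }
    return pd.DataFrame.from_dict(rows, orient="index")
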