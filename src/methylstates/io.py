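"""Writers/readers for site-call tables and region BED files.

Site calls: tab-delimited with header
``probe_id chrom pos beta layer1_state final_state``.

Regions: BED6 plus two extra columns (chrom, start, end, name=state,
score=round(1000*mean_beta), strand=".", n_cpg, mean_beta), 0-based
half-open per the BED standard.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .profiles import chrom_sort_key
from .regions import Region

SITE_CALL_COLUMNS = ["probe_id", "chrom", "pos", "beta", "layer1_state", "final_state"]


def write_site_calls(calls: pd.DataFrame, path) -> None:
    """Write a site-call frame as TSV (header always present)."""
    missing = [c for c in SITE_CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValidationError(f"site-call frame lacks column(s) {missing}")
    calls.loc[:, SITE_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_site_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: not a site-call table (missing {missing})")
    return df


def write_region_bed(regions: Sequence[Region], path, header: str | None = None) -> None:
    """Write regions as BED6+2, sorted by (chrom, start).

    ``header`` becomes a leading ``#`` comment line when given (used by
    the CLI to record the configuration that produced the file).
    """
    regions = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for r in regions:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start - 1),  # 1-based inclusive -> 0-based half-open
                        str(r.end),
                        r.state,
                        str(int(round(1000 * r.mean_beta))),
                        ".",
                        str(r.n_cpg),
                        f"{r.mean_beta:.6g}",
                    ]
                )
                + "\n"
            )


def read_region_bed(path) -> pd.DataFrame:
    """Read a labeled region BED (>= 4 columns) into a frame.

    Returns columns chrom, start, end (BED convention), state, and,
    when present, score, n_cpg, mean_beta.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: need >= 4 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            row = {"chrom": parts[0], "start": start, "end": end, "state": parts[3]}
            if len(parts) >= 5:
                row["score"] = int(parts[4])
            if len(parts) >= 7:
                row["n_cpg"] = int(parts[6])
            if len(parts) >= 8:
                row["mean_beta"] = float(parts[7])
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_regions(df: pd.DataFrame) -> list[Region]:
    """BED-convention frame -> Region list (no CpG membership)."""
    out = []
    for _, row in df.iterrows():
        out.append(
            Region(
                chrom=str(row["chrom"]),
                start=int(row["start"]) + 1,
                end=int(row["end"]),
                cpg_indices=np.arange(int(row.get("n_cpg", 0))),
                mean_beta=float(row.get("mean_beta", np.nan)),
                state=str(row["state"]),
            )
        )
    return out
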