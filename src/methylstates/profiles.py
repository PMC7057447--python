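"""Per-probe methylation profiles: reading, filtering and island annotation.

A :class:`MethylationProfile` holds the ordered per-CpG records (probe id,
chromosome, 1-based position, beta-value) for one sample on one array
platform.  The beta-value is the fraction of methylated signal at a probe
and lives in [0, 1]; it is the observation that the HMM layers consume.

Coordinates follow the Illumina manifest convention on input (1-based
positions) and the BED convention (0-based, half-open) on interval input
and output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["probe_id", "chrom", "pos", "beta", "detection_p", "island_member"]

_CHROM_NUM_RE = re.compile(r"^(?:chr)?(\d+)$", re.IGNORECASE)


class Platform(str, Enum):
    """Array platform; decides the default open-sea merge gap."""

    HM450K = "HM450K"
    EPIC = "EPIC"
    GENERIC = "GENERIC"


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Karyotype-ish ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = _CHROM_NUM_RE.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def _norm_chrom(chrom: str) -> str:
    c = chrom.lower()
    return c[3:] if c.startswith("chr") else c


def is_sex_chrom(chrom: str) -> bool:
    """True for chrX/chrY under tolerant spelling ('X', 'chrx', ...)."""
    return _norm_chrom(chrom) in ("x", "y")


@dataclass(frozen=True)
class TableDialect:
    """Column mapping and delimiter for a delimited beta-value table."""

    sep: str = "\t"
    probe_id: str = "probe_id"
    chrom: str = "chrom"
    pos: str = "pos"
    beta: str = "beta"
    detection_p: str | None = "detection_p"


class MethylationProfile:
    """Genome-sorted per-CpG beta-values for one sample.

    Parameters
    ----------
    records
        DataFrame with columns ``probe_id, chrom, pos, beta`` and
        optionally ``detection_p`` and ``island_member``.  Rows are
        validated, then sorted by (chrom, pos); duplicated (chrom, pos)
        entries are dropped (first kept, with a logged count).
    platform
        Array platform; controls platform-dependent defaults downstream.
    """

    def __init__(self, records: pd.DataFrame, platform: Platform = Platform.GENERIC):
        df = records.copy()
        for col in ("probe_id", "chrom", "pos", "beta"):
            if col not in df.columns:
                raise ValidationError(f"profile is missing required column {col!r}")
        if "detection_p" not in df.columns:
            df["detection_p"] = np.nan
        if "island_member" not in df.columns:
            df["island_member"] = False

        df["probe_id"] = df["probe_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["beta"] = df["beta"].astype(float)
        df["detection_p"] = df["detection_p"].astype(float)
        df["island_member"] = df["island_member"].astype(bool)

        bad = ~np.isfinite(df["beta"]) | (df["beta"] < 0) | (df["beta"] > 1)
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"beta outside [0, 1] at row {row} "
                f"(probe {df.loc[row, 'probe_id']}, beta={df.loc[row, 'beta']})"
            )
        if (df["pos"] < 1).any():
            row = df.index[df["pos"] < 1][0]
            raise ValidationError(f"non-positive position at row {row}")

        df = df.sort_values(
            ["chrom", "pos"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            kind="mergesort",
        )
        dup = df.duplicated(["chrom", "pos"])
        if dup.any():
            logger.warning("dropping %d duplicated (chrom, pos) records", int(dup.sum()))
            df = df[~dup]
        self.records = df.loc[:, PROFILE_COLUMNS].reset_index(drop=True)
        self.platform = Platform(platform)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationProfile):
            return NotImplemented
        return self.platform == other.platform and self.records.equals(other.records)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.records["chrom"]))

    def chains(self) -> Iterator[tuple[str, pd.DataFrame]]:
        """Yield (chromosome, records) blocks in genomic order."""
        for chrom in self.chroms:
            yield chrom, self.records[self.records["chrom"] == chrom]

    def beta_chains(self) -> list[np.ndarray]:
        """Per-chromosome beta arrays in genomic order (HMM observations)."""
        return [sub["beta"].to_numpy() for _, sub in self.chains()]

    def replace_records(self, records: pd.DataFrame) -> "MethylationProfile":
        return MethylationProfile(records, platform=self.platform)


@dataclass
class IslandAnnotation:
    """CpG-island intervals per chromosome, 0-based half-open, merged.

    ``intervals`` maps chromosome -> (k, 2) int array of sorted,
    non-overlapping [start, end) rows; merging of overlapping or
    book-ended input intervals is mandatory and happens on construction.
    """

    intervals: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and (arr[:, 0] >= arr[:, 1]).any():
                raise ValidationError(f"empty or inverted island interval on {chrom}")
            merged[chrom] = merge_intervals(arr)
        self.intervals = merged

    def membership(self, chrom: str, pos0: np.ndarray, flank: int = 0) -> np.ndarray:
        """Boolean mask: is each 0-based point within `flank` bp of an island?"""
        pos0 = np.asarray(pos0, dtype=np.int64)
        ivs = self.intervals.get(chrom)
        if ivs is None or not len(ivs):
            return np.zeros(pos0.shape, dtype=bool)
        starts = ivs[:, 0] - flank
        ends = ivs[:, 1] + flank  # half-open; point p inside iff start <= p < end
        # flanked intervals may overlap each other; a searchsorted on starts
        # with a running-max of ends handles that without a re-merge
        run_end = np.maximum.accumulate(ends)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] = pos0[ok] < run_end[idx[ok]]
        return ok


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/book-ended [start, end) rows; returns sorted array."""
    if not len(arr):
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].tolist()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def read_beta_table(
    path,
    dialect: TableDialect = TableDialect(),
    platform: Platform = Platform.GENERIC,
) -> MethylationProfile:
    """Read a delimited per-probe beta table (minfi-export style).

    Rows with missing beta are dropped (count logged).  A beta outside
    [0, 1] raises :class:`ValidationError` naming the offending row.
    """
    try:
        raw = pd.read_csv(path, sep=dialect.sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse beta table {path}: {exc}") from exc
    colmap = {
        dialect.probe_id: "probe_id",
        dialect.chrom: "chrom",
        dialect.pos: "pos",
        dialect.beta: "beta",
    }
    if dialect.detection_p and dialect.detection_p in raw.columns:
        colmap[dialect.detection_p] = "detection_p"
    missing = [c for c in colmap if c not in raw.columns]
    if missing:
        raise FormatError(f"beta table {path} lacks column(s) {missing}")
    df = raw.rename(columns=colmap)

    n_missing = int(df["beta"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing beta", n_missing)
        df = df[df["beta"].notna()]
    return MethylationProfile(df, platform=platform)


def filter_probes(
    profile: MethylationProfile,
    p_cutoff: float = 0.05,
    drop_sex: bool = True,
    blacklist: set[str] | Sequence[str] | None = None,
) -> MethylationProfile:
    """Apply the standard probe-level filters.

    Removes probes whose detection p-value exceeds ``p_cutoff`` (probes
    without a detection p-value are kept), probes on the sex chromosomes
    when ``drop_sex``, and probes whose id is in ``blacklist`` (e.g. a
    SNP-overlapping probe list).  Removed counts per reason are logged.
    Idempotent by construction.
    """
    if not (0 < p_cutoff < 1):
        raise ValidationError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    df = profile.records
    bad_p = df["detection_p"].notna() & (df["detection_p"] > p_cutoff)
    bad_sex = df["chrom"].map(is_sex_chrom) if drop_sex else pd.Series(False, index=df.index)
    bl = set(map(str, blacklist)) if blacklist else set()
    bad_bl = df["probe_id"].isin(bl) if bl else pd.Series(False, index=df.index)
    logger.info(
        "filter_probes: removed %d (detection p > %g), %d (sex chromosome), %d (blacklist)",
        int(bad_p.sum()), p_cutoff, int(bad_sex.sum()), int(bad_bl.sum()),
    )
    kept = df[~(bad_p | bad_sex | bad_bl)]
    if kept.empty:
        logger.warning("filter_probes: no probes survive the filters")
    return profile.replace_records(kept)


def read_island_bed(path) -> IslandAnnotation:
    """Read a CpG-island BED3+ file (0-based half-open) and merge intervals."""
    per_chrom: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            per_chrom.setdefault(chrom, []).append([start, end])
    return IslandAnnotation(
        {c: np.asarray(v, dtype=np.int64) for c, v in per_chrom.items()}
    )


def annotate_islands(
    profile: MethylationProfile, islands: IslandAnnotation, flank: int = 300
) -> MethylationProfile:
    """Flag island-associated CpGs.

    A site is island-associated iff it lies inside an island interval or
    within ``flank`` bp of an island boundary.  The flag feeds the
    gap-threshold choice during region building.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    df = profile.records.copy()
    member = np.zeros(len(df), dtype=bool)
    for chrom in profile.chroms:
        sel = (df["chrom"] == chrom).to_numpy()
        pos0 = df.loc[sel, "pos"].to_numpy() - 1  # 1-based -> 0-based point
        member[sel] = islands.membership(chrom, pos0, flank=flank)
    df["island_member"] = member
    return profile.replace_records(df)
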