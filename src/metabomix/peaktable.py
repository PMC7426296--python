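"""Peak-table and sample-design ingestion, filtering, and replicate collapsing.

A peak table holds extracted LC-MS features (one row per peak: m/z, retention
time, polarity, apex height) together with per-sample peak areas.  The sample
design records, for every injected sample, its genotype, treatment, biological
replicate and technical replicate, so that technical injections can be
collapsed onto biological replicates by geometric mean before any statistics.

Positive- and negative-mode tables are kept separate through identification
and differential testing; merging happens only in final reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "load_peak_table",
    "load_design",
    "validate_design",
    "filter_peaks",
    "collapse_technical",
]

_META_COLUMNS = ("peak_id", "mz", "rt", "polarity", "height")
_DESIGN_REQUIRED = ("sample_id", "genotype", "biological_replicate", "technical_replicate")
#: m/z values outside the instrument scan range are a data error, not a filter.
DEFAULT_SCAN_RANGE = (50.0, 1700.0)


@dataclass
class PeakTable:
    """Extracted peaks plus their per-sample areas.

    ``meta`` is indexed by peak_id with columns mz, rt, polarity, height;
    ``areas`` shares the index and has one column per sample.  After
    :func:`collapse_technical` the area columns are biological replicates and
    ``collapse_flags`` records where zero areas were dropped from a geometric
    mean.
    """

    meta: pd.DataFrame
    areas: pd.DataFrame
    collapse_flags: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.areas.index):
            raise ValueError("meta and areas must share the peak_id index")

    @property
    def samples(self) -> list:
        return list(self.areas.columns)

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, peak_ids) -> "PeakTable":
        flags = None
        if self.collapse_flags is not None:
            flags = self.collapse_flags.loc[peak_ids]
        return PeakTable(self.meta.loc[peak_ids], self.areas.loc[peak_ids], flags)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.meta, self.areas], axis=1).reset_index()

    def to_csv(self, path: Union[str, Path], sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _read_delimited(path: Union[str, Path]) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check required design columns and fill optional ones with defaults."""
    df = design.copy()
    missing = [c for c in _DESIGN_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sample design missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    if "treatment" not in df.columns:
        df["treatment"] = "none"
    if "organ" not in df.columns:
        df["organ"] = "kidney"
    return df


def load_design(path: Union[str, Path]) -> pd.DataFrame:
    return validate_design(_read_delimited(path))


def load_peak_table(
    path: Union[str, Path],
    design: pd.DataFrame,
    scan_range: Tuple[float, float] = DEFAULT_SCAN_RANGE,
) -> PeakTable:
    """Read a delimited peak table whose sample columns match the design.

    Errors on a missing sample column (named in the message), a duplicate
    peak_id, or a negative area.  An empty file yields an empty table with a
    logged warning.
    """
    design = validate_design(design)
    frame = _read_delimited(path)
    missing_meta = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise ValueError(f"peak table missing columns: {missing_meta}")
    sample_ids = list(design["sample_id"])
    missing = [s for s in sample_ids if s not in frame.columns]
    if missing:
        raise ValueError(f"peak table missing sample column(s): {missing}")
    if frame["peak_id"].duplicated().any():
        dupes = frame.loc[frame["peak_id"].duplicated(), "peak_id"].tolist()
        raise ValueError(f"duplicate peak_id values: {dupes[:5]}")
    if frame.empty:
        log.warning("peak table %s is empty", path)
    frame = frame.set_index("peak_id")
    meta = frame[list(_META_COLUMNS[1:])].copy()
    meta["mz"] = pd.to_numeric(meta["mz"])
    lo, hi = scan_range
    if len(meta) and ((meta["mz"] < lo) | (meta["mz"] > hi)).any():
        bad = meta.index[(meta["mz"] < lo) | (meta["mz"] > hi)].tolist()
        raise ValueError(
            f"m/z outside scan range {scan_range} for peak(s): {bad[:5]}"
        )
    areas = frame[sample_ids].astype(float)
    if len(areas) and (areas.to_numpy() < 0).any():
        raise ValueError("negative peak area in peak table")
    log.info("loaded %d peaks x %d samples from %s", len(meta), len(sample_ids), path)
    return PeakTable(meta, areas)


def filter_peaks(
    table: PeakTable,
    rt_min: float = 2.0,
    rt_max: float = 13.0,
    min_height: float = 1000.0,
) -> PeakTable:
    """Keep peaks with rt_min <= rt <= rt_max and height strictly > min_height.

    Defaults reproduce feature-extraction ingestion: retention time within
    2-13 min and absolute height above 1000 counts (a peak at exactly 1000 is
    removed).
    """
    keep = (
        (table.meta["rt"] >= rt_min)
        & (table.meta["rt"] <= rt_max)
        & (table.meta["height"] > min_height)
    )
    return table.subset(table.meta.index[keep])


def collapse_technical(
    table: PeakTable, design: pd.DataFrame
) -> Tuple[PeakTable, pd.DataFrame]:
    """Collapse technical replicates onto biological replicates by geometric mean.

    Zero areas are dropped from the geometric mean (a flag is recorded); a
    biological replicate whose technical injections are all zero collapses to
    zero.  Returns the collapsed table (one area column per biological
    replicate) and the biological-level design (one row per biological
    replicate, ``technical_replicate`` set to ``"pooled"``).

    Biological replicate identifiers must be unique across the design; they
    become the collapsed sample ids.
    """
    design = validate_design(design)
    groups = design.groupby("biological_replicate", sort=False)
    bio_rows = []
    collapsed: dict = {}
    some_dropped: dict = {}
    for bio_id, grp in groups:
        cols = [s for s in grp["sample_id"] if s in table.areas.columns]
        if not cols:
            raise ValueError(
                f"biological replicate {bio_id!r} has no technical replicates "
                "present in the peak table"
            )
        keys = grp[["genotype", "treatment", "organ"]].drop_duplicates()
        if len(keys) > 1:
            raise ValueError(
                f"biological replicate {bio_id!r} maps to multiple groups"
            )
        vals = table.areas[cols].to_numpy(dtype=float)
        pos = vals > 0
        npos = pos.sum(axis=1)
        logs = np.log(vals, out=np.zeros_like(vals), where=pos)
        gm = np.exp(logs.sum(axis=1) / np.maximum(npos, 1))
        gm[npos == 0] = 0.0
        collapsed[bio_id] = gm
        some_dropped[bio_id] = npos < vals.shape[1]
        row = keys.iloc[0].to_dict()
        row.update(
            sample_id=bio_id,
            biological_replicate=bio_id,
            technical_replicate="pooled",
            n_technical=len(cols),
        )
        bio_rows.append(row)
    areas = pd.DataFrame(collapsed, index=table.areas.index)
    flags = pd.DataFrame(some_dropped, index=table.areas.index)
    bio_design = pd.DataFrame(bio_rows)
    n_flagged = int(flags.to_numpy().sum())
    if n_flagged:
        log.info("dropped zero areas from %d geometric means", n_flagged)
    return PeakTable(table.meta.copy(), areas, flags), bio_design
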