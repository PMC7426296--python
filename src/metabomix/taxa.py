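"""16S taxon-level group comparison.

Operates on a taxon-by-sample table whose rows carry a full seven-rank
taxonomy path (domain;phylum;class;order;family;genus;species, empty ranks
allowed at the tail; Greengenes-style ``g__`` prefixes are stripped on load).
Counts are converted to relative abundances per sample before testing.

The group comparison reports, per taxon, the percent change of the group-B
mean relative to group A and a one-sided equal-variance t test taken in the
direction of the observed change (anti-conservative by construction, since
the direction is data-driven; see the methods note).  Taxonomic flow for a
group of samples is summarized as a parent->child edge list across adjacent
ranks (a Sankey decomposition), with unclassified mass kept in explicit
"unclassified" children so that child weights always sum to the parent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "RANKS",
    "TaxonTable",
    "load_taxon_table",
    "aggregate_taxa",
    "compare_groups",
    "sankey_flows",
]

RANKS: Tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_PREFIX = re.compile(r"^[dkpcofgs]__")


def _clean_path(path: str) -> Tuple[str, ...]:
    parts = [_PREFIX.sub("", p.strip()) for p in str(path).split(";")]
    if len(parts) > len(RANKS):
        raise ValueError(f"taxonomy path has more than {len(RANKS)} ranks: {path!r}")
    parts += [""] * (len(RANKS) - len(parts))
    # empty ranks are only allowed as a contiguous tail
    seen_empty = False
    for p in parts:
        if p == "":
            seen_empty = True
        elif seen_empty:
            raise ValueError(f"taxonomy path has an internal gap: {path!r}")
    return tuple(parts)


@dataclass
class TaxonTable:
    """Taxa (rows, keyed by full taxonomy path) by samples (columns)."""

    abundances: pd.DataFrame  # index: 7-rank ';'-joined path

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def samples(self) -> list:
        return list(self.abundances.columns)

    def __len__(self) -> int:
        return len(self.abundances)

    def relative(self) -> "TaxonTable":
        """Normalize each sample to sum to 1 (no-op on an already relative table)."""
        totals = self.abundances.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total abundance")
        return TaxonTable(self.abundances / totals)

    def to_csv(self, path: Union[str, Path], sep: str = "\t") -> None:
        out = self.abundances.copy()
        out.insert(0, "taxonomy", out.index)
        out.to_csv(path, sep=sep, index=False)


def load_taxon_table(
    path: Union[str, Path], taxonomy_col: str = "taxonomy"
) -> TaxonTable:
    """Read a delimited taxon table with a semicolon-separated taxonomy column."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    if taxonomy_col not in frame.columns:
        raise ValueError(f"taxon table missing taxonomy column {taxonomy_col!r}")
    paths = [";".join(_clean_path(p)) for p in frame[taxonomy_col]]
    values = frame.drop(columns=[taxonomy_col]).astype(float)
    values.index = pd.Index(paths, name="taxonomy")
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=False).sum()
    return TaxonTable(values)


def aggregate_taxa(table: TaxonTable, rank: str) -> TaxonTable:
    """Sum abundances over all taxa sharing the taxonomy prefix up to ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    prefixes = [
        ";".join(str(p).split(";")[:depth]) for p in table.abundances.index
    ]
    grouped = table.abundances.groupby(prefixes, sort=False).sum()
    grouped.index.name = "taxonomy"
    return TaxonTable(grouped)


def compare_groups(
    table: TaxonTable,
    design: pd.DataFrame,
    factor: str = "genotype",
    group_a: str = "WT",
    group_b: str = "KO",
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon percent change of group B vs group A with a one-sided t test.

    Counts are first converted to relative abundances per sample.  The
    one-sided equal-variance t test is taken in the direction of the observed
    change; taxa with p below ``p_threshold`` are flagged.  Output is ranked
    by |percent change|.  A taxon with zero group-A mean has an undefined
    percent change and is flagged as such.
    """
    if factor not in design.columns:
        raise ValueError(f"design has no column {factor!r}")
    a_samples = design.loc[design[factor] == group_a, "sample_id"].tolist()
    b_samples = design.loc[design[factor] == group_b, "sample_id"].tolist()
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    rel = table.relative().abundances
    a = rel[a_samples].to_numpy(dtype=float)
    b = rel[b_samples].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    delta = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        percent_change = np.where(mean_a > 0, delta / mean_a * 100.0, np.nan)
    p_one = np.empty(len(rel))
    t_stat = np.empty(len(rel))
    for i in range(len(rel)):
        if a[i].var() == 0 and b[i].var() == 0:
            # degenerate data: at t = 0 the one-sided p is exactly 1/2
            t_stat[i] = 0.0
            p_one[i] = 0.5 if delta[i] == 0 else 0.0
            continue
        side = "greater" if delta[i] >= 0 else "less"
        res = stats.ttest_ind(b[i], a[i], equal_var=True, alternative=side)
        t_stat[i] = res.statistic if np.isfinite(res.statistic) else 0.0
        p_one[i] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    out = pd.DataFrame(
        {
            "mean_" + group_a: mean_a,
            "mean_" + group_b: mean_b,
            "percent_change": percent_change,
            "t_statistic": t_stat,
            "p_one_sided": p_one,
            "flagged": (p_one < p_threshold) & np.isfinite(percent_change),
            "undefined_baseline": ~np.isfinite(percent_change),
        },
        index=rel.index,
    )
    out = out.sort_values(
        "percent_change", key=lambda s: s.abs(), ascending=False, kind="mergesort"
    )
    return out


def sankey_flows(table: TaxonTable, samples: Sequence[str]) -> pd.DataFrame:
    """Parent->child edge list of group-mean abundance across adjacent ranks.

    Empty tail ranks are relabelled "unclassified" so that the weights of a
    node's children always sum to the node's own weight (mass conservation at
    every rank).
    """
    rel = table.relative().abundances[list(samples)]
    means = rel.mean(axis=1)
    filled = []
    for path in means.index:
        parts = [p if p else "unclassified" for p in str(path).split(";")]
        filled.append(parts)
    edges: Dict[Tuple[str, str], float] = {}
    for parts, weight in zip(filled, means.to_numpy()):
        for depth in range(1, len(RANKS)):
            parent = ";".join(parts[:depth])
            child = ";".join(parts[: depth + 1])
            edges[(parent, child)] = edges.get((parent, child), 0.0) + float(weight)
    out = pd.DataFrame(
        [(p, c, w) for (p, c), w in edges.items()],
        columns=["parent_taxon", "child_taxon", "weight"],
    )
    return out.sort_values(["parent_taxon", "child_taxon"], kind="mergesort").reset_index(
        drop=True
    )
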