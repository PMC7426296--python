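"""Per-compound quantification and differential statistics.

Identified peaks are summed into one row per compound (abundant species elute
over several peaks), log2-transformed after adding a small fudge factor (the
10th percentile of the stratum's values, taming fold changes of noisy
low-abundance rows), and compared between groups with a two-sample t test.
Multiple testing is corrected with Storey q-values; a compound is called
significant when q is at or below the threshold and the raw-scale fold change
is at least the minimal-change threshold in either direction
(max(Fc, 1/Fc) >= fc_threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .chemmass import CompoundDatabase
from .ident import Identification
from .peaktable import PeakTable

log = logging.getLogger(__name__)

__all__ = [
    "CompoundMatrix",
    "TransformSpec",
    "Contrast",
    "aggregate_by_compound",
    "load_compound_matrix",
    "log_transform",
    "differential_test",
    "storey_qvalues",
    "significance_filter",
    "report_tables",
    "run_differential",
]


@dataclass
class CompoundMatrix:
    """Summed raw peak areas: one row per identified compound, one column per
    biological sample.  ``info`` carries name, formula and class label."""

    values: pd.DataFrame
    info: pd.DataFrame
    stratum: str = ""

    def __post_init__(self) -> None:
        if len(self.values) and (self.values.to_numpy() < 0).any():
            raise ValueError("compound matrix values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def aggregate_by_compound(
    identifications: Sequence[Identification],
    peaks: PeakTable,
    db: Optional[CompoundDatabase] = None,
    stratum: str = "",
) -> CompoundMatrix:
    """Sum peak areas over all peaks sharing a compound identity, per sample.

    Only accepted identifications (status ``standard`` or ``assigned``)
    contribute; ambiguous-isomer and unassigned peaks are excluded.
    """
    rows: Dict[str, np.ndarray] = {}
    meta: Dict[str, Dict[str, str]] = {}
    for ident in identifications:
        if ident.status not in ("standard", "assigned"):
            continue
        compound_id = ident.compound_ids[0]
        area = peaks.areas.loc[ident.peak_id].to_numpy(dtype=float)
        if compound_id in rows:
            rows[compound_id] = rows[compound_id] + area
        else:
            rows[compound_id] = area.copy()
            meta[compound_id] = {"formula": ident.formula}
    if not rows:
        log.warning("no assigned peaks; compound matrix is empty")
        values = pd.DataFrame(columns=peaks.samples)
        info = pd.DataFrame(columns=["name", "formula", "class_label"])
        return CompoundMatrix(values, info, stratum)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=peaks.samples)
    values.index.name = "compound_id"
    info = pd.DataFrame.from_dict(meta, orient="index")
    info.index.name = "compound_id"
    if db is not None:
        lookup = db.frame.set_index("compound_id")
        info["name"] = lookup["name"].reindex(info.index)
        info["class_label"] = lookup["class_label"].reindex(info.index).fillna("others")
    else:
        info["name"] = info.index
        info["class_label"] = "others"
    return CompoundMatrix(values, info[["name", "formula", "class_label"]], stratum)


def load_compound_matrix(
    path: Union[str, Path],
    sample_columns: Optional[Sequence[str]] = None,
    stratum: str = "",
) -> CompoundMatrix:
    """Read an externally processed compound-level table from delimited text.

    Expected columns: ``compound_id`` plus optional ``name``, ``formula``,
    ``class_label``; every remaining (or explicitly listed) column is a
    sample.  This is the entry point for re-running the differential stage on
    tables produced outside this pipeline.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep).set_index("compound_id")
    info_cols = [c for c in ("name", "formula", "class_label") if c in frame.columns]
    if sample_columns is None:
        sample_columns = [c for c in frame.columns if c not in info_cols]
    values = frame[list(sample_columns)].astype(float)
    info = frame[info_cols].copy()
    if "name" not in info:
        info["name"] = info.index
    if "formula" not in info:
        info["formula"] = ""
    if "class_label" not in info:
        info["class_label"] = "others"
    return CompoundMatrix(values, info[["name", "formula", "class_label"]], stratum)


@dataclass(frozen=True)
class TransformSpec:
    """log2 transform metadata: fudge factor c (area units) and its rule."""

    fudge: float
    base: int = 2
    percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.fudge < 0:
            raise ValueError("fudge factor must be non-negative")


def log_transform(
    matrix: Union[CompoundMatrix, pd.DataFrame]
) -> Tuple[pd.DataFrame, TransformSpec]:
    """log2(value + c), with c the 10th percentile of the stratum's values.

    The percentile uses linear interpolation between order statistics.  An
    all-zero matrix would require log2(0) and is an error.
    """
    values = matrix.values if isinstance(matrix, CompoundMatrix) else matrix
    if values.size == 0:
        raise ValueError("cannot log-transform an empty matrix")
    c = float(np.percentile(values.to_numpy(dtype=float).ravel(), 10.0))
    if c == 0 and (values.to_numpy() == 0).any():
        raise ValueError(
            "fudge factor is 0 and the matrix contains zeros; log2(0) undefined"
        )
    transformed = np.log2(values + c)
    return transformed, TransformSpec(fudge=c)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: numerator vs denominator levels of a factor.

    ``within`` optionally restricts the samples first (e.g. compare genotypes
    within treatment == "none").  Fold changes are reported as
    numerator / denominator.
    """

    factor: str
    numerator: str
    denominator: str
    within: Optional[Dict[str, str]] = None

    @property
    def name(self) -> str:
        tag = f"{self.numerator}_vs_{self.denominator}"
        if self.within:
            tag += "_" + "_".join(f"{k}-{v}" for k, v in sorted(self.within.items()))
        return tag

    def split(self, design: pd.DataFrame) -> Tuple[list, list]:
        df = design
        if self.within:
            for col, val in self.within.items():
                if col not in df.columns:
                    raise ValueError(f"design has no column {col!r}")
                df = df[df[col] == val]
        if self.factor not in df.columns:
            raise ValueError(f"design has no column {self.factor!r}")
        num = df.loc[df[self.factor] == self.numerator, "sample_id"].tolist()
        den = df.loc[df[self.factor] == self.denominator, "sample_id"].tolist()
        return num, den


def differential_test(
    transformed: pd.DataFrame,
    raw: pd.DataFrame,
    design: pd.DataFrame,
    contrast: Contrast,
    variant: str = "student",
    fc_means: str = "arithmetic",
) -> pd.DataFrame:
    """Per-compound two-sample t test on transformed values.

    ``variant`` selects the equal-variance t test (``"student"``, the primary
    path), Welch (``"welch"``) or a paired test (``"paired"``, requiring equal
    group sizes in matching order).  Fold change Fc is the ratio of raw-scale
    group means, numerator/denominator; ``fc_means="geometric"`` switches to
    geometric group means (zero areas collapse the geometric mean to zero).
    Compounds with zero within-group variance in both arms and unequal means
    get an undefined p (flagged).
    """
    num, den = contrast.split(design)
    if len(num) < 2 or len(den) < 2:
        raise ValueError(
            f"each contrast arm needs >= 2 biological replicates "
            f"(got {len(num)} vs {len(den)})"
        )
    x = transformed[num].to_numpy(dtype=float)
    y = transformed[den].to_numpy(dtype=float)
    if variant == "student":
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    elif variant == "welch":
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    elif variant == "paired":
        if x.shape[1] != y.shape[1]:
            raise ValueError("paired test requires equal group sizes")
        t, p = stats.ttest_rel(x, y, axis=1)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    equal_means = np.isclose(x.mean(axis=1), y.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, np.nan, p)

    if fc_means == "arithmetic":
        mean_num = raw[num].mean(axis=1).to_numpy(dtype=float)
        mean_den = raw[den].mean(axis=1).to_numpy(dtype=float)
    elif fc_means == "geometric":
        with np.errstate(divide="ignore"):
            mean_num = np.exp(np.log(raw[num].to_numpy(dtype=float)).mean(axis=1))
            mean_den = np.exp(np.log(raw[den].to_numpy(dtype=float)).mean(axis=1))
    else:
        raise ValueError(f"fc_means must be arithmetic|geometric, got {fc_means!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_num / mean_den
        log2fc = np.log2(fc)
    results = pd.DataFrame(
        {
            "mean_numerator": mean_num,
            "mean_denominator": mean_den,
            "fold_change": fc,
            "log2fc": log2fc,
            "t_statistic": t,
            "p_value": p,
            "degenerate": degenerate & ~equal_means,
        },
        index=transformed.index,
    )
    results.index.name = "compound_id"
    return results


def storey_qvalues(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed-lambda pi0 estimate.

    pi0 = #{p > lambda} / (m (1 - lambda)), with the count floored at 1 and
    the estimate capped at 1; q_(i) = min_{j >= i} pi0 * m * p_(j) / j over
    the sorted p-values.  Output is monotone in p and lies in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    m = p.size
    pi0 = min(1.0, max(int((p > lam).sum()), 1) / (m * (1.0 - lam)))
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    raw = pi0 * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def significance_filter(
    results: pd.DataFrame,
    q_threshold: float = 0.15,
    fc_threshold: float = 1.2,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Flag compounds with q <= q_threshold and max(Fc, 1/Fc) >= fc_threshold.

    Adds ``significant`` and ``direction`` ("up"/"down"/"") columns and
    returns counts of up- and downregulated compounds.
    """
    if "q_value" not in results.columns:
        raise ValueError("results must contain a q_value column (run storey_qvalues)")
    out = results.copy()
    fc = out["fold_change"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.maximum(fc, 1.0 / fc)
    sig = (out["q_value"].to_numpy() <= q_threshold) & (change >= fc_threshold)
    sig &= np.isfinite(fc)
    out["significant"] = sig
    out["direction"] = np.where(sig & (fc >= 1), "up", np.where(sig, "down", ""))
    counts = {
        "n_significant": int(sig.sum()),
        "n_up": int((out["direction"] == "up").sum()),
        "n_down": int((out["direction"] == "down").sum()),
        "n_tested": int(len(out)),
    }
    return out, counts


def report_tables(
    results: pd.DataFrame, transformed: Optional[pd.DataFrame] = None
) -> Dict[str, pd.DataFrame]:
    """Volcano table, heatmap matrix of significant compounds, class summary.

    The volcano table carries log2 fold change and -log10 p; the heatmap
    matrix holds transformed values of significant compounds grouped by class;
    the class summary gives the fraction of significant compounds per class
    (fractions sum to 1 whenever anything is significant).
    """
    if "significant" not in results.columns:
        raise ValueError("run significance_filter before report_tables")
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(results["p_value"].to_numpy(dtype=float))
    volcano = pd.DataFrame(
        {
            "log2fc": results["log2fc"],
            "neg_log10_p": neg_log10_p,
            "significant": results["significant"],
        },
        index=results.index,
    )
    sig = results[results["significant"]]
    if "class_label" in sig.columns:
        sig_sorted = sig.sort_values(["class_label"], kind="mergesort")
    else:
        sig_sorted = sig
    if transformed is not None and len(sig_sorted):
        heatmap = transformed.loc[sig_sorted.index]
    else:
        heatmap = pd.DataFrame(
            index=sig_sorted.index,
            columns=transformed.columns if transformed is not None else [],
        )
    if len(sig) and "class_label" in sig.columns:
        counts = sig["class_label"].value_counts()
        class_summary = pd.DataFrame(
            {"n_significant": counts, "fraction": counts / counts.sum()}
        )
    else:
        class_summary = pd.DataFrame(columns=["n_significant", "fraction"])
    class_summary.index.name = "class_label"
    return {"volcano": volcano, "heatmap": heatmap, "class_summary": class_summary}


def run_differential(
    matrix: CompoundMatrix,
    design: pd.DataFrame,
    contrast: Contrast,
    q_threshold: float = 0.15,
    fc_threshold: float = 1.2,
    lam: float = 0.5,
    variant: str = "student",
    fc_means: str = "arithmetic",
) -> Tuple[pd.DataFrame, Dict[str, int], Dict[str, pd.DataFrame], TransformSpec]:
    """Transform, test, correct and filter one contrast on one stratum."""
    transformed, spec = log_transform(matrix)
    results = differential_test(
        transformed, matrix.values, design, contrast, variant, fc_means
    )
    valid = results["p_value"].notna()
    q = np.full(len(results), np.nan)
    if valid.any():
        q[valid.to_numpy()] = storey_qvalues(results.loc[valid, "p_value"], lam=lam)
    results["q_value"] = q
    results = results.join(matrix.info)
    results, counts = significance_filter(results, q_threshold, fc_threshold)
    tables = report_tables(results, transformed)
    return results, counts, tables, spec
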