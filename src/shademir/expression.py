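"""Count normalization and regulation classification.

miRNA regulation between two conditions (sun vs shade) is summarized as
log2 fold change of median-of-ratios-normalized means, with a permissive
two-sided Poisson-ratio test.  Classes follow the shortlist conventions:
up / down at |log2FC| >= 1 (inclusive) with p <= 0.9, unique_sun /
unique_shade for features with raw zeros in the other condition, neutral
otherwise.  Target transcripts are classified at the microarray cutoff of
|log2FC| >= 0.25 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulationCall",
    "ExpressionRecord",
    "NormalizationError",
    "size_factors",
    "classify_mirna",
    "classify_targets",
    "ddct",
    "poisson_ratio_test",
]

REG_CLASSES = ("up", "down", "neutral", "unique_sun", "unique_shade", "undetected")


class NormalizationError(ValueError):
    pass


@dataclass
class RegulationCall:
    feature_id: str
    log2fc: float
    p_value: float
    reg_class: str
    fc_cutoff: float = 1.0
    p_cutoff: float = 0.9
    unique_min_count: float = 5.0


@dataclass
class ExpressionRecord:
    transcript_id: str
    log2fc: float
    expr_class: str  # up | down | neutral


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scale factor per library (column).

    For each feature with a positive geometric mean across libraries, the
    ratio count / geometric-mean is formed; the factor of a library is the
    median of its ratios.
    """
    if matrix.empty or not (matrix.to_numpy() > 0).any():
        raise NormalizationError("all-zero count matrix cannot be normalized")
    counts = matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    positive = np.isfinite(logs).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no feature has nonzero counts in every library"
        )
    log_gm = logs[positive].mean(axis=1, keepdims=True)
    ratios = np.exp(logs[positive] - log_gm)
    factors = np.median(ratios, axis=0)
    if not (factors > 0).all():
        raise NormalizationError("non-positive size factor")
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def poisson_ratio_test(sum_a: float, sum_b: float) -> float:
    """Two-sided Poisson ratio test via the conditional binomial: given the
    total, the count of one condition is Binomial(total, 1/2) under H0."""
    x = int(round(sum_a))
    n = x + int(round(sum_b))
    if n == 0:
        return 1.0
    return float(stats.binomtest(x, n, 0.5).pvalue)


def classify_mirna(
    matrix: pd.DataFrame,
    conditions: Mapping[str, str],
    fc_cutoff: float = 1.0,
    p_cutoff: float = 0.9,
    unique_min_count: float = 5.0,
    pseudocount: float = 1.0,
    test: Callable[[float, float], float] = poisson_ratio_test,
) -> list[RegulationCall]:
    """Classify each feature of a two-condition count matrix.

    ``conditions`` maps library (column) name -> "sun" | "shade".
    log2FC is shade over sun on normalized means with a pseudocount;
    unique_* classes are decided on raw zeros and take precedence.
    """
    labels = set(conditions.values())
    if labels != {"sun", "shade"}:
        raise ValueError(f"condition labels must be sun/shade, got {sorted(labels)}")
    missing = [c for c in matrix.columns if c not in conditions]
    if missing:
        raise ValueError(f"libraries without condition label: {missing}")
    sun_libs = [c for c in matrix.columns if conditions[c] == "sun"]
    shade_libs = [c for c in matrix.columns if conditions[c] == "shade"]
    factors = size_factors(matrix)
    norm = matrix / factors
    calls: list[RegulationCall] = []
    for fid, row in matrix.iterrows():
        raw_sun = row[sun_libs].to_numpy(dtype=float)
        raw_shade = row[shade_libs].to_numpy(dtype=float)
        n_sun = norm.loc[fid, sun_libs].to_numpy(dtype=float)
        n_shade = norm.loc[fid, shade_libs].to_numpy(dtype=float)
        mean_sun, mean_shade = n_sun.mean(), n_shade.mean()
        log2fc = float(np.log2((mean_shade + pseudocount) / (mean_sun + pseudocount)))
        p = test(n_shade.sum(), n_sun.sum())
        if not raw_sun.any() and not raw_shade.any():
            cls = "undetected"
        elif not raw_sun.any() and mean_shade >= unique_min_count:
            cls = "unique_shade"
        elif not raw_shade.any() and mean_sun >= unique_min_count:
            cls = "unique_sun"
        elif log2fc >= fc_cutoff and p <= p_cutoff:
            cls = "up"
        elif log2fc <= -fc_cutoff and p <= p_cutoff:
            cls = "down"
        else:
            cls = "neutral"
        calls.append(
            RegulationCall(str(fid), log2fc, p, cls, fc_cutoff, p_cutoff, unique_min_count)
        )
    return calls


def classify_targets(
    table: pd.DataFrame | Mapping[str, float],
    cutoff: float = 0.25,
) -> list[ExpressionRecord]:
    """Threshold transcript log2FC at +/-cutoff (inclusive).

    ``table`` is a DataFrame with columns transcript_id / log2fc (or an
    id -> log2fc mapping).  Duplicate transcript ids are an input error.
    """
    if isinstance(table, pd.DataFrame):
        ids = table["transcript_id"].astype(str).tolist()
        fcs = table["log2fc"].astype(float).tolist()
    else:
        ids = [str(k) for k in table]
        fcs = [float(v) for v in table.values()]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids: {dupes}")
    records = []
    for tid, fc in zip(ids, fcs):
        if fc >= cutoff:
            cls = "up"
        elif fc <= -cutoff:
            cls = "down"
        else:
            cls = "neutral"
        records.append(ExpressionRecord(tid, fc, cls))
    return records


def ddct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method."""
    for v in (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("cycle numbers must be finite")
    ddct_val = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_val))


def calls_to_frame(calls: Sequence[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.feature_id, c.log2fc, c.p_value, c.reg_class) for c in calls],
        columns=["feature_id", "log2fc", "p_value", "reg_class"],
    )
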