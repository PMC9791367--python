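"""Per-focal-gene summaries of the cis-vs-trans pleiotropy contrast and the
associated statistical tests.

For each focal gene the contrast is the difference between the median
pleiotropy of its trans-regulatory deletions and the pleiotropy of its own
(cis) deletion; a positive difference means the typical trans deletion is
the more pleiotropic one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import stats

from .errors import ConfigError, ValidationError
from .pleiotropy import CisTransPair, PleiotropyRecord

logger = logging.getLogger(__name__)

MEASURES = ("count", "parallel_count", "euclidean")


@dataclass(frozen=True)
class FocalSummary:
    focal: str
    cis_value: float
    median_trans_value: float
    difference: float  # median_trans_value - cis_value
    n_trans: int


def _pair_value(pair: CisTransPair, measure: str) -> float:
    if measure == "count":
        return float(pair.trans_count)
    if measure == "parallel_count":
        return float(pair.parallel_count)
    if measure == "euclidean":
        return float(pair.trans_euclidean)
    raise ConfigError(f"unknown measure {measure!r}")


def _cis_value(record: PleiotropyRecord, measure: str) -> float:
    if measure in ("count", "parallel_count"):
        return float(record.cis_count)
    if measure == "euclidean":
        return float(record.cis_euclidean)
    raise ConfigError(f"unknown measure {measure!r}")


def focal_summaries(
    pairs: Iterable[CisTransPair],
    records: Iterable[PleiotropyRecord],
    measure: str = "count",
) -> list[FocalSummary]:
    """One summary per focal gene: cis value, median trans value, difference.

    The median is the standard midpoint-of-two for an even number of trans
    regulators. Focal genes present in ``records`` but with zero pairs are
    excluded with a warning (no contrast exists for them).
    """
    by_focal: dict[str, list[float]] = {}
    for pair in pairs:
        by_focal.setdefault(pair.focal, []).append(_pair_value(pair, measure))
    rec_map = {r.gene: r for r in records}
    missing = set(by_focal) - set(rec_map)
    if missing:
        raise ValidationError(
            f"{len(missing)} focal genes lack a pleiotropy record, "
            f"e.g. {sorted(missing)[:3]}"
        )
    skipped = [g for g in rec_map if g not in by_focal]
    if skipped:
        logger.warning(
            "%d focal genes have zero pairs under this restriction and are "
            "excluded from summaries", len(skipped),
        )
    summaries = []
    for focal in rec_map:
        if focal not in by_focal:
            continue
        trans_vals = by_focal[focal]
        cis = _cis_value(rec_map[focal], measure)
        med = float(np.median(trans_vals))
        summaries.append(
            FocalSummary(
                focal=focal,
                cis_value=cis,
                median_trans_value=med,
                difference=med - cis,
                n_trans=len(trans_vals),
            )
        )
    return summaries


def one_sided_difference_test(
    differences: Sequence[float],
) -> tuple[float, int, float]:
    """One-sample t-test of mean(differences) > 0; returns (t, df, upper p)."""
    arr = np.asarray(list(differences), dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 differences for a t-test")
    if np.allclose(arr, arr[0]):
        raise ValidationError(
            "zero variance in differences; use a sign or permutation test"
        )
    res = stats.ttest_1samp(arr, 0.0, alternative="greater")
    return float(res.statistic), int(arr.size - 1), float(res.pvalue)


def welch_difference_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t-test, two-sided.

    Identical samples are a well-defined no-difference case and return
    (0, df, 1); degenerate variance in *both* samples otherwise is an error.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples must have size >= 2")
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValidationError("degenerate variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def proportion_cis_greater(
    items: Union[Sequence[FocalSummary], Sequence[CisTransPair]],
    mode: str = "per_focal",
    measure: str = "count",
    records: Iterable[PleiotropyRecord] = (),
) -> tuple[int, int, float]:
    """Fraction of focal genes (or pairs) whose cis deletion is *strictly*
    more pleiotropic than the trans side; ties count as not greater.

    ``per_focal`` expects FocalSummary items and compares cis to the median
    trans value. ``per_pair`` expects CisTransPair items plus the per-gene
    records, and compares cis to each pair's trans value.
    """
    items = list(items)
    if not items:
        raise ValidationError("empty input")
    if mode == "per_focal":
        num = sum(1 for s in items if s.cis_value > s.median_trans_value)
        den = len(items)
    elif mode == "per_pair":
        rec_map = {r.gene: r for r in records}
        num = 0
        for pair in items:
            cis = _cis_value(rec_map[pair.focal], measure)
            if cis > _pair_value(pair, measure):
                num += 1
        den = len(items)
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    return num, den, num / den
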