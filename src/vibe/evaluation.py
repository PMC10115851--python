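"""Overlap metrics for segmentation validation.

Given an automatic mask A and a reference (e.g. manually segmented)
mask M on the same voxel grid of total size V:

    Dice        = 2|A ∩ M| / (|A| + |M|)
    Jaccard     = |A ∩ M| / |A ∪ M|
    Sensitivity = |A ∩ M| / |M|
    Specificity = (V - |A ∪ M|) / (V - |M|)

All four are computed with integer voxel counts until the final
division.  Dice and Jaccard satisfy J = D / (2 - D).  Specificity is
near 1 whenever the brain occupies a small fraction of the image, so it
is useful for comparisons, not as an absolute quality score.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .core import Volume
from .errors import GeometryError, UndefinedMetricError

__all__ = [
    "OverlapCounts",
    "dice",
    "evaluate_cohort",
    "evaluate_masks",
    "jaccard",
    "sensitivity",
    "specificity",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Voxel counts underlying all four metrics."""

    a: int       # |A|
    m: int       # |M|
    am: int      # |A ∩ M|
    v: int       # total voxels

    def __post_init__(self) -> None:
        if min(self.a, self.m, self.am, self.v) < 0:
            raise UndefinedMetricError("overlap counts must be non-negative")
        if self.am > min(self.a, self.m) or max(self.a, self.m) > self.v:
            raise UndefinedMetricError(f"inconsistent overlap counts {self}")

    @property
    def union(self) -> int:
        return self.a + self.m - self.am

    @classmethod
    def from_masks(cls, a_mask, m_mask) -> "OverlapCounts":
        a = _mask_array(a_mask)
        m = _mask_array(m_mask)
        if a.shape != m.shape:
            raise GeometryError(f"mask shapes differ: {a.shape} vs {m.shape}")
        return cls(
            a=int(np.count_nonzero(a)),
            m=int(np.count_nonzero(m)),
            am=int(np.count_nonzero(a & m)),
            v=int(a.size),
        )


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, Volume):
        return mask.data > 0
    return np.asarray(mask) > 0


def _counts(a, m) -> OverlapCounts:
    if isinstance(a, OverlapCounts):
        return a
    return OverlapCounts.from_masks(a, m)


def dice(a, m=None) -> float:
    """Dice similarity coefficient; undefined when both masks are empty."""
    c = _counts(a, m)
    if c.a + c.m == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    return 2.0 * c.am / (c.a + c.m)


def jaccard(a, m=None) -> float:
    """Jaccard index; undefined when both masks are empty."""
    c = _counts(a, m)
    if c.union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks are empty")
    return c.am / c.union


def sensitivity(a, m=None) -> float:
    """Fraction of reference voxels captured; undefined for an empty reference."""
    c = _counts(a, m)
    if c.m == 0:
        raise UndefinedMetricError("Sensitivity undefined: reference mask is empty")
    return c.am / c.m


def specificity(a, m=None, v: int | None = None) -> float:
    """Fraction of background voxels correctly excluded."""
    c = _counts(a, m)
    total = int(v) if v is not None else c.v
    if total < c.union:
        raise UndefinedMetricError("total voxel count smaller than |A ∪ M|")
    if total <= c.m:
        raise UndefinedMetricError("Specificity undefined: reference fills the image")
    return (total - c.union) / (total - c.m)


def evaluate_masks(a, m) -> dict[str, float]:
    """All four metrics for one mask pair, as a plain dict."""
    c = OverlapCounts.from_masks(a, m)
    return {
        "dice": dice(c),
        "jaccard": jaccard(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
    }


_METRICS = ("dice", "jaccard", "sensitivity", "specificity")


def evaluate_cohort(pairs, case_ids=None, csv_path=None):
    """Per-case metrics plus cohort mean and sample (n-1) standard deviation.

    ``pairs`` is a sequence of (A, M) mask pairs.  Cases on which a
    metric is undefined are recorded with an error message and excluded
    from the aggregates; the number of such cases is reported under
    ``n_errors``.  Returns ``(records, summary)``; when ``csv_path`` is
    given the per-case table is also written as CSV with columns
    case_id, dice, jaccard, sensitivity, specificity.
    """
    pairs = list(pairs)
    if not pairs:
        raise UndefinedMetricError("evaluate_cohort needs at least one mask pair")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(pairs))]
    records = []
    for cid, (a, m) in zip(case_ids, pairs):
        rec: dict = {"case_id": cid}
        try:
            rec.update(evaluate_masks(a, m))
        except (UndefinedMetricError, GeometryError) as exc:
            rec["error"] = str(exc)
        records.append(rec)

    valid = [r for r in records if "error" not in r]
    summary: dict = {"n": len(valid), "n_errors": len(records) - len(valid)}
    for metric in _METRICS:
        vals = [r[metric] for r in valid]
        if vals:
            summary[f"{metric}_mean"] = float(np.mean(vals))
            summary[f"{metric}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        else:
            summary[f"{metric}_mean"] = math.nan
            summary[f"{metric}_sd"] = math.nan

    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["case_id", *_METRICS, "error"])
            writer.writeheader()
            for rec in records:
                writer.writerow({k: rec.get(k, "") for k in ["case_id", *_METRICS, "error"]})
    return records, summary
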