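"""Concordance metrics for CNV call sets and raw copy-number tracks.

Two regions on the same chromosome are *concordant* when more than half of
either one is covered by the other (strict inequality: exactly half does not
match).  On top of that rule sit the call-set metrics:

* precision — fraction of predicted regions supported by at least one truth
  region; recall — fraction of truth regions recovered by at least one
  prediction;
* batch-stability ratio — for several call sets of the same sample obtained
  under different reference batches, regions are clustered by single linkage
  under the concordance relation; U counts clusters, I counts clusters that
  contain a region from every set, and I/U measures how batch-independent
  the calling is;
* rank (Mann-Whitney) AUC for single-locus classification of raw copy
  numbers, ties counted 1/2;
* track variance after rescaling a track to a target median (2 for a
  diploid benchmark, 1 for a haploid one).

Reported percentages and ratios round half-up to 2 decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateTrackError, InvalidInputError, InvalidRegionError


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if (
            not isinstance(self.start, (int, np.integer))
            or not isinstance(self.end, (int, np.integer))
            or self.start >= self.end
        ):
            raise InvalidRegionError(
                f"malformed region {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def as_region(r) -> Region:
    if isinstance(r, Region):
        return r
    chrom, start, end, *rest = r
    return Region(chrom, int(start), int(end), rest[0] if rest else "")


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (matching printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def concordant(a, b) -> bool:
    """More than 50% of either region covered by the other (strict)."""
    a, b = as_region(a), as_region(b)
    if a.chrom != b.chrom:
        return False
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return overlap / len(a) > 0.5 or overlap / len(b) > 0.5


@dataclass
class EvaluationReport:
    """Counts and ratios of a predicted-vs-truth call-set comparison."""

    n_predicted: int
    n_supported: int
    n_true: int
    n_recovered: int

    @property
    def precision(self) -> float:
        return self.n_supported / self.n_predicted if self.n_predicted else math.nan

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_true if self.n_true else math.nan

    @property
    def precision_percent(self) -> float:
        return round2(100.0 * self.precision)

    @property
    def recall_percent(self) -> float:
        return round2(100.0 * self.recall)

    def to_dict(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_supported": self.n_supported,
            "n_true": self.n_true,
            "n_recovered": self.n_recovered,
            "precision": self.precision,
            "recall": self.recall,
            "precision_percent": self.precision_percent,
            "recall_percent": self.recall_percent,
        }


def precision_recall(predicted, truth) -> EvaluationReport:
    """Support/recovery counts under the >50% concordance rule.

    A predicted region is *supported* if concordant with any truth region; a
    truth region is *recovered* if concordant with any prediction.  Empty
    sets leave the corresponding ratio undefined (NaN, with a warning).
    """
    pred = [as_region(r) for r in predicted]
    true = [as_region(r) for r in truth]
    by_chrom: dict[str, list[Region]] = {}
    for t in true:
        by_chrom.setdefault(t.chrom, []).append(t)
    supported = 0
    recovered_flags = {id(t): False for t in true}
    for p in pred:
        hit = False
        for t in by_chrom.get(p.chrom, ()):
            if concordant(p, t):
                hit = True
                recovered_flags[id(t)] = True
        supported += hit
    if not pred:
        warnings.warn("no predicted regions: precision undefined", stacklevel=2)
    if not true:
        warnings.warn("no truth regions: recall undefined", stacklevel=2)
    return EvaluationReport(
        n_predicted=len(pred),
        n_supported=supported,
        n_true=len(true),
        n_recovered=sum(recovered_flags.values()),
    )


def iou_ratio(intersection: int, union: int) -> float:
    """Intersection/union count ratio, rounded as printed (2 decimals)."""
    if union <= 0:
        raise InvalidInputError("union count must be positive")
    return round2(intersection / union)


def batch_stability_ratio(call_sets) -> tuple[int, int, float]:
    """(I, U, I/U) over call sets of one sample from different batches.

    Regions from all sets are merged and clustered by single linkage under
    the concordance relation.  U is the number of clusters; I the number of
    clusters represented in EVERY set.
    """
    sets = [[as_region(r) for r in s] for s in call_sets]
    if len(sets) < 2:
        raise InvalidInputError("need at least 2 call sets")
    tagged = [(i, r) for i, s in enumerate(sets) for r in s]
    if not tagged:
        warnings.warn("all call sets empty: ratio undefined", stacklevel=2)
        return 0, 0, math.nan
    n = len(tagged)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if concordant(tagged[i][1], tagged[j][1]):
                parent[find(i)] = find(j)

    clusters: dict[int, set[int]] = {}
    for idx, (set_idx, _) in enumerate(tagged):
        clusters.setdefault(find(idx), set()).add(set_idx)
    U = len(clusters)
    I = sum(1 for members in clusters.values() if len(members) == len(sets))
    return I, U, iou_ratio(I, U)


def roc_auc(scores_positive, scores_negative) -> float:
    """Mann-Whitney AUC with ties counted 1/2.

    Equals the area under the ROC curve obtained by sweeping a threshold on
    the score and calling "positive" at score >= threshold.
    """
    pos = np.asarray(list(scores_positive), dtype=float)
    neg = np.asarray(list(scores_negative), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both score lists must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise InvalidInputError("scores must be finite")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def track_variance(track, scale_to_median: float = 2.0) -> float:
    """Sample variance of a raw CN track after rescaling its median.

    Accepts a :class:`~wavecnv.normalization.RawCNTrack` or a plain array.
    The track is multiplied so its median equals ``scale_to_median`` (2 for
    a diploid benchmark, 1 for haploid), then the n-1 variance is returned.
    """
    values = np.asarray(getattr(track, "values", track), dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty track")
    med = float(np.median(values))
    if med <= 0 or not np.isfinite(med):
        raise DegenerateTrackError("track median must be positive to rescale")
    scaled = values * (scale_to_median / med)
    return float(np.var(scaled, ddof=1)) if values.size > 1 else 0.0
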