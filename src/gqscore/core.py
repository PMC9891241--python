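"""The GQS scoring engine.

A genomic region's quality is judged by how well each SNP's association
significance agrees with the significance predicted from its linkage
disequilibrium (LD) with the region's index SNP (the lowest-P variant).
The prediction is a straight line through the origin in the
(r², −log10 P) plane, anchored at the index SNP:

    p_hat = r² · p_index

For each SNP the residual e = p_obs − p_hat and the ratio S = e / p_hat
measure the fraction of signal gained (S > 0) or lost (S < 0) relative to
expectation.  SNPs in strong LD (r² > 0.4) that lose more signal than a
linear drop threshold allows are outliers; the region score is

    GQS = 1 − (max outlier distance to the threshold line) /
              (worst-case distance, from the point of total loss at r² = 1)

so GQS = 1 means no outliers, values in [0, 1) grade how close the worst
outlier comes to total signal loss, and GQS = −1 flags a region with no
SNP in sufficient LD to support the index at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .exceptions import DegenerateRegionError, VariantLookupError

__all__ = [
    "DropThreshold",
    "ScoredSNP",
    "RegionResult",
    "neg_log10_p",
    "predict_logp",
    "residual_and_ratio",
    "threshold_loss",
    "classify_outlier",
    "perp_distance",
    "band_assignment",
    "naive_flag",
    "score_region",
    "gqs_region",
    "rescore_with_index",
]

#: |S| cut points separating the 68 / 95 / 99 % annotation bands.
BAND_EDGES = (0.68, 0.95, 0.99)
BAND_NAMES = ("within68", "within95", "within99", "beyond99")

#: Loss fraction above which the naive single-SNP flag fires.
NAIVE_LOSS_CUTOFF = 0.75

#: Smallest P accepted before clamping (so −log10 P stays finite).
MIN_P = 5e-324


@dataclass(frozen=True)
class DropThreshold:
    """Linear outlier boundary in the (r², signal-loss) plane.

    The default runs from 100 % loss at r² = 0.4 down to 40 % loss at
    r² = 1.0 (i.e. loss = 1.4 − r²).  SNPs with r² at or below
    ``r2_floor`` are considered too variable to be informative and are
    never outliers.
    """

    r2_floor: float = 0.4
    loss_at_floor: float = 1.0
    loss_at_one: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_floor < 1.0:
            raise ValueError(f"r2_floor must be in (0, 1), got {self.r2_floor}")
        if not 0.0 < self.loss_at_one <= self.loss_at_floor <= 1.0:
            raise ValueError(
                "need 0 < loss_at_one <= loss_at_floor <= 1, got "
                f"loss_at_one={self.loss_at_one}, loss_at_floor={self.loss_at_floor}"
            )

    @property
    def slope(self) -> float:
        return (self.loss_at_one - self.loss_at_floor) / (1.0 - self.r2_floor)

    def loss_at(self, r2: float) -> float:
        """Threshold loss at ``r2`` (linear interpolation; r2 >= r2_floor)."""
        if r2 < self.r2_floor:
            raise ValueError(
                f"threshold undefined below the r2 floor ({r2} < {self.r2_floor})"
            )
        return self.loss_at_floor + self.slope * (r2 - self.r2_floor)

    def distance(self, r2: float, loss: float) -> float:
        """Perpendicular (Euclidean point-to-line) distance from (r2, loss)."""
        return abs(loss - self.loss_at(r2)) / math.sqrt(1.0 + self.slope**2)

    @property
    def worst_case_distance(self) -> float:
        """Distance from the total-loss-at-complete-LD corner (1, 1)."""
        return self.distance(1.0, 1.0)


@dataclass(frozen=True)
class ScoredSNP:
    """One region member's full GQS bookkeeping."""

    var_id: str
    r2: float
    p_obs: float  # observed −log10 P
    p_hat: float  # predicted −log10 P
    e: float  # residual p_obs − p_hat
    s: float  # ratio e / p_hat
    loss: float  # max(0, −s), fraction of expected signal lost
    band: str  # annotation band by |s|
    is_outlier: bool
    perp_dist: float  # distance to the drop threshold (0 unless outlier)


@dataclass
class RegionResult:
    """Per-region outcome: the scored members and the summary GQS."""

    index_id: str
    index_p: float
    scored: list[ScoredSNP]
    n_outliers: int
    max_loss_dist: float  # strongest outlier's distance (segment c–d)
    worst_case_dist: float  # total-loss distance (segment a–b)
    gqs: float
    strongest_outlier: str | None = None
    secondary_signal_ids: list[str] = field(default_factory=list)
    region: object | None = None  # RegionSpec when scored via the pipeline

    @property
    def n_scored(self) -> int:
        return len(self.scored)


def neg_log10_p(p: float) -> float:
    """−log10 of a P-value, clamping non-positive P to the float floor.

    Huge meta-analyses legitimately underflow double precision (P = 0 in
    the file); clamping keeps −log10 P finite rather than discarding the
    strongest signals.
    """
    if p > 1.0:
        raise ValueError(f"P-value {p} > 1")
    if p <= 0.0 or p < MIN_P:
        p = MIN_P
    return -math.log10(p)


def predict_logp(r2: float, index_logp: float) -> float:
    """Predicted −log10 P: the origin-anchored line p_hat = r² · p_index."""
    if index_logp <= 0.0:
        raise DegenerateRegionError(
            "index SNP has P = 1 (zero −log10 P); no regression line exists"
        )
    if not 0.0 < r2 <= 1.0:
        raise ValueError(f"r2 must be in (0, 1], got {r2}")
    return r2 * index_logp


def residual_and_ratio(p_obs: float, p_hat: float) -> tuple[float, float]:
    """Residual e = p_obs − p_hat and ratio S = e / p_hat.

    S >= −1 always, since p_obs >= 0; S = −1 is total signal loss.
    """
    if p_hat <= 0.0:
        raise ValueError(f"p_hat must be positive, got {p_hat}")
    if p_obs < 0.0:
        raise ValueError(f"p_obs must be non-negative, got {p_obs}")
    e = p_obs - p_hat
    return e, e / p_hat


def threshold_loss(r2: float, thr: DropThreshold = DropThreshold()) -> float:
    """Threshold loss at ``r2``; with defaults this is 1.4 − r²."""
    return thr.loss_at(r2)


def perp_distance(r2: float, loss: float, thr: DropThreshold = DropThreshold()) -> float:
    """Euclidean distance from the point (r², loss) to the threshold line."""
    return thr.distance(r2, loss)


def band_assignment(s: float) -> str:
    """Annotation band from |S|: within68 / within95 / within99 / beyond99.

    Bands are symmetric in sign (gain-side SNPs band identically) and are
    used for plots and tables only — they never enter the GQS.
    """
    a = abs(s)
    for edge, name in zip(BAND_EDGES, BAND_NAMES):
        if a <= edge:
            return name
    return BAND_NAMES[-1]


def naive_flag(s: float) -> bool:
    """Naive single-SNP screen: losing strictly more than 75 % of signal."""
    return max(0.0, -s) > NAIVE_LOSS_CUTOFF


def classify_outlier(r2: float, loss: float, thr: DropThreshold = DropThreshold()) -> bool:
    """True iff the SNP sits strictly above the drop threshold.

    Requires r² strictly above the floor; SNPs that gain signal
    (loss = 0) are never outliers — gains hint at secondary independent
    signals, handled by re-indexing, not by the score.
    """
    if r2 <= thr.r2_floor:
        return False
    return loss > thr.loss_at(r2)


def _score_one(
    var_id: str,
    r2: float,
    p_obs: float,
    index_logp: float,
    thr: DropThreshold,
) -> ScoredSNP:
    p_hat = predict_logp(r2, index_logp)
    e, s = residual_and_ratio(p_obs, p_hat)
    loss = max(0.0, -s)
    outlier = classify_outlier(r2, loss, thr)
    dist = thr.distance(r2, loss) if outlier else 0.0
    return ScoredSNP(
        var_id=var_id,
        r2=r2,
        p_obs=p_obs,
        p_hat=p_hat,
        e=e,
        s=s,
        loss=loss,
        band=band_assignment(s),
        is_outlier=outlier,
        perp_dist=dist,
    )


def gqs_region(
    scored: Sequence[ScoredSNP],
    thr: DropThreshold = DropThreshold(),
    *,
    index_id: str = "",
    index_p: float = float("nan"),
    gain_advisory_level: float = 1.0,
) -> RegionResult:
    """Summarize a region from its scored members (index SNP excluded).

    GQS = −1 when no member has r² above the floor (nothing supports the
    index's LD pattern); 1 when supported with no outliers; otherwise
    1 − max(outlier distance)/worst-case distance, which lies in [0, 1).
    """
    worst = thr.worst_case_distance
    scored = list(scored)
    if not scored:
        warnings.warn("empty region: no scored SNPs, GQS = -1", stacklevel=2)

    supporters = [sn for sn in scored if sn.r2 > thr.r2_floor]
    outliers = [sn for sn in scored if sn.is_outlier]
    secondary = sorted(
        sn.var_id
        for sn in scored
        if sn.r2 > thr.r2_floor and sn.s > gain_advisory_level
    )

    if not supporters:
        gqs, n_out, max_dist, strongest = -1.0, 0, 0.0, None
    elif not outliers:
        gqs, n_out, max_dist, strongest = 1.0, 0, 0.0, None
    else:
        max_dist = max(sn.perp_dist for sn in outliers)
        # ties on distance: name the lexicographically smallest ID
        strongest = min(sn.var_id for sn in outliers if sn.perp_dist == max_dist)
        n_out = len(outliers)
        gqs = 1.0 - max_dist / worst

    return RegionResult(
        index_id=index_id,
        index_p=index_p,
        scored=scored,
        n_outliers=n_out,
        max_loss_dist=max_dist,
        worst_case_dist=worst,
        gqs=gqs,
        strongest_outlier=strongest,
        secondary_signal_ids=secondary,
    )


def score_region(
    records: Iterable,
    profile,
    thr: DropThreshold = DropThreshold(),
    *,
    equilibrium_floor: float = 0.01,
    gain_advisory_level: float = 1.0,
) -> RegionResult:
    """Run the full per-region scoring given summary stats and an LD profile.

    ``records`` are SummaryStatRecord-like objects (``var_id``,
    ``p_value``); ``profile`` maps variant IDs to r² with the index
    (an :class:`~gqscore.ld.LDProfile`).  Variants in linkage equilibrium
    (r² below ``equilibrium_floor``) are dropped as noise, the index is
    excluded from its own scored set, and summary variants without LD are
    ignored (they carry no evidence either way).
    """
    by_id = {}
    for rec in records:
        prev = by_id.get(rec.var_id)
        if prev is None or rec.p_value < prev.p_value:
            by_id[rec.var_id] = rec

    index_id = profile.index_id
    if index_id not in by_id:
        raise VariantLookupError(
            f"index SNP {index_id!r} absent from the summary statistics"
        )
    index_p = by_id[index_id].p_value
    index_logp = neg_log10_p(index_p)
    if index_logp <= 0.0:
        raise DegenerateRegionError(
            f"index SNP {index_id!r} has P = 1; region is degenerate"
        )

    scored = []
    for var_id, r2 in profile.r2.items():
        if var_id == index_id or var_id not in by_id:
            continue
        if r2 < equilibrium_floor or r2 <= 0.0:
            continue
        p_obs = neg_log10_p(by_id[var_id].p_value)
        scored.append(_score_one(var_id, r2, p_obs, index_logp, thr))
    scored.sort(key=lambda sn: sn.var_id)

    result = gqs_region(
        scored,
        thr,
        index_id=index_id,
        index_p=index_p,
        gain_advisory_level=gain_advisory_level,
    )
    return result


def rescore_with_index(
    records: Iterable,
    panel,
    new_index_id: str,
    thr: DropThreshold = DropThreshold(),
    *,
    min_pairs: int = 10,
    equilibrium_floor: float = 0.01,
) -> RegionResult:
    """Re-run scoring with a different index SNP, recomputing LD to it.

    Used to probe gain-side SNPs for secondary independent signals: if a
    gaining SNP anchors its own clean LD/significance pattern, rescoring
    on it yields a high GQS for that signal.
    """
    from .ld import filter_equilibrium, r2_to_index

    profile = r2_to_index(panel, new_index_id, min_pairs=min_pairs)
    profile = filter_equilibrium(profile, floor=equilibrium_floor)
    return score_region(records, profile, thr, equilibrium_floor=equilibrium_floor)
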