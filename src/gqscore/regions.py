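"""Region discovery: greedy distance clumping and targeted gene±flank spans.

Independent significant regions are built greedily: take the globally
smallest-P unassigned variant below the significance threshold, open a
±half-window region around it, assign everything inside, repeat.
Distance clumping (rather than LD clumping) keeps region discovery
independent of the LD reference — incomplete LD coverage is exactly the
failure mode the score should surface downstream, not hide here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .exceptions import EmptyRegionError
from .io import RegionSpec, SummaryStatRecord

__all__ = ["ClumpConfig", "find_regions", "targeted_region"]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class ClumpConfig:
    p_threshold: float = GENOME_WIDE_P
    half_window: int = 500_000
    merge_overlaps: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if self.half_window <= 0:
            raise ValueError(f"half_window must be positive, got {self.half_window}")


def _rank_key(rec: SummaryStatRecord):
    # ties in P broken by position, then ID, for determinism
    return (rec.p_value, rec.pos, rec.var_id)


def find_regions(
    records: Iterable[SummaryStatRecord], cfg: ClumpConfig = ClumpConfig()
) -> list[RegionSpec]:
    """Greedy clumping of genome-wide-significant variants into regions.

    Returns regions sorted by (chrom, start), each carrying its index
    variant ID; overlapping same-chromosome regions are merged (keeping
    the smaller-P index) when ``cfg.merge_overlaps``.  No significant
    variant → empty list.
    """
    recs = sorted(records, key=_rank_key)
    assigned: set[int] = set()
    raw: list[tuple[RegionSpec, float]] = []
    for i, rec in enumerate(recs):
        if i in assigned or rec.p_value >= cfg.p_threshold:
            continue
        start = max(1, rec.pos - cfg.half_window)
        end = rec.pos + cfg.half_window
        for j in range(i, len(recs)):
            other = recs[j]
            if (
                j not in assigned
                and other.chrom == rec.chrom
                and start <= other.pos <= end
            ):
                assigned.add(j)
        raw.append(
            (
                RegionSpec(chrom=rec.chrom, start=start, end=end, index_id=rec.var_id),
                rec.p_value,
            )
        )

    raw.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    if not cfg.merge_overlaps:
        return [r for r, _ in raw]

    merged: list[tuple[RegionSpec, float]] = []
    for region, p in raw:
        if merged and merged[-1][0].chrom == region.chrom and region.start <= merged[-1][0].end:
            prev, prev_p = merged[-1]
            keep_prev = prev_p <= p
            merged[-1] = (
                RegionSpec(
                    chrom=prev.chrom,
                    start=prev.start,
                    end=max(prev.end, region.end),
                    index_id=prev.index_id if keep_prev else region.index_id,
                ),
                min(prev_p, p),
            )
        else:
            merged.append((region, p))
    return [r for r, _ in merged]


def targeted_region(
    chrom: str,
    gene_start: int,
    gene_end: int,
    records: Iterable[SummaryStatRecord],
    flank: int = 50_000,
    label: str | None = None,
) -> RegionSpec:
    """Build a gene±flank region and pick its lowest-P record as index.

    The index need not be genome-wide significant — targeted queries ask
    about a locus of prior interest, not about discovery.  Raises
    :class:`EmptyRegionError` when no summary record falls inside.
    """
    if gene_start > gene_end:
        raise ValueError(f"gene_start {gene_start} > gene_end {gene_end}")
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    start = max(1, gene_start - flank)
    end = gene_end + flank
    inside = [
        r
        for r in records
        if r.chrom == chrom and start <= r.pos <= end
    ]
    if not inside:
        raise EmptyRegionError(f"no summary records inside {chrom}:{start}-{end}")
    index = min(inside, key=_rank_key)
    return RegionSpec(chrom=chrom, start=start, end=end, label=label, index_id=index.var_id)


def records_in_region(
    records: Iterable[SummaryStatRecord], region: RegionSpec
) -> list[SummaryStatRecord]:
    """Subset records overlapping a region (order preserved)."""
    return [
        r
        for r in records
        if r.chrom == region.chrom and region.start <= r.pos <= region.end
    ]
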