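"""End-to-end orchestration: summary stats + LD source + regions → results.

This is the layer the CLI wraps: it discovers or accepts regions, builds
an LD profile per region (from reference genotypes or a precomputed
table), matches panel variants to summary variants, and runs the scorer.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

from .core import DropThreshold, RegionResult, score_region
from .exceptions import InputError, VariantLookupError
from .io import RegionSpec, SummaryStatRecord
from .ld import GenotypePanel, LDProfile, filter_equilibrium, load_panel, r2_to_index
from .regions import ClumpConfig, find_regions, records_in_region

logger = logging.getLogger("gqscore")

__all__ = ["match_profile_to_records", "score_regions_with_panel", "score_with_ld_table"]


def match_profile_to_records(
    profile: LDProfile,
    panel: GenotypePanel,
    records: Sequence[SummaryStatRecord],
) -> LDProfile:
    """Re-key a panel-derived LD profile onto summary-statistic variant IDs.

    Matching is by ID first, then by (chrom, pos, allele set).  Panel
    variants with no summary counterpart are dropped; summary variants
    with no LD are left out of the profile (and counted in a warning) —
    incomplete overlap is a finding, not an error.
    """
    by_id = {r.var_id for r in records}
    by_locus = {
        (r.chrom, r.pos, frozenset((r.a1, r.a2))): r.var_id for r in records
    }
    panel_by_id = {v.var_id: v for v in panel.variants}

    remapped: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    index_id = profile.index_id
    for vid, val in profile.r2.items():
        if vid in by_id:
            new_id = vid
        else:
            v = panel_by_id.get(vid)
            key = (v.chrom, v.pos, frozenset((v.ref, v.alt))) if v else None
            new_id = by_locus.get(key) if key else None
            if new_id is None:
                continue
        remapped[new_id] = val
        if vid in profile.n_pairs:
            n_pairs[new_id] = profile.n_pairs[vid]
        if vid == profile.index_id:
            index_id = new_id

    n_without_ld = sum(1 for r in records if r.var_id not in remapped)
    if n_without_ld:
        warnings.warn(
            f"{n_without_ld} summary variants have no LD estimate and are "
            "not scored",
            stacklevel=2,
        )
    return LDProfile(index_id=index_id, r2=remapped, n_pairs=n_pairs)


def _pick_index(
    region: RegionSpec, inside: Sequence[SummaryStatRecord]
) -> SummaryStatRecord:
    if region.index_id:
        for r in inside:
            if r.var_id == region.index_id:
                return r
        raise VariantLookupError(
            f"forced index {region.index_id!r} not inside {region.span}"
        )
    return min(inside, key=lambda r: (r.p_value, r.pos, r.var_id))


def score_regions_with_panel(
    records: Sequence[SummaryStatRecord],
    panel_path: str | Path,
    regions: Sequence[RegionSpec] | None = None,
    thr: DropThreshold = DropThreshold(),
    clump: ClumpConfig = ClumpConfig(),
    *,
    min_pairs: int = 10,
    equilibrium_floor: float = 0.01,
) -> list[RegionResult]:
    """Score every region, computing LD to each region's index from genotypes."""
    records = list(records)
    if regions is None:
        regions = find_regions(records, clump)
        logger.info("clumping found %d significant regions", len(regions))

    results: list[RegionResult] = []
    for region in regions:
        inside = records_in_region(records, region)
        if not inside:
            logger.warning("region %s has no summary records; skipped", region.span)
            continue
        index = _pick_index(region, inside)
        panel = load_panel(panel_path, region)
        try:
            pid = _panel_id_for(index, panel)
        except VariantLookupError:
            logger.warning(
                "index %s of %s absent from the LD panel; region skipped",
                index.var_id,
                region.span,
            )
            continue
        profile = r2_to_index(panel, pid, min_pairs=min_pairs)
        profile = filter_equilibrium(profile, floor=equilibrium_floor)
        profile = match_profile_to_records(profile, panel, inside)
        res = score_region(
            inside, profile, thr, equilibrium_floor=equilibrium_floor
        )
        res.region = region
        results.append(res)
    return results


def _panel_id_for(rec: SummaryStatRecord, panel: GenotypePanel) -> str:
    for v in panel.variants:
        if v.var_id == rec.var_id:
            return v.var_id
    for v in panel.variants:
        if (
            v.chrom == rec.chrom
            and v.pos == rec.pos
            and frozenset((v.ref, v.alt)) == frozenset((rec.a1, rec.a2))
        ):
            return v.var_id
    raise VariantLookupError(f"variant {rec.var_id!r} not present in panel")


def score_with_ld_table(
    records: Sequence[SummaryStatRecord],
    profile: LDProfile,
    region: RegionSpec | None = None,
    thr: DropThreshold = DropThreshold(),
    *,
    equilibrium_floor: float = 0.01,
) -> RegionResult:
    """Score one region whose LD comes from a precomputed table."""
    inside = (
        records_in_region(records, region) if region is not None else list(records)
    )
    if not inside:
        raise InputError("no summary records to score")
    if not profile.index_id:
        index = min(inside, key=lambda r: (r.p_value, r.pos, r.var_id))
        profile = LDProfile(index_id=index.var_id, r2=dict(profile.r2))
    profile = filter_equilibrium(profile, floor=equilibrium_floor)
    res = score_region(inside, profile, thr, equilibrium_floor=equilibrium_floor)
    res.region = region
    return res
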