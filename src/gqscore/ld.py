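"""Reference-panel LD: r² between a region's index SNP and every member.

r² is the squared Pearson correlation of unphased alt-allele dosages
(composite LD) — no phasing required, and it is what reference-panel LD
to an index SNP conventionally means.  Missing genotypes are handled
pairwise-complete with a minimum-pairs guard so tiny overlaps cannot
produce spurious r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .exceptions import InputError, VariantLookupError

__all__ = [
    "PanelVariant",
    "GenotypePanel",
    "LDProfile",
    "load_panel",
    "load_vcf_panel",
    "load_dosage_panel",
    "r2_to_index",
    "filter_equilibrium",
]

MISSING = -1  # dosage sentinel


@dataclass(frozen=True)
class PanelVariant:
    chrom: str
    pos: int
    var_id: str
    ref: str
    alt: str


@dataclass
class GenotypePanel:
    """Ordered variants with an (n_variants, n_samples) dosage matrix.

    Dosages are alt-allele counts in {0, 1, 2}; missing is ``MISSING``.
    """

    variants: list[PanelVariant]
    dosages: np.ndarray  # int8, shape (n_variants, n_samples)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.variants):
            raise ValueError("dosage matrix shape does not match variant count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, var_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.var_id == var_id:
                return i
        raise VariantLookupError(f"variant {var_id!r} not present in panel")


@dataclass
class LDProfile:
    """Per-region map of variant ID → r² with the index SNP."""

    index_id: str
    r2: dict[str, float]
    n_pairs: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.r2)

    def __contains__(self, var_id: str) -> bool:
        return var_id in self.r2


def _vcf_dosage(gt: tuple, alt_index: int) -> int:
    """Alt-allele dosage for one ALT of a (possibly multi-allelic) call.

    Any half-call (an allele of None, e.g. "./1") makes the genotype
    missing for every split variant.
    """
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    return sum(1 for a in gt if a == alt_index)


def load_vcf_panel(path: str | Path, region=None) -> GenotypePanel:
    """Load genotypes from a VCF (plain or bgzipped) as alt-allele dosages.

    Multi-allelic records are split into one bi-allelic variant per ALT
    with independent dosages.  When ``region`` (a RegionSpec-like object
    with chrom/start/end) is given, only overlapping variants are kept;
    an empty overlap yields an empty panel, not an error.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise InputError(f"VCF not found: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    variants: list[PanelVariant] = []
    rows: list[list[int]] = []
    with vf:
        for rec in vf:
            if region is not None:
                if str(rec.chrom) != str(region.chrom):
                    continue
                if rec.pos < region.start or rec.pos > region.end:
                    continue
            alts = rec.alts or ()
            gts = [rec.samples[s].get("GT") for s in samples]
            for ai, alt in enumerate(alts, start=1):
                if len(alts) == 1:
                    vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                else:
                    base = rec.id or f"{rec.chrom}:{rec.pos}"
                    vid = f"{base}:{rec.ref}:{alt}"
                variants.append(
                    PanelVariant(str(rec.chrom), rec.pos, vid, rec.ref or ".", alt)
                )
                rows.append([_vcf_dosage(gt, ai) for gt in gts])

    dosages = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypePanel(variants, dosages, samples)


def load_dosage_panel(path: str | Path, region=None) -> GenotypePanel:
    """Load a plain-text dosage matrix.

    Format: a header row of sample IDs, then one row per variant:
    ``chrom pos id ref alt d1 d2 ...`` with ``.`` for missing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"dosage matrix not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"empty dosage matrix: {path}")
    samples = lines[0].split()
    variants: list[PanelVariant] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 5 + len(samples):
            raise InputError(
                f"{path}:{lineno}: expected {5 + len(samples)} fields, got {len(parts)}"
            )
        chrom, pos_s, vid, ref, alt = parts[:5]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
        if region is not None and (
            chrom != str(region.chrom) or pos < region.start or pos > region.end
        ):
            continue
        row = []
        for tok in parts[5:]:
            if tok == ".":
                row.append(MISSING)
            elif tok in ("0", "1", "2"):
                row.append(int(tok))
            else:
                raise InputError(f"{path}:{lineno}: bad dosage {tok!r}")
        variants.append(PanelVariant(chrom, pos, vid, ref, alt))
        rows.append(row)
    dosages = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypePanel(variants, dosages, samples)


def load_panel(path: str | Path, region=None) -> GenotypePanel:
    """Load a genotype panel, dispatching on file type (VCF vs dosage matrix)."""
    p = Path(path)
    name = p.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return load_vcf_panel(p, region)
    return load_dosage_panel(p, region)


def r2_to_index(
    panel: GenotypePanel, index_id: str, min_pairs: int = 10
) -> LDProfile:
    """r² of every panel variant with the index, pairwise-complete.

    Variants with fewer than ``min_pairs`` complete pairs, or zero dosage
    variance over the complete pairs, are omitted.  The index itself is
    reported with r² = 1.
    """
    if min_pairs < 2:
        raise ValueError(f"min_pairs must be >= 2, got {min_pairs}")
    idx = panel.index_of(index_id)
    d = panel.dosages.astype(np.float64)
    x = d[idx]
    x_ok = panel.dosages[idx] != MISSING

    r2: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    for i, var in enumerate(panel.variants):
        y_ok = panel.dosages[i] != MISSING
        ok = x_ok & y_ok
        n = int(ok.sum())
        if n < min_pairs:
            continue
        xi, yi = x[ok], d[i][ok]
        vx = xi.var()
        vy = yi.var()
        if vx == 0.0 or vy == 0.0:
            if i == idx:
                continue  # monomorphic index: no profile entry even for itself
            continue
        cov = ((xi - xi.mean()) * (yi - yi.mean())).mean()
        val = (cov * cov) / (vx * vy)
        r2[var.var_id] = min(float(val), 1.0)
        n_pairs[var.var_id] = n
    if index_id in r2:
        r2[index_id] = 1.0
    return LDProfile(index_id=index_id, r2=r2, n_pairs=n_pairs)


def filter_equilibrium(profile: LDProfile, floor: float = 0.01) -> LDProfile:
    """Drop variants in linkage equilibrium (r² below ``floor``); keep the index."""
    if not 0.0 <= floor < 1.0:
        raise ValueError(f"floor must be in [0, 1), got {floor}")
    kept = {
        vid: v
        for vid, v in profile.r2.items()
        if v >= floor or vid == profile.index_id
    }
    return LDProfile(
        index_id=profile.index_id,
        r2=kept,
        n_pairs={vid: n for vid, n in profile.n_pairs.items() if vid in kept},
    )
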