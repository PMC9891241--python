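"""Reading and writing GWAS summary statistics, LD tables and result tables.

Consortium summary-statistic files share no fixed schema, so columns are
resolved through a configurable synonym table (daner-style case/control
files, consortium exports and plain ``CHR SNP BP A1 A2 P`` toys all
parse out of the box).  Region lists are BED-like text; positions are handled
1-based inclusive throughout (BED starts are shifted on read).
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .core import MIN_P, RegionResult, ScoredSNP
from .exceptions import ConfigError, InputError
from .ld import LDProfile

__all__ = [
    "SummaryStatRecord",
    "RegionSpec",
    "ParsedSumstats",
    "DEFAULT_SYNONYMS",
    "read_sumstats",
    "read_ld_table",
    "read_regions",
    "write_region_results",
    "read_region_results",
    "write_snp_table",
    "read_snp_table",
]


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association result."""

    chrom: str
    pos: int
    var_id: str
    a1: str = "."
    a2: str = "."
    p_value: float = 1.0
    n: float | None = None
    effect: float | None = None
    se: float | None = None
    freq: float | None = None


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval (1-based inclusive) with optional forced index."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    index_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def span(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ParsedSumstats:
    """Parsed records plus parse bookkeeping (drops, clamps, duplicates)."""

    records: list[SummaryStatRecord]
    n_dropped: int = 0
    n_clamped: int = 0
    duplicate_ids: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# role → recognized header names (matched case-insensitively; FRQ-prefixed
# daner frequency columns are matched by prefix)
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "chrom": ("CHR", "#CHROM", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION", "BASE_PAIR_LOCATION"),
    "var_id": ("SNP", "ID", "MARKERNAME", "RSID", "SNPID", "VARIANT_ID"),
    "p_value": ("P", "PVAL", "P-VALUE", "PVALUE", "P_VALUE", "P.VALUE"),
    "a1": ("A1", "ALLELE1", "EA", "EFFECT_ALLELE", "REF"),
    "a2": ("A2", "ALLELE2", "OA", "NEA", "OTHER_ALLELE", "ALT"),
    "n": ("N", "NEFF", "N_EFF", "NTOT", "N_TOTAL", "SAMPLESIZE"),
    "effect": ("BETA", "B", "EFFECT", "OR", "LOG_ODDS", "Z"),
    "se": ("SE", "STDERR", "STDERRLOGOR", "STANDARD_ERROR"),
    "freq": ("FRQ", "FREQ", "MAF", "EAF", "AF", "FREQ1"),
}
_FREQ_PREFIXES = ("FRQ_A", "FRQ_U", "FREQ_")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _resolve_columns(
    header: Sequence[str], synonyms: dict[str, tuple[str, ...]]
) -> dict[str, str]:
    upper = {h.upper(): h for h in header}
    mapping: dict[str, str] = {}
    for role, names in synonyms.items():
        for name in names:
            if name.upper() in upper:
                mapping[role] = upper[name.upper()]
                break
    if "freq" not in mapping:
        for h in header:
            if h.upper().startswith(_FREQ_PREFIXES):
                mapping["freq"] = h
                break
    return mapping


def read_sumstats(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    synonyms: dict[str, tuple[str, ...]] | None = None,
) -> ParsedSumstats:
    """Read a header-bearing whitespace/tab summary-statistics file.

    ``dialect`` maps roles (``chrom``, ``pos``, ``var_id``, ``p_value``,
    ...) directly to column names and overrides synonym resolution.
    Rows whose P is unparseable or outside (0, 1] are dropped and
    counted; P = 0 is clamped to the smallest positive double (counted as
    clamped, not dropped).  Duplicate variant IDs keep the smallest-P
    record, mirroring index-SNP selection.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary statistics file not found: {path}")
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(fh, sep=r"\s+", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise InputError(f"empty summary statistics file: {path}") from exc
    if df.empty and df.columns.empty:
        raise InputError(f"empty summary statistics file: {path}")

    mapping = _resolve_columns(list(df.columns), synonyms or DEFAULT_SYNONYMS)
    if dialect:
        mapping.update(dialect)
    missing = [c for c in mapping.values() if c not in df.columns]
    if missing:
        raise ConfigError(f"dialect names absent columns: {missing}")
    if "p_value" not in mapping:
        raise ConfigError(
            f"cannot resolve a P-value column in header {list(df.columns)}"
        )
    if "var_id" not in mapping and not ("chrom" in mapping and "pos" in mapping):
        raise ConfigError(
            "cannot resolve variant identity: need an ID column or both "
            f"chromosome and position columns in header {list(df.columns)}"
        )

    def col(role: str, i: int):
        return df[mapping[role]].iat[i] if role in mapping else None

    def fnum(val) -> float | None:
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        try:
            return float(val)
        except (TypeError, ValueError):
            return None

    records: list[SummaryStatRecord] = []
    n_dropped = n_clamped = 0
    for i in range(len(df)):
        p = fnum(col("p_value", i))
        if p is None or p > 1.0 or p < 0.0 or math.isnan(p):
            n_dropped += 1
            continue
        if p == 0.0:
            p = MIN_P
            n_clamped += 1
        chrom = col("chrom", i)
        pos = fnum(col("pos", i))
        vid = col("var_id", i)
        if vid is None or (isinstance(vid, float) and math.isnan(vid)):
            vid = f"{chrom}:{int(pos)}" if chrom is not None and pos else None
        if vid is None:
            n_dropped += 1
            continue
        records.append(
            SummaryStatRecord(
                chrom=str(chrom) if chrom is not None else ".",
                pos=int(pos) if pos is not None else 0,
                var_id=str(vid),
                a1=str(col("a1", i)) if col("a1", i) is not None else ".",
                a2=str(col("a2", i)) if col("a2", i) is not None else ".",
                p_value=p,
                n=fnum(col("n", i)),
                effect=fnum(col("effect", i)),
                se=fnum(col("se", i)),
                freq=fnum(col("freq", i)),
            )
        )

    seen: dict[str, int] = {}
    dupes: list[str] = []
    deduped: list[SummaryStatRecord] = []
    for rec in records:
        if rec.var_id in seen:
            dupes.append(rec.var_id)
            j = seen[rec.var_id]
            if rec.p_value < deduped[j].p_value:
                deduped[j] = rec
        else:
            seen[rec.var_id] = len(deduped)
            deduped.append(rec)
    if dupes:
        warnings.warn(
            f"{len(dupes)} duplicated variant IDs in {path.name}; "
            "kept the smallest-P record for each",
            stacklevel=2,
        )
    return ParsedSumstats(
        records=deduped,
        n_dropped=n_dropped,
        n_clamped=n_clamped,
        duplicate_ids=sorted(set(dupes)),
    )


def read_ld_table(path: str | Path, index_id: str | None = None) -> LDProfile:
    """Read a precomputed LD table into an :class:`~gqscore.ld.LDProfile`.

    Accepts a two-column ``variant_id  r2`` table (header optional) or a
    PLINK ``.ld``-style table (columns SNP_A/SNP_B/R2).  r² outside
    [0, 1] is rejected with the offending line number.  Unless given,
    the index is taken as the variant with the largest r² (normally 1).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"LD table not found: {path}")
    lines = [
        (i, ln)
        for i, ln in enumerate(path.read_text().splitlines(), start=1)
        if ln.strip()
    ]
    r2: dict[str, float] = {}
    plink_cols: tuple[int, int, int | None] | None = None
    plink_index: str | None = None
    for lineno, ln in lines:
        parts = ln.split()
        upper = [p.upper() for p in parts]
        if "SNP_B" in upper and "R2" in upper:  # PLINK .ld header
            ai = upper.index("SNP_A") if "SNP_A" in upper else None
            plink_cols = (upper.index("SNP_B"), upper.index("R2"), ai)
            continue
        if plink_cols is not None:
            bi, ri, ai = plink_cols
            if max(bi, ri) >= len(parts):
                raise InputError(f"{path}:{lineno}: truncated PLINK .ld row")
            vid, val_s = parts[bi], parts[ri]
            if ai is not None and ai < len(parts):
                plink_index = parts[ai]  # SNP_A names the index variant
        elif len(parts) == 2:
            vid, val_s = parts
        else:
            raise InputError(
                f"{path}:{lineno}: expected 2 columns or a PLINK .ld table, "
                f"got {len(parts)} fields"
            )
        try:
            val = float(val_s)
        except ValueError:
            if lineno == lines[0][0] and not r2:
                continue  # tolerate a simple two-column header row
            raise InputError(f"{path}:{lineno}: r2 {val_s!r} is not a number")
        if not 0.0 <= val <= 1.0:
            raise InputError(f"{path}:{lineno}: r2 = {val} outside [0, 1]")
        r2[vid] = val

    if index_id is None and plink_index is not None:
        index_id = plink_index
        r2.setdefault(index_id, 1.0)
    if index_id is None and r2:
        index_id = max(r2, key=lambda v: (r2[v], v))
        if r2[index_id] < 1.0:
            warnings.warn(
                f"no r2 = 1 entry in {path.name}; using {index_id} "
                f"(r2 = {r2[index_id]}) as index",
                stacklevel=2,
            )
    return LDProfile(index_id=index_id or "", r2=r2)


def read_regions(path: str | Path, bed_coords: bool = True) -> list[RegionSpec]:
    """Read a 3–5 column BED-like region list.

    Columns: chrom, start, end[, label][, index_id].  With
    ``bed_coords`` (default) starts are 0-based half-open as in BED and
    converted to 1-based inclusive.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"region file not found: {path}")
    regions: list[RegionSpec] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split()
        if len(parts) < 3:
            raise InputError(f"{path}:{lineno}: need at least 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: bad coordinates") from exc
        if bed_coords:
            start += 1
        regions.append(
            RegionSpec(
                chrom=parts[0],
                start=start,
                end=end,
                label=parts[3] if len(parts) > 3 else None,
                index_id=parts[4] if len(parts) > 4 else None,
            )
        )
    return regions


def _fmt_gqs(g: float) -> str:
    if g in (-1.0, 1.0):
        return str(int(g))
    return f"{g:.3f}"


REGION_HEADER = ("CHR", "INDEX_SNP", "P", "OUTLIERS", "GQS")


def write_region_results(results: Sequence[RegionResult], path: str | Path) -> None:
    """Write the per-region table: chrom, index SNP, index P, outliers, GQS.

    GQS is printed to 3 decimals; the sentinel −1 and the perfect score 1
    are printed as bare integers.
    """
    path = Path(path)
    rows = []
    for res in results:
        chrom = res.region.chrom if res.region is not None else "."
        rows.append(
            f"{chrom}\t{res.index_id}\t{res.index_p:.6g}\t"
            f"{res.n_outliers}\t{_fmt_gqs(res.gqs)}"
        )
    path.write_text("\t".join(REGION_HEADER) + "\n" + "".join(r + "\n" for r in rows))


def read_region_results(path: str | Path) -> pd.DataFrame:
    """Read back a per-region results table as a DataFrame."""
    return pd.read_csv(path, sep="\t")


SNP_HEADER = (
    "VAR_ID",
    "R2",
    "P_OBS",
    "P_HAT",
    "E",
    "S",
    "LOSS",
    "BAND",
    "IS_OUTLIER",
    "PERP_DIST",
)


def write_snp_table(scored: Sequence[ScoredSNP], path: str | Path) -> None:
    """Write the per-SNP scoring table (one row per non-index region member)."""
    path = Path(path)
    lines = ["\t".join(SNP_HEADER)]
    for sn in scored:
        lines.append(
            f"{sn.var_id}\t{sn.r2:.6g}\t{sn.p_obs:.6g}\t{sn.p_hat:.6g}\t"
            f"{sn.e:.6g}\t{sn.s:.6g}\t{sn.loss:.6g}\t{sn.band}\t"
            f"{int(sn.is_outlier)}\t{sn.perp_dist:.6g}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_snp_table(path: str | Path) -> list[ScoredSNP]:
    """Read back a per-SNP table (e.g. to re-render plots)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SNP_HEADER) - set(df.columns)
    if missing:
        raise InputError(f"per-SNP table {path} lacks columns {sorted(missing)}")
    return [
        ScoredSNP(
            var_id=str(row.VAR_ID),
            r2=float(row.R2),
            p_obs=float(row.P_OBS),
            p_hat=float(row.P_HAT),
            e=float(row.E),
            s=float(row.S),
            loss=float(row.LOSS),
            band=str(row.BAND),
            is_outlier=bool(row.IS_OUTLIER),
            perp_dist=float(row.PERP_DIST),
        )
        for row in df.itertuples()
    ]
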