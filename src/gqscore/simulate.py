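"""Synthetic case/control GWAS with known LD, causal signal and artifacts.

Haplotypes follow a first-order Markov copy model: the allele at site j
copies site j−1's allele with probability ``ld_decay``, otherwise it is
drawn fresh at that site's minor-allele frequency.  This produces
geometric LD decay along the region (adjacent-site correlation ≈
``ld_decay``) — the only property the scoring method consumes — without
pretending to population-genetic realism.  A binary phenotype comes from
a logistic model on the causal SNP's dosage, association is a 1-df
allele-count chi-square per SNP, and technical artifacts (differential
case missingness, batch allele mis-coding, cohort dropout in a
fixed-effects meta-analysis) are injected with ground-truth labels so
detection behaviour is testable end to end.

Defaults mirror a small simulated GWAS cohort of 464 cases and 516
controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .exceptions import SimulationError, VariantLookupError
from .io import SummaryStatRecord
from .ld import MISSING, GenotypePanel, PanelVariant

__all__ = [
    "SimConfig",
    "ArtifactSpec",
    "SyntheticTruth",
    "SimResult",
    "simulate_haplotypes",
    "simulate_phenotype_and_test",
    "association_test",
    "inject_artifacts",
    "meta_analyze",
    "simulate_study",
    "simulate_meta_study",
    "true_r2_profile",
    "write_dataset",
]

ARTIFACT_KINDS = ("differential_missingness", "cohort_dropout", "allele_flip")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic GWAS region."""

    n_cases: int = 464
    n_controls: int = 516
    n_snps: int = 60
    ld_decay: float = 0.95  # adjacent-site haplotype copy probability
    maf_range: tuple[float, float] = (0.2, 0.5)
    causal_index: int | None = None  # causal SNP's position in the variant order (default: middle)
    causal_or: float = 2.0
    artifact_specs: tuple["ArtifactSpec", ...] = ()
    seed: int = 0
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing: int = 1_000

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps) <= 0:
            raise ValueError("n_cases, n_controls and n_snps must be positive")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError(f"ld_decay must be in [0, 1), got {self.ld_decay}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must sit inside (0, 0.5], got {self.maf_range}")
        if self.causal_index is None:
            object.__setattr__(self, "causal_index", self.n_snps // 2)
        if not 0 <= self.causal_index < self.n_snps:
            raise ValueError("causal_index out of range")
        if self.causal_or <= 0.0:
            raise ValueError("causal_or must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected technical artifact.

    ``severity`` is kind-specific: the per-genotype case-missingness
    rate, the fraction of meta-analysis cohorts lacking the SNP, or the
    per-sample flip probability inside the mis-coded batch (half of the
    samples) for allele flips.
    """

    kind: str
    target_snps: tuple[str, ...]
    severity: float

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for a simulated dataset."""

    causal: str
    corrupted: dict[str, str]  # variant id → artifact kind
    true_r2: dict[str, float]  # population r² with the causal variant


@dataclass
class SimResult:
    """Everything one simulated study produced."""

    config: SimConfig
    panel: GenotypePanel  # clean genotypes (the LD reference)
    corrupted_panel: GenotypePanel  # genotypes after artifact injection
    status: np.ndarray  # 1 = case, 0 = control
    records: list[SummaryStatRecord]  # association results on corrupted data
    truth: SyntheticTruth


def _var_ids(cfg: SimConfig) -> list[str]:
    return [f"snp{j:04d}" for j in range(cfg.n_snps)]


def simulate_haplotypes(cfg: SimConfig) -> GenotypePanel:
    """Simulate 2·N haplotypes under the Markov copy model; sum to genotypes."""
    rng = np.random.default_rng([cfg.seed, 1])
    n_hap = 2 * cfg.n_samples
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    fresh = rng.random((n_hap, cfg.n_snps)) < mafs  # fresh Bernoulli draws
    copy = rng.random((n_hap, cfg.n_snps)) < cfg.ld_decay
    hap = np.empty((n_hap, cfg.n_snps), dtype=np.int8)
    hap[:, 0] = fresh[:, 0]
    for j in range(1, cfg.n_snps):
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    geno = hap[0::2] + hap[1::2]  # (n_samples, n_snps)

    ids = _var_ids(cfg)
    variants = [
        PanelVariant(cfg.chrom, cfg.start_pos + j * cfg.spacing, ids[j], "A", "G")
        for j in range(cfg.n_snps)
    ]
    return GenotypePanel(variants, geno.T.astype(np.int8), [f"s{i}" for i in range(cfg.n_samples)])


def true_r2_profile(cfg: SimConfig) -> dict[str, float]:
    """Analytic population r² of every site with the causal site.

    Under the copy model the covariance between sites d apart is
    c^d · Var(earlier site); marginal frequencies follow the recursion
    m_j = c·m_{j−1} + (1−c)·p_j.  Dosage correlation equals haplotype
    allele correlation, so r² = corr².
    """
    rng = np.random.default_rng([cfg.seed, 1])
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    c = cfg.ld_decay
    m = np.empty(cfg.n_snps)
    m[0] = p[0]
    for j in range(1, cfg.n_snps):
        m[j] = c * m[j - 1] + (1.0 - c) * p[j]
    sd = np.sqrt(m * (1.0 - m))
    k = cfg.causal_index
    ids = _var_ids(cfg)
    out: dict[str, float] = {}
    for j in range(cfg.n_snps):
        lo, hi = min(j, k), max(j, k)
        corr = (c ** (hi - lo)) * sd[lo] / sd[hi] if sd[hi] > 0 else 0.0
        out[ids[j]] = float(corr * corr)
    return out


def _logistic_status(
    g_causal: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    beta = math.log(cfg.causal_or)
    target = cfg.n_cases / cfg.n_samples

    def excess(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + beta * g_causal))) - target

    alpha = optimize.brentq(excess, -30.0, 30.0)
    prob = special.expit(alpha + beta * g_causal)
    return (rng.random(cfg.n_samples) < prob).astype(np.int8)


def association_test(
    panel: GenotypePanel, status: np.ndarray
) -> list[SummaryStatRecord]:
    """Per-SNP 1-df allele-count chi-square on the case/control 2×2 table.

    Effect and SE are the allele log odds ratio with its Woolf SE
    (Haldane 0.5 correction when a cell is empty); per-SNP N counts the
    non-missing individuals.
    """
    status = np.asarray(status)
    records: list[SummaryStatRecord] = []
    for i, var in enumerate(panel.variants):
        d = panel.dosages[i]
        ok = d != MISSING
        n_used = int(ok.sum())
        cases = ok & (status == 1)
        ctrls = ok & (status == 0)
        a_case = float(d[cases].sum())
        a_ctrl = float(d[ctrls].sum())
        r_case = 2.0 * cases.sum() - a_case
        r_ctrl = 2.0 * ctrls.sum() - a_ctrl
        table = np.array([[a_case, r_case], [a_ctrl, r_ctrl]])
        total = table.sum()
        rows = table.sum(axis=1)
        cols = table.sum(axis=0)
        if total == 0 or (rows == 0).any() or (cols == 0).any():
            p, chi2 = 1.0, 0.0
        else:
            expected = np.outer(rows, cols) / total
            chi2 = float(((table - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(chi2, df=1))
        t = table + 0.5 if (table == 0).any() else table
        effect = math.log((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
        se = math.sqrt((1.0 / t).sum())
        freq = (a_case + a_ctrl) / (2.0 * n_used) if n_used else float("nan")
        records.append(
            SummaryStatRecord(
                chrom=var.chrom,
                pos=var.pos,
                var_id=var.var_id,
                a1=var.alt,
                a2=var.ref,
                p_value=min(max(p, 5e-324), 1.0),
                n=float(n_used),
                effect=effect,
                se=se,
                freq=freq,
            )
        )
    return records


def simulate_phenotype_and_test(
    panel: GenotypePanel, cfg: SimConfig
) -> tuple[list[SummaryStatRecord], np.ndarray]:
    """Draw case/control status from the causal SNP and test every SNP.

    Returns the association records and the status vector (needed again
    when artifacts force re-testing).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    g_causal = panel.dosages[cfg.causal_index].astype(np.float64)
    if np.all(g_causal == g_causal[0]):
        raise SimulationError("causal SNP is monomorphic in the simulated panel")
    status = _logistic_status(g_causal, cfg, rng)
    return association_test(panel, status), status


def inject_artifacts(
    panel: GenotypePanel,
    status: np.ndarray,
    specs: Sequence[ArtifactSpec],
    seed: int,
) -> tuple[GenotypePanel, list[SummaryStatRecord], SyntheticTruth]:
    """Corrupt genotypes per the artifact specs and re-test associations.

    ``differential_missingness`` emulates a failing genotype-calling
    cluster in the case batch: alt-allele-carrying case genotypes at the
    target SNPs are set missing at the severity rate (controls, and
    ref-homozygous cases, untouched).  The missingness is informative,
    so the case allele frequency deflates and the SNP's tested
    significance collapses while the clean reference panel's r² is
    unchanged.  ``allele_flip`` recodes dosage d → 2−d at
    target SNPs within a fixed random half of samples (each with
    probability severity) — a mis-coded batch.  ``cohort_dropout`` is a
    meta-analysis artifact; see :func:`simulate_meta_study`.
    """
    rng = np.random.default_rng([seed, 3])
    dosages = panel.dosages.copy()
    ids = {v.var_id: i for i, v in enumerate(panel.variants)}
    corrupted: dict[str, str] = {}
    # the mis-coded batch is one fixed random half of the cohort
    batch = rng.permutation(panel.n_samples)[: panel.n_samples // 2]
    for spec in specs:
        if spec.kind == "cohort_dropout":
            for vid in spec.target_snps:
                if vid not in ids:
                    raise VariantLookupError(f"artifact target {vid!r} not in panel")
                corrupted[vid] = spec.kind
            continue
        for vid in spec.target_snps:
            if vid not in ids:
                raise VariantLookupError(f"artifact target {vid!r} not in panel")
            if spec.severity == 0.0:
                continue
            i = ids[vid]
            if spec.kind == "differential_missingness":
                hit = (
                    (np.asarray(status) == 1)
                    & (dosages[i] > 0)
                    & (rng.random(panel.n_samples) < spec.severity)
                )
                dosages[i, hit] = MISSING
            elif spec.kind == "allele_flip":
                hit = batch[rng.random(batch.size) < spec.severity]
                sel = dosages[i, hit]
                dosages[i, hit] = np.where(sel == MISSING, sel, 2 - sel)
            corrupted[vid] = spec.kind

    new_panel = GenotypePanel(list(panel.variants), dosages, list(panel.samples))
    return new_panel, association_test(new_panel, status), SyntheticTruth(
        causal="", corrupted=corrupted, true_r2={}
    )


def simulate_study(cfg: SimConfig) -> SimResult:
    """Full pipeline: haplotypes → phenotype → artifacts → summary stats."""
    panel = simulate_haplotypes(cfg)
    _, status = simulate_phenotype_and_test(panel, cfg)
    corrupted_panel, records, truth = inject_artifacts(
        panel, status, cfg.artifact_specs, cfg.seed
    )
    truth.causal = panel.variants[cfg.causal_index].var_id
    truth.true_r2 = true_r2_profile(cfg)
    return SimResult(
        config=cfg,
        panel=panel,
        corrupted_panel=corrupted_panel,
        status=status,
        records=records,
        truth=truth,
    )


def meta_analyze(
    cohort_records: Sequence[Sequence[SummaryStatRecord]],
) -> list[SummaryStatRecord]:
    """Fixed-effects inverse-variance meta-analysis over K cohorts.

    Each SNP is combined over the cohorts that carry it; per-SNP N sums
    the contributing cohorts' N, so incomplete overlap yields deflated
    significance relative to fully-covered LD neighbours — the
    meta-analysis failure mode the scorer detects.  SNPs absent from
    every cohort are simply not emitted.
    """
    if not cohort_records:
        raise ValueError("need at least one cohort")
    by_id: dict[str, list[SummaryStatRecord]] = {}
    order: list[str] = []
    for recs in cohort_records:
        for rec in recs:
            if rec.var_id not in by_id:
                by_id[rec.var_id] = []
                order.append(rec.var_id)
            by_id[rec.var_id].append(rec)

    out: list[SummaryStatRecord] = []
    for vid in order:
        group = by_id[vid]
        if len(group) == 1:
            out.append(group[0])  # nothing to combine; keep the score test's P
            continue
        w = np.array([1.0 / (r.se**2) for r in group])
        b = np.array([r.effect for r in group])
        beta = float((w * b).sum() / w.sum())
        se = float(1.0 / math.sqrt(w.sum()))
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        first = group[0]
        out.append(
            replace(
                first,
                p_value=min(max(p, 5e-324), 1.0),
                effect=beta,
                se=se,
                n=float(sum(r.n or 0.0 for r in group)),
            )
        )
    return out


def simulate_meta_study(
    cfg: SimConfig, n_cohorts: int = 4, dropout: ArtifactSpec | None = None
) -> SimResult:
    """Simulate K equally-sized cohorts from one population and meta-analyze.

    ``dropout`` (kind ``cohort_dropout``) removes its target SNPs from a
    ``severity`` fraction of the cohorts (rounded to at least one kept),
    reproducing incomplete SNP overlap across meta-analyzed studies.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    panel = simulate_haplotypes(cfg)
    _, status = simulate_phenotype_and_test(panel, cfg)

    dropped: dict[str, str] = {}
    drop_ids: set[str] = set()
    n_drop = 0
    if dropout is not None:
        if dropout.kind != "cohort_dropout":
            raise ValueError("simulate_meta_study expects a cohort_dropout spec")
        drop_ids = set(dropout.target_snps)
        n_drop = min(n_cohorts - 1, round(dropout.severity * n_cohorts))
        for vid in drop_ids:
            dropped[vid] = "cohort_dropout"

    bounds = np.linspace(0, panel.n_samples, n_cohorts + 1).astype(int)
    cohort_records: list[list[SummaryStatRecord]] = []
    for k in range(n_cohorts):
        sel = slice(bounds[k], bounds[k + 1])
        sub = GenotypePanel(
            list(panel.variants), panel.dosages[:, sel], panel.samples[sel]
        )
        recs = association_test(sub, np.asarray(status)[sel])
        if k < n_drop:
            recs = [r for r in recs if r.var_id not in drop_ids]
        cohort_records.append(recs)

    records = meta_analyze(cohort_records)
    truth = SyntheticTruth(
        causal=panel.variants[cfg.causal_index].var_id,
        corrupted=dropped,
        true_r2=true_r2_profile(cfg),
    )
    return SimResult(
        config=cfg,
        panel=panel,
        corrupted_panel=panel,
        status=np.asarray(status),
        records=records,
        truth=truth,
    )


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Emit a simulated dataset as plain-text files.

    Writes the summary statistics (readable by the summary-stats
    parser), the clean dosage panel (readable by the LD loader), the
    truth labels, and a key=value sidecar of the configuration.  Output
    is byte-identical for identical configurations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "panel": outdir / "panel.dosage.txt",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.txt",
    }

    lines = ["CHR\tSNP\tBP\tA1\tA2\tP\tN\tBETA\tSE\tFRQ"]
    for r in result.records:
        lines.append(
            f"{r.chrom}\t{r.var_id}\t{r.pos}\t{r.a1}\t{r.a2}\t{r.p_value:.6g}\t"
            f"{r.n:.6g}\t{r.effect:.6g}\t{r.se:.6g}\t{r.freq:.6g}"
        )
    paths["sumstats"].write_text("\n".join(lines) + "\n")

    panel = result.panel
    rows = [" ".join(panel.samples)]
    for i, v in enumerate(panel.variants):
        ds = " ".join(
            "." if d == MISSING else str(int(d)) for d in panel.dosages[i]
        )
        rows.append(f"{v.chrom} {v.pos} {v.var_id} {v.ref} {v.alt} {ds}")
    paths["panel"].write_text("\n".join(rows) + "\n")

    tlines = ["SNP\tARTIFACT\tTRUE_R2_CAUSAL\tIS_CAUSAL"]
    for v in panel.variants:
        tlines.append(
            f"{v.var_id}\t{result.truth.corrupted.get(v.var_id, '.')}\t"
            f"{result.truth.true_r2.get(v.var_id, float('nan')):.6g}\t"
            f"{int(v.var_id == result.truth.causal)}"
        )
    paths["truth"].write_text("\n".join(tlines) + "\n")

    cfg = result.config
    kv = {
        "n_cases": cfg.n_cases,
        "n_controls": cfg.n_controls,
        "n_snps": cfg.n_snps,
        "ld_decay": cfg.ld_decay,
        "maf_low": cfg.maf_range[0],
        "maf_high": cfg.maf_range[1],
        "causal_index": cfg.causal_index,
        "causal_or": cfg.causal_or,
        "seed": cfg.seed,
        "chrom": cfg.chrom,
        "start_pos": cfg.start_pos,
        "spacing": cfg.spacing,
        "artifacts": ";".join(
            f"{a.kind}:{','.join(a.target_snps)}:{a.severity}"
            for a in cfg.artifact_specs
        )
        or ".",
    }
    paths["config"].write_text(
        "".join(f"{k}={v}\n" for k, v in kv.items())
    )
    return paths
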