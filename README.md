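# gqscore

LD-aware quality scoring of associated regions in GWAS summary statistics.

## The problem

Genome-wide association studies report per-SNP significance, but technical
artifacts — failing genotype-calling clusters, allele mis-coding, incomplete
SNP overlap between meta-analyzed cohorts — can corrupt individual variants
without tripping standard QC. The tell-tale signature is a SNP in strong
linkage disequilibrium (LD) with a region's top hit that is nevertheless far
less significant than that LD predicts. Traditionally such regions are caught
(or missed) by eyeballing regional association plots; `gqscore` replaces that
visual inspection with a single quantitative score per region.

## The score

Within an associated region, let the *index SNP* be the variant with the
smallest P-value, and let `r²` be each member SNP's LD with the index. When
the association is real and the LD information is correct, the expected
significance of each SNP follows a straight line through the origin in the
(r², −log₁₀P) plane:

    p̂ = r² · p_index,          p = observed −log₁₀ P
    e = p − p̂                  (residual)
    S = e / p̂                  (fraction of signal gained, S>0, or lost, S<0)

A SNP's *signal loss* is `max(0, −S) ∈ [0, 1]`. SNPs with `r² > 0.4` whose
loss exceeds a linear **drop threshold** — by default 100 % loss at r² = 0.4
falling to 40 % loss at r² = 1.0, i.e. `loss = 1.4 − r²` — are outliers.
The region's score is

    GQS = 1 − (max outlier distance to the threshold line)
            / (worst-case distance, from the total-loss point (1, 1))

where distances are perpendicular (point-to-line) in the (r², loss) plane;
the default worst-case distance is (1 − 0.4)/√2 ≈ 0.424. Semantics:

| GQS   | meaning |
|-------|---------|
| 1     | all SNPs consistent with the LD pattern — high confidence |
| [0,1) | outliers present; smaller = worst outlier closer to total signal loss |
| −1    | no SNP with r² > 0.4 supports the index — nothing to judge, inspect manually |

SNPs that *gain* signal (S > 0) never count against the score: they suggest a
secondary independent association, which can be probed by re-scoring the
region with that SNP as index (`rescore_with_index`).

## Worked example

Simulate a 60-SNP case/control region (464 cases, 516 controls, causal odds
ratio 2) with a genotype-calling failure injected at `snp0031`, a SNP in
r² ≈ 0.9 with the causal variant, then score it:

```bash
gqs simulate --seed 11 --out sim --artifact differential_missingness:snp0031:0.6
gqs score --sumstats sim/sumstats.tsv --panel sim/panel.dosage.txt --out scored --plots
```

The log ends with

```
INFO clumping found 1 significant regions
INFO region index=snp0030 outliers=1 GQS=0.335
```

and `scored/regions.tsv` contains

```
CHR	INDEX_SNP	P	OUTLIERS	GQS
1	snp0030	3.29824e-08	1	0.335
```

One region was found, indexed by `snp0030` (P = 3.3×10⁻⁸). The corrupted
SNP's row in the per-SNP table `scored/snps_snp0030.tsv`:

```
VAR_ID   R2        P_OBS     P_HAT    E         S          LOSS      BAND      IS_OUTLIER  PERP_DIST
snp0031  0.899757  0.679274  6.73173  -6.05246  -0.899094  0.899094  within95  1           0.28203
```

`snp0031` sits at r² = 0.90 with the index, so the line predicts
−log₁₀P ≈ 6.7; it was observed at 0.68 — a 90 % signal loss, 0.282 above the
drop threshold. The score 1 − 0.282/0.424 = 0.335 flags the region for
inspection, and the four diagnostic plots (regional association, significance
vs LD, residual-ratio histogram, GQS plane) are written alongside. Rerunning
the same commands reproduces every output byte for byte.

Real data work the same way: point `--sumstats` at any header-bearing
whitespace/tab summary-statistics file (column names are resolved through a
synonym table covering daner-style and consortium exports), and give LD either as
reference genotypes (`--panel`, VCF or plain dosage matrix from an
ancestry-appropriate reference) or as a precomputed table (`--ld-table`,
two-column or PLINK `.ld`). `gqs region --span CHR:START-END --flank 50000`
scores a targeted locus whose index need not be genome-wide significant.

## Layout

- `gqscore.core` — the scoring mathematics (prediction line, residual ratio,
  drop threshold, outlier distances, region score)
- `gqscore.io` — summary statistics / LD tables / regions / result tables
- `gqscore.ld` — r² to the index SNP from reference genotypes
- `gqscore.regions` — greedy clumping and targeted gene±flank regions
- `gqscore.simulate` — synthetic GWAS and meta-analysis with injected,
  ground-truth-labelled artifacts
- `gqscore.plots`, `gqscore.cli` — diagnostics and the `gqs` command

See `docs/methods.md` for the model, parameter choices and limitations.
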