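"""Synthetic twin-cohort generator.

Produces a discovery cohort (genotypes + continuous "insulin" phenotype), a
test cohort sharing the same allele frequencies, reference-style GWAS
summary statistics, adversity components with missing-at-random gaps, and a
continuous outcome carrying a planted score-by-adversity interaction. Every
generator is a pure function of (config, seed): distinct deterministic
substreams are derived from the config seed, so regenerating any piece
yields identical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .geno_io import GenotypeMatrix
from .geno_io import GwasSummary

# substream tags for seed derivation
(_S_FREQ, _S_DISC, _S_TEST, _S_BETA, _S_PHENO, _S_ADV, _S_OUT, _S_META,
 _S_GWAS_NOISE) = range(9)

#: unambiguous effect/other allele pairs (no A/T or C/G)
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


@dataclass
class AdversityComponentSpec:
    name: str
    kind: str  # binary | continuous_low_tail | continuous_high_tail
    missing_rate: float = 0.1
    prevalence: float = 0.15  # binary components


def default_adversity_spec() -> list[AdversityComponentSpec]:
    return [
        AdversityComponentSpec("smoking", "binary"),
        AdversityComponentSpec("low_income", "binary"),
        AdversityComponentSpec("health_events", "binary"),
        AdversityComponentSpec("birth_size", "continuous_low_tail"),
        AdversityComponentSpec("depression", "continuous_high_tail"),
        AdversityComponentSpec("anxiety", "continuous_high_tail"),
    ]


@dataclass
class GxeParams:
    bX: float = 0.0
    bM: float = 0.0
    bXM: float = -0.33
    noise_sd: float = 1.0
    intercept: float = 6.0


@dataclass
class SimConfig:
    """All knobs for the synthetic cohorts; defaults run in seconds."""

    n_discovery: int = 2000
    n_test: int = 600
    n_snps: int = 500
    n_causal: int = 20
    beta_sd: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.4
    h2: float = 0.3
    gwas_ref_n: int = 100_000
    adversity_spec: list[AdversityComponentSpec] = field(
        default_factory=default_adversity_spec
    )
    gxe: GxeParams = field(default_factory=GxeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValidationError("h2 must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie in (0, 0.5]")
        for name in ("n_discovery", "n_test", "n_snps", "n_causal",
                     "ld_block_size", "gwas_ref_n"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_causal > self.n_snps:
            raise ValidationError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValidationError("ld_rho must be in [0, 1)")
        for spec in self.adversity_spec:
            if not 0.0 <= spec.missing_rate < 1.0:
                raise ValidationError(
                    f"component {spec.name!r}: missing rate must be < 1"
                )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


def _snp_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_snps))
    return [f"snp{i:0{width}d}" for i in range(1, cfg.n_snps + 1)]


def snp_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic SNP metadata: LD blocks are 1 kb-spaced runs separated
    by 1 Mb so clump/prune windows act within blocks only."""
    rng = _rng(cfg, _S_META)
    ids = _snp_ids(cfg)
    block = np.arange(cfg.n_snps) // cfg.ld_block_size
    within = np.arange(cfg.n_snps) % cfg.ld_block_size
    pos = block * 1_000_000 + within * 1_000 + 1
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), cfg.n_snps)]
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": "1",
            "pos": pos.astype(int),
            "counted_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
        }
    )


def allele_frequencies(cfg: SimConfig) -> np.ndarray:
    """Generating counted-allele frequencies, shared by both cohorts."""
    lo, hi = cfg.maf_range
    return _rng(cfg, _S_FREQ).uniform(lo, hi, cfg.n_snps)


def causal_snp_ids(cfg: SimConfig) -> list[str]:
    """Deterministic causal subset: one SNP per block until exhausted, so
    causal signals are spread across LD blocks."""
    ids = _snp_ids(cfg)
    picks = []
    step = max(cfg.ld_block_size, 1)
    for i in range(cfg.n_causal):
        picks.append(ids[(i * step) % cfg.n_snps])
    if len(set(picks)) != cfg.n_causal:  # wrapped onto occupied blocks
        picks = ids[: cfg.n_causal]
    return picks


def true_effect_sizes(cfg: SimConfig) -> dict[str, float]:
    """True per-allele effects for causal SNPs (Normal(0, beta_sd^2))."""
    rng = _rng(cfg, _S_BETA)
    return {
        sid: float(b)
        for sid, b in zip(causal_snp_ids(cfg), rng.normal(0.0, cfg.beta_sd, cfg.n_causal))
    }


def simulate_genotypes(cfg: SimConfig, cohort: str = "discovery") -> GenotypeMatrix:
    """Hard-call genotypes in HWE with block LD.

    Each haplotype allele is a thresholded latent Gaussian sharing a
    block-level factor (weight sqrt(ld_rho)); the two haplotypes are
    independent, so single-SNP genotype frequencies follow HWE exactly.
    """
    if cohort not in ("discovery", "test"):
        raise ValidationError("cohort must be 'discovery' or 'test'")
    n = cfg.n_discovery if cohort == "discovery" else cfg.n_test
    rng = _rng(cfg, _S_DISC if cohort == "discovery" else _S_TEST)
    freqs = allele_frequencies(cfg)
    thresholds = stats.norm.ppf(freqs)  # allele present when z < Phi^-1(f)
    n_blocks = int(np.ceil(cfg.n_snps / cfg.ld_block_size))
    dosage = np.zeros((n, cfg.n_snps))
    w_shared = np.sqrt(cfg.ld_rho)
    w_own = np.sqrt(1.0 - cfg.ld_rho)
    for _hap in range(2):
        shared = rng.standard_normal((n, n_blocks))
        noise = rng.standard_normal((n, cfg.n_snps))
        block_of = np.arange(cfg.n_snps) // cfg.ld_block_size
        z = w_shared * shared[:, block_of] + w_own * noise
        dosage += (z < thresholds[None, :]).astype(float)
    prefix = "d" if cohort == "discovery" else "t"
    sample_ids = [f"{prefix}{i:05d}" for i in range(1, n + 1)]
    return GenotypeMatrix(sample_ids, snp_metadata(cfg), dosage)


def simulate_gwas(
    snp_meta: pd.DataFrame, causal_ids: list[str], cfg: SimConfig
) -> GwasSummary:
    """Reference-style GWAS summary statistics.

    Estimated betas are true effects plus sampling noise at the analytic SE
    ``1 / sqrt(2 f (1-f) n_ref)``; p-values come from the implied z, so null
    SNPs have Uniform(0,1) p and strong causal SNPs tiny p.
    """
    unknown = set(causal_ids) - set(snp_meta["snp_id"])
    if unknown:
        raise ValidationError(f"causal ids absent from snp_meta: {sorted(unknown)[:5]}")
    rng = _rng(cfg, _S_GWAS_NOISE)
    true_b = true_effect_sizes(cfg)
    freqs = allele_frequencies(cfg)
    freq_of = dict(zip(_snp_ids(cfg), freqs))
    rows = []
    noise = rng.standard_normal(len(snp_meta))
    for i, row in snp_meta.iterrows():
        sid = row["snp_id"]
        f = freq_of.get(sid, 0.25)
        se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * cfg.gwas_ref_n)
        beta_hat = true_b.get(sid, 0.0) + se * noise[i]
        z = beta_hat / se
        p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
        rows.append(
            {
                "snp_id": sid,
                "chrom": row["chrom"],
                "pos": row["pos"],
                "effect_allele": row["counted_allele"],
                "other_allele": row["other_allele"],
                "beta": float(beta_hat),
                "p_value": p,
            }
        )
    return GwasSummary(pd.DataFrame(rows))


def genetic_value(geno: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """True dosage-weighted genetic value of each sample."""
    true_b = true_effect_sizes(cfg)
    w = np.array([true_b.get(s, 0.0) for s in geno.snp_meta["snp_id"]])
    return geno.imputed_dosages() @ w


def simulate_insulin(
    geno: GenotypeMatrix,
    gwas: GwasSummary,  # noqa: ARG001 - interface parity; true effects come from cfg
    causal_ids: list[str],
    cfg: SimConfig,
) -> np.ndarray:
    """Continuous phenotype = genetic value + Gaussian noise at the
    configured heritability."""
    present = set(geno.snp_meta["snp_id"])
    absent = [s for s in causal_ids if s not in present]
    if absent:
        raise ValidationError(f"causal SNPs absent from genotypes: {absent[:5]}")
    rng = _rng(cfg, _S_PHENO)
    g = genetic_value(geno, cfg)
    var_g = float(g.var())
    if cfg.h2 == 0.0:
        return rng.standard_normal(geno.n_samples)
    if var_g == 0.0:
        raise ValidationError("zero genetic variance with h2 > 0")
    if cfg.h2 == 1.0:
        return g.copy()
    noise_sd = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
    return g + rng.normal(0.0, noise_sd, geno.n_samples)


def simulate_adversity(cfg: SimConfig, n: int):
    """Adversity components with missing-at-random gaps.

    Binary components are Bernoulli(prevalence); continuous ones standard
    normal. Returns a list of :class:`~prsgxe.phenotypes.AdversityComponent`.
    """
    from .phenotypes import AdversityComponent

    if not cfg.adversity_spec:
        raise ValidationError("adversity_spec is empty")
    rng = _rng(cfg, _S_ADV)
    out = []
    for spec in cfg.adversity_spec:
        if spec.kind == "binary":
            v = rng.binomial(1, spec.prevalence, n).astype(float)
        else:
            v = rng.standard_normal(n)
        miss = rng.random(n) < spec.missing_rate
        v[miss] = np.nan
        out.append(AdversityComponent(spec.name, spec.kind, v))
    return out


def simulate_outcome(
    x, m, covariates=None, cfg: SimConfig | None = None
) -> np.ndarray:
    """Continuous outcome with the planted interaction:
    ``intercept + bX*x + bM*m + bXM*x*m + noise`` (plus optional covariate
    effects of zero by default)."""
    if cfg is None:
        cfg = SimConfig()
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise ValidationError("x and m must be aligned")
    g = cfg.gxe
    lp = g.intercept + g.bX * x + g.bM * m + g.bXM * x * m
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.shape[0]:
            cov = cov.T
        if cov.shape[0] != x.shape[0]:
            raise ValidationError("covariates do not match sample count")
        # covariates enter the design downstream but carry no true effect
    rng = _rng(cfg, _S_OUT)
    if g.noise_sd == 0.0:
        return lp
    return lp + rng.normal(0.0, g.noise_sd, x.shape[0])


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    """Write the samples x SNPs dosage TSV the loaders consume."""
    df = pd.DataFrame(geno.dosages, columns=geno.snp_ids)
    df.insert(0, "sample_id", geno.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_snp_meta_tsv(geno: GenotypeMatrix, path) -> None:
    geno.snp_meta.to_csv(path, sep="\t", index=False)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as an uncompressed VCF (GT only).

    Non-integer dosages are rounded; counted allele is written as ALT.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, row in geno.snp_meta.iterrows():
            calls = []
            for d in geno.dosages[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                f"{row['other_allele']}\t{row['counted_allele']}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
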