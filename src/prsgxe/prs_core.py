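"""Polygenic-score construction with threshold selection and SNP refinement.

Workflow: LD-clump the GWAS against a reference panel, scan a grid of
GWAS p-value cutoffs for the score that best predicts the training
phenotype, then keep only SNPs individually associated with that phenotype
(raw per-SNP p below ``alpha_refine``) and transfer the resulting weighted
score to an independent cohort, standardized there.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .geno_io import GenotypeMatrix, GwasSummary, _safe_r2
from .gxe_stats import fit_ols

#: 100 equally spaced GWAS p-value cutoffs on (0, 1].
DEFAULT_GRID = [round(0.01 * i, 2) for i in range(1, 101)]
DEFAULT_ALPHA_REFINE = 0.05
DEFAULT_CLUMP_WINDOW_KB = 250.0
DEFAULT_CLUMP_R2 = 0.2


@dataclass
class ClumpResult:
    """Index SNPs retained by greedy clumping and, for each removed SNP,
    the index SNP responsible."""

    retained: list[str]
    removed_by: dict[str, str]

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.removed_by)
        if overlap:
            raise ValidationError(f"SNPs both retained and removed: {sorted(overlap)[:5]}")


@dataclass
class ThresholdScan:
    """Grid of cutoffs with incremental R^2 and PRS-coefficient p per row."""

    table: pd.DataFrame  # columns: threshold, n_snps, r2_incremental, p_prs
    best_threshold: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class RefinedSnpSet:
    """SNP subset surviving per-SNP refinement, with GWAS weights."""

    entries: pd.DataFrame  # columns: snp_id, weight, refine_p
    alpha_refine: float
    source_threshold: float

    def __post_init__(self) -> None:
        need = ["snp_id", "weight", "refine_p"]
        missing = [c for c in need if c not in self.entries.columns]
        if missing:
            raise ValidationError(f"refined set missing columns {missing}")
        if (self.entries["refine_p"] >= self.alpha_refine).any():
            raise ValidationError("refined set contains refine_p >= alpha_refine")
        if not np.isfinite(self.entries["weight"]).all():
            raise ValidationError("refined set contains non-finite weights")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.entries["snp_id"])

    def content_hash(self) -> str:
        return hashlib.sha256(self._tsv_text().encode()).hexdigest()

    def _tsv_text(self) -> str:
        df = self.entries.copy()
        df["weight"] = df["weight"].map(lambda v: f"{v:.10g}")
        df["refine_p"] = df["refine_p"].map(lambda v: f"{v:.10g}")
        return df.to_csv(sep="\t", index=False)

    def to_tsv(self, path) -> None:
        """Write entries as TSV plus a JSON sidecar with provenance."""
        path = str(path)
        with open(path, "w") as fh:
            fh.write(self._tsv_text())
        sidecar = {
            "source_threshold": self.source_threshold,
            "alpha_refine": self.alpha_refine,
            "sha256": self.content_hash(),
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "RefinedSnpSet":
        path = str(path)
        entries = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        return cls(
            entries=entries,
            alpha_refine=sidecar["alpha_refine"],
            source_threshold=sidecar["source_threshold"],
        )


@dataclass
class PrsProfile:
    """Per-sample raw and standardized (mean 0, SD 1) polygenic scores."""

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        ok = ~np.isnan(self.standardized)
        if ok.sum() >= 2:
            m = float(self.standardized[ok].mean())
            s = float(self.standardized[ok].std())
            if abs(m) > 1e-9 or abs(s - 1.0) > 1e-9:
                raise ValidationError("standardized scores are not mean 0 / SD 1")


def _standardize(raw: np.ndarray) -> np.ndarray:
    sd = raw.std()  # population SD: (0, 2) -> (-1, 1)
    if sd == 0:
        raise ValidationError("score is constant; cannot standardize")
    return (raw - raw.mean()) / sd


def ld_clump(
    gwas: GwasSummary,
    ref: GenotypeMatrix,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> ClumpResult:
    """Greedy LD clumping by ascending GWAS p-value.

    Each index SNP removes not-yet-retained SNPs within ``window_kb`` on the
    same chromosome whose r^2 with it (in the reference panel) exceeds
    ``r2_max``. Ties on p-value break lexicographically on snp_id.
    """
    meta = ref.snp_meta
    shared = gwas.table[gwas.table["snp_id"].isin(set(meta["snp_id"]))]
    if shared.empty:
        raise ValidationError("no overlap between GWAS and reference panel")
    order = shared.sort_values(["p_value", "snp_id"], kind="mergesort")["snp_id"]
    col = {sid: j for j, sid in enumerate(meta["snp_id"])}
    chrom = meta["chrom"].to_numpy()
    pos = meta["pos"].to_numpy()
    window_bp = window_kb * 1000.0

    snp_ids = meta["snp_id"].to_numpy()
    candidates = set(order)
    removed_by: dict[str, str] = {}
    retained: list[str] = []
    retained_set: set[str] = set()
    for sid in order:
        if sid in removed_by:
            continue
        retained.append(sid)
        retained_set.add(sid)
        j = col[sid]
        near = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp)
        for k in np.flatnonzero(near):
            other = snp_ids[k]
            if (
                other == sid
                or other in removed_by
                or other in retained_set
                or other not in candidates
            ):
                continue
            if _safe_r2(ref.dosages[:, j], ref.dosages[:, k]) > r2_max:
                removed_by[other] = sid
    return ClumpResult(retained=retained, removed_by=removed_by)


def compute_prs(
    geno: GenotypeMatrix, gwas: GwasSummary, threshold: float
) -> PrsProfile:
    """Weighted allele-count score over SNPs with GWAS p <= threshold.

    Missing dosages are mean-imputed per SNP. Raw and standardized
    (population SD) scores are returned.
    """
    pmap = gwas.p_value_of()
    bmap = gwas.beta_of()
    mask = np.array(
        [pmap.get(s, np.inf) <= threshold for s in geno.snp_meta["snp_id"]]
    )
    if not mask.any():
        raise ValidationError(f"no SNP passes threshold {threshold}")
    d = geno.imputed_dosages()[:, mask]
    w = np.array([bmap[s] for s in geno.snp_meta["snp_id"][mask]])
    raw = d @ w
    return PrsProfile(
        sample_ids=list(geno.sample_ids),
        raw=raw,
        standardized=_standardize(raw),
        n_snps_used=int(mask.sum()),
    )


def _covariate_design(n: int, covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValidationError("covariates do not match sample count")
    names = ["intercept"] + [f"cov{j}" for j in range(cov.shape[1])]
    return np.column_stack([np.ones(n), cov]), names


def threshold_scan(
    geno: GenotypeMatrix,
    gwas: GwasSummary,
    phenotype,
    covariates=None,
    grid: list[float] | None = None,
) -> ThresholdScan:
    """Evaluate PRS prediction of the training phenotype over a cutoff grid.

    For each cutoff, fits ``phenotype ~ covariates + PRS`` and records the
    PRS coefficient p-value and the incremental R^2 over the
    covariates-only model. Cutoffs admitting zero SNPs are recorded with
    ``n_snps = 0`` and NaN statistics. Best threshold: minimum p, ties
    broken by larger incremental R^2 then smaller cutoff.
    """
    if grid is None:
        grid = list(DEFAULT_GRID)
    if not grid:
        raise ValidationError("threshold grid is empty")
    grid = sorted(float(t) for t in grid)
    if len(set(grid)) != len(grid):
        raise ValidationError("threshold grid has duplicates")
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != geno.n_samples:
        raise ValidationError("phenotype length does not match samples")
    base_X, base_names = _covariate_design(geno.n_samples, covariates)
    r2_base = fit_ols(y, base_X, base_names).r_squared if base_X.shape[1] > 1 else 0.0

    pvals = np.array([gwas.p_value_of().get(s, np.inf) for s in geno.snp_meta["snp_id"]])
    betas = np.array([gwas.beta_of().get(s, 0.0) for s in geno.snp_meta["snp_id"]])
    d = geno.imputed_dosages()

    rows = []
    for t in grid:
        mask = pvals <= t
        n_snps = int(mask.sum())
        if n_snps == 0:
            rows.append((t, 0, np.nan, np.nan))
            continue
        raw = d[:, mask] @ betas[mask]
        if raw.std() == 0:
            rows.append((t, n_snps, np.nan, np.nan))
            continue
        X = np.column_stack([base_X, _standardize(raw)])
        fit = fit_ols(y, X, base_names + ["prs"])
        rows.append((t, n_snps, fit.r_squared - r2_base, fit.p("prs")))
    table = pd.DataFrame(rows, columns=["threshold", "n_snps", "r2_incremental", "p_prs"])
    usable = table.dropna(subset=["p_prs"])
    if usable.empty:
        raise ValidationError("no grid cutoff admitted a usable PRS")
    best = usable.sort_values(
        ["p_prs", "r2_incremental", "threshold"],
        ascending=[True, False, True],
        kind="mergesort",
    ).iloc[0]
    return ThresholdScan(table=table, best_threshold=float(best["threshold"]))


def refine_snps(
    geno: GenotypeMatrix,
    gwas: GwasSummary,
    phenotype,
    covariates=None,
    source_threshold: float = 1.0,
    alpha_refine: float = DEFAULT_ALPHA_REFINE,
) -> RefinedSnpSet:
    """Per-SNP regression filter inside the selected threshold.

    For every SNP with GWAS p <= ``source_threshold``, fits
    ``phenotype ~ covariates + dosage`` and keeps SNPs whose dosage
    coefficient has raw p < ``alpha_refine`` (no multiple-testing
    correction). Weights remain the original GWAS betas.

    Implementation note: covariates are partialled out of both phenotype and
    dosages once (Frisch-Waugh), so each per-SNP p-value equals the full
    multiple-regression p-value.
    """
    y = np.asarray(phenotype, dtype=float)
    pmap = gwas.p_value_of()
    bmap = gwas.beta_of()
    ids = geno.snp_meta["snp_id"]
    mask = np.array([pmap.get(s, np.inf) <= source_threshold for s in ids])
    if not mask.any():
        raise ValidationError(f"no SNP passes source threshold {source_threshold}")
    base_X, _ = _covariate_design(geno.n_samples, covariates)
    q, _ = np.linalg.qr(base_X)
    resid = lambda v: v - q @ (q.T @ v)  # noqa: E731
    ey = resid(y)
    G = geno.imputed_dosages()[:, mask]
    eg = G - q @ (q.T @ G)
    ss_g = (eg ** 2).sum(axis=0)
    usable = ss_g > 0
    slope = np.zeros(eg.shape[1])
    pvals = np.ones(eg.shape[1])
    slope[usable] = (eg[:, usable].T @ ey) / ss_g[usable]
    df = geno.n_samples - base_X.shape[1] - 1
    if df <= 0:
        raise ValidationError("not enough samples for per-SNP refinement")
    rss = (ey ** 2).sum() - slope ** 2 * ss_g
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / ss_g)
        tstat = slope / se
    pvals[usable] = 2.0 * stats.t.sf(np.abs(tstat[usable]), df)

    cand_ids = list(ids[mask])
    keep = pvals < alpha_refine
    if not keep.any():
        raise ValidationError(
            "refinement retained zero SNPs; consider a larger alpha_refine "
            "or a different source threshold"
        )
    entries = pd.DataFrame(
        {
            "snp_id": [cand_ids[i] for i in np.flatnonzero(keep)],
            "weight": [bmap[cand_ids[i]] for i in np.flatnonzero(keep)],
            "refine_p": pvals[keep],
        }
    )
    return RefinedSnpSet(
        entries=entries,
        alpha_refine=alpha_refine,
        source_threshold=source_threshold,
    )


def compute_rprs(test_geno: GenotypeMatrix, refined: RefinedSnpSet) -> PrsProfile:
    """Score a test cohort with the refined SNP set.

    Refined SNPs absent from the cohort are dropped with a warning listing
    them; the score is standardized within the test cohort.
    """
    present = set(test_geno.snp_meta["snp_id"])
    missing = [s for s in refined.snp_ids if s not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} refined SNP(s) absent from test cohort: {missing}",
            stacklevel=2,
        )
    used = refined.entries[~refined.entries["snp_id"].isin(missing)]
    if used.empty:
        raise ValidationError("no refined SNP present in test cohort")
    weights = dict(zip(used["snp_id"], used["weight"]))
    cols = [j for j, s in enumerate(test_geno.snp_meta["snp_id"]) if s in weights]
    d = test_geno.imputed_dosages()[:, cols]
    w = np.array([weights[test_geno.snp_meta["snp_id"].iloc[j]] for j in cols])
    raw = d @ w
    return PrsProfile(
        sample_ids=list(test_geno.sample_ids),
        raw=raw,
        standardized=_standardize(raw),
        n_snps_used=len(cols),
    )
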