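"""Genotype / GWAS-summary I/O, allele alignment, QC and population structure.

Dosages are stored as floats in [0, 2]; missing calls are ``numpy.nan``.
Missing-data policy: PRS and PCA mean-impute per SNP, while LD and HWE use
pairwise-complete samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConstantInputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

GWAS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "p_value",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
#: Strand-ambiguous allele pairs dropped during alignment.
_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics (effect sizes and p-values)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"GWAS summary missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def p_value_of(self) -> dict[str, float]:
        return dict(zip(self.table["snp_id"], self.table["p_value"]))

    def beta_of(self) -> dict[str, float]:
        return dict(zip(self.table["snp_id"], self.table["beta"]))

    def subset(self, snp_ids) -> "GwasSummary":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return GwasSummary(self.table.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    ``snp_meta`` columns: snp_id, chrom, pos, counted_allele, other_allele.
    ``dosages[i, j]`` is the dosage of ``counted_allele`` for sample i at
    SNP j, in [0, 2] or NaN when missing.
    """

    sample_ids: list[str]
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValidationError("snp_meta length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if self.snp_meta["snp_id"].duplicated().any():
            dups = self.snp_meta.loc[self.snp_meta["snp_id"].duplicated(), "snp_id"]
            raise ValidationError(f"duplicate snp ids: {list(dups)[:5]}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0, 2] at sample {self.sample_ids[i]!r}, "
                f"snp {self.snp_meta['snp_id'].iloc[j]!r}: {self.dosages[i, j]}"
            )
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_meta.index[self.snp_meta["snp_id"] == snp_id]
        if len(j) == 0:
            raise KeyError(snp_id)
        return self.dosages[:, j[0]]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        wanted = set(snp_ids)
        mask = self.snp_meta["snp_id"].isin(wanted).to_numpy()
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_meta=self.snp_meta.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing cells replaced by the per-SNP mean."""
        d = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return d

    def allele_freqs(self) -> np.ndarray:
        """Counted-allele frequency per SNP (non-missing samples)."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class QcThresholds:
    """Per-SNP QC cutoffs: call rate, minor-allele frequency, HWE p."""

    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-30

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def preset(cls, name: str) -> "QcThresholds":
        presets = {
            "default": cls(0.95, 0.05, 1e-30),
            "alternate": cls(0.95, 0.01, 5e-7),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValidationError(f"unknown QC preset {name!r}") from None


@dataclass
class PruneConfig:
    """Sliding-window LD pruning parameters."""

    window_kb: float = 50.0
    step_snps: int = 5
    r2_max: float = 0.2

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValidationError("window_kb must be > 0")
        if self.step_snps < 1:
            raise ValidationError("step_snps must be >= 1")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValidationError("r2_max must be in [0, 1]")


def read_gwas_summary(path) -> GwasSummary:
    """Read a GWAS summary TSV and validate every row.

    Expected header: snp_id, chrom, pos, effect_allele, other_allele,
    beta, p_value. Errors name the offending 1-based file line.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error type
        raise ParseError(f"cannot read GWAS summary {path}: {exc}") from exc
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    df = df[GWAS_COLUMNS]

    def _line(i: int) -> str:
        # header is line 1, first data row line 2
        return f"{path} line {i + 2}"

    for col in ("beta", "p_value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            raise ParseError(f"{_line(int(np.flatnonzero(bad)[0]))}: bad {col}")
        df[col] = vals
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any() or (pos != pos.round()).any() or (pos < 1).any():
        i = int(np.flatnonzero(pos.isna() | (pos != pos.round()) | (pos < 1))[0])
        raise ParseError(f"{_line(i)}: pos must be a positive integer")
    df["pos"] = pos.astype(int)

    bad_p = ~((df["p_value"] > 0) & (df["p_value"] <= 1))
    if bad_p.any():
        i = int(np.flatnonzero(bad_p)[0])
        raise ParseError(f"{_line(i)}: p_value must be in (0, 1]")
    if not np.isfinite(df["beta"]).all():
        i = int(np.flatnonzero(~np.isfinite(df["beta"]))[0])
        raise ParseError(f"{_line(i)}: beta must be finite")
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(f"{_line(i)}: {col} must be one of A/C/G/T")
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        i = int(np.flatnonzero(same)[0])
        raise ParseError(f"{_line(i)}: effect_allele equals other_allele")
    dup = df["snp_id"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ParseError(f"{_line(i)}: duplicate snp_id {df['snp_id'].iloc[i]!r}")
    return GwasSummary(df)


def _parse_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: htslib import is comparatively slow

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ParseError(f"{path}: VCF has no sample columns")
    meta_rows = []
    dosage_rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ParseError(
                f"{path}: multi-allelic record at {v.CHROM}:{v.POS} unsupported"
            )
        ds = None
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
            with np.errstate(invalid="ignore"):
                if np.any((row < 0) | (row > 2)):
                    raise ParseError(f"{path}: DS outside [0, 2] at {v.CHROM}:{v.POS}")
        else:
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            gt = v.gt_types.astype(float)
            row = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        meta_rows.append(
            {
                "snp_id": vid,
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "counted_allele": v.ALT[0],  # dosage counts ALT copies
                "other_allele": v.REF,
            }
        )
        dosage_rows.append(row)
    if not meta_rows:
        raise ParseError(f"{path}: no variant records")
    dosages = np.array(dosage_rows, dtype=float).T  # samples x snps
    return GenotypeMatrix(sample_ids, pd.DataFrame(meta_rows), dosages)


def _parse_dosage_tsv(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: first column must be 'sample_id'")
    snp_ids = [c for c in df.columns if c != "sample_id"]
    if not snp_ids:
        raise ParseError(f"{path}: no SNP columns")
    dosages = df[snp_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (dosages < 0) | (dosages > 2)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: dosage {dosages[i, j]} outside [0, 2] "
            f"(sample {df['sample_id'].iloc[i]!r}, snp {snp_ids[j]!r})"
        )
    if snp_meta is not None:
        meta = snp_meta.set_index("snp_id").reindex(snp_ids).reset_index()
        if meta["pos"].isna().any():
            absent = meta.loc[meta["pos"].isna(), "snp_id"].tolist()
            raise ParseError(f"{path}: snp_meta missing entries for {absent[:5]}")
        meta["pos"] = meta["pos"].astype(int)
    else:
        # No positional metadata shipped with a bare dosage TSV: synthesise
        # placeholder coordinates and unknown alleles ('N' = assume aligned).
        meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": "0",
                "pos": np.arange(1, len(snp_ids) + 1),
                "counted_allele": "N",
                "other_allele": "N",
            }
        )
    return GenotypeMatrix(list(df["sample_id"]), meta, dosages)


def load_genotypes(path, format: str = "vcf", snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load genotypes from a VCF (GT, DS honored) or a dosage TSV.

    Hard calls map 0/0 -> 0, 0/1 -> 1, 1/1 -> 2 copies of ALT; ``./.``
    becomes NaN. For ``dosage_tsv`` an optional ``snp_meta`` frame supplies
    coordinates and alleles; otherwise placeholders are used.
    """
    if format == "vcf":
        return _parse_vcf(path)
    if format == "dosage_tsv":
        return _parse_dosage_tsv(path, snp_meta)
    raise ValidationError(f"unknown genotype format {format!r}")


def align_alleles(geno: GenotypeMatrix, gwas: GwasSummary) -> GenotypeMatrix:
    """Orient dosages so the counted allele is the GWAS effect allele.

    Flips d -> 2 - d where the matrix counted the GWAS other allele. SNPs
    with strand-ambiguous pairs (A/T, C/G) or irreconcilable alleles are
    dropped and logged. SNPs absent from the GWAS are dropped. Columns with
    unknown alleles ('N') are kept as-is and assumed pre-aligned.
    """
    eff = gwas.table.set_index("snp_id")["effect_allele"]
    oth = gwas.table.set_index("snp_id")["other_allele"]
    keep_idx: list[int] = []
    flip: list[bool] = []
    dropped_ambiguous: list[str] = []
    dropped_mismatch: list[str] = []
    for j, row in geno.snp_meta.iterrows():
        sid = row["snp_id"]
        if sid not in eff.index:
            continue
        a, b = row["counted_allele"], row["other_allele"]
        if a == "N" or b == "N":
            keep_idx.append(j)
            flip.append(False)
            continue
        if frozenset({a, b}) in _AMBIGUOUS_PAIRS:
            dropped_ambiguous.append(sid)
            continue
        e, o = eff.loc[sid], oth.loc[sid]
        if a == e and b == o:
            keep_idx.append(j)
            flip.append(False)
        elif a == o and b == e:
            keep_idx.append(j)
            flip.append(True)
        else:
            dropped_mismatch.append(sid)
    for sid in dropped_ambiguous:
        logger.info("align_alleles: dropped strand-ambiguous SNP %s", sid)
    for sid in dropped_mismatch:
        logger.info("align_alleles: dropped irreconcilable SNP %s", sid)
    if not keep_idx:
        raise AlignmentError("no SNPs overlap between genotypes and GWAS after alignment")
    meta = geno.snp_meta.iloc[keep_idx].copy().reset_index(drop=True)
    dos = geno.dosages[:, keep_idx].copy()
    flip_arr = np.asarray(flip)
    if flip_arr.any():
        dos[:, flip_arr] = 2.0 - dos[:, flip_arr]
        meta.loc[flip_arr, ["counted_allele", "other_allele"]] = meta.loc[
            flip_arr, ["other_allele", "counted_allele"]
        ].to_numpy()
    return GenotypeMatrix(list(geno.sample_ids), meta, dos)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against HWE proportions."""
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValidationError("hwe_test requires at least one genotype")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: trivially consistent with HWE
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_p_per_snp(geno: GenotypeMatrix) -> np.ndarray:
    """HWE p per SNP from rounded hard calls on pairwise-complete samples."""
    out = np.empty(geno.n_snps)
    for j in range(geno.n_snps):
        d = geno.dosages[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            out[j] = np.nan
            continue
        hard = np.clip(np.rint(d), 0, 2).astype(int)
        counts = np.bincount(hard, minlength=3)
        # orientation of hom classes does not change the chi-square
        out[j] = hwe_test(int(counts[2]), int(counts[1]), int(counts[0]))
    return out


def qc_filter(geno: GenotypeMatrix, thr: QcThresholds | None = None) -> GenotypeMatrix:
    """Drop SNPs failing call-rate, MAF, or HWE thresholds.

    Per-criterion removal counts are logged; criteria are evaluated on the
    input matrix (a SNP may fail several).
    """
    if thr is None:
        thr = QcThresholds()
    call_rate = 1.0 - np.isnan(geno.dosages).mean(axis=0)
    freq = geno.allele_freqs()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = _hwe_p_per_snp(geno)

    fail_call = call_rate < thr.call_rate_min
    fail_maf = np.isnan(maf) | (maf < thr.maf_min)
    fail_hwe = np.isnan(hwe_p) | (hwe_p < thr.hwe_p_min)
    logger.info(
        "qc_filter: removed %d (call rate), %d (MAF), %d (HWE) of %d SNPs",
        int(fail_call.sum()),
        int(fail_maf.sum()),
        int(fail_hwe.sum()),
        geno.n_snps,
    )
    keep = ~(fail_call | fail_maf | fail_hwe)
    if not keep.any():
        raise ValidationError("qc_filter removed every SNP")
    return GenotypeMatrix(
        list(geno.sample_ids),
        geno.snp_meta.loc[keep].reset_index(drop=True),
        geno.dosages[:, keep],
    )


def ld_r2(d_a: np.ndarray, d_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete samples; a constant vector makes r^2 undefined
    and raises :class:`ConstantInputError`.
    """
    a = np.asarray(d_a, dtype=float)
    b = np.asarray(d_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValidationError("need >= 2 pairwise-complete samples")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ConstantInputError("r^2 undefined for a constant dosage vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def _safe_r2(a: np.ndarray, b: np.ndarray) -> float:
    """ld_r2 treating undefined (constant-vector) correlations as 0."""
    try:
        return ld_r2(a, b)
    except ConstantInputError:
        return 0.0


def prune_ld(geno: GenotypeMatrix, cfg: PruneConfig | None = None) -> list[str]:
    """Greedy positional LD pruning.

    SNPs are visited in (chrom, pos, snp_id) order; a SNP is retained only
    if its r^2 with every already-retained SNP within ``window_kb`` upstream
    on the same chromosome is <= ``r2_max``. Guarantees no retained pair
    within any window exceeds the threshold; deterministic and invariant to
    sample order.
    """
    if cfg is None:
        cfg = PruneConfig()
    order = geno.snp_meta.sort_values(
        ["chrom", "pos", "snp_id"], kind="mergesort"
    ).index.to_numpy()
    window_bp = cfg.window_kb * 1000.0
    retained: list[int] = []
    for j in order:
        chrom_j = geno.snp_meta.at[j, "chrom"]
        pos_j = geno.snp_meta.at[j, "pos"]
        ok = True
        for k in reversed(retained):
            if geno.snp_meta.at[k, "chrom"] != chrom_j:
                break
            if pos_j - geno.snp_meta.at[k, "pos"] > window_bp:
                break
            if _safe_r2(geno.dosages[:, j], geno.dosages[:, k]) > cfg.r2_max:
                ok = False
                break
        if ok:
            retained.append(j)
    return [geno.snp_meta.at[j, "snp_id"] for j in retained]


def compute_pcs(
    geno: GenotypeMatrix, k: int, cfg: PruneConfig | None = None
) -> np.ndarray:
    """Principal-component coordinates of the standardized dosage matrix.

    LD pruning (``cfg``) is applied first when given; constant SNPs are
    excluded; missing dosages are mean-imputed. Returns an
    n_samples x k array ordered by decreasing explained variance.
    """
    work = geno
    if cfg is not None:
        work = geno.subset_snps(prune_ld(geno, cfg))
    d = work.imputed_dosages()
    sd = d.std(axis=0)
    nonconst = sd > 0
    d = d[:, nonconst]
    if d.shape[1] < k:
        raise ValidationError(
            f"only {d.shape[1]} non-constant SNPs available for {k} PCs"
        )
    z = (d - d.mean(axis=0)) / d.std(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise ValidationError(f"k={k} exceeds matrix rank {rank}")
    return u[:, :k] * s[:k]
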