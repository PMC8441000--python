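import numpy as np
import pandas as pd
import pytest

from prsgxe import synthetic_data as sd
from prsgxe.errors import ValidationError
from prsgxe.prs_core import (
    DEFAULT_GRID,
    RefinedSnpSet,
    compute_prs,
    compute_rprs,
    ld_clump,
    refine_snps,
    threshold_scan,
)

from conftest import make_geno, make_gwas


def oracle_clump(gwas, ref, r2_max, window_kb):
    """Independent exhaustive greedy clumping oracle."""
    meta = ref.snp_meta
    shared = gwas.table[gwas.table["snp_id"].isin(set(meta["snp_id"]))]
    order = shared.sort_values(["p_value", "snp_id"], kind="mergesort")["snp_id"].tolist()
    col = {s: j for j, s in enumerate(meta["snp_id"])}
    removed = {}
    retained = []
    for sid in order:
        if sid in removed:
            continue
        retained.append(sid)
        j = col[sid]
        for other in order:
            if other == sid or other in removed or other in retained:
                continue
            k = col[other]
            if meta["chrom"].iloc[j] != meta["chrom"].iloc[k]:
                continue
            if abs(int(meta["pos"].iloc[j]) - int(meta["pos"].iloc[k])) > window_kb * 1000:
                continue
            a, b = ref.dosages[:, j], ref.dosages[:, k]
            ok = ~(np.isnan(a) | np.isnan(b))
            if a[ok].std() == 0 or b[ok].std() == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 > r2_max:
                removed[other] = sid
    return retained, removed


class TestLdClump:
    def test_correlated_pair_keeps_smaller_p(self, rng):
        a = rng.integers(0, 3, 200).astype(float)
        b = np.clip(a + rng.normal(0, 0.55, 200), 0, 2)  # r2 well above 0.2
        ref = make_geno(np.column_stack([a, b]), pos=[1000, 2000])
        gwas = make_gwas(["snp001", "snp002"], [0.1, 0.1], [1e-4, 1e-2])
        res = ld_clump(gwas, ref, r2_max=0.2, window_kb=250)
        assert res.retained == ["snp001"]
        assert res.removed_by == {"snp002": "snp001"}

    def test_uncorrelated_all_retained(self, rng):
        d = rng.binomial(2, 0.5, (500, 4)).astype(float)
        ref = make_geno(d)
        gwas = make_gwas(ref.snp_ids, [0.1] * 4, [0.04, 0.03, 0.02, 0.01])
        res = ld_clump(gwas, ref, r2_max=0.2, window_kb=250)
        assert sorted(res.retained) == sorted(ref.snp_ids)

    def test_matches_exhaustive_oracle_30_snps(self, rng):
        base = rng.integers(0, 3, (150, 5)).astype(float)
        cols = [
            np.clip(base[:, rng.integers(0, 5)] + rng.normal(0, 0.7, 150), 0, 2)
            for _ in range(30)
        ]
        ref = make_geno(
            np.column_stack(cols),
            pos=sorted(rng.integers(1, 100_000, 30).tolist()),
        )
        pvals = rng.uniform(1e-6, 1, 30)
        gwas = make_gwas(ref.snp_ids, rng.normal(0, 0.1, 30), pvals)
        res = ld_clump(gwas, ref, r2_max=0.2, window_kb=50)
        exp_retained, exp_removed = oracle_clump(gwas, ref, 0.2, 50)
        assert res.retained == exp_retained
        assert res.removed_by == exp_removed

    def test_partition_invariant(self, rng):
        d = rng.binomial(2, 0.4, (100, 10)).astype(float)
        ref = make_geno(d, pos=sorted(rng.integers(1, 20_000, 10).tolist()))
        gwas = make_gwas(ref.snp_ids, [0.1] * 10, rng.uniform(0.001, 1, 10))
        res = ld_clump(gwas, ref, 0.2, 50)
        assert set(res.retained) | set(res.removed_by) == set(ref.snp_ids)
        assert not set(res.retained) & set(res.removed_by)

    def test_empty_overlap_errors(self, rng):
        ref = make_geno(rng.binomial(2, 0.5, (10, 2)).astype(float))
        gwas = make_gwas(["absent"], [0.1], [0.5])
        with pytest.raises(ValidationError):
            ld_clump(gwas, ref)


class TestComputePrs:
    def test_single_snp_hand_sum(self):
        geno = make_geno([[0.0], [1.0], [2.0]])
        gwas = make_gwas(["snp001"], [0.5], [0.01])
        prof = compute_prs(geno, gwas, threshold=0.05)
        np.testing.assert_allclose(prof.raw, [0.0, 0.5, 1.0])

    def test_threshold_excluding_all_errors(self):
        geno = make_geno([[0.0], [1.0]])
        gwas = make_gwas(["snp001"], [0.5], [0.5])
        with pytest.raises(ValidationError, match="0.1"):
            compute_prs(geno, gwas, threshold=0.1)

    def test_matches_double_loop_oracle(self, rng):
        n, m = 20, 10
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_geno(d)
        betas = rng.normal(0, 0.3, m)
        pvals = rng.uniform(0.001, 1, m)
        gwas = make_gwas(geno.snp_ids, betas, pvals)
        t = 0.5
        prof = compute_prs(geno, gwas, t)
        expected = np.zeros(n)
        for i in range(n):
            for j in range(m):
                if pvals[j] <= t:
                    expected[i] += d[i, j] * betas[j]
        np.testing.assert_allclose(prof.raw, expected, rtol=1e-12)

    def test_nesting_of_threshold_sets(self, rng):
        d = rng.binomial(2, 0.4, (30, 15)).astype(float)
        geno = make_geno(d)
        gwas = make_gwas(geno.snp_ids, rng.normal(0, 0.2, 15), rng.uniform(0.001, 1, 15))
        n1 = compute_prs(geno, gwas, 0.3).n_snps_used
        n2 = compute_prs(geno, gwas, 0.8).n_snps_used
        assert n1 <= n2
        assert compute_prs(geno, gwas, 1.0).n_snps_used == 15

    def test_standardized_mean_sd(self, rng):
        d = rng.binomial(2, 0.4, (50, 5)).astype(float)
        geno = make_geno(d)
        gwas = make_gwas(geno.snp_ids, rng.normal(0, 0.2, 5), [0.01] * 5)
        s = compute_prs(geno, gwas, 1.0).standardized
        assert s.mean() == pytest.approx(0, abs=1e-9)
        assert s.std() == pytest.approx(1, abs=1e-9)


class TestThresholdScan:
    @pytest.fixture
    def training(self, rng):
        n, m = 400, 60
        d = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
        geno = make_geno(d, pos=list(range(1000, 1000 + 100_000 * m, 100_000)))
        betas = np.zeros(m)
        betas[:6] = rng.choice([-1, 1], 6) * 0.3
        pvals = np.concatenate([rng.uniform(0.001, 0.05, 6), rng.uniform(0.1, 1, m - 6)])
        gwas = make_gwas(geno.snp_ids, betas, pvals)
        y = d @ betas + rng.normal(0, 1.0, n)
        return geno, gwas, y

    def test_default_grid_has_100_cutoffs(self, training):
        geno, gwas, y = training
        scan = threshold_scan(geno, gwas, y)
        assert len(scan.table) == 100
        assert list(scan.table["threshold"]) == DEFAULT_GRID

    def test_n_snps_non_decreasing(self, training):
        geno, gwas, y = training
        scan = threshold_scan(geno, gwas, y)
        assert (np.diff(scan.table["n_snps"]) >= 0).all()

    def test_zero_snp_cutoffs_recorded(self, rng):
        geno = make_geno(rng.binomial(2, 0.4, (50, 3)).astype(float))
        gwas = make_gwas(geno.snp_ids, [0.2, 0.3, -0.1], [0.5, 0.6, 0.7])
        y = rng.normal(0, 1, 50)
        scan = threshold_scan(geno, gwas, y, grid=[0.1, 0.6, 1.0])
        row = scan.table.iloc[0]
        assert row["n_snps"] == 0 and np.isnan(row["p_prs"])

    def test_best_threshold_in_grid(self, training):
        geno, gwas, y = training
        scan = threshold_scan(geno, gwas, y)
        assert scan.best_threshold in set(scan.table["threshold"])

    def test_causal_threshold_beats_exclusion(self):
        # causal SNPs all at p <= 0.1: best cutoff should explain at least as
        # much variance as the smallest cutoff that drops some causal SNP
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n, m = 500, 80
            d = rng.binomial(2, rng.uniform(0.15, 0.5, m), (n, m)).astype(float)
            geno = make_geno(d, pos=list(range(1000, 1000 + 100_000 * m, 100_000)))
            betas = np.zeros(m)
            betas[:8] = rng.choice([-1, 1], 8) * 0.3
            pvals = np.concatenate(
                [rng.uniform(0.02, 0.1, 8), rng.uniform(0.15, 1.0, m - 8)]
            )
            gwas = make_gwas(geno.snp_ids, betas, pvals)
            y = d @ betas + rng.normal(0, 1.2, n)
            scan = threshold_scan(geno, gwas, y)
            tbl = scan.table.set_index("threshold")
            best_r2 = tbl.loc[scan.best_threshold, "r2_incremental"]
            excl_r2 = tbl.loc[0.02, "r2_incremental"]  # drops some causal SNPs
            if np.isnan(excl_r2) or best_r2 >= excl_r2:
                wins += 1
        assert wins >= 11  # majority of 20 seeds

    def test_empty_grid_errors(self, training):
        geno, gwas, y = training
        with pytest.raises(ValidationError):
            threshold_scan(geno, gwas, y, grid=[])


class TestRefineSnps:
    def test_alpha_boundary(self, rng):
        n, m = 300, 12
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_geno(d)
        gwas = make_gwas(geno.snp_ids, rng.normal(0, 0.2, m), [0.01] * m)
        y = d[:, 0] * 0.2 + rng.normal(0, 1, n)
        base = refine_snps(geno, gwas, y, source_threshold=1.0, alpha_refine=1.0)
        probe = base.entries.iloc[len(base) // 2]
        p_mid = float(probe["refine_p"])
        above = refine_snps(geno, gwas, y, source_threshold=1.0,
                            alpha_refine=p_mid * 1.000001)
        below = refine_snps(geno, gwas, y, source_threshold=1.0,
                            alpha_refine=p_mid)
        assert probe["snp_id"] in above.snp_ids
        assert probe["snp_id"] not in below.snp_ids  # strict '<' at the cutoff

    def test_null_retention_rate_near_alpha(self):
        kept = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            n, m = 150, 200
            d = rng.binomial(2, 0.4, (n, m)).astype(float)
            geno = make_geno(d, pos=list(range(1000, 1000 + 1000 * m, 1000)))
            gwas = make_gwas(geno.snp_ids, rng.normal(0, 0.1, m), [0.5] * m)
            y = rng.normal(0, 1, n)  # independent of genotypes
            try:
                res = refine_snps(geno, gwas, y, source_threshold=1.0, alpha_refine=0.05)
                kept += len(res)
            except ValidationError:
                pass
            total += m
        expected = 0.05 * total
        band = 2.58 * np.sqrt(total * 0.05 * 0.95)
        assert abs(kept - expected) <= band

    def test_subset_of_threshold_set(self, rng):
        n, m = 200, 20
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_geno(d)
        pvals = rng.uniform(0.001, 1, m)
        gwas = make_gwas(geno.snp_ids, rng.normal(0, 0.3, m), pvals)
        y = d @ rng.normal(0, 0.2, m) + rng.normal(0, 1, n)
        res = refine_snps(geno, gwas, y, source_threshold=0.5, alpha_refine=0.8)
        admitted = {s for s, p in zip(geno.snp_ids, pvals) if p <= 0.5}
        assert set(res.snp_ids) <= admitted

    def test_zero_retained_advises(self, rng):
        n, m = 100, 5
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_geno(d)
        gwas = make_gwas(geno.snp_ids, [0.1] * m, [0.01] * m)
        y = rng.normal(0, 1, n)
        with pytest.raises(ValidationError, match="alpha"):
            refine_snps(geno, gwas, y, source_threshold=1.0, alpha_refine=1e-12)

    def test_weights_are_gwas_betas(self, rng):
        n, m = 200, 6
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_geno(d)
        betas = rng.normal(0, 0.3, m)
        gwas = make_gwas(geno.snp_ids, betas, [0.01] * m)
        y = d @ betas + rng.normal(0, 0.5, n)
        res = refine_snps(geno, gwas, y, source_threshold=1.0, alpha_refine=0.5)
        bmap = dict(zip(geno.snp_ids, betas))
        for _, row in res.entries.iterrows():
            assert row["weight"] == bmap[row["snp_id"]]

    def test_refinement_per_snp_p_matches_full_ols(self, rng):
        # Frisch-Waugh shortcut must reproduce the multiple-regression p
        import statsmodels.api as sm

        n, m = 120, 4
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        geno = make_geno(d)
        gwas = make_gwas(geno.snp_ids, [0.1] * m, [0.01] * m)
        cov = rng.normal(0, 1, (n, 2))
        y = d[:, 1] * 0.3 + cov[:, 0] * 0.5 + rng.normal(0, 1, n)
        res = refine_snps(geno, gwas, y, covariates=cov,
                          source_threshold=1.0, alpha_refine=1.0)
        for _, row in res.entries.iterrows():
            j = geno.snp_ids.index(row["snp_id"])
            X = sm.add_constant(np.column_stack([cov, d[:, j]]))
            p = sm.OLS(y, X).fit().pvalues[-1]
            assert row["refine_p"] == pytest.approx(p, rel=1e-8)


class TestComputeRprs:
    def test_standardized_mean_sd(self, rng):
        d = rng.binomial(2, 0.4, (80, 4)).astype(float)
        geno = make_geno(d)
        refined = RefinedSnpSet(
            entries=pd.DataFrame(
                {"snp_id": geno.snp_ids, "weight": rng.normal(0, 0.3, 4),
                 "refine_p": [0.01] * 4}
            ),
            alpha_refine=0.05,
            source_threshold=0.24,
        )
        prof = compute_rprs(geno, refined)
        assert prof.standardized.mean() == pytest.approx(0, abs=1e-9)
        assert prof.standardized.std() == pytest.approx(1, abs=1e-9)

    def test_single_snp_hand_values(self):
        geno = make_geno([[0.0], [2.0]])
        refined = RefinedSnpSet(
            entries=pd.DataFrame({"snp_id": ["snp001"], "weight": [0.3],
                                  "refine_p": [0.01]}),
            alpha_refine=0.05,
            source_threshold=0.24,
        )
        prof = compute_rprs(geno, refined)
        np.testing.assert_allclose(prof.raw, [0.0, 0.6])
        np.testing.assert_allclose(prof.standardized, [-1.0, 1.0])

    def test_absent_snp_warns_and_uses_rest(self, rng):
        d = rng.binomial(2, 0.4, (50, 2)).astype(float)
        geno = make_geno(d)
        refined = RefinedSnpSet(
            entries=pd.DataFrame(
                {"snp_id": ["snp001", "snp002", "ghost"],
                 "weight": [0.2, -0.1, 0.4], "refine_p": [0.01] * 3}
            ),
            alpha_refine=0.05,
            source_threshold=0.24,
        )
        with pytest.warns(UserWarning, match="ghost"):
            prof = compute_rprs(geno, refined)
        assert prof.n_snps_used == 2

    def test_zero_overlap_errors(self, rng):
        geno = make_geno(rng.binomial(2, 0.4, (10, 1)).astype(float))
        refined = RefinedSnpSet(
            entries=pd.DataFrame({"snp_id": ["ghost"], "weight": [0.1],
                                  "refine_p": [0.01]}),
            alpha_refine=0.05,
            source_threshold=0.24,
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                compute_rprs(geno, refined)


class TestRefinedSnpSetSerialization:
    def test_round_trip_and_hash(self, tmp_path, rng):
        entries = pd.DataFrame(
            {"snp_id": ["rs1", "rs2"], "weight": [0.123456, -0.2],
             "refine_p": [0.01, 0.04]}
        )
        refined = RefinedSnpSet(entries=entries, alpha_refine=0.05, source_threshold=0.24)
        path = tmp_path / "refined.tsv"
        refined.to_tsv(path)
        back = RefinedSnpSet.from_tsv(path)
        assert back.snp_ids == refined.snp_ids
        assert back.alpha_refine == 0.05
        assert back.content_hash() == refined.content_hash()

    def test_invariant_refine_p_below_alpha(self):
        with pytest.raises(ValidationError):
            RefinedSnpSet(
                entries=pd.DataFrame(
                    {"snp_id": ["rs1"], "weight": [0.1], "refine_p": [0.2]}
                ),
                alpha_refine=0.05,
                source_threshold=0.24,
            )


class TestRecoveryProperties:
    def test_refined_set_enriches_causal_fraction(self):
        """Refinement should concentrate causal SNPs relative to the full
        threshold set in most seeds (planted effects, h2 = 0.3)."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            sc = sd.SimConfig(
                n_discovery=2000, n_test=100, n_snps=500, n_causal=20,
                h2=0.3, seed=3000 + seed,
            )
            geno = sd.simulate_genotypes(sc, "discovery")
            causal = sd.causal_snp_ids(sc)
            # planted |beta| >= 0.15 with random signs
            betas = {c: float(s * b) for c, s, b in zip(
                causal, rng.choice([-1, 1], len(causal)),
                rng.uniform(0.15, 0.3, len(causal)))}
            w = np.array([betas.get(s, 0.0) for s in geno.snp_ids])
            g = geno.imputed_dosages() @ w
            noise_sd = np.sqrt(g.var() * (1 - sc.h2) / sc.h2)
            y = g + rng.normal(0, noise_sd, geno.n_samples)
            freqs = sd.allele_frequencies(sc)
            se = 1.0 / np.sqrt(2 * freqs * (1 - freqs) * sc.gwas_ref_n)
            beta_hat = w + se * rng.standard_normal(sc.n_snps)
            from scipy import stats as st
            pv = np.clip(2 * st.norm.sf(np.abs(beta_hat / se)), 1e-300, 1.0)
            gwas = make_gwas(geno.snp_ids, beta_hat, pv,
                             pos=list(geno.snp_meta["pos"]),
                             chrom=list(geno.snp_meta["chrom"]))
            scan = threshold_scan(geno, gwas, y)
            thr_set = [s for s, p in zip(geno.snp_ids, pv) if p <= scan.best_threshold]
            refined = refine_snps(geno, gwas, y,
                                  source_threshold=scan.best_threshold,
                                  alpha_refine=0.05)
            frac_full = np.mean([s in causal for s in thr_set])
            frac_ref = np.mean([s in causal for s in refined.snp_ids])
            if frac_ref >= frac_full:
                wins += 1
        assert wins >= int(0.8 * n_seeds)

    def test_end_to_end_determinism(self):
        def build():
            rng = np.random.default_rng(42)
            sc = sd.SimConfig(n_discovery=400, n_snps=100, n_causal=8, seed=42)
            geno = sd.simulate_genotypes(sc, "discovery")
            causal = sd.causal_snp_ids(sc)
            gwas = sd.simulate_gwas(geno.snp_meta, causal, sc)
            y = sd.simulate_insulin(geno, gwas, causal, sc)
            return refine_snps(geno, gwas, y, source_threshold=0.5, alpha_refine=0.3)

        assert build().content_hash() == build().content_hash()
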