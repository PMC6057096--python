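"""Signed -log10(p) concordance, min-rank null, and enrichment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

import polyglia as pg
from polyglia.concordance import (
    ModuleDefinition,
    concordance_rho,
    min_rank_probability,
    module_concordance,
    module_enrichment,
    signed_scores,
)


def scan_frame(betas, pvals):
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(betas))],
            "beta": betas,
            "p": pvals,
        }
    )


class TestSignedScores:
    def test_basic_values(self):
        s = signed_scores(scan_frame([1.0, -2.0, 0.5], [0.01, 0.1, 1.0]))
        np.testing.assert_allclose(s.to_numpy(), [2.0, -1.0, 0.0])

    def test_zero_p_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            s = signed_scores(scan_frame([1.0], [0.0]))
        assert s.iloc[0] == 300.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            signed_scores(scan_frame([1.0], [1.5]))


class TestConcordanceRho:
    def test_identity_and_antiidentity(self, rng):
        a = pd.Series(rng.normal(size=12), index=[f"v{i}" for i in range(12)])
        rho, _ = concordance_rho(a, a)
        assert rho == pytest.approx(1.0)
        rho, _ = concordance_rho(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_null_mean_rho_near_zero(self, rng):
        """Independent vectors: mean Spearman rho within 3 SE of 0."""
        n, reps = 50, 300
        rhos = []
        for _ in range(reps):
            idx = [f"v{i}" for i in range(n)]
            a = pd.Series(rng.uniform(size=n), index=idx)
            b = pd.Series(rng.uniform(size=n), index=idx)
            rhos.append(concordance_rho(a, b)[0])
        rhos = np.asarray(rhos)
        assert abs(rhos.mean()) < 3 * rhos.std(ddof=1) / np.sqrt(reps)

    def test_exact_permutation_p_for_tiny_n(self):
        idx = list("abcdef")
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=idx)
        b = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=idx)
        rho, p = concordance_rho(a, b)
        assert rho == pytest.approx(1.0)
        # perfect concordance: only the 2 sign-extreme orderings of 6! tie it
        assert p == pytest.approx(2 / 720)

    def test_constant_vector_returns_nan_with_warning(self, rng):
        idx = [f"v{i}" for i in range(8)]
        a = pd.Series(np.ones(8), index=idx)
        b = pd.Series(rng.normal(size=8), index=idx)
        with pytest.warns(UserWarning, match="constant"):
            rho, p = concordance_rho(a, b)
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_variants_rejected(self):
        a = pd.Series([1.0, 2.0], index=["v0", "v1"])
        with pytest.raises(ValueError, match="at least 4"):
            concordance_rho(a, a)

    def test_sign_flip_equivariance(self, rng):
        """Negating one phenotype's betas negates every rho exactly."""
        betas = rng.normal(size=20)
        pvals = rng.uniform(0.001, 1.0, 20)
        b2 = rng.normal(size=20)
        p2 = rng.uniform(0.001, 1.0, 20)
        a = signed_scores(scan_frame(betas, pvals))
        b = signed_scores(scan_frame(b2, p2))
        b_neg = signed_scores(scan_frame(-b2, p2))
        assert concordance_rho(a, b)[0] == pytest.approx(-concordance_rho(a, b_neg)[0])


class TestMinRankProbability:
    def test_headline_value_at_full_size(self):
        # P(min of 5 draws from 1..47 <= 1) = 1 - C(46,5)/C(47,5) = 5/47
        assert min_rank_probability(1, 5, 47) == pytest.approx(5 / 47)

    def test_k_equals_m_min_is_always_one(self):
        assert min_rank_probability(1, 10, 10) == pytest.approx(1.0)

    def test_pair_example_by_enumeration(self):
        # M=10, k=2: P(min <= 1) over all 45 pairs = 9/45 = 0.2
        assert min_rank_probability(1, 2, 10) == pytest.approx(0.2)

    @pytest.mark.parametrize("M", [5, 8, 12])
    def test_closed_forms_match_exhaustive_enumeration(self, M):
        for k in range(1, M + 1):
            subsets = list(combinations(range(1, M + 1), k))
            for r in range(1, M - k + 2):
                tail = sum(min(s) <= r for s in subsets) / len(subsets)
                point = sum(min(s) == r for s in subsets) / len(subsets)
                assert min_rank_probability(r, k, M) == pytest.approx(tail)
                assert min_rank_probability(r, k, M, mode="point") == pytest.approx(point)

    @pytest.mark.parametrize("M,k", [(10, 3), (47, 5), (15, 15)])
    def test_point_masses_sum_to_one(self, M, k):
        total = sum(
            min_rank_probability(r, k, M, mode="point") for r in range(1, M - k + 2)
        )
        assert total == pytest.approx(1.0)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            min_rank_probability(7, 5, 10)  # min of 5 from 10 is at most 6
        with pytest.raises(ValueError):
            min_rank_probability(0, 5, 10)


class TestModuleEnrichment:
    def test_hand_enumerated_example(self):
        # N=20, K=5 marked, module of 4, overlap 3:
        # (C(5,3)C(15,1) + C(5,4)C(15,0)) / C(20,4) = 155/4845
        p, immune = module_enrichment(4, 3, 5, 20)
        assert p == pytest.approx(155 / 4845)
        assert not immune

    def test_module_equals_universe(self):
        p, _ = module_enrichment(20, 5, 5, 20)
        assert p == pytest.approx(1.0)

    def test_zero_overlap_probability_one(self):
        p, immune = module_enrichment(4, 0, 5, 20)
        assert p == pytest.approx(1.0) and not immune

    def test_strong_enrichment_flagged_immune(self):
        p, immune = module_enrichment(50, 40, 60, 2000)
        assert p < 1e-10 and immune

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            module_enrichment(4, 5, 5, 20)  # overlap > module size

    def test_module_definition_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModuleDefinition("m1", ("g1", "g1"))
        with pytest.raises(ValueError, match="overlap"):
            ModuleDefinition("m1", ("g1",), microglial_overlap=2)


class TestModuleConcordance:
    @staticmethod
    def _scans(rng, n_modules=15, n_variants=40, concordant=("m01",)):
        """Density scan plus module scans; listed modules share the
        density effect pattern (concordant signs), others are null."""
        base_beta = rng.normal(size=n_variants)
        base_p = rng.uniform(0.001, 1.0, n_variants)
        density = scan_frame(base_beta, base_p)
        module_scans = {}
        for i in range(1, n_modules + 1):
            mid = f"m{i:02d}"
            if mid in concordant:
                jitter = np.clip(base_p * np.exp(rng.normal(0, 0.2, n_variants)), 1e-6, 1.0)
                module_scans[mid] = scan_frame(base_beta + 0.1 * rng.normal(size=n_variants), jitter)
            else:
                module_scans[mid] = scan_frame(
                    rng.normal(size=n_variants), rng.uniform(0.001, 1.0, n_variants)
                )
        return density, module_scans

    def test_planted_concordant_immune_module_ranks_first(self, rng):
        density, scans = self._scans(rng)
        res = module_concordance(density, scans, immune_modules=["m01", "m02"])
        assert res.table.iloc[0]["module_id"] == "m01"
        assert res.immune_min_rank == 1
        assert res.min_rank_p == pytest.approx(min_rank_probability(1, 2, 15))

    def test_point_mode_reported(self, rng):
        density, scans = self._scans(rng)
        res = module_concordance(density, scans, immune_modules=["m01"], mode="point")
        assert res.mode == "point"
        assert res.min_rank_p == pytest.approx(
            min_rank_probability(res.immune_min_rank, 1, 15, mode="point")
        )

    def test_missing_immune_modules_rejected(self, rng):
        density, scans = self._scans(rng)
        with pytest.raises(ValueError, match="immune"):
            module_concordance(density, scans, immune_modules=["zz"])


class TestConcordancePower:
    def test_shared_architecture_puts_immune_module_in_top_ranks(self):
        """When a variant set truly affects density and an immune module
        proportionally, that module's concordance rank lands in the top
        5 of 47 far more often than the null rate P(min<=5) ~ 0.43."""
        from polyglia.cohort import DEFAULT_IMMUNE_MODULES, default_module_ids
        from polyglia.screen import COVARIATES_NEUROPATH

        hits = reps = 0
        for seed in range(6):
            spec = pg.ArchitectureSpec.diffuse(20, polygenic_effect=0.0, seed=600 + seed)
            erng = np.random.default_rng(600 + seed)
            spec.driver_indices = np.arange(20)
            spec.driver_effects = erng.choice([-1, 1], 20) * erng.uniform(0.02, 0.2, 20)
            gm = pg.simulate_genotypes(spec, 400)
            cov = pg.simulate_covariates(400, seed=600 + seed)
            pheno, _ = pg.simulate_phenotypes(gm, spec, cov)
            table = pg.weight_table(spec, "s")
            eqtls = [
                (vid, DEFAULT_IMMUNE_MODULES[0], 2.5 * eff)
                for vid, eff in zip(gm.variant_ids, spec.driver_effects)
            ]
            expr, immune = pg.simulate_modules(gm, eqtls, seed=600 + seed)
            dscan = pg.per_variant_scan(
                table, gm, pheno["microglia_all"], cov, COVARIATES_NEUROPATH, maf_min=0.0
            )
            scans = {
                m: pg.per_variant_scan(
                    table, gm, expr[m], cov, COVARIATES_NEUROPATH, maf_min=0.0
                )
                for m in default_module_ids()
            }
            res = pg.module_concordance(dscan, scans, immune)
            planted_rank = res.table.set_index("module_id").loc[
                DEFAULT_IMMUNE_MODULES[0], "rank"
            ]
            hits += planted_rank <= 5
            reps += 1
        assert hits / reps >= 5 / 6  # null rate for top-5 is ~0.43


class TestDirectModuleScreen:
    def test_planted_anticorrelated_module_detected_negative(self):
        spec = pg.ArchitectureSpec.single_driver(15, seed=55)
        gm = pg.simulate_genotypes(spec, 700)
        cov = pg.simulate_covariates(700, seed=55)
        pheno, _ = pg.simulate_phenotypes(gm, spec, cov)
        rng = np.random.default_rng(0)
        density = pheno["microglia_midfrontal_stage123"]
        z = (density - density.mean()) / density.std()
        expr, _ = pg.simulate_modules(gm, [], seed=9)
        expr["m10"] = -0.4 * z.to_numpy() + rng.normal(0, 1, 700)
        grid = pg.direct_module_screen(
            density.rename("density"), expr, cov, ("age", "sex", "pc1", "pc2", "pc3")
        )
        cell = grid.cell("density", "m10")
        assert cell["t"] < 0 and cell["significant"]
        n_sig = len(grid.significant_cells)
        assert n_sig <= 3  # the planted module, not broad false positives
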