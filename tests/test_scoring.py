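"""Allele harmonization and average per-allele score computation."""

import numpy as np
import pandas as pd
import pytest

from polyglia.scoring import GenotypeMatrix, WeightTable, compute_grs, harmonize, recompute_excluding


def make_table(weights, effect=None, other=None, eaf=None, trait="t"):
    m = len(weights)
    return WeightTable(
        trait,
        pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1),
                "effect_allele": effect or ["A"] * m,
                "other_allele": other or ["G"] * m,
                "weight": weights,
                "effect_allele_freq": eaf if eaf is not None else [np.nan] * m,
            }
        ),
    )


def make_geno(dosage, counted=None, other=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        subject_ids=np.array([f"s{i}" for i in range(n)]),
        variant_ids=np.array([f"v{i}" for i in range(m)]),
        dosage=dosage,
        counted_allele=np.asarray(counted or ["A"] * m),
        other_allele=np.asarray(other or ["G"] * m),
    )


def brute_force_score(weights, dosage, eaf_fallback=None):
    """Independent per-subject loop implementing the scoring rule."""
    n, m = dosage.shape
    out = np.zeros(n)
    for j in range(n):
        total = 0.0
        for i in range(m):
            d = dosage[j, i]
            if not np.isfinite(d):
                col = dosage[:, i]
                obs = col[np.isfinite(col)]
                f = obs.mean() / 2.0 if obs.size else eaf_fallback[i]
                d = 2.0 * f
            total += weights[i] * d
        out[j] = total / (2.0 * m)
    return out


class TestComputeGRS:
    def test_single_variant_homozygote(self):
        # M=1, w=ln2, d=2 -> (2 ln2)/(2*1) = ln2
        ss = compute_grs(make_table([np.log(2)]), make_geno([[2.0], [2.0]]))
        assert ss.scores.iloc[0] == pytest.approx(np.log(2))

    def test_zero_weights_zero_scores(self):
        ss = compute_grs(make_table([0.0, 0.0]), make_geno([[1, 2], [0, 1]]))
        np.testing.assert_array_equal(ss.scores.to_numpy(), 0.0)

    def test_missing_entry_imputed_at_twice_sample_frequency(self):
        # w=(0.1,0.3); subject 0 has (1, missing); sample EAF of v1 = 0.5
        # -> (1*0.1 + 2*0.5*0.3)/4 = 0.1
        dosage = np.array([[1.0, np.nan], [0.0, 1.0], [2.0, 1.0]])
        ss = compute_grs(make_table([0.1, 0.3]), make_geno(dosage))
        assert ss.scores.iloc[0] == pytest.approx(0.1)
        assert ss.n_missing.iloc[0] == 1 and ss.n_missing.iloc[1] == 0

    def test_all_missing_column_falls_back_to_table_frequency(self):
        dosage = np.array([[1.0, np.nan], [0.0, np.nan]])
        ss = compute_grs(make_table([0.1, 0.3], eaf=[0.5, 0.25]), make_geno(dosage))
        # imputed dosage 2*0.25 = 0.5 for the second variant
        assert ss.scores.iloc[0] == pytest.approx((0.1 + 0.5 * 0.3) / 4)

    def test_all_missing_without_frequency_errors_with_name(self):
        dosage = np.array([[1.0, np.nan], [0.0, np.nan]])
        with pytest.raises(ValueError, match="v1"):
            compute_grs(make_table([0.1, 0.3]), make_geno(dosage))

    def test_matches_brute_force_on_random_cohort(self, rng):
        m, n = 12, 40
        w = rng.normal(size=m)
        dosage = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        dosage[rng.random((n, m)) < 0.1] = np.nan
        ss = compute_grs(make_table(list(w)), make_geno(dosage))
        np.testing.assert_allclose(ss.scores.to_numpy(), brute_force_score(w, dosage), atol=1e-12)

    def test_stacked_tables_average_like_m_weighted_mean(self, rng):
        """Linearity: a 2M-variant score is the M-weighted mean of halves."""
        m, n = 8, 30
        w = rng.normal(size=2 * m)
        dosage = rng.binomial(2, 0.5, size=(n, 2 * m)).astype(float)
        full = compute_grs(make_table(list(w)), make_geno(dosage)).scores.to_numpy()
        a = compute_grs(make_table(list(w[:m])), make_geno(dosage[:, :m])).scores.to_numpy()
        gb = make_geno(dosage[:, m:])
        tb = make_table(list(w[m:]))
        tb.variants["variant_id"] = [f"v{i+m}" for i in range(m)]
        gb.variant_ids = np.array([f"v{i+m}" for i in range(m)])
        b = compute_grs(tb, gb).scores.to_numpy()
        np.testing.assert_allclose(full, (a + b) / 2.0, atol=1e-12)

    def test_constant_weight_shift_acts_through_formula_only(self, rng):
        """No hidden centering: shifting weights by c shifts scores by
        c * (mean per-allele dosage across variants)."""
        m, n = 6, 25
        w = rng.normal(size=m)
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        base = compute_grs(make_table(list(w)), make_geno(dosage)).scores.to_numpy()
        shift = compute_grs(make_table(list(w + 1.7)), make_geno(dosage)).scores.to_numpy()
        expected = base + 1.7 * dosage.sum(axis=1) / (2 * m)
        np.testing.assert_allclose(shift, expected, atol=1e-12)

    def test_mcar_missingness_leaves_mean_score_unbiased(self, rng):
        """Frequency imputation: E[score] unchanged under MCAR (3 SE)."""
        m, n, reps = 10, 400, 30
        w = rng.normal(size=m)
        deltas = []
        for _ in range(reps):
            dosage = rng.binomial(2, 0.4, size=(n, m)).astype(float)
            complete = compute_grs(make_table(list(w)), make_geno(dosage)).scores
            masked = dosage.copy()
            masked[rng.random((n, m)) < 0.15] = np.nan
            with_miss = compute_grs(make_table(list(w)), make_geno(masked)).scores
            deltas.append(with_miss.mean() - complete.mean())
        deltas = np.asarray(deltas)
        assert abs(deltas.mean()) < 3 * deltas.std(ddof=1) / np.sqrt(reps)


class TestHarmonize:
    def test_matching_alleles_leave_dosage_unchanged(self):
        t = make_table([0.2])
        g = make_geno([[2.0], [1.0]])
        _, hg = harmonize(t, g)
        np.testing.assert_array_equal(hg.dosage, [[2.0], [1.0]])

    def test_swapped_alleles_flip_dosage(self):
        t = make_table([0.2], effect=["G"], other=["A"])
        g = make_geno([[2.0], [0.0]])  # counts A, table's other allele
        _, hg = harmonize(t, g)
        np.testing.assert_array_equal(hg.dosage, [[0.0], [2.0]])

    def test_irreconcilable_alleles_dropped_with_warning(self):
        t = make_table([0.2, 0.3], effect=["A", "C"], other=["G", "G"])
        g = make_geno([[1.0, 1.0], [0.0, 2.0]])  # v1 counts A/G, table says C/G
        with pytest.warns(UserWarning, match="irreconcilable"):
            ht, hg = harmonize(t, g)
        assert list(ht.variants["variant_id"]) == ["v0"]

    def test_empty_intersection_errors(self):
        t = make_table([0.2])
        g = make_geno([[1.0], [1.0]])
        g.variant_ids = np.array(["other"])
        with pytest.raises(ValueError, match="no variants shared"):
            harmonize(t, g)

    def test_resigning_weights_preserves_centered_scores(self, rng):
        """Negative weight re-signed + dosage flipped: scores shift by a
        constant only, so centered scores (and any regression) match."""
        m, n = 5, 40
        w = rng.normal(size=m)  # mixed signs
        dosage = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        t, g = make_table(list(w)), make_geno(dosage)
        base = compute_grs(*harmonize(t, g)).scores.to_numpy()
        ht, hg = harmonize(t, g, resign_weights=True)
        assert (ht.variants["weight"] >= 0).all()
        resigned = compute_grs(ht, hg).scores.to_numpy()
        np.testing.assert_allclose(
            resigned - resigned.mean(), base - base.mean(), atol=1e-12
        )

    def test_palindromic_kept_with_warning_or_dropped(self):
        t = make_table([0.2], effect=["A"], other=["T"])
        g = make_geno([[1.0], [2.0]], counted=["A"], other=["T"])
        with pytest.warns(UserWarning, match="palindromic"):
            ht, _ = harmonize(t, g)
        assert len(ht) == 1
        with pytest.raises(ValueError):  # dropping the only variant empties it
            harmonize(t, g, drop_ambiguous=True)


class TestRecomputeExcluding:
    def test_empty_exclusion_is_identity(self, rng):
        w = rng.normal(size=6)
        dosage = rng.binomial(2, 0.4, size=(20, 6)).astype(float)
        t, g = make_table(list(w)), make_geno(dosage)
        np.testing.assert_allclose(
            recompute_excluding(t, g, []).scores, compute_grs(t, g).scores
        )

    def test_excluding_only_nonzero_weight_zeroes_scores(self):
        t = make_table([0.5, 0.0])
        g = make_geno([[1.0, 2.0], [2.0, 0.0]])
        ss = recompute_excluding(t, g, ["v0"])
        np.testing.assert_array_equal(ss.scores.to_numpy(), 0.0)
        assert ss.n_variants_used == 1

    def test_cannot_exclude_everything(self):
        t = make_table([0.5])
        g = make_geno([[1.0], [2.0]])
        with pytest.raises(ValueError, match="every variant"):
            recompute_excluding(t, g, ["v0"])

    def test_unknown_exclusion_id_errors(self):
        t = make_table([0.5, 0.2])
        g = make_geno([[1.0, 0.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="nope"):
            recompute_excluding(t, g, ["nope"])

    def test_removing_zero_weight_variant_only_rescales(self, rng):
        """Dropping a w=0 variant changes the denominator 2M -> 2(M-1)
        but nothing else: correlation with the original is exactly 1."""
        w = np.append(rng.normal(size=7), 0.0)
        dosage = rng.binomial(2, 0.5, size=(50, 8)).astype(float)
        t, g = make_table(list(w)), make_geno(dosage)
        before = compute_grs(t, g).scores.to_numpy()
        after = recompute_excluding(t, g, ["v7"]).scores.to_numpy()
        np.testing.assert_allclose(after, before * 8 / 7, atol=1e-12)


class TestWeightTableValidation:
    def test_duplicate_ids_rejected(self):
        df = make_table([0.1, 0.2]).variants
        df.loc[1, "variant_id"] = "v0"
        with pytest.raises(ValueError, match="duplicate"):
            WeightTable("t", df)

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            make_table([0.1], effect=["A"], other=["A"])
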