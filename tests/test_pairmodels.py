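"""Pooled-allele and Group I/II/III models for SNP pairs."""

import numpy as np
import pandas as pd
import pytest

from haplopair.association import AlleleTable2x2, chi2_p, odds_ratio, woolf_ci
from haplopair.containers import MISSING, GenotypeMatrix, Phenotypes
from haplopair.pairmodels import (
    GroupCounts,
    PolarizedPair,
    additive_test,
    classify_group,
    group_counts,
    multiplicative_test,
    pair_scan,
    polarize,
    pooled_allele_table,
)
from haplopair.ppi import SnpPair


def _two_locus_matrix(da, db, n_case):
    """Matrix with two variants (ALT dosages da, db) and case/control split."""
    da, db = np.asarray(da, dtype=np.int8), np.asarray(db, dtype=np.int8)
    n = len(da)
    samples = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame({
        "variant_id": ["vA", "vB"], "chrom": ["1", "2"], "pos": [100, 200],
        "ref": ["A", "C"], "alt": ["G", "T"],
    })
    gm = GenotypeMatrix(np.column_stack([da, db]), samples, variants)
    status = ["case"] * n_case + ["control"] * (n - n_case)
    pheno = Phenotypes(pd.Series(status, index=pd.Index(samples, name="sample_id")))
    return gm, pheno


PAIR = SnpPair("vA", "vB", "GA", "GB", 0.9)
# negative allele = ALT at both loci
POL = PolarizedPair(PAIR, "G", "A", "T", "C")


class TestPolarize:
    def _results(self, or_a, or_b):
        return pd.DataFrame({
            "variant_id": ["vA", "vB"],
            "effect_allele": ["G", "T"],
            "other_allele": ["A", "C"],
            "or_value": [or_a, or_b],
            "or_other": [1 / or_a, 1 / or_b],
        })

    def test_or_gt1_direction_is_negative(self):
        pol = polarize(PAIR, self._results(2.0, 0.5))
        assert (pol.negative_allele_a, pol.positive_allele_a) == ("G", "A")
        assert (pol.negative_allele_b, pol.positive_allele_b) == ("C", "T")

    def test_swapping_effect_labels_leaves_polarity_unchanged(self):
        res = self._results(2.0, 2.0)
        swapped = res.copy()
        swapped["effect_allele"], swapped["other_allele"] = (
            res["other_allele"], res["effect_allele"])
        swapped["or_value"], swapped["or_other"] = res["or_other"], res["or_value"]
        a = polarize(PAIR, res)
        b = polarize(PAIR, swapped)
        assert (a.negative_allele_a, a.negative_allele_b) == (
            b.negative_allele_a, b.negative_allele_b)

    def test_or_exactly_one_unpolarizable(self):
        with pytest.raises(ValueError, match="no risk direction"):
            polarize(PAIR, self._results(1.0, 2.0))

    def test_absent_variant_rejected(self):
        with pytest.raises(KeyError):
            polarize(SnpPair("vX", "vB", "GA", "GB", 0.9),
                     self._results(2.0, 2.0))

    def test_planted_risk_allele_recovered(self):
        """Polarity from stage-1 ORs matches the generator's planted risk
        allele (ALT) in nearly all replicates at large n."""
        from haplopair.association import run_gwas
        from haplopair.simulate import SimConfig, simulate_cohort

        hits = 0
        n_reps = 20
        for seed in range(n_reps):
            cfg = SimConfig(n_case=2000, n_control=2000, n_variants=2,
                            maf_range=(0.2, 0.2), missing_rate=0.0,
                            planted_pair_effects=((0, 1, 2.0),), seed=seed)
            cohort = simulate_cohort(cfg)
            res = run_gwas(cohort.genotypes, cohort.phenotypes)
            pair = SnpPair("snp00000", "snp00001", "GA", "GB", 0.9)
            pol = polarize(pair, res)
            alt_a = cohort.variants.iloc[0]["alt"]
            alt_b = cohort.variants.iloc[1]["alt"]
            hits += (pol.negative_allele_a == alt_a
                     and pol.negative_allele_b == alt_b)
        assert hits >= 0.95 * n_reps


class TestPooledAlleleTable:
    def test_double_homozygous_risk_case(self):
        gm, pheno = _two_locus_matrix([2], [2], n_case=1)
        t = pooled_allele_table(POL, gm, pheno)
        assert (t.a, t.b, t.c, t.d) == (4, 0, 0, 0)

    def test_complete_data_totals_are_four_per_individual(self):
        rng = np.random.default_rng(0)
        da, db = rng.integers(0, 3, 144), rng.integers(0, 3, 144)
        gm, pheno = _two_locus_matrix(da, db, n_case=144)
        t = pooled_allele_table(POL, gm, pheno)
        assert t.a + t.b == 4 * 144 == 576

    def test_missing_locus_drops_exactly_two_alleles(self):
        gm, pheno = _two_locus_matrix([2, 1], [MISSING, 1], n_case=2)
        t = pooled_allele_table(POL, gm, pheno)
        # individual 1: locus A contributes 2 negative; locus B missing
        # individual 2: 1+1 negative, 1+1 positive
        assert (t.a, t.b) == (4, 2)
        assert t.a + t.b == 6  # not a multiple of 4

    def test_matches_enumeration_with_random_holes(self, rng):
        da = rng.integers(-1, 3, size=20)
        db = rng.integers(-1, 3, size=20)
        if (da == MISSING).all() and (db == MISSING).all():
            da[0] = 1
        gm, pheno = _two_locus_matrix(da, db, n_case=9)
        t = pooled_allele_table(POL, gm, pheno)
        neg = {True: 0, False: 0}
        pos = {True: 0, False: 0}
        for i in range(20):
            is_case = i < 9
            for d in (da[i], db[i]):
                if d == MISSING:
                    continue
                neg[is_case] += int(d)
                pos[is_case] += 2 - int(d)
        assert (t.a, t.b, t.c, t.d) == (neg[True], pos[True], neg[False], pos[False])

    def test_entirely_missing_pair_rejected(self):
        gm, pheno = _two_locus_matrix([MISSING, MISSING], [MISSING, MISSING], 1)
        with pytest.raises(ValueError, match="no non-missing"):
            pooled_allele_table(POL, gm, pheno)


class TestMultiplicativeTest:
    @pytest.mark.parametrize(
        "cells, or_expected",
        [
            ((103, 473, 60, 592), 2.15),
            ((156, 420, 120, 532), 1.65),
            ((84, 492, 53, 599), 1.93),
        ],
    )
    def test_reported_pooled_tables(self, cells, or_expected):
        t = AlleleTable2x2(*cells)
        orr, (lo, hi), p = multiplicative_test(t)
        assert orr == pytest.approx(or_expected, abs=0.005)

    def test_shared_code_identity_with_stage1_statistics(self):
        t = AlleleTable2x2(103, 473, 60, 592)
        orr, ci, p = multiplicative_test(t)
        assert orr == odds_ratio(t)
        assert ci == woolf_ci(t)
        assert p == chi2_p(t)[1]


class TestClassifyGroup:
    @pytest.mark.parametrize("da, db, group", [
        (2, 2, "I"), (2, 1, "I"), (1, 2, "I"),
        (2, 0, "II"), (1, 1, "II"), (0, 2, "II"),
        (1, 0, "III"), (0, 1, "III"), (0, 0, "III"),
    ])
    def test_nine_combinations_partition_three_by_three(self, da, db, group):
        assert classify_group(da, db) == group

    def test_symmetric_in_arguments(self):
        for da in range(3):
            for db in range(3):
                assert classify_group(da, db) == classify_group(db, da)

    def test_missing_dosage_rejected(self):
        with pytest.raises(ValueError):
            classify_group(MISSING, 1)

    def test_group_counts_exclude_incomplete_individuals(self):
        gm, pheno = _two_locus_matrix([2, 2, MISSING], [2, MISSING, 2], 3)
        g = group_counts(POL, gm, pheno)
        assert (g.case_I, g.case_II, g.case_III) == (1, 0, 0)


class TestAdditiveTest:
    def test_balanced_groups_are_null(self):
        g = GroupCounts(10, 0, 10, 10, 0, 10)
        orr, _, p = additive_test(g)
        assert orr == 1.0 and p == 1.0

    def test_pooled_reference_contrast(self):
        g = GroupCounts(20, 30, 10, 10, 30, 20)
        orr, _, _ = additive_test(g, contrast="I_vs_II+III")
        assert orr == pytest.approx((20 * 50) / (40 * 10))

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            additive_test(GroupCounts(1, 1, 1, 1, 1, 1), contrast="II_vs_I")

    def test_planted_additive_effect_detected(self):
        """Per-negative-allele OR 1.6: Group I vs III contrast is positive
        and significant in nearly all large-n replicates, with Group II
        intermediate on average."""
        from haplopair.association import run_gwas
        from haplopair.simulate import SimConfig, simulate_cohort

        n_reps = 20
        detected = 0
        or_i, or_ii = [], []
        pair = SnpPair("snp00000", "snp00001", "GA", "GB", 0.9)
        for seed in range(n_reps):
            cfg = SimConfig(n_case=2000, n_control=2000, n_variants=2,
                            maf_range=(0.3, 0.3), missing_rate=0.0,
                            planted_pair_effects=((0, 1, 1.6),), seed=seed)
            cohort = simulate_cohort(cfg)
            va, vb = cohort.variants.iloc[0], cohort.variants.iloc[1]
            pol = PolarizedPair(pair, va["alt"], va["ref"], vb["alt"], vb["ref"])
            g = group_counts(pol, cohort.genotypes, cohort.phenotypes)
            orr, _, p = additive_test(g)
            detected += (orr > 1.0) and (p < 0.05)
            or_i.append(orr)
            # Group II vs III contrast
            t = AlleleTable2x2(g.case_II, g.case_III, g.control_II, g.control_III)
            or_ii.append(odds_ratio(t))
        assert detected >= 0.9 * n_reps
        assert 1.0 < np.mean(or_ii) < np.mean(or_i)


class TestPairScan:
    def _scan_inputs(self, rng, n_pairs=3):
        da = rng.integers(0, 3, size=60)
        db = rng.integers(0, 3, size=60)
        gm, pheno = _two_locus_matrix(da, db, n_case=30)
        res = pd.DataFrame({
            "variant_id": ["vA", "vB"],
            "effect_allele": ["G", "T"],
            "other_allele": ["A", "C"],
            "or_value": [1.5, 1.5],
            "or_other": [1 / 1.5, 1 / 1.5],
        })
        return gm, pheno, res

    def test_single_pair_threshold_is_alpha(self, rng):
        gm, pheno, res = self._scan_inputs(rng)
        out = pair_scan([PAIR], gm, pheno, res)
        assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.05)

    def test_divisor_counts_tested_pairs(self, rng):
        gm, pheno, res = self._scan_inputs(rng)
        pairs = [PAIR, SnpPair("vB", "vA", "GB", "GA", 0.8)]
        out = pair_scan(pairs, gm, pheno, res)
        assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.025)

    def test_empty_pair_list_rejected(self, rng):
        gm, pheno, res = self._scan_inputs(rng)
        with pytest.raises(ValueError):
            pair_scan([], gm, pheno, res)

    def test_failing_pair_recorded_and_scan_continues(self, rng):
        gm, pheno, res = self._scan_inputs(rng)
        pairs = [PAIR, SnpPair("vA", "missing", "GA", "GX", 0.9)]
        out = pair_scan(pairs, gm, pheno, res)
        assert (out["error"] != "").sum() == 1
        # divisor counts only the pair that was actually tested
        assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.05)
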