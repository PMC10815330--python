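"""Sequential QC filters and the staged removal ledger."""

import numpy as np
import pandas as pd
import pytest

from haplopair.containers import MISSING, GenotypeMatrix, Phenotypes
from haplopair.qc import (
    QCReport,
    QCThresholds,
    apply_qc,
    call_rates,
    hwe_test,
    minor_allele_frequency,
)


def _matrix(dosages, chroms=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_s, n_v = dosages.shape
    chroms = chroms or ["1"] * n_v
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(n_v)],
        "chrom": chroms,
        "pos": np.arange(n_v) * 100 + 1,
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n_s)], variants)


def _pheno(samples, n_case):
    status = ["case"] * n_case + ["control"] * (len(samples) - n_case)
    return Phenotypes(pd.Series(status, index=pd.Index(samples, name="sample_id")))


class TestCallRates:
    def test_complete_matrix_rates_are_one(self):
        gm = _matrix(np.zeros((4, 3)))
        s, v = call_rates(gm)
        assert (s == 1.0).all() and (v == 1.0).all()

    def test_five_percent_missing_sample(self, rng):
        dosages = np.zeros((1, 100), dtype=np.int8)
        dosages[0, :5] = MISSING
        s, _ = call_rates(_matrix(dosages))
        assert s[0] == pytest.approx(0.95)

    def test_random_mask_matches_exhaustive_count(self, rng):
        dosages = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        mask = rng.random((10, 10)) < 0.3
        dosages[mask] = MISSING
        s, v = call_rates(_matrix(dosages))
        for i in range(10):
            assert s[i] == sum(dosages[i, j] != MISSING for j in range(10)) / 10
        for j in range(10):
            assert v[j] == sum(dosages[i, j] != MISSING for i in range(10)) / 10

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            call_rates(_matrix(np.zeros((0, 0))))


class TestMAF:
    def test_monomorphic_reference(self):
        assert minor_allele_frequency(np.zeros(50, dtype=int)) == 0.0

    def test_reported_case_frequency(self):
        # 144 diploid cases carrying 84 of 288 minor alleles
        calls = np.zeros(144, dtype=int)
        calls[:42] = 2  # 84 alleles
        assert minor_allele_frequency(calls) == pytest.approx(0.29, abs=0.005)

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            calls = rng.integers(-1, 3, size=25)
            if (calls == MISSING).all():
                continue
            ok = [g for g in calls if g != MISSING]
            p = sum(ok) / (2 * len(ok))
            assert minor_allele_frequency(calls) == pytest.approx(min(p, 1 - p))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(np.full(5, MISSING))


class TestHWE:
    @pytest.mark.parametrize("counts", [(25, 50, 25), (36, 48, 16)])
    def test_exact_proportions_give_null(self, counts):
        chi2, p = hwe_test(*counts)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_formula(self):
        # p-hat = 0.5: expected (25, 50, 25) out of 100
        chi2, _ = hwe_test(30, 40, 30)
        expected = (30 - 25) ** 2 / 25 + (40 - 50) ** 2 / 50 + (30 - 25) ** 2 / 25
        assert chi2 == pytest.approx(expected)

    def test_monomorphic_convention(self):
        assert hwe_test(50, 0, 0) == (0.0, 1.0)

    def test_no_calls_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestApplyQC:
    def test_reported_staged_ledger_balances(self):
        """With the published staged removal counts from 654,027 autosomal
        markers, exactly 327,038 survive."""
        report = QCReport(
            n_variants_in=654_027,
            n_removed_call_rate=25_323,
            n_samples_removed=3,
            n_removed_maf=231_362,
            n_removed_hwe=70_304,
        )
        report.n_variants_kept = (
            report.n_variants_in - report.n_removed_call_rate
            - report.n_removed_maf - report.n_removed_hwe
        )
        report.check()
        assert report.n_variants_kept == 327_038

    def test_permissive_thresholds_are_identity(self, pair_cohort):
        thr = QCThresholds(min_sample_call_rate=0.0, min_variant_call_rate=0.0,
                           min_maf=0.0, hwe_alpha=0.0, autosomes_only=False)
        gm, report = apply_qc(pair_cohort.genotypes, pair_cohort.phenotypes, thr)
        assert gm.n_variants == pair_cohort.genotypes.n_variants
        assert gm.n_samples == pair_cohort.genotypes.n_samples
        assert report.n_removed_call_rate == 0
        assert report.n_removed_maf == 0
        assert report.n_removed_hwe == 0
        assert report.n_removed_nonautosomal == 0

    def test_removals_match_independent_classifier(self, pair_cohort):
        """Each variant is attributed to the first failing filter; an
        independent per-variant classifier must agree with the ledger."""
        thr = QCThresholds()
        gm_in = pair_cohort.genotypes
        pheno = pair_cohort.phenotypes
        gm, report = apply_qc(gm_in, pheno, thr)

        # brute-force staged reclassification, one variant at a time
        autosomes = {str(i) for i in range(1, 23)}
        n_auto = n_cr = 0
        survivors = []
        for j in range(gm_in.n_variants):
            col = gm_in.dosages[:, j]
            if str(gm_in.variants.iloc[j]["chrom"]) not in autosomes:
                n_auto += 1
            elif (col != MISSING).mean() < thr.min_variant_call_rate:
                n_cr += 1
            else:
                survivors.append(j)
        # sample stage: call rate over the surviving variants only
        keep_sample = [
            np.mean([gm_in.dosages[i, j] != MISSING for j in survivors])
            >= thr.min_sample_call_rate
            for i in range(gm_in.n_samples)
        ]
        n_samples_removed = keep_sample.count(False)
        kept_samples = [s for s, k in zip(gm_in.samples, keep_sample) if k]
        case_mask = pheno.case_mask(kept_samples)
        n_maf = n_hwe = n_kept = 0
        for j in survivors:
            col = gm_in.dosages[np.asarray(keep_sample), j]
            ok = col != MISSING
            p = col[ok].sum() / (2 * ok.sum())
            if min(p, 1 - p) < thr.min_maf:
                n_maf += 1
                continue
            ctrl = col[~case_mask]
            ctrl = ctrl[ctrl != MISSING]
            n0, n1, n2 = (ctrl == 0).sum(), (ctrl == 1).sum(), (ctrl == 2).sum()
            if hwe_test(int(n0), int(n1), int(n2))[1] < thr.hwe_alpha:
                n_hwe += 1
                continue
            n_kept += 1
        assert report.n_samples_removed == n_samples_removed
        assert report.n_removed_nonautosomal == n_auto
        assert report.n_removed_call_rate == n_cr
        assert report.n_removed_maf == n_maf
        assert report.n_removed_hwe == n_hwe
        assert report.n_variants_kept == n_kept

    def test_conservation_invariant(self, pair_cohort, null_cohort):
        for cohort in (pair_cohort, null_cohort):
            _, report = apply_qc(cohort.genotypes, cohort.phenotypes)
            total = (report.n_removed_nonautosomal + report.n_removed_call_rate
                     + report.n_removed_maf + report.n_removed_hwe
                     + report.n_variants_kept)
            assert total == report.n_variants_in

    def test_idempotence(self, pair_cohort):
        thr = QCThresholds()
        gm1, _ = apply_qc(pair_cohort.genotypes, pair_cohort.phenotypes, thr)
        gm2, rep2 = apply_qc(gm1, pair_cohort.phenotypes, thr)
        assert gm2.n_variants == gm1.n_variants
        assert np.array_equal(gm2.dosages, gm1.dosages)

    @pytest.mark.parametrize("maf_lo, maf_hi", [(0.01, 0.05), (0.05, 0.20)])
    def test_raising_maf_floor_is_monotone(self, pair_cohort, maf_lo, maf_hi):
        _, rep_lo = apply_qc(pair_cohort.genotypes, pair_cohort.phenotypes,
                             QCThresholds(min_maf=maf_lo))
        _, rep_hi = apply_qc(pair_cohort.genotypes, pair_cohort.phenotypes,
                             QCThresholds(min_maf=maf_hi))
        assert rep_hi.n_variants_kept <= rep_lo.n_variants_kept

    def test_x_decoys_removed_by_autosome_filter(self, pair_cohort):
        gm, report = apply_qc(pair_cohort.genotypes, pair_cohort.phenotypes)
        assert report.n_removed_nonautosomal == 4
        assert not gm.variants["chrom"].eq("X").any()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(min_maf=1.5)
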