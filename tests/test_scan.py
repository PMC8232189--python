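"""Single-marker scans, simpleM thresholds, cofactors, p_G, epistasis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import hadamard

from ryeqtl.abh import AbhMatrix
from ryeqtl.genome import QtlEffectSpec, SelectionSpec, TrialDesign, uniform_genome
from ryeqtl.scan import (
    confidence_interval,
    effective_marker_number,
    epistasis_scan,
    explained_covariance,
    explained_variance,
    genome_scan,
    prepare_scan,
    scan_single_marker,
    select_cofactors_cm1,
    select_cofactors_cm2,
)
from ryeqtl.simulate import simulate_f2, simulate_phenotypes

PEREN_NOISE = TrialDesign(
    n_locations=2, n_replicates=2, sigma2_location=0.22, sigma2_replicate=0.08,
    sigma2_gxl=1.18, sigma2_error=1.39, sigma2_g_residual=0.9,
)


def _abh_from_codes(codes: np.ndarray) -> AbhMatrix:
    n, m = codes.shape
    return AbhMatrix(
        calls=codes.astype(np.int8),
        genotype_ids=[f"G{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(m)],
    )


def _plots_from_genotype_values(values: np.ndarray, ids, reps=2) -> pd.DataFrame:
    rows = []
    for k in range(reps):
        for gid, v in zip(ids, values):
            rows.append(
                {"genotype": gid, "location": "L1", "replicate": f"R{k + 1}",
                 "trait": "t", "value": v}
            )
    return pd.DataFrame(rows)


class TestEffectiveMarkerNumber:
    def test_single_marker(self):
        rng = np.random.default_rng(0)
        abh = _abh_from_codes(rng.choice([0, 1, 2], size=(30, 1)))
        spec = effective_marker_number(abh)
        assert spec.q_eff == 1
        assert spec.per_test == pytest.approx(0.05)

    def test_ten_duplicate_pairs_give_q_eff_10(self):
        """Twenty columns forming ten identical, mutually uncorrelated pairs:
        the correlation spectrum is ten 2s and ten 0s, so q_eff = 10."""
        h = hadamard(16)[:, 1:11]  # ten orthogonal, zero-mean columns
        base = ((h + 1)).astype(np.int8)  # maps to codes {0, 2}
        codes = np.repeat(base, 2, axis=1)
        abh = _abh_from_codes(codes)
        spec = effective_marker_number(abh)
        assert spec.q_eff == 10
        assert spec.epistasis_per_test == pytest.approx(0.05 / (10 * 9))

    def test_independent_markers_keep_most_dimensions(self):
        rng = np.random.default_rng(1)
        codes = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(1000, 100))
        spec = effective_marker_number(_abh_from_codes(codes))
        assert 90 <= spec.q_eff <= 100

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        codes = rng.choice([0, 1, 2], size=(40, 3))
        codes[:, 1] = 1
        with pytest.warns(UserWarning, match="constant"):
            spec = effective_marker_number(_abh_from_codes(codes))
        assert spec.n_markers == 2

    def test_threshold_validation(self):
        from ryeqtl.scan import ThresholdSpec

        with pytest.raises(ValueError):
            ThresholdSpec(alpha=0.0, q_eff=1, n_markers=1)
        with pytest.raises(ValueError):
            ThresholdSpec(alpha=0.05, q_eff=5, n_markers=2)


class TestSingleMarkerScan:
    def test_planted_qtl_detected_below_simpleM_threshold(self):
        """Power: a cd = 1.34 additive QTL at n = 178 passes the genome-wide
        simpleM threshold in at least 80 % of 200 simulated trials."""
        # threshold from a full-scale (7 x 113 markers) simulated F2
        big = simulate_f2(
            uniform_genome(tuple((f"{j}R", 120.0) for j in range(1, 8)), 113),
            178, rng=np.random.default_rng(10),
        )
        threshold = effective_marker_number(big).per_test
        genome = uniform_genome((("1R", 100.0),), 5)
        qtl = QtlEffectSpec(trait="t", locus=("1R", 50.0), cd_effect=1.34, d_effect=0.0)
        hits = 0
        n_sims = 200
        for s in range(n_sims):
            rng = np.random.default_rng(5000 + s)
            f2 = simulate_f2(genome, 178, rng=rng)
            res = simulate_phenotypes(f2, [qtl], PEREN_NOISE, rng=rng, trait="t")
            ctx = prepare_scan(f2, res.plots, "t")
            if scan_single_marker(ctx, "1R_002")["p_cdd"] <= threshold:
                hits += 1
        assert hits >= 0.8 * n_sims

    def test_pure_dominance_pattern(self):
        """A and B classes share the mean, H is shifted: the dominance test
        dominates the codominant one."""
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(120, 2))
        abh = _abh_from_codes(codes)
        values = np.where(codes[:, 0] == 1, 2.0, 0.0) + rng.normal(0, 1e-3, 120)
        pheno = _plots_from_genotype_values(values, abh.genotype_ids)
        ctx = prepare_scan(abh, pheno, "t")
        row = scan_single_marker(ctx, "M0")
        assert row["p_d"] < 1e-10
        assert row["p_d"] < row["p_cd"] * 1e-3

    def test_null_pvalues_uniform(self, null_scan_pvalues):
        """Combined incremental Wald statistic is chi-square(2)-calibrated."""
        ks = stats.kstest(null_scan_pvalues, "uniform")
        assert ks.pvalue > 0.01

    def test_effect_estimates_unbiased(self, effect_recovery):
        effs, (cd_truth, d_truth) = effect_recovery
        for j, truth in enumerate((cd_truth, d_truth)):
            mcse = effs[:, j].std(ddof=1) / np.sqrt(len(effs))
            assert abs(effs[:, j].mean() - truth) <= 2 * mcse

    def test_negative_effect_sign_means_a_allele_increases_trait(self):
        genome = uniform_genome((("5R", 60.0),), 3)
        rng = np.random.default_rng(4)
        f2 = simulate_f2(genome, 178, rng=rng)
        qtl = QtlEffectSpec(trait="fert", locus=("5R", 30.0), cd_effect=-18.4, d_effect=14.9)
        design = TrialDesign(n_locations=1, n_replicates=2, sigma2_replicate=2.6,
                             sigma2_error=94.9, sigma2_g_residual=50.0)
        res = simulate_phenotypes(f2, [qtl], design, rng=rng, trait="fert", mu=85.0)
        ctx = prepare_scan(f2, res.plots, "fert")
        row = scan_single_marker(ctx, "5R_001")
        assert row["eff_cd"] < 0  # B dosage lowers the trait == A raises it
        assert row["eff_cd"] == pytest.approx(-18.4, abs=3 * row["se_cd"])

    def test_empty_b_class_flags_dominance_inestimable(self):
        """At a Z-selected marker the B class is empty; the d effect cannot be
        separated from cd and is flagged with p_d = 1."""
        genome = uniform_genome((("2R", 60.0),), 3)
        sel = SelectionSpec(z_locus=("2R", 30.0))
        rng = np.random.default_rng(5)
        f2 = simulate_f2(genome, 150, selection=sel, rng=rng)
        res = simulate_phenotypes(
            f2, [], TrialDesign(n_locations=1, n_replicates=2, sigma2_error=1.0),
            rng=rng, trait="t",
        )
        ctx = prepare_scan(f2, res.plots, "t")
        row = scan_single_marker(ctx, "2R_001")
        assert row["n_B"] == 0
        assert row["p_d"] == 1.0
        assert "d_inestimable" in row["flags"]

    def test_counts_cover_scanned_sample(self):
        genome = uniform_genome((("1R", 60.0),), 3)
        rng = np.random.default_rng(6)
        f2 = simulate_f2(genome, 90, rng=rng)
        res = simulate_phenotypes(
            f2, [], TrialDesign(n_locations=1, n_replicates=2, sigma2_error=1.0),
            rng=rng, trait="t",
        )
        ctx = prepare_scan(f2, res.plots, "t")
        row = scan_single_marker(ctx, "1R_001")
        assert row["n_A"] + row["n_H"] + row["n_B"] == 90

    def test_genomewide_type_one_error_bounded(self):
        """Fraction of null full-genome scans with any marker passing the
        simpleM threshold stays at or below 0.10 (nominal 0.05; simpleM is
        anti-conservative under strong linkage)."""
        genome = uniform_genome(tuple((f"{j}R", 120.0) for j in range(1, 8)), 113)
        n_sims = 20
        false_positives = 0
        for s in range(n_sims):
            rng = np.random.default_rng(6000 + s)
            f2 = simulate_f2(genome, 178, rng=rng)
            values = rng.normal(0, 1, (178, 2, 2))
            pheno = pd.DataFrame(
                {
                    "genotype": np.repeat(f2.genotype_ids, 4),
                    "location": np.tile(np.repeat(["L1", "L2"], 2), 178),
                    "replicate": np.tile(["R1", "R2"], 2 * 178),
                    "trait": "t",
                    "value": values.reshape(-1),
                }
            )
            spec = effective_marker_number(f2)
            ctx = prepare_scan(f2, pheno, "t")
            pmin = min(
                scan_single_marker(ctx, m)["p_cdd"] for m in f2.marker_ids
            )
            if pmin <= spec.per_test:
                false_positives += 1
        assert false_positives / n_sims <= 0.10


class TestCofactorSelection:
    def test_cm1_empty_when_nothing_passes(self):
        scan = pd.DataFrame(
            {"marker": ["a", "b"], "chromosome": ["1R", "2R"], "p_cdd": [0.5, 0.2]}
        )
        assert select_cofactors_cm1(scan, 1e-4) == []

    def test_cm1_one_peak_per_chromosome(self):
        scan = pd.DataFrame(
            {
                "marker": ["a1", "a2", "b1"],
                "chromosome": ["1R", "1R", "2R"],
                "p_cdd": [1e-6, 1e-9, 1e-7],
            }
        )
        assert sorted(select_cofactors_cm1(scan, 1e-4)) == ["a2", "b1"]

    def test_cm1_recovers_true_qtl_markers(self):
        """Three strong unlinked QTLs: CM1 picks exactly their peak markers."""
        genome = uniform_genome(tuple((f"{j}R", 80.0) for j in (1, 2, 3)), 5)
        qtls = [
            QtlEffectSpec(trait="t", locus=(f"{j}R", 40.0), cd_effect=2.0, d_effect=0.0)
            for j in (1, 2, 3)
        ]
        hits = 0
        runs = 20
        for s in range(runs):
            rng = np.random.default_rng(7000 + s)
            f2 = simulate_f2(genome, 178, rng=rng)
            res = simulate_phenotypes(f2, qtls, PEREN_NOISE, rng=rng, trait="t")
            scan_df, spec, _ = genome_scan(f2, res.plots, "t")
            cofs = select_cofactors_cm1(scan_df, spec.per_test)
            if sorted(cofs) == ["1R_002", "2R_002", "3R_002"]:
                hits += 1
        assert hits >= 0.9 * runs

    def test_cm2_null_trait_selects_nothing(self):
        """The Schwarz-BIC stepwise search keeps the null model for noise.

        The BIC entry hurdle at n = 178 is chi2(1) > log(178), i.e. about a
        2.3 % false-entry chance per candidate, so the empty-null-model rate
        is assessed per candidate marker: with one null candidate the search
        must come back empty in at least 95 % of simulations, and the
        per-candidate false-entry rate must match the chi-square tail.
        """
        rng = np.random.default_rng(8)
        empty = 0
        runs = 100
        for _ in range(runs):
            cd = pd.DataFrame(
                {"M0": rng.choice([0.0, 1.0, 2.0], p=[0.25, 0.5, 0.25], size=178)},
                index=[f"G{i}" for i in range(178)],
            )
            blues = pd.Series(rng.normal(0, 1, 178), index=cd.index)
            if select_cofactors_cm2(blues, cd) == []:
                empty += 1
        assert empty >= 0.95 * runs
        # false-entry rate consistent with P(chi2_1 > log n) ~ 2.3 %
        p_entry = 1 - stats.chi2.cdf(np.log(178), df=1)
        assert (runs - empty) / runs <= p_entry + 3 * np.sqrt(p_entry / runs)

    def test_cm2_selects_strong_qtl_marker(self):
        """A QTL explaining half the variance of the BLUEs is found: the
        stepwise search returns exactly its peak-region marker.

        The candidate panel is kept small (five markers, 20 cM apart) so the
        ~2.3 % per-candidate BIC false-entry rate leaves the exact-selection
        probability above the 90 % bound being asserted.
        """
        genome = uniform_genome((("1R", 80.0),), 5)
        exact = 0
        found = 0
        runs = 30
        for s in range(runs):
            rng = np.random.default_rng(8000 + s)
            f2 = simulate_f2(genome, 178, rng=rng)
            cd = pd.DataFrame(
                f2.cd_matrix(), index=f2.genotype_ids, columns=f2.marker_ids
            )
            x = cd["1R_002"].to_numpy()
            blues = pd.Series(
                x + rng.normal(0, np.sqrt(0.5), 178), index=cd.index
            )
            chosen = select_cofactors_cm2(blues, cd)
            in_region = [c for c in chosen if abs(int(c.split("_")[1]) - 2) <= 1]
            if in_region:
                found += 1
            if chosen and chosen == in_region:
                exact += 1
        assert found == runs  # the QTL region is never missed
        assert exact >= 0.9 * runs

    def test_cm2_deterministic(self):
        rng = np.random.default_rng(9)
        cd = pd.DataFrame(
            rng.choice([0.0, 1.0, 2.0], size=(100, 20)),
            index=[f"G{i}" for i in range(100)],
            columns=[f"M{j}" for j in range(20)],
        )
        blues = pd.Series(cd["M3"] + rng.normal(0, 0.5, 100), index=cd.index)
        assert select_cofactors_cm2(blues, cd) == select_cofactors_cm2(blues, cd)

    def test_scan_never_reports_cofactor_against_itself(self):
        genome = uniform_genome((("1R", 80.0), ("2R", 80.0)), 5)
        qtls = [
            QtlEffectSpec(trait="t", locus=(f"{j}R", 40.0), cd_effect=2.0, d_effect=0.0)
            for j in (1, 2)
        ]
        rng = np.random.default_rng(10)
        f2 = simulate_f2(genome, 178, rng=rng)
        res = simulate_phenotypes(f2, qtls, PEREN_NOISE, rng=rng, trait="t")
        scan_df, spec, cofs = genome_scan(f2, res.plots, "t", cofactors="cm1")
        assert cofs  # cofactors were selected
        for cof in cofs:
            row = scan_df[scan_df["marker"] == cof].iloc[0]
            assert cof not in row["cofactors_used"].split(",")


class TestConfidenceInterval:
    def _profile(self, cms, neglogs, chrom="1R"):
        return pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(len(cms))],
                "chromosome": chrom,
                "cM": cms,
                "p_cdd": [10.0**-v for v in neglogs],
            }
        )

    def test_symmetric_profile(self):
        prof = self._profile([0, 10, 20, 30, 40], [2, 4, 6, 4, 2])
        assert confidence_interval(prof, "m2") == (10.0, 30.0)

    def test_single_marker_chromosome(self):
        prof = self._profile([12.5], [3])
        assert confidence_interval(prof, "m0") == (12.5, 12.5)

    def test_monotone_profile_at_chromosome_end(self):
        prof = self._profile([0, 10, 20], [4.5, 5.5, 6.5])
        assert confidence_interval(prof, "m2") == (10.0, 20.0)

    def test_peak_not_in_profile_rejected(self):
        prof = self._profile([0, 10], [2, 3])
        with pytest.raises(ValueError, match="not in the profile"):
            confidence_interval(prof, "nope")


class TestExplainedVariance:
    def test_no_markers_is_zero(self):
        genome = uniform_genome((("1R", 60.0),), 3)
        rng = np.random.default_rng(11)
        f2 = simulate_f2(genome, 100, rng=rng)
        res = simulate_phenotypes(
            f2, [], TrialDesign(n_locations=1, n_replicates=2, sigma2_error=1.0,
                                sigma2_g_residual=1.0),
            rng=rng, trait="t",
        )
        assert explained_variance(f2, res.plots, "t", []) == (0.0, False)

    def test_monogenic_trait_fully_explained(self):
        genome = uniform_genome((("1R", 60.0),), 3)
        rng = np.random.default_rng(12)
        f2 = simulate_f2(genome, 150, rng=rng)
        design = TrialDesign(n_locations=1, n_replicates=2, sigma2_error=1e-4)
        qtl = QtlEffectSpec(trait="t", locus=("1R", 30.0), cd_effect=1.0, d_effect=0.5)
        res = simulate_phenotypes(f2, [qtl], design, rng=rng, trait="t")
        p_g, flagged = explained_variance(f2, res.plots, "t", ["1R_001"])
        assert not flagged
        assert p_g > 0.99

    def test_additivity_for_unlinked_qtls(self, additivity_result):
        """Joint explained variance equals the sum of single-marker values."""
        singles, joint = additivity_result
        assert abs(joint - sum(singles)) < 0.02


class TestExplainedCovariance:
    def _shared_qtl_data(self, seed, shared=True, polygenic_cov=False):
        genome = uniform_genome((("1R", 80.0), ("2R", 80.0)), 5)
        rng = np.random.default_rng(seed)
        f2 = simulate_f2(genome, 178, rng=rng)
        design = TrialDesign(n_locations=1, n_replicates=2, sigma2_replicate=0.05,
                             sigma2_error=0.5, sigma2_g_residual=0.0)
        qa = QtlEffectSpec(trait="a", locus=("1R", 40.0), cd_effect=1.2, d_effect=0.0)
        locus_b = ("1R", 40.0) if shared else ("2R", 40.0)
        qb = QtlEffectSpec(trait="b", locus=locus_b, cd_effect=1.0, d_effect=0.0)
        ra = simulate_phenotypes(f2, [qa], design, rng=rng, trait="a")
        rb = simulate_phenotypes(f2, [qb], design, rng=rng, trait="b")
        data = pd.concat([ra.plots, rb.plots], ignore_index=True)
        if polygenic_cov:
            shared_g = rng.normal(0, 1.0, 178)
            lookup = dict(zip(f2.genotype_ids, shared_g))
            data["value"] = data["value"] + data["genotype"].map(lookup)
        return f2, data

    def test_no_markers_is_zero(self):
        f2, data = self._shared_qtl_data(13)
        assert explained_covariance(f2, data, "a", "b", []) == (0.0, False)

    def test_pleiotropic_qtl_explains_covariance(self):
        """A single shared QTL is the only source of genetic covariance, so
        adjusting for its marker removes (nearly) all of it."""
        vals = []
        for s in range(8):
            f2, data = self._shared_qtl_data(1400 + s)
            p_cov, flagged = explained_covariance(f2, data, "a", "b", ["1R_002"])
            assert not flagged
            vals.append(p_cov)
        assert abs(np.mean(vals) - 1.0) < 0.15

    def test_marker_unrelated_to_shared_genetics_explains_nothing(self):
        f2, data = self._shared_qtl_data(15, shared=False, polygenic_cov=True)
        p_cov, flagged = explained_covariance(f2, data, "a", "b", ["2R_002"])
        assert not flagged
        # trait-b-only QTL cannot account for the shared polygenic covariance
        assert abs(p_cov) < 0.3

    def test_zero_base_covariance_flagged(self):
        genome = uniform_genome((("1R", 40.0),), 3)
        rng = np.random.default_rng(16)
        f2 = simulate_f2(genome, 120, rng=rng)
        design = TrialDesign(n_locations=1, n_replicates=2, sigma2_error=1.0)
        ra = simulate_phenotypes(f2, [], design, rng=rng, trait="a")
        rb = simulate_phenotypes(f2, [], design, rng=rng, trait="b")
        data = pd.concat([ra.plots, rb.plots], ignore_index=True)
        p_cov, flagged = explained_covariance(f2, data, "a", "b", ["1R_001"])
        if flagged:
            assert np.isnan(p_cov)


class TestEpistasis:
    def test_complementary_epistasis_detected(self):
        """Effect only when both loci carry a B allele (dominant complementary
        gene action): the cd:cd interaction is the dominant signal."""
        rng = np.random.default_rng(17)
        codes = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(200, 2))
        abh = _abh_from_codes(codes)
        value = ((codes[:, 0] >= 1) & (codes[:, 1] >= 1)).astype(float) * 2.0
        value = value + rng.normal(0, 1e-3, 200)
        pheno = _plots_from_genotype_values(value, abh.genotype_ids)
        epi = epistasis_scan(abh, pheno, "t", [("M0", "M1")])
        cd_cd = epi[epi["term"] == "cd_cd"].iloc[0]
        assert cd_cd["p"] < 0.05

    def test_additive_qtls_show_no_interaction(self):
        genome = uniform_genome((("1R", 80.0), ("2R", 80.0)), 3)
        qtls = [
            QtlEffectSpec(trait="t", locus=(f"{j}R", 40.0), cd_effect=1.5, d_effect=0.0)
            for j in (1, 2)
        ]
        strict = 0.05 / (100 * 99)
        runs = 20
        clean = 0
        for s in range(runs):
            rng = np.random.default_rng(9000 + s)
            f2 = simulate_f2(genome, 178, rng=rng)
            res = simulate_phenotypes(f2, qtls, PEREN_NOISE, rng=rng, trait="t")
            epi = epistasis_scan(f2, res.plots, "t", [("1R_001", "2R_001")])
            inter = epi[epi["term"].isin(["cd_cd", "d_d", "m1d_m2cd", "m2d_m1cd"])]
            if (inter["p"].dropna() > strict).all():
                clean += 1
        assert clean == runs

    def test_same_marker_pair_rejected(self):
        genome = uniform_genome((("1R", 40.0),), 3)
        rng = np.random.default_rng(18)
        f2 = simulate_f2(genome, 60, rng=rng)
        res = simulate_phenotypes(
            f2, [], TrialDesign(n_locations=1, n_replicates=2, sigma2_error=1.0),
            rng=rng, trait="t",
        )
        with pytest.raises(ValueError, match="itself"):
            epistasis_scan(f2, res.plots, "t", [("1R_000", "1R_000")])

    def test_empty_interaction_cell_flagged(self):
        """With no double-carrier class the d:d interaction is inestimable."""
        rng = np.random.default_rng(19)
        m1 = rng.choice([0, 1], size=150).astype(np.int8)
        m2 = np.where(m1 == 1, 0, rng.choice([0, 1, 2], size=150)).astype(np.int8)
        abh = _abh_from_codes(np.stack([m1, m2], axis=1))
        value = rng.normal(0, 1, 150)
        pheno = _plots_from_genotype_values(value, abh.genotype_ids)
        epi = epistasis_scan(abh, pheno, "t", [("M0", "M1")])
        flagged = epi[epi["flags"] == "inestimable"]
        assert len(flagged) > 0
        assert flagged["p"].isna().all()
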