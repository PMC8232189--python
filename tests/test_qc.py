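"""Marker QC: ABH encoding, filters, redundancy, imputation, distortion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ryeqtl.abh import CODE_MISSING, AbhMatrix, from_dataframe
from ryeqtl.genome import SelectionSpec, uniform_genome
from ryeqtl.qc import (
    RawGenotypeMatrix,
    allele_frequency_profile,
    collapse_redundant,
    distortion_counts,
    distortion_scan,
    encode_abh,
    filter_missing,
    find_duplicate_genotypes,
    impute_by_flanks,
    multivalent_screen,
    raw_from_abh,
)
from ryeqtl.simulate import add_duplicate_markers, add_missing_calls, simulate_f2


def _raw(calls, p1, p2, ids=None):
    calls = np.asarray(calls, dtype=object)
    n, m = calls.shape
    return RawGenotypeMatrix(
        calls=calls,
        genotype_ids=ids or [f"G{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(m)],
        parent1_calls=np.asarray(p1, dtype=object),
        parent2_calls=np.asarray(p2, dtype=object),
    )


class TestEncodeAbh:
    def test_heterozygote_and_homozygote_coding(self):
        raw = _raw([["GT"], ["GG"], ["TT"]], ["GG"], ["TT"])
        abh, _ = encode_abh(raw)
        assert abh.to_dataframe()["M0"].tolist() == ["H", "A", "B"]

    def test_missing_parent_coded_against_reference(self):
        # parent1 missing, parent2 = TT: GG offspring get the A code
        raw = _raw([["GG"], ["TT"], ["GT"]], ["NA"], ["TT"])
        abh, _ = encode_abh(raw)
        assert abh.to_dataframe()["M0"].tolist() == ["A", "B", "H"]

    def test_both_parents_uninformative_dropped(self):
        raw = _raw([["GG"], ["TT"]], ["GT"], ["NA"])
        abh, report = encode_abh(raw)
        assert abh.n_markers == 0
        assert report.dropped_ambiguous_parents == ["M0"]

    def test_non_segregating_dropped(self):
        raw = _raw([["GG"], ["GG"], ["GG"]], ["GG"], ["TT"])
        abh, report = encode_abh(raw)
        assert abh.n_markers == 0
        assert report.dropped_non_segregating == ["M0"]

    def test_roundtrip_through_raw_calls(self):
        genome = uniform_genome((("1R", 40.0),), 5)
        f2 = simulate_f2(genome, 50, rng=np.random.default_rng(0))
        raw = raw_from_abh(f2)
        back, _ = encode_abh(raw)
        assert (back.calls == f2.calls).all()


class TestFilterMissing:
    def _with_missing(self, n_missing: int) -> AbhMatrix:
        calls = np.ones((182, 1), dtype=np.int8)
        calls[:91, 0] = 0  # keep the marker segregating
        calls[:n_missing, 0] = CODE_MISSING
        return AbhMatrix(
            calls=calls,
            genotype_ids=[f"G{i}" for i in range(182)],
            marker_ids=["M0"],
        )

    def test_strictly_above_ten_percent_dropped(self):
        assert filter_missing(self._with_missing(19)).n_markers == 0  # 19/182 = 10.4 %

    def test_at_most_ten_percent_retained(self):
        assert filter_missing(self._with_missing(18)).n_markers == 1  # 9.9 %

    def test_complete_marker_retained(self):
        assert filter_missing(self._with_missing(0)).n_markers == 1


class TestCollapseRedundant:
    def test_identical_columns_collapse_to_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=np.int8)
        abh = AbhMatrix(
            calls=np.stack([col, col], axis=1),
            genotype_ids=[f"G{i}" for i in range(10)],
            marker_ids=["M0", "M1"],
        )
        unique, groups = collapse_redundant(abh)
        assert unique.n_markers == 1
        assert groups.n_unique == 1
        assert sorted(groups.groups[0]) == ["M0", "M1"]

    def test_transitive_groups_on_ten_genotype_fixture(self):
        rng = np.random.default_rng(1)
        m1 = rng.choice([0, 1, 2], size=10, p=[0.25, 0.5, 0.25]).astype(np.int8)
        m3 = rng.choice([0, 1, 2], size=10, p=[0.25, 0.5, 0.25]).astype(np.int8)
        m4 = rng.choice([0, 1, 2], size=10, p=[0.25, 0.5, 0.25]).astype(np.int8)
        calls = np.stack([m1, m1, m3, m4, m4], axis=1)
        abh = AbhMatrix(
            calls=calls,
            genotype_ids=[f"G{i}" for i in range(10)],
            marker_ids=[f"M{j}" for j in range(5)],
        )
        # brute-force oracle: pairwise |corr| = 1 edges
        cd = calls.astype(float)
        expected_edges = {
            (i, j)
            for i in range(5)
            for j in range(i + 1, 5)
            if abs(np.corrcoef(cd[:, i], cd[:, j])[0, 1]) > 1 - 1e-12
        }
        assert expected_edges == {(0, 1), (3, 4)}
        unique, groups = collapse_redundant(abh)
        assert unique.n_markers == 3

    def test_representative_has_least_missing(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=np.int8)
        withmiss = col.copy()
        withmiss[0] = CODE_MISSING
        abh = AbhMatrix(
            calls=np.stack([withmiss, col], axis=1),
            genotype_ids=[f"G{i}" for i in range(6)],
            marker_ids=["gappy", "complete"],
        )
        unique, groups = collapse_redundant(abh)
        assert groups.representatives == ["complete"]
        assert unique.marker_ids.tolist() == ["complete"]
        # representative choice never increases total missingness
        assert (unique.calls == CODE_MISSING).sum() <= (abh.calls == CODE_MISSING).sum()

    def test_pipeline_recovers_planted_unique_marker_count(self):
        genome = uniform_genome((("1R", 90.0), ("2R", 90.0)), 10)
        f2 = simulate_f2(genome, 178, rng=np.random.default_rng(2))
        rng = np.random.default_rng(3)
        planted = add_duplicate_markers(f2, 30, rng)
        planted = add_missing_calls(planted, 0.02, rng)
        filtered = filter_missing(planted)
        unique, groups = collapse_redundant(filtered)
        assert unique.n_markers == f2.n_markers
        assert groups.n_unique == f2.n_markers

    def test_idempotence(self):
        genome = uniform_genome((("1R", 90.0),), 8)
        f2 = simulate_f2(genome, 60, rng=np.random.default_rng(4))
        planted = add_duplicate_markers(f2, 5, np.random.default_rng(5))
        once, _ = collapse_redundant(filter_missing(planted))
        twice, _ = collapse_redundant(filter_missing(once))
        assert once == twice


class TestImputeByFlanks:
    def _abh(self, rows, chrom=None):
        rows = np.asarray(rows, dtype=np.int8)
        m = rows.shape[1]
        return AbhMatrix(
            calls=rows,
            genotype_ids=[f"G{i}" for i in range(rows.shape[0])],
            marker_ids=[f"M{j}" for j in range(m)],
            chromosome=chrom if chrom is not None else ["1R"] * m,
            position_cm=np.arange(m, dtype=float),
        )

    def test_agreeing_flanks_fill(self):
        abh = self._abh([[0, CODE_MISSING, 0]])
        out, report = impute_by_flanks(abh)
        assert out.calls[0, 1] == 0
        assert report.n_flank_filled == 1
        assert report.n_second_pass_filled == 0

    def test_disagreeing_flanks_go_to_second_pass(self):
        abh = self._abh([[0, CODE_MISSING, 1], [0, 0, 1], [0, 0, 1]])
        out, report = impute_by_flanks(abh)
        assert report.n_flank_filled == 0
        assert report.n_second_pass_filled == 1
        assert out.calls[0, 1] == 0  # modal state of the marker

    def test_chromosome_end_unresolved_by_flanks(self):
        abh = self._abh([[CODE_MISSING, 1, 1], [0, 1, 1]])
        out, report = impute_by_flanks(abh)
        assert report.n_flank_filled == 0
        assert report.n_second_pass_filled == 1

    def test_unordered_positions_rejected(self):
        abh = self._abh([[0, 1, 0]])
        abh.position_cm = np.array([2.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="not ordered"):
            impute_by_flanks(abh)


class TestDistortion:
    @pytest.mark.parametrize(
        "counts, chi2, p",
        [
            ((45, 90, 45), 0.0, 1.0),
            ((62, 96, 18), 23.454545, 8.0707e-06),  # chi2 = 324/44 + 64/88 + 676/44
            ((90, 90, 0), 90.0, None),  # (90-45)^2/45 + 0 + 45^2/45
        ],
    )
    def test_against_hand_computed_values(self, counts, chi2, p):
        got_chi2, got_p = distortion_counts(*counts)
        assert got_chi2 == pytest.approx(chi2, rel=1e-6)
        if p is not None:
            assert got_p == pytest.approx(p, rel=1e-3)

    def test_zero_calls_rejected(self):
        with pytest.raises(ValueError):
            distortion_counts(0, 0, 0)

    def test_scan_pvalues_uniform_on_neutral_data(self):
        genome = uniform_genome(tuple((f"{j}R", 100.0) for j in range(1, 8)), 20)
        f2 = simulate_f2(genome, 10_000, rng=np.random.default_rng(6))
        scan = distortion_scan(f2)
        # calibration: the significant fraction at 5 % is binomially consistent
        n_sig = int(scan["significant_05"].sum())
        assert n_sig <= stats.binom.ppf(0.999, len(scan), 0.05)
        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 0.01


class TestAlleleFrequencies:
    def test_counting_with_missing_category(self):
        df = pd.DataFrame(
            {"M0": ["A", "A", "H", "H", "B", "B", "NA", "NA"]},
            index=[f"G{i}" for i in range(8)],
        )
        abh = from_dataframe(df)
        prof = allele_frequency_profile(abh)
        row = prof.iloc[0]
        assert (row["freq_A"], row["freq_H"], row["freq_B"], row["freq_missing"]) == (
            0.25, 0.25, 0.25, 0.25,
        )

    def test_neutral_simulation_has_half_heterozygotes(self):
        genome = uniform_genome((("1R", 100.0),), 11)
        f2 = simulate_f2(genome, 10_000, rng=np.random.default_rng(7))
        prof = allele_frequency_profile(f2)
        assert abs(prof["freq_H"].mean() - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_z_selection_removes_b_allele_at_locus(self):
        genome = uniform_genome((("2R", 100.0),), 11)
        sel = SelectionSpec(z_locus=("2R", 50.0))
        f2 = simulate_f2(genome, 5000, selection=sel, rng=np.random.default_rng(8))
        prof = allele_frequency_profile(f2).set_index("marker")
        assert prof.loc["2R_005", "freq_B"] == 0.0


class TestMultivalentScreen:
    def test_neutral_simulation_is_not_flagged(self):
        genome = uniform_genome(
            (("1R", 100.0), ("2R", 100.0), ("3R", 100.0)), 8
        )
        f2 = simulate_f2(genome, 500, rng=np.random.default_rng(9))
        _, flags = multivalent_screen(f2, flag_threshold=0.5)
        assert flags == []

    def test_co_segregating_trio_flagged(self):
        genome = uniform_genome(
            (("1R", 100.0), ("2R", 100.0), ("6R", 100.0), ("7R", 100.0)), 6
        )
        sel = SelectionSpec(multivalent_chromosomes=frozenset({"2R", "6R", "7R"}))
        f2 = simulate_f2(genome, 500, selection=sel, rng=np.random.default_rng(10))
        _, flags = multivalent_screen(f2, flag_threshold=0.5)
        assert sorted(flags) == [("2R", "6R"), ("2R", "7R"), ("6R", "7R")]

    def test_same_chromosome_pairs_excluded(self):
        # tightly linked markers on one chromosome must not flag anything
        genome = uniform_genome((("1R", 1.0), ("2R", 100.0)), 5)
        f2 = simulate_f2(genome, 400, rng=np.random.default_rng(11))
        mat, flags = multivalent_screen(f2, flag_threshold=0.5)
        assert np.isnan(mat.loc["1R", "1R"])
        assert flags == []


class TestDuplicateGenotypes:
    def test_identical_rows_detected(self):
        genome = uniform_genome((("1R", 80.0),), 20)
        f2 = simulate_f2(genome, 30, rng=np.random.default_rng(12))
        calls = np.vstack([f2.calls, f2.calls[5]])
        abh = AbhMatrix(
            calls=calls,
            genotype_ids=[*f2.genotype_ids, "CLONE"],
            marker_ids=f2.marker_ids,
        )
        pairs = find_duplicate_genotypes(abh)
        assert (f2.genotype_ids[5], "CLONE") in pairs
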