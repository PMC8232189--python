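"""End-to-end orchestration: simulate -> QC -> map -> phenotype models ->
marker scans -> reports, with per-stage accounting in a run manifest."""

from __future__ import annotations

import json
import logging
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abh import AbhMatrix
from .config import RunManifest, StudyConfig
from .genome import uniform_genome
from .incompatibility import (
    MultivalentModel,
    expected_f2_ratio,
    expected_f3_ratio_s5,
    multivalent_viable_fraction,
)
from .io import (
    read_genotype_csv,
    read_phenotype_csv,
    write_genotype_csv,
    write_phenotype_csv,
    write_truth_yaml,
    write_tsv,
)
from .linkage import build_map
from .pheno import fit_univariate, heritability
from .qc import (
    allele_frequency_profile,
    collapse_redundant,
    distortion_scan,
    filter_missing,
    find_duplicate_genotypes,
    impute_by_flanks,
    multivalent_screen,
)
from .scan import (
    confidence_interval,
    effective_marker_number,
    epistasis_scan,
    explained_variance,
    genome_scan,
)
from .simulate import simulate_study

__all__ = ["run_pipeline", "ratios_report"]

log = logging.getLogger("ryeqtl")


def ratios_report() -> dict:
    """Exact expectations from the incompatibility and multivalent models."""
    z = expected_f2_ratio("Z", selection=True)
    s5_f2 = expected_f2_ratio("S5", selection=False)
    f3_geno, f3_alleles = expected_f3_ratio_s5()
    allele_ratio: Fraction = f3_alleles[0] / f3_alleles[1]
    return {
        "f2_z_ratio_AHB": list(z.as_integer_ratio()),
        "f2_s5_ratio_AHB": list(s5_f2.as_integer_ratio()),
        "f3_s5_genotype_ratio_AHB": list(f3_geno.as_integer_ratio()),
        "f3_s5_allele_ratio_AB": [allele_ratio.numerator, allele_ratio.denominator],
        "multivalent_viable_fraction_3_pairs": float(
            multivalent_viable_fraction(MultivalentModel(n_pairs=3))
        ),
    }


def run_pipeline(config: StudyConfig) -> RunManifest:
    """Run the full analysis; every stage's output is written and counted.

    Any stage error aborts the run with the stage name recorded and the
    manifest written up to that point.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: getattr(config, k) for k in config.__dataclass_fields__},
        seed=config.seed,
        version=__version__,
    )
    stage = "init"
    try:
        # ------------------------------------------------------ simulate
        stage = "simulate"
        if config.simulate:
            genome = uniform_genome(
                tuple((f"{i}R", 120.0) for i in range(1, 8)),
                markers_per_chromosome=113,
            )
            study = simulate_study(
                genome=genome, n_genotypes=config.n_genotypes, seed=config.seed
            )
            abh, pheno = study.abh, study.phenotypes
            write_genotype_csv(abh, out / "genotypes.csv")
            write_phenotype_csv(pheno, out / "phenotypes.csv")
            write_truth_yaml(study.truth, out / "truth.yaml")
            manifest.record(
                stage, genotypes=abh.n_genotypes, markers_out=abh.n_markers
            )
        else:
            abh = read_genotype_csv(config.genotype_csv)
            pheno = read_phenotype_csv(config.phenotype_csv)
            manifest.record(
                stage, genotypes=abh.n_genotypes, markers_out=abh.n_markers
            )

        # ------------------------------------------------------------ qc
        stage = "qc"
        m_in = abh.n_markers
        abh = filter_missing(abh, config.max_missing_fraction)
        m_filtered = abh.n_markers
        log.info("missingness filter: %d -> %d markers", m_in, m_filtered)
        abh, groups = collapse_redundant(abh)
        m_unique = abh.n_markers
        log.info("redundancy collapse: %d -> %d markers", m_filtered, m_unique)
        if abh.has_map:
            abh, impute_report = impute_by_flanks(abh)
            write_tsv(distortion_scan(abh), out / "distortion.tsv")
            write_tsv(allele_frequency_profile(abh), out / "allele_frequencies.tsv")
            screen, flagged = multivalent_screen(abh)
            screen.to_csv(out / "multivalent_screen.tsv", sep="\t")
            (out / "multivalent_flags.json").write_text(json.dumps(flagged))
        else:
            impute_report = None
            flagged = []
        # duplicate genotypes: one member per pair is removed before map
        # construction, both members before marker-trait mapping
        dup = find_duplicate_genotypes(abh)
        second_members = sorted({b for _, b in dup})
        both_members = sorted({g for pair in dup for g in pair})
        abh_map = abh.drop_genotypes(second_members) if second_members else abh
        abh = abh.drop_genotypes(both_members) if both_members else abh
        manifest.record(
            stage,
            markers_in=m_in,
            markers_after_missing_filter=m_filtered,
            markers_out=m_unique,
            redundancy_groups=groups.n_unique,
            second_pass_imputations=(
                impute_report.n_second_pass_filled if impute_report else None
            ),
            duplicate_pairs=len(dup),
            genotypes_for_mapping=abh.n_genotypes,
            multivalent_flags=len(flagged),
        )

        # ----------------------------------------------------------- map
        stage = "map"
        if config.build_map:
            genetic_map = build_map(abh_map, rf_max=config.rf_max, lod_min=config.lod_min)
            write_tsv(genetic_map, out / "linkage_map.tsv")
            manifest.record(
                stage,
                markers_in=m_unique,
                markers_out=int(len(genetic_map)),
                groups=int(genetic_map["group"].nunique()),
            )

        # --------------------------------------------------------- pheno
        stage = "pheno"
        pheno_rows = []
        blues_frames = []
        traits = [t for t in config.traits if (pheno["trait"] == t).any()]
        for trait in traits:
            rand = fit_univariate(pheno, trait, genotype_as="random")
            fixed = fit_univariate(pheno, trait, genotype_as="fixed")
            h2 = heritability(rand.components["genotype"], fixed.av_vd)
            for comp, val in rand.components.items():
                pheno_rows.append(
                    {
                        "trait": trait,
                        "component": comp,
                        "variance": val,
                        "se": rand.se.get(comp, float("nan")),
                    }
                )
            pheno_rows.append(
                {"trait": trait, "component": "H2", "variance": h2, "se": float("nan")}
            )
            bl = fixed.blues.assign(trait=trait, av_vd=fixed.av_vd, lsd=fixed.lsd)
            blues_frames.append(bl)
        write_tsv(pd.DataFrame(pheno_rows), out / "variance_components.tsv")
        if blues_frames:
            write_tsv(pd.concat(blues_frames), out / "blues.tsv")
        manifest.record(stage, traits=len(traits))

        # ---------------------------------------------------------- scan
        stage = "scan"
        thresholds = effective_marker_number(abh, share=config.pca_share, alpha=config.alpha)
        qtl_rows = []
        scan_tables = {}
        for trait in traits:
            scan_df, spec, cofs = genome_scan(
                abh,
                pheno,
                trait,
                cofactors=config.cofactors,
                redundancy=groups,
                alpha=config.alpha,
                pca_share=config.pca_share,
            )
            scan_tables[trait] = scan_df
            write_tsv(scan_df, out / f"scan_{trait}.tsv")
            passed = scan_df[scan_df["p_cdd"] <= spec.per_test]
            peaks = []
            for chrom, grp in passed.groupby("chromosome"):
                peak = grp.loc[grp["p_cdd"].idxmin()]
                ci = confidence_interval(
                    scan_df[scan_df["chromosome"] == chrom], peak["marker"]
                )
                p_g, p_g_flag = explained_variance(abh, pheno, trait, [peak["marker"]])
                peaks.append(peak["marker"])
                qtl_rows.append(
                    {
                        "trait": trait,
                        "marker": peak["marker"],
                        "chromosome": chrom,
                        "cM": peak["cM"],
                        "ci_left": ci[0],
                        "ci_right": ci[1],
                        "p_cdd": peak["p_cdd"],
                        "eff_cd": peak["eff_cd"],
                        "eff_d": peak["eff_d"],
                        "p_G": p_g,
                        "p_G_truncated": p_g_flag,
                    }
                )
            if len(peaks) > 1:
                p_g_joint, _ = explained_variance(abh, pheno, trait, peaks)
                qtl_rows.append(
                    {
                        "trait": trait,
                        "marker": "+".join(peaks),
                        "chromosome": "joint",
                        "p_G": p_g_joint,
                    }
                )
        if qtl_rows:
            write_tsv(pd.DataFrame(qtl_rows), out / "qtl_report.tsv")
        manifest.record(
            stage,
            q_eff=thresholds.q_eff,
            threshold=thresholds.per_test,
            qtl_count=len(qtl_rows),
        )

        # ------------------------------------------------------ epistasis
        if config.epistasis:
            stage = "epistasis"
            for trait in traits:
                scan_df = scan_tables[trait]
                top = scan_df.nsmallest(4, "p_cdd")["marker"].tolist()
                pairs = [(a, b) for i, a in enumerate(top) for b in top[i + 1 :]]
                if pairs:
                    epi = epistasis_scan(abh, pheno, trait, pairs, thresholds)
                    write_tsv(epi, out / f"epistasis_{trait}.tsv")
            manifest.record(stage, traits=len(traits))

        # --------------------------------------------------------- ratios
        stage = "ratios"
        (out / "ratios.json").write_text(json.dumps(ratios_report(), indent=2))
        manifest.record(stage)
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.to_yaml(out / "manifest.yaml")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    manifest.to_yaml(out / "manifest.yaml")
    return manifest
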