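"""Shared fixtures: heavy simulation studies are session-scoped so module
tests and the acceptance suite reuse one computation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ryeqtl.abh import AbhMatrix
from ryeqtl.genome import QtlEffectSpec, TrialDesign, uniform_genome
from ryeqtl.pheno import fit_univariate
from ryeqtl.scan import explained_variance, prepare_scan, scan_single_marker
from ryeqtl.simulate import simulate_f2, simulate_phenotypes

#: Trial variance components at the scale reported for the perenniality
#: score in the emulated study (two locations, two clonal replicates).
TABLE_COMPONENTS = {
    "genotype": 3.72,
    "location": 0.22,
    "replicate": 0.08,
    "gxl": 1.18,
    "residual": 1.39,
}

PERENNIALITY_TRIAL = TrialDesign(
    n_locations=2,
    n_replicates=2,
    sigma2_location=0.22,
    sigma2_replicate=0.08,
    sigma2_gxl=1.18,
    sigma2_error=1.39,
    sigma2_g_residual=3.72,
)


def make_balanced_plots(values: np.ndarray, genotype_ids=None) -> pd.DataFrame:
    """Long-format plot table from an (L, R, G) value cube."""
    L, R, G = values.shape
    ids = genotype_ids if genotype_ids is not None else [f"G{i:04d}" for i in range(G)]
    rows = []
    for j in range(L):
        for k in range(R):
            for i in range(G):
                rows.append(
                    {
                        "genotype": ids[i],
                        "location": f"L{j + 1}",
                        "replicate": f"R{k + 1}",
                        "trait": "t",
                        "value": values[j, k, i],
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def table1_recovery():
    """REML estimates from 200 simulated trials at the planted components."""
    genome = uniform_genome((("1R", 100.0),), 3)
    f2 = simulate_f2(genome, 178, rng=np.random.default_rng(42))
    ests = {k: [] for k in TABLE_COMPONENTS}
    for s in range(200):
        res = simulate_phenotypes(
            f2, [], PERENNIALITY_TRIAL, rng=np.random.default_rng(1000 + s), trait="t"
        )
        fit = fit_univariate(res.plots, "t", genotype_as="random")
        for k in TABLE_COMPONENTS:
            ests[k].append(fit.components[k])
    return {k: np.asarray(v) for k, v in ests.items()}


@pytest.fixture(scope="session")
def effect_recovery():
    """Scan effect estimates for a planted QTL over 200 simulations."""
    genome = uniform_genome((("1R", 100.0),), 5)
    design = TrialDesign(
        n_locations=2,
        n_replicates=2,
        sigma2_location=0.22,
        sigma2_replicate=0.08,
        sigma2_gxl=1.18,
        sigma2_error=1.39,
        sigma2_g_residual=0.9,
    )
    qtl = QtlEffectSpec(trait="t", locus=("1R", 50.0), cd_effect=1.34, d_effect=0.6)
    effs = []
    for s in range(200):
        rng = np.random.default_rng(2000 + s)
        f2 = simulate_f2(genome, 178, rng=rng)
        res = simulate_phenotypes(f2, [qtl], design, rng=rng, trait="t")
        ctx = prepare_scan(f2, res.plots, "t")
        row = scan_single_marker(ctx, "1R_002")
        effs.append([row["eff_cd"], row["eff_d"], row["p_cdd"]])
    return np.asarray(effs), (1.34, 0.6)


@pytest.fixture(scope="session")
def null_scan_pvalues():
    """Combined-Wald p-values from independent null traits and null markers."""
    ps = []
    rng = np.random.default_rng(77)
    for _ in range(100):
        n, m = 178, 20
        calls = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(n, m)).astype(np.int8)
        abh = AbhMatrix(
            calls=calls,
            genotype_ids=[f"G{i}" for i in range(n)],
            marker_ids=[f"M{j}" for j in range(m)],
        )
        vals = rng.normal(0, 1, (n, 2, 2))
        pheno = pd.DataFrame(
            {
                "genotype": np.repeat(abh.genotype_ids, 4),
                "location": np.tile(np.repeat(["L1", "L2"], 2), n),
                "replicate": np.tile(["R1", "R2"], 2 * n),
                "trait": "t",
                "value": vals.reshape(-1),
            }
        )
        ctx = prepare_scan(abh, pheno, "t")
        ps.extend(scan_single_marker(ctx, f"M{j}")["p_cdd"] for j in range(m))
    return np.asarray(ps)


@pytest.fixture(scope="session")
def additivity_result():
    """Joint vs summed single-marker explained variance, five unlinked QTLs.

    Uses a large population (n = 20,000) so that sample correlations between
    unlinked marker codes — the finite-sample term that breaks exact
    additivity — are negligible.
    """
    genome = uniform_genome(tuple((f"{j}R", 80.0) for j in range(1, 6)), 5)
    design = TrialDesign(
        n_locations=2,
        n_replicates=2,
        sigma2_location=0.22,
        sigma2_replicate=0.08,
        sigma2_gxl=1.18,
        sigma2_error=1.39,
        sigma2_g_residual=0.9,
    )
    qtls = [
        QtlEffectSpec(trait="t", locus=(f"{j}R", 40.0), cd_effect=eff, d_effect=d)
        for j, (eff, d) in enumerate(
            [(1.15, 0.07), (1.34, -0.04), (0.64, 1.61), (-0.69, 1.32), (0.58, 0.34)],
            start=1,
        )
    ]
    markers = [f"{j}R_002" for j in range(1, 6)]
    rng = np.random.default_rng(51)
    f2 = simulate_f2(genome, 20000, rng=rng)
    res = simulate_phenotypes(f2, qtls, design, rng=rng, trait="t")
    singles = [explained_variance(f2, res.plots, "t", [m])[0] for m in markers]
    joint, _ = explained_variance(f2, res.plots, "t", markers)
    return singles, joint
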