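"""Single-marker and epistasis genome scans with simpleM thresholds.

Each marker enters the trial mixed model as a pair of fixed effects: the
codominant dosage ``x_cd`` in {0, 1, 2} for {A, H, B} and the dominance
indicator ``x_d`` in {0, 1, 0}.  Effects are tested sequentially
(incremental Wald chi-squares: first ``x_cd`` on 1 df, then ``x_d`` on
1 df; the combined test adds the two statistics on 2 df).  Variance
components are estimated once per trait from the cofactor-free trial model
and held fixed during the scan (two-stage GLS); optional random
marker-by-location interaction terms can be re-estimated per marker.

The genome-wide significance level is alpha divided by the effective
number of markers (simpleM): the count of principal-component eigenvalues
of the marker correlation matrix needed to explain 99.5 % of the
variation.  Epistasis scans divide by ``q_eff * (q_eff - 1)``, the number
of ordered marker pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, solve_triangular

from .abh import CODE_MISSING, AbhMatrix
from .pheno import _trait_frame, _try_cube, fit_bivariate, fit_univariate
from .qc import RedundancyGroups, pairwise_complete_correlation
from .reml import (
    build_covariance,
    design_matrix,
    reml_balanced_genotype_covariates,
    reml_fit,
)

__all__ = [
    "ThresholdSpec",
    "ScanContext",
    "prepare_scan",
    "scan_single_marker",
    "genome_scan",
    "effective_marker_number",
    "select_cofactors_cm1",
    "select_cofactors_cm2",
    "confidence_interval",
    "explained_variance",
    "explained_covariance",
    "epistasis_scan",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """simpleM multiple-testing thresholds."""

    alpha: float
    q_eff: int
    n_markers: int

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= self.q_eff <= max(self.n_markers, 1):
            raise ValueError("q_eff must be between 1 and the number of markers")

    @property
    def per_test(self) -> float:
        return self.alpha / self.q_eff

    @property
    def epistasis_per_test(self) -> float:
        return self.alpha / (self.q_eff * max(self.q_eff - 1, 1))


def effective_marker_number(
    abh: AbhMatrix, share: float = 0.995, alpha: float = 0.05
) -> ThresholdSpec:
    """simpleM effective marker number from the marker correlation spectrum.

    Eigen-decomposes the correlation matrix of the codominant-coded markers
    and returns the smallest number of leading eigenvalues whose cumulative
    share reaches ``share`` of the total.  Constant marker columns are
    excluded with a warning.
    """
    cd = abh.cd_matrix()
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(cd, axis=0)
    keep = np.nonzero(variances > 0)[0]
    if keep.size < cd.shape[1]:
        warnings.warn(
            f"{cd.shape[1] - keep.size} constant marker column(s) excluded from "
            "the effective-marker-number calculation",
            stacklevel=2,
        )
    cd = cd[:, keep]
    m = cd.shape[1]
    if m == 0:
        raise ValueError("no segregating markers")
    if m == 1:
        return ThresholdSpec(alpha=alpha, q_eff=1, n_markers=1)
    corr = pairwise_complete_correlation(cd)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    cum = np.cumsum(eig) / eig.sum()
    q_eff = int(np.searchsorted(cum, share - 1e-12) + 1)
    return ThresholdSpec(alpha=alpha, q_eff=min(q_eff, m), n_markers=m)


# ----------------------------------------------------------------------
# Scan context: trait data + fixed variance structure


def _chol_psd(v: np.ndarray) -> np.ndarray:
    """Cholesky with a tiny diagonal ridge; tolerates boundary (zero)
    variance components that make the plot covariance numerically singular."""
    ridge = 1e-8 * float(np.max(np.diag(v))) + 1e-30
    return np.linalg.cholesky(v + ridge * np.eye(v.shape[0]))


@dataclass
class ScanContext:
    """Per-trait scanning state: plot data, genotype mapping, GLS whitener."""

    abh: AbhMatrix
    trait: str
    plots: pd.DataFrame  # genotype, location, replicate, value
    geno_rows: np.ndarray  # abh row index per plot
    components: dict[str, float]
    base_fit: object
    _chol: np.ndarray | None = field(default=None, repr=False)
    _subset_cache: dict = field(default_factory=dict, repr=False)

    def whitener(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Cholesky factor of the plot covariance (optionally row-subset)."""
        if mask is None or mask.all():
            if self._chol is None:
                v = build_covariance(self.plots, self.components)
                self._chol = _chol_psd(v)
            return self._chol, np.ones(len(self.plots), dtype=bool)
        key = mask.tobytes()
        if key not in self._subset_cache:
            v = build_covariance(self.plots[mask], self.components)
            self._subset_cache[key] = _chol_psd(v)
            if len(self._subset_cache) > 8:
                self._subset_cache.pop(next(iter(self._subset_cache)))
        return self._subset_cache[key], mask


def prepare_scan(abh: AbhMatrix, pheno: pd.DataFrame, trait: str) -> ScanContext:
    """Fit the cofactor-free trial model and freeze its covariance for GLS."""
    plots = _trait_frame(pheno, trait)
    known = set(abh.genotype_ids.tolist())
    plots = plots[plots["genotype"].isin(known)].reset_index(drop=True)
    if plots.empty:
        raise ValueError("no phenotyped genotypes overlap the marker matrix")
    base = fit_univariate(pheno, trait, genotype_as="random")
    lookup = {g: i for i, g in enumerate(abh.genotype_ids)}
    geno_rows = np.asarray([lookup[g] for g in plots["genotype"]])
    return ScanContext(
        abh=abh,
        trait=trait,
        plots=plots,
        geno_rows=geno_rows,
        components=base.components,
        base_fit=base,
    )


def _marker_plot_codes(
    ctx: ScanContext, marker_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plot-level (x_cd, x_d, non-missing mask) for one marker."""
    calls = ctx.abh.calls[ctx.geno_rows, marker_idx]
    ok = calls != CODE_MISSING
    x_cd = calls.astype(float)
    x_d = (calls == 1).astype(float)
    return x_cd, x_d, ok


def _sequential_wald(
    lw: np.ndarray,
    y: np.ndarray,
    blocks: list[np.ndarray],
) -> tuple[list[float], list[int], np.ndarray, np.ndarray]:
    """Incremental Wald chi-squares for successive fixed-effect blocks.

    All arrays are whitened with the Cholesky factor ``lw`` so ordinary
    least squares on the transformed data is GLS with known covariance; the
    drop in residual sum of squares when a block enters is its chi-square
    on (rank gained) df.  Returns per-block statistics and rank gains plus
    the full-model coefficients and their covariance.
    """
    yw = solve_triangular(lw, y, lower=True)
    xw_parts = [solve_triangular(lw, b, lower=True) for b in blocks]
    stats_out: list[float] = []
    dfs: list[int] = []
    x_acc = xw_parts[0]
    beta, rss, rank, _ = np.linalg.lstsq(x_acc, yw, rcond=None)
    prev_rss = float(rss[0]) if rss.size else float(((yw - x_acc @ beta) ** 2).sum())
    prev_rank = int(rank)
    for part in xw_parts[1:]:
        x_acc = np.hstack([x_acc, part])
        beta, rss, rank, _ = np.linalg.lstsq(x_acc, yw, rcond=None)
        cur_rss = float(rss[0]) if rss.size else float(((yw - x_acc @ beta) ** 2).sum())
        stats_out.append(max(prev_rss - cur_rss, 0.0))
        dfs.append(int(rank) - prev_rank)
        prev_rss, prev_rank = cur_rss, int(rank)
    # full-model coefficients and covariance (pseudo-inverse when singular)
    xtx = x_acc.T @ x_acc
    cov = np.linalg.pinv(xtx)
    beta_full = cov @ (x_acc.T @ yw)
    return stats_out, dfs, beta_full, cov


def _cofactor_columns(
    ctx: ScanContext, cofactors: list[str], exclude: set[str]
) -> tuple[np.ndarray, list[str]]:
    cols = []
    used = []
    for cof in cofactors:
        if cof in exclude:
            continue
        idx = ctx.abh.marker_index(cof)
        x_cd, x_d, ok = _marker_plot_codes(ctx, idx)
        if not ok.all():
            x_cd = np.where(ok, x_cd, np.nanmean(x_cd[ok]))
            x_d = np.where(ok, x_d, np.nanmean(x_d[ok]))
        cols.extend([x_cd, x_d])
        used.append(cof)
    if not cols:
        return np.empty((len(ctx.plots), 0)), used
    return np.column_stack(cols), used


def _marker_location_components(
    ctx: ScanContext,
    x_cd: np.ndarray,
    x_d: np.ndarray,
    fixed: np.ndarray,
    mask: np.ndarray,
) -> tuple[dict[str, float], list[str]]:
    """Re-estimate variance components with random marker-by-location terms."""
    sub = ctx.plots[mask]
    loc = design_matrix(sub["location"].to_numpy())
    terms = {
        "genotype": design_matrix(sub["genotype"].to_numpy()),
        "location": loc,
        "replicate": design_matrix(
            (sub["location"].astype(str) + "/" + sub["replicate"].astype(str)).to_numpy()
        ),
        "gxl": design_matrix(
            (sub["genotype"].astype(str) + "/" + sub["location"].astype(str)).to_numpy()
        ),
        "cd_x_location": x_cd[mask, None] * loc,
        "d_x_location": x_d[mask, None] * loc,
    }
    res = reml_fit(sub["value"].to_numpy(), fixed[mask], terms, n_starts=1,
                   start={**ctx.components,
                          "cd_x_location": 0.1 * ctx.components.get("residual", 1.0),
                          "d_x_location": 0.1 * ctx.components.get("residual", 1.0)})
    dropped = []
    vscale = float(np.var(sub["value"])) or 1.0
    comps = dict(res.variances)
    for nm in ("cd_x_location", "d_x_location"):
        if comps.get(nm, 0.0) < 1e-6 * vscale:
            comps.pop(nm)
            dropped.append(nm)
    return comps, dropped


def scan_single_marker(
    ctx: ScanContext,
    marker: str,
    cofactors: list[str] | None = None,
    redundancy: RedundancyGroups | None = None,
    marker_location_random: bool = False,
) -> dict:
    """Test one marker (codominant first, dominant second) in the trial model.

    Returns a scan-row dict with incremental p-values, effect sizes with
    standard errors, and per-class genotype counts over the scanned
    (trait-phenotyped, marker-non-missing) sample.
    """
    idx = ctx.abh.marker_index(marker)
    x_cd, x_d, ok = _marker_plot_codes(ctx, idx)
    exclude = {marker}
    if redundancy is not None:
        exclude.update(redundancy.group_of(marker))
    cof_mat, cof_used = _cofactor_columns(ctx, cofactors or [], exclude)
    # drop cofactors collinear with the tested marker
    flags: list[str] = []
    if cof_mat.shape[1]:
        keep_cols = []
        for c in range(cof_mat.shape[1]):
            r = np.corrcoef(cof_mat[ok, c], x_cd[ok])[0, 1] if np.std(cof_mat[ok, c]) > 0 else 0.0
            if abs(r) >= 1.0 - 1e-12:
                flags.append("collinear_cofactor_dropped")
                continue
            keep_cols.append(c)
        cof_mat = cof_mat[:, keep_cols]
    calls = ctx.abh.calls[ctx.geno_rows, idx]
    scanned = calls[ok]
    genos_scanned = ctx.plots.loc[ok, "genotype"]
    by_geno = pd.DataFrame({"g": genos_scanned, "c": scanned}).drop_duplicates("g")
    n_a = int((by_geno["c"] == 0).sum())
    n_h = int((by_geno["c"] == 1).sum())
    n_b = int((by_geno["c"] == 2).sum())
    if len(np.unique(scanned)) < 2:
        raise ValueError(f"marker {marker!r} does not segregate in the scanned sample")
    y = ctx.plots["value"].to_numpy()
    intercept = np.ones((len(ctx.plots), 1))
    blocks = [
        np.hstack([intercept[ok], cof_mat[ok]]) if cof_mat.shape[1] else intercept[ok],
        x_cd[ok, None],
        x_d[ok, None],
    ]
    if marker_location_random:
        fixed_full = np.hstack([intercept, cof_mat, x_cd[:, None], x_d[:, None]])
        comps, dropped = _marker_location_components(ctx, x_cd, x_d, fixed_full, ok)
        flags.extend(f"dropped_{nm}" for nm in dropped)
        v = build_covariance(ctx.plots[ok], comps)
        loc_codes = pd.factorize(ctx.plots.loc[ok, "location"])[0]
        same_l = loc_codes[:, None] == loc_codes[None, :]
        if "cd_x_location" in comps:
            v += comps["cd_x_location"] * np.outer(x_cd[ok], x_cd[ok]) * same_l
        if "d_x_location" in comps:
            v += comps["d_x_location"] * np.outer(x_d[ok], x_d[ok]) * same_l
        lw = _chol_psd(v)
    else:
        lw, _ = ctx.whitener(None if ok.all() else ok)
    wald, dfs, beta, cov = _sequential_wald(lw, y[ok], blocks)
    w_cd, w_d = wald
    df_cd, df_d = dfs
    p_cd = float(stats.chi2.sf(w_cd, df_cd)) if df_cd > 0 else 1.0
    if df_d == 0:
        p_d = 1.0
        flags.append("d_inestimable")
    else:
        p_d = float(stats.chi2.sf(w_d, df_d))
    p_cdd = float(stats.chi2.sf(w_cd + w_d, max(df_cd + df_d, 1)))
    k0 = blocks[0].shape[1]
    eff_cd = float(beta[k0])
    se_cd = float(np.sqrt(max(cov[k0, k0], 0.0)))
    eff_d = float(beta[k0 + 1]) if df_d > 0 else float("nan")
    se_d = float(np.sqrt(max(cov[k0 + 1, k0 + 1], 0.0))) if df_d > 0 else float("nan")
    return {
        "marker": marker,
        "chromosome": ctx.abh.chromosome[idx] if ctx.abh.has_map else pd.NA,
        "cM": float(ctx.abh.position_cm[idx]) if ctx.abh.has_map else np.nan,
        "p_cd": p_cd,
        "p_d": p_d,
        "p_cdd": p_cdd,
        "eff_cd": eff_cd,
        "se_cd": se_cd,
        "eff_d": eff_d,
        "se_d": se_d,
        "n_A": n_a,
        "n_H": n_h,
        "n_B": n_b,
        "cofactors_used": ",".join(cof_used),
        "flags": ";".join(flags),
    }


# ----------------------------------------------------------------------
# Cofactor selection


def select_cofactors_cm1(scan: pd.DataFrame, threshold: float) -> list[str]:
    """Per chromosome, the most significant marker passing the threshold.

    ``scan`` is a cofactor-free genome scan table; chromosomes where no
    marker passes contribute nothing.  When the returned set is used,
    cofactors on the tested marker's own chromosome must be dropped (done
    by :func:`genome_scan`).
    """
    passed = scan[scan["p_cdd"] <= threshold]
    out: list[str] = []
    for _, grp in passed.groupby("chromosome", sort=True):
        out.append(grp.loc[grp["p_cdd"].idxmin(), "marker"])
    return out


def select_cofactors_cm2(
    blues: pd.Series,
    cd: pd.DataFrame,
) -> list[str]:
    """Stepwise forward/backward cofactor search on BLUEs with Schwarz BIC.

    A plain linear model of the BLUEs on codominant marker codes, starting
    from the intercept-only null model; at each step the single add-or-drop
    move that most decreases ``BIC = n log(RSS / n) + log(n) (p + 1)`` is
    taken, until no move improves.  Ties break to the lower marker index,
    making the procedure deterministic for a fixed column order.
    """
    common = blues.index.intersection(cd.index)
    y = blues.loc[common].to_numpy(dtype=float)
    x = cd.loc[common]
    n = len(y)
    markers = list(x.columns)
    cols = {m: x[m].to_numpy(dtype=float) for m in markers}

    def bic(active: list[str]) -> float:
        if active:
            design = np.column_stack([np.ones(n)] + [cols[m] for m in active])
        else:
            design = np.ones((n, 1))
        beta, rss, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rss.size:
            rss_v = float(rss[0])
        else:
            rss_v = float(((y - design @ beta) ** 2).sum())
        rss_v = max(rss_v, 1e-300)
        return n * np.log(rss_v / n) + np.log(n) * design.shape[1]

    active: list[str] = []
    current = bic(active)
    while True:
        best_move: tuple[str, str] | None = None
        best_bic = current
        for m in markers:
            if m in active:
                cand = [a for a in active if a != m]
                move = ("drop", m)
            else:
                cand = active + [m]
                move = ("add", m)
            b = bic(cand)
            if b < best_bic - 1e-9:
                best_bic = b
                best_move = move
        if best_move is None:
            break
        kind, m = best_move
        if kind == "add":
            active.append(m)
        else:
            active.remove(m)
        current = best_bic
    return sorted(active, key=markers.index)


# ----------------------------------------------------------------------
# Genome scan


def genome_scan(
    abh: AbhMatrix,
    pheno: pd.DataFrame,
    trait: str,
    cofactors: str | list[str] = "none",
    redundancy: RedundancyGroups | None = None,
    alpha: float = 0.05,
    pca_share: float = 0.995,
    blues: pd.Series | None = None,
    marker_location_random: bool = False,
) -> tuple[pd.DataFrame, ThresholdSpec, list[str]]:
    """Scan every segregating marker for association with a trait.

    ``cofactors`` is ``'none'``, ``'cm1'`` (per-chromosome peaks of a
    cofactor-free scan that pass the simpleM threshold), ``'cm2'``
    (BIC-stepwise selection on BLUEs; requires ``blues`` or computes them),
    or an explicit marker list.  Cofactors on the tested marker's own
    chromosome (CM1) or in its redundancy group are excluded per test.
    """
    ctx = prepare_scan(abh, pheno, trait)
    thresholds = effective_marker_number(abh, share=pca_share, alpha=alpha)

    def run(cof_list: list[str], own_chrom: bool) -> pd.DataFrame:
        rows = []
        for marker in abh.marker_ids:
            cofs = cof_list
            if own_chrom and abh.has_map and cof_list:
                chrom = abh.chromosome[abh.marker_index(marker)]
                cofs = [
                    c for c in cof_list
                    if abh.chromosome[abh.marker_index(c)] != chrom
                ]
            try:
                rows.append(
                    scan_single_marker(
                        ctx, marker, cofactors=cofs, redundancy=redundancy,
                        marker_location_random=marker_location_random,
                    )
                )
            except ValueError:
                continue  # non-segregating marker in the scanned sample
        return pd.DataFrame(rows)

    if cofactors == "none":
        return run([], False), thresholds, []
    if isinstance(cofactors, list):
        return run(cofactors, False), thresholds, cofactors
    if cofactors == "cm1":
        free = run([], False)
        cofs = select_cofactors_cm1(free, thresholds.per_test)
        return run(cofs, True), thresholds, cofs
    if cofactors == "cm2":
        if blues is None:
            fixed = fit_univariate(pheno, trait, genotype_as="fixed")
            blues = fixed.blues.set_index("genotype")["blue"]
        cd = pd.DataFrame(
            abh.cd_matrix(), index=abh.genotype_ids, columns=abh.marker_ids
        ).dropna(axis=0)
        cofs = select_cofactors_cm2(blues, cd)
        return run(cofs, False), thresholds, cofs
    raise ValueError(f"unknown cofactor mode {cofactors!r}")


# ----------------------------------------------------------------------
# QTL summaries


def confidence_interval(
    scan: pd.DataFrame, peak_marker: str
) -> tuple[float, float]:
    """log10 p-value drop-of-1 support interval around a peak marker.

    ``scan`` must cover a single chromosome.  Extends outward from the peak
    while -log10(p_cdd) stays strictly within 1 of the peak value; the first
    marker at or beyond the one-unit drop bounds the interval on each side
    (a one-sided interval ends at the terminal marker).  Returns the cM
    positions of the two bounding markers.
    """
    if scan["chromosome"].nunique() > 1:
        raise ValueError("confidence interval expects a single-chromosome profile")
    prof = scan.sort_values("cM").reset_index(drop=True)
    hits = prof.index[prof["marker"] == peak_marker]
    if len(hits) == 0:
        raise ValueError(f"peak marker {peak_marker!r} not in the profile")
    peak = int(hits[0])
    nl = -np.log10(np.clip(prof["p_cdd"].to_numpy(), 1e-300, None))
    floor = nl[peak] - 1.0
    left = peak
    while left > 0:
        left -= 1
        if nl[left] <= floor:
            break
    right = peak
    while right < len(prof) - 1:
        right += 1
        if nl[right] <= floor:
            break
    return float(prof.loc[left, "cM"]), float(prof.loc[right, "cM"])


def _marker_effect_columns(
    abh: AbhMatrix, plots: pd.DataFrame, markers: list[str]
) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(abh.genotype_ids)}
    geno_rows = np.asarray([lookup[g] for g in plots["genotype"]])
    cols = []
    for m in markers:
        idx = abh.marker_index(m)
        calls = abh.calls[geno_rows, idx]
        if (calls == CODE_MISSING).any():
            raise ValueError(f"marker {m!r} has missing calls among phenotyped genotypes")
        cols.extend([calls.astype(float), (calls == 1).astype(float)])
    if not cols:
        return np.empty((len(plots), 0))
    x = np.column_stack(cols)
    # reduce to a linearly independent column set (redundant markers)
    q, r = np.linalg.qr(x - x.mean(axis=0))
    keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1.0)
    return x[:, keep]


def explained_variance(
    abh: AbhMatrix,
    pheno: pd.DataFrame,
    trait: str,
    markers: list[str],
) -> tuple[float, bool]:
    """Explained genetic variance p_G of a marker set.

    The reduction of the genotype variance component when the markers'
    codominant-plus-dominant fixed effects are added to the trial model,
    divided by the full genetic variance.  Negative estimates are truncated
    to 0 and flagged (second return value).
    """
    base = fit_univariate(pheno, trait, genotype_as="random")
    s2_base = base.components["genotype"]
    if s2_base <= 0:
        raise ValueError("base genetic variance is zero")
    if not markers:
        return 0.0, False
    plots = _trait_frame(pheno, trait)
    plots = plots[plots["genotype"].isin(set(abh.genotype_ids.tolist()))].reset_index(drop=True)
    single = base.design == "single"
    cube = _try_cube(plots)
    if cube is not None:
        # balanced fast path: marker covariates live in the genotype-mean
        # subspace, so the adjusted REML factors exactly
        if single:
            cube = cube.reshape(cube.shape[0] * cube.shape[1], cube.shape[2])
        genos = sorted(plots["genotype"].unique())
        geno_frame = pd.DataFrame(
            {"genotype": genos, "location": "L", "replicate": "R", "value": 0.0}
        )
        xg = np.hstack(
            [np.ones((len(genos), 1)), _marker_effect_columns(abh, geno_frame, markers)]
        )
        adj = reml_balanced_genotype_covariates(cube, xg, single=single)
    else:
        x = np.hstack(
            [np.ones((len(plots), 1)), _marker_effect_columns(abh, plots, markers)]
        )
        terms = {"genotype": design_matrix(plots["genotype"].to_numpy())}
        if not single:
            terms["location"] = design_matrix(plots["location"].to_numpy())
        terms["replicate"] = design_matrix(
            (plots["location"].astype(str) + "/" + plots["replicate"].astype(str)).to_numpy()
        )
        if not single:
            terms["gxl"] = design_matrix(
                (plots["genotype"].astype(str) + "/" + plots["location"].astype(str)).to_numpy()
            )
        adj = reml_fit(plots["value"].to_numpy(), x, terms, n_starts=1, start=base.components)
    s2_adj = adj.variances["genotype"]
    p_g = (s2_base - s2_adj) / s2_base
    if p_g < 0:
        return 0.0, True
    return float(p_g), False


def explained_covariance(
    abh: AbhMatrix,
    pheno: pd.DataFrame,
    trait1: str,
    trait2: str,
    markers: list[str],
) -> tuple[float, bool]:
    """Explained genetic covariance p_CovG of a marker set (bivariate model).

    Analogous to p_G on the genetic covariance component.  When the base
    genetic covariance is numerically zero the quantity is undefined and
    the flag is set (NaN returned).
    """
    base = fit_bivariate(pheno, trait1, trait2)
    cov_base = float(base.genetic_cov[0, 1])
    if abs(cov_base) < 1e-8:
        return float("nan"), True
    if not markers:
        return 0.0, False
    from .pheno import _paired_plots

    wide = _paired_plots(pheno, trait1, trait2)
    plots = wide.rename(columns={"value_1": "value"})[
        ["genotype", "location", "replicate", "value"]
    ]
    covariates = _marker_effect_columns(abh, plots, markers)
    adj = fit_bivariate(pheno, trait1, trait2, genotype_covariates=covariates)
    cov_adj = float(adj.genetic_cov[0, 1])
    return float((cov_base - cov_adj) / cov_base), False


# ----------------------------------------------------------------------
# Epistasis


_EPI_TERMS = ("m1_cd", "m2_cd", "m1_d", "m2_d", "cd_cd", "d_d", "m1d_m2cd", "m2d_m1cd")


def epistasis_scan(
    abh: AbhMatrix,
    pheno: pd.DataFrame,
    trait: str,
    pairs: list[tuple[str, str]],
    thresholds: ThresholdSpec | None = None,
    marker_location_random: bool = False,
) -> pd.DataFrame:
    """Pairwise marker-interaction scan with incremental Wald tests.

    For each pair the fixed-effect sequence is ``m1_cd + m2_cd + m1_d +
    m2_d + m1_cd:m2_cd + m1_d:m2_d + m1_d:m2_cd``; the asymmetric
    ``d:cd`` interaction is additionally tested in the swapped orientation
    as the last increment of a parallel sequence.  Interaction terms whose
    design cell is empty are flagged inestimable (p = NaN).  With a
    threshold spec, significance is assessed at ``alpha / (q_eff (q_eff -
    1))``.
    """
    ctx = prepare_scan(abh, pheno, trait)
    y = ctx.plots["value"].to_numpy()
    intercept = np.ones((len(ctx.plots), 1))
    rows = []
    for m1, m2 in pairs:
        if m1 == m2:
            raise ValueError("a marker cannot be paired with itself")
        i1, i2 = ctx.abh.marker_index(m1), ctx.abh.marker_index(m2)
        cd1, d1, ok1 = _marker_plot_codes(ctx, i1)
        cd2, d2, ok2 = _marker_plot_codes(ctx, i2)
        ok = ok1 & ok2
        if marker_location_random and ctx.plots["location"].nunique() > 1:
            sub = ctx.plots[ok]
            loc = design_matrix(sub["location"].to_numpy())
            terms = {
                "genotype": design_matrix(sub["genotype"].to_numpy()),
                "location": loc,
                "replicate": design_matrix(
                    (sub["location"].astype(str) + "/" + sub["replicate"].astype(str)).to_numpy()
                ),
                "gxl": design_matrix(
                    (sub["genotype"].astype(str) + "/" + sub["location"].astype(str)).to_numpy()
                ),
                "m1cd_x_location": cd1[ok, None] * loc,
                "m1d_x_location": d1[ok, None] * loc,
                "m2cd_x_location": cd2[ok, None] * loc,
                "m2d_x_location": d2[ok, None] * loc,
            }
            start = {**ctx.components}
            for nm in list(terms):
                start.setdefault(nm, 0.1 * ctx.components.get("residual", 1.0))
            fit = reml_fit(
                sub["value"].to_numpy(),
                np.hstack([intercept[ok], cd1[ok, None], d1[ok, None], cd2[ok, None], d2[ok, None]]),
                terms,
                n_starts=1,
                start=start,
            )
            vscale = float(np.var(sub["value"])) or 1.0
            comps = {
                k: v for k, v in fit.variances.items()
                if not (k.endswith("_x_location") and v < 1e-6 * vscale)
            }
            v = build_covariance(sub, comps)
            loc_codes = pd.factorize(sub["location"])[0]
            same_l = loc_codes[:, None] == loc_codes[None, :]
            for nm, xv in (
                ("m1cd_x_location", cd1[ok]),
                ("m1d_x_location", d1[ok]),
                ("m2cd_x_location", cd2[ok]),
                ("m2d_x_location", d2[ok]),
            ):
                if nm in comps:
                    v += comps[nm] * np.outer(xv, xv) * same_l
            lw = _chol_psd(v)
        else:
            lw, _ = ctx.whitener(None if ok.all() else ok)
        mk = lambda a: a[ok, None]  # noqa: E731
        main = [mk(cd1), mk(cd2), mk(d1), mk(d2)]
        seq_a = [intercept[ok]] + main + [
            mk(cd1 * cd2), mk(d1 * d2), mk(d1 * cd2)
        ]
        seq_b = [intercept[ok]] + main + [
            mk(cd1 * cd2), mk(d1 * d2), mk(d2 * cd1)
        ]
        wald_a, dfs_a, _, _ = _sequential_wald(lw, y[ok], seq_a)
        wald_b, dfs_b, _, _ = _sequential_wald(lw, y[ok], seq_b)
        per_term = list(zip(_EPI_TERMS[:7], wald_a, dfs_a)) + [
            (_EPI_TERMS[7], wald_b[-1], dfs_b[-1])
        ]
        for term, w, df in per_term:
            if df == 0:
                p = float("nan")
                flag = "inestimable"
            else:
                p = float(stats.chi2.sf(w, df))
                flag = ""
            rows.append(
                {
                    "marker1": m1,
                    "marker2": m2,
                    "term": term,
                    "wald": w,
                    "df": df,
                    "p": p,
                    "significant": (
                        bool(p <= thresholds.epistasis_per_test)
                        if thresholds is not None and np.isfinite(p)
                        else pd.NA
                    ),
                    "flags": flag,
                }
            )
    return pd.DataFrame(rows)
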