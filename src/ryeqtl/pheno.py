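"""Mixed-model analysis of the plot-level phenotypes.

The trial model is ``y_ijkl = mu + g_i + l_j + r_jk + (gl)_ij + e_ijkl``
with genotype g, location l, replicate-in-location r, genotype-by-location
interaction and plot residual.  Genotype is modelled as random to estimate
variance components and as fixed to obtain BLUEs (best linear unbiased
estimators of genotype means), the mean variance of a difference of two
BLUEs (av.VD), least-significant differences, and the entry-mean
heritability ``H^2 = sigma2_g / (sigma2_g + av.VD / 2)``.

A bivariate model for two traits assigns an unstructured 2x2 covariance to
the genotype and residual terms and a diagonal covariance to the replicate
term, using only plots with records for both traits (no location effect).
The fertility score is derived from the visually scored non-seed set as
``fertility = 100 - non-seed set``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .reml import (
    REMLResult,
    _minimize_multistart,
    _subspace_ss,
    _variance_se,
    design_matrix,
    reml_balanced,
    reml_fit,
)

__all__ = [
    "UnivariateFit",
    "BivariateFit",
    "fit_univariate",
    "fit_bivariate",
    "heritability",
    "balanced_av_vd",
    "derive_fertility",
    "to_non_fertility",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ----------------------------------------------------------------------
# Data wrangling


def _trait_frame(data: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = data[(data["trait"] == trait) & data["value"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return sub.reset_index(drop=True)


def _try_cube(sub: pd.DataFrame) -> np.ndarray | None:
    """(L, R, G) observation cube when the design is balanced and complete."""
    locs = sorted(sub["location"].unique())
    genos = sorted(sub["genotype"].unique())
    reps_per_loc = {
        loc: sorted(sub.loc[sub["location"] == loc, "replicate"].unique())
        for loc in locs
    }
    n_rep = {len(v) for v in reps_per_loc.values()}
    if len(n_rep) != 1:
        return None
    r = n_rep.pop()
    if len(sub) != len(locs) * r * len(genos):
        return None
    cube = np.full((len(locs), r, len(genos)), np.nan)
    li = {v: i for i, v in enumerate(locs)}
    gi = {v: i for i, v in enumerate(genos)}
    for loc in locs:
        ri = {v: i for i, v in enumerate(reps_per_loc[loc])}
        block = sub[sub["location"] == loc]
        cube[li[loc], [ri[v] for v in block["replicate"]], [gi[v] for v in block["genotype"]]] = block[
            "value"
        ].to_numpy()
    if np.isnan(cube).any():
        return None
    return cube


# ----------------------------------------------------------------------
# Univariate fit


@dataclass
class UnivariateFit:
    """Variance components and (when genotype is fixed) BLUE summaries."""

    trait: str
    genotype_as: str
    design: str  # "multi" or "single"
    components: dict[str, float]
    se: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    n_genotypes: int
    n_locations: int
    n_replicates: int
    loglik_path: list[float] = field(default_factory=list)
    blues: pd.DataFrame | None = None
    av_vd: float | None = None
    lsd: float | None = None
    residual_df: int | None = None


def _balanced_fixed_genotype(cube: np.ndarray, single: bool) -> tuple[dict, dict, float, bool, list]:
    """REML for the genotype-fixed model on a balanced cube (spectral path).

    The genotype cell-mean space is the union of the subspaces that are in
    the mean on every non-genotype axis; those subspaces drop from the
    restricted likelihood.
    """
    ss, dims = _subspace_ss(cube)
    if single:  # axes (R, G); random: replicate, residual
        names = ["replicate", "residual"]
        masks: dict[str, tuple[int, ...] | None] = {"replicate": (1,), "residual": None}
        fixed_axes = (0,)
    else:  # axes (L, R, G); random: location, replicate, gxl, residual
        names = ["location", "replicate", "gxl", "residual"]
        masks = {"location": (1, 2), "replicate": (2,), "gxl": (1,), "residual": None}
        fixed_axes = (0, 1)
    combos = [
        c
        for c in ss
        if not all(c[a] == 0 for a in fixed_axes)  # exclude the genotype space
    ]
    mult = np.zeros((len(combos), len(names)))
    for ci, combo in enumerate(combos):
        for ni, nm in enumerate(names):
            axes = masks[nm]
            if axes is None:
                mult[ci, ni] = 1.0
            elif all(combo[a] == 0 for a in axes):
                m = 1
                for a in axes:
                    m *= cube.shape[a]
                mult[ci, ni] = m
    ss_vec = np.array([ss[c] for c in combos])
    dim_vec = np.array([dims[c] for c in combos], dtype=float)
    n_res = int(dim_vec.sum())

    def nll(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 500):
            return 1e30
        lam = mult @ np.exp(theta)
        if (lam <= 0).any():
            return 1e30
        return 0.5 * (n_res * _LOG2PI + float(dim_vec @ np.log(lam)) + float((ss_vec / lam).sum()))

    vscale = float(cube.var()) or 1.0
    theta, fval, ok, path = _minimize_multistart(nll, len(names), vscale, polish=True)
    sig = dict(zip(names, np.exp(theta).tolist()))
    se = _variance_se(nll, theta, names)
    return sig, se, -fval, ok, path


def fit_univariate(
    data: pd.DataFrame,
    trait: str,
    genotype_as: str = "random",
    design: str = "auto",
) -> UnivariateFit:
    """Fit the trial mixed model for one trait.

    With ``genotype_as='random'`` the genetic variance is estimated; with
    ``'fixed'`` the genotype means (BLUEs) are estimated together with
    av.VD and the LSD at the 5 % level.  Single-location data drops the
    location and genotype-by-location terms.  Balanced complete designs use
    the exact spectral likelihood; anything else falls back to the dense
    REML path.
    """
    if genotype_as not in ("random", "fixed"):
        raise ValueError("genotype_as must be 'random' or 'fixed'")
    sub = _trait_frame(data, trait)
    n_loc = sub["location"].nunique()
    single = n_loc == 1 if design == "auto" else design == "single"
    genos = sorted(sub["genotype"].unique())
    g = len(genos)
    if g < 2:
        raise ValueError("need at least two genotypes")
    n_rep = sub.groupby("location")["replicate"].nunique().max()
    if genotype_as == "fixed" and single and n_rep == 1:
        raise ValueError(
            "genotype fixed with one location and one replicate leaves no residual"
        )
    cube = _try_cube(sub)
    if cube is not None and single:
        cube = cube.reshape(cube.shape[0] * cube.shape[1], cube.shape[2])

    if genotype_as == "random":
        if cube is not None:
            if single:
                masks = {"genotype": (0,), "replicate": (1,), "residual": None}
            else:
                masks = {
                    "genotype": (0, 1),
                    "location": (1, 2),
                    "replicate": (2,),
                    "gxl": (1,),
                    "residual": None,
                }
            res = reml_balanced(cube, masks)
        else:
            terms = {"genotype": design_matrix(sub["genotype"].to_numpy())}
            if not single:
                terms["location"] = design_matrix(sub["location"].to_numpy())
            terms["replicate"] = design_matrix(
                (sub["location"].astype(str) + "/" + sub["replicate"].astype(str)).to_numpy()
            )
            if not single:
                terms["gxl"] = design_matrix(
                    (sub["genotype"].astype(str) + "/" + sub["location"].astype(str)).to_numpy()
                )
            res = reml_fit(sub["value"].to_numpy(), np.ones((len(sub), 1)), terms)
        return UnivariateFit(
            trait=trait,
            genotype_as="random",
            design="single" if single else "multi",
            components=res.variances,
            se=res.se,
            loglik=res.loglik,
            converged=res.converged,
            n_obs=res.n_obs,
            n_genotypes=g,
            n_locations=n_loc,
            n_replicates=int(n_rep),
            loglik_path=res.loglik_path,
        )

    # genotype fixed: BLUEs
    if cube is not None:
        if single:
            sig, se, ll, ok, path = _balanced_fixed_genotype(cube, single=True)
            blue_vals = cube.mean(axis=0)
            r = cube.shape[0]
            a = sig["residual"] / r
            b = sig["replicate"] / r
            av_vd = 2.0 * a
        else:
            sig, se, ll, ok, path = _balanced_fixed_genotype(cube, single=False)
            blue_vals = cube.mean(axis=(0, 1))
            L, R = cube.shape[0], cube.shape[1]
            a = sig["gxl"] / L + sig["residual"] / (L * R)
            b = sig["location"] / L + sig["replicate"] / (L * R)
            av_vd = 2.0 * a
        cov = a * np.eye(g) + b * np.ones((g, g))
        n_obs = int(np.prod(cube.shape[:-1])) * g
        resid_df = n_obs - g
        se_blue = np.sqrt(np.diag(cov))
        beta = blue_vals
        loglik, converged, path_ = ll, ok, path
    else:
        x = design_matrix(sub["genotype"].to_numpy())
        terms: dict[str, np.ndarray] = {}
        if not single:
            terms["location"] = design_matrix(sub["location"].to_numpy())
        terms["replicate"] = design_matrix(
            (sub["location"].astype(str) + "/" + sub["replicate"].astype(str)).to_numpy()
        )
        if not single:
            terms["gxl"] = design_matrix(
                (sub["genotype"].astype(str) + "/" + sub["location"].astype(str)).to_numpy()
            )
        res = reml_fit(sub["value"].to_numpy(), x, terms)
        sig, se = res.variances, res.se
        beta = res.beta
        cov = res.cov_beta
        av_vd = float(
            2.0 * (g * np.trace(cov) - cov.sum()) / (g * (g - 1))
        )
        se_blue = np.sqrt(np.diag(cov))
        n_obs = res.n_obs
        resid_df = n_obs - x.shape[1]
        loglik, converged, path_ = res.loglik, res.converged, res.loglik_path
    lsd = float(stats.t.ppf(0.975, resid_df) * np.sqrt(av_vd)) if resid_df > 0 else float("nan")
    blues = pd.DataFrame({"genotype": genos, "blue": beta, "se": se_blue})
    return UnivariateFit(
        trait=trait,
        genotype_as="fixed",
        design="single" if single else "multi",
        components=sig,
        se=se,
        loglik=loglik,
        converged=converged,
        n_obs=n_obs,
        n_genotypes=g,
        n_locations=n_loc,
        n_replicates=int(n_rep),
        loglik_path=path_,
        blues=blues,
        av_vd=float(av_vd),
        lsd=lsd,
        residual_df=resid_df,
    )


# ----------------------------------------------------------------------
# Heritability


def heritability(sigma2_g: float, av_vd: float) -> float:
    """Entry-mean heritability ``H^2 = sigma2_g / (sigma2_g + av.VD / 2)``."""
    if sigma2_g < 0:
        raise ValueError("sigma2_g must be non-negative")
    if av_vd <= 0:
        raise ValueError("av.VD must be positive")
    return sigma2_g / (sigma2_g + av_vd / 2.0)


def balanced_av_vd(
    sigma2_e: float,
    n_locations: int,
    n_replicates: int,
    sigma2_gxl: float = 0.0,
) -> float:
    """Balanced-design approximation ``av.VD = 2 (s2_gl / L + s2_e / (L R))``."""
    if n_locations < 1 or n_replicates < 1:
        raise ValueError("need at least one location and replicate")
    return 2.0 * (sigma2_gxl / n_locations + sigma2_e / (n_locations * n_replicates))


def derive_fertility(non_seed_set: pd.Series | np.ndarray) -> np.ndarray:
    """Fertility (%) from the scored non-seed set: ``100 - non-seed set``."""
    return 100.0 - np.asarray(non_seed_set, dtype=float)


def to_non_fertility(fertility: pd.Series | np.ndarray) -> np.ndarray:
    """Non-fertility (%) from fertility, for the bivariate model."""
    return 100.0 - np.asarray(fertility, dtype=float)


# ----------------------------------------------------------------------
# Bivariate fit


@dataclass
class BivariateFit:
    """Bivariate REML fit: unstructured genotype and residual covariance."""

    traits: tuple[str, str]
    genetic_cov: np.ndarray  # 2x2
    residual_cov: np.ndarray  # 2x2
    replicate_vars: np.ndarray  # (2,)
    genetic_correlation: float
    genetic_cov_se: float  # SE of the genetic covariance (off-diagonal)
    loglik: float
    converged: bool
    n_plots: int
    n_genotypes: int


def _paired_plots(data: pd.DataFrame, trait1: str, trait2: str) -> pd.DataFrame:
    a = _trait_frame(data, trait1)[["genotype", "location", "replicate", "value"]]
    b = _trait_frame(data, trait2)[["genotype", "location", "replicate", "value"]]
    wide = a.merge(
        b, on=["genotype", "location", "replicate"], suffixes=("_1", "_2")
    )
    if wide["genotype"].nunique() < 3:
        raise ValueError("need at least three genotypes with complete trait pairs")
    return wide


def _bivariate_nll_factory(
    y: np.ndarray,
    same_g: np.ndarray,
    same_r: np.ndarray,
    x: np.ndarray,
    independent: bool,
):
    p2 = same_g.shape[0]
    eye = np.eye(p2)
    n = 2 * p2
    p = x.shape[1]

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if independent:
            a11g, a22g, a11r, a22r, ld1, ld2 = theta
            a21g = a21r = 0.0
        else:
            a11g, a21g, a22g, a11r, a21r, a22r, ld1, ld2 = theta
        lg = np.array([[np.exp(a11g), 0.0], [a21g, np.exp(a22g)]])
        lr = np.array([[np.exp(a11r), 0.0], [a21r, np.exp(a22r)]])
        return lg @ lg.T, lr @ lr.T, np.exp([ld1, ld2])

    def build_v(theta: np.ndarray) -> np.ndarray:
        gcov, rcov, d = unpack(theta)
        v = np.empty((n, n))
        v[:p2, :p2] = gcov[0, 0] * same_g + d[0] * same_r + rcov[0, 0] * eye
        v[p2:, p2:] = gcov[1, 1] * same_g + d[1] * same_r + rcov[1, 1] * eye
        off = gcov[0, 1] * same_g + rcov[0, 1] * eye
        v[:p2, p2:] = off
        v[p2:, :p2] = off.T
        return v

    def nll_v(v: np.ndarray) -> float:
        try:
            cf = cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            return 1e30
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        vi_yx = cho_solve(cf, np.column_stack([y, x]))
        vi_y, vi_x = vi_yx[:, 0], vi_yx[:, 1:]
        xtvix = x.T @ vi_x
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            return 1e30
        xvy = x.T @ vi_y
        ypy = float(y @ vi_y - xvy @ np.linalg.solve(xtvix, xvy))
        return 0.5 * ((n - p) * _LOG2PI + logdet_v + logdet_x + ypy)

    def nll(theta: np.ndarray) -> float:
        return nll_v(build_v(theta))

    def nll_natural(params: np.ndarray) -> float:
        """Same likelihood on (G11, G12, G22, R11, R12, R22, d1, d2)."""
        g11, g12, g22, r11, r12, r22, d1v, d2v = params
        if min(g11, g22, r11, r22) <= 0 or min(d1v, d2v) < 0:
            return 1e30
        v = np.empty((n, n))
        v[:p2, :p2] = g11 * same_g + d1v * same_r + r11 * eye
        v[p2:, p2:] = g22 * same_g + d2v * same_r + r22 * eye
        off = g12 * same_g + r12 * eye
        v[:p2, p2:] = off
        v[p2:, :p2] = off.T
        return nll_v(v)

    return nll, unpack, nll_natural


def _bivariate_balanced_nll_factory(
    cube1: np.ndarray, cube2: np.ndarray, independent: bool
):
    """Exact bivariate restricted likelihood for a balanced (rep x genotype)
    paired design via simultaneous diagonalization: four 2x2 subproblems."""
    r_lev, g_lev = cube1.shape
    n = 2 * r_lev * g_lev
    p_plots = r_lev * g_lev

    combos = [(0, 0), (0, 1), (1, 0), (1, 1)]
    s_mats: dict[tuple[int, int], np.ndarray] = {}
    dims: dict[tuple[int, int], int] = {}
    for combo in combos:
        pieces = []
        mult = 1
        for cube in (cube1, cube2):
            piece = cube
            m = 1
            for axis, b in enumerate(combo):
                mean = piece.mean(axis=axis, keepdims=True)
                if b == 0:
                    piece = mean
                    m *= cube.shape[axis]
                else:
                    piece = piece - mean
            pieces.append(piece)
            mult = m
        s = np.empty((2, 2))
        s[0, 0] = (pieces[0] * pieces[0]).sum() * mult
        s[1, 1] = (pieces[1] * pieces[1]).sum() * mult
        s[0, 1] = s[1, 0] = (pieces[0] * pieces[1]).sum() * mult
        s_mats[combo] = s
        dims[combo] = (1 if combo[0] == 0 else r_lev - 1) * (
            1 if combo[1] == 0 else g_lev - 1
        )

    def unpack(theta: np.ndarray):
        if independent:
            a11g, a22g, a11r, a22r, ld1, ld2 = theta
            a21g = a21r = 0.0
        else:
            a11g, a21g, a22g, a11r, a21r, a22r, ld1, ld2 = theta
        lg = np.array([[np.exp(a11g), 0.0], [a21g, np.exp(a22g)]])
        lr = np.array([[np.exp(a11r), 0.0], [a21r, np.exp(a22r)]])
        return lg @ lg.T, lr @ lr.T, np.exp([ld1, ld2])

    def nll_mats(gcov: np.ndarray, rcov: np.ndarray, d: np.ndarray) -> float:
        total = 0.0
        for combo in combos:
            a = r_lev if combo[0] == 0 else 0  # genotype-share multiplier
            b = g_lev if combo[1] == 0 else 0  # replicate-share multiplier
            m = a * gcov + b * np.diag(d) + rcov
            det = m[0, 0] * m[1, 1] - m[0, 1] ** 2
            if det <= 0 or m[0, 0] <= 0:
                return 1e30
            if combo == (0, 0):
                total += np.log(det)  # cancels against log|X'V^-1 X|
                continue
            inv = np.array([[m[1, 1], -m[0, 1]], [-m[0, 1], m[0, 0]]]) / det
            total += dims[combo] * np.log(det) + float(
                (inv * s_mats[combo]).sum()
            )
        total += 2.0 * np.log(p_plots) - np.log(
            np.linalg.det(
                r_lev * gcov + g_lev * np.diag(d) + rcov
            )
        )
        return 0.5 * ((n - 2) * _LOG2PI + total)

    def nll(theta: np.ndarray) -> float:
        return nll_mats(*unpack(theta))

    def nll_natural(params: np.ndarray) -> float:
        g11, g12, g22, r11, r12, r22, d1v, d2v = params
        if min(g11, g22, r11, r22) <= 0 or min(d1v, d2v) < 0:
            return 1e30
        gcov = np.array([[g11, g12], [g12, g22]])
        rcov = np.array([[r11, r12], [r12, r22]])
        return nll_mats(gcov, rcov, np.array([d1v, d2v]))

    return nll, unpack, nll_natural


def _paired_cubes(wide: pd.DataFrame) -> tuple[np.ndarray, np.ndarray] | None:
    """(rep x genotype) cubes for both traits when the pair set is balanced."""
    wide = wide.assign(
        plotrep=wide["location"].astype(str) + "/" + wide["replicate"].astype(str)
    )
    reps = sorted(wide["plotrep"].unique())
    genos = sorted(wide["genotype"].unique())
    if len(wide) != len(reps) * len(genos):
        return None
    c1 = np.full((len(reps), len(genos)), np.nan)
    c2 = np.full((len(reps), len(genos)), np.nan)
    ri = {v: i for i, v in enumerate(reps)}
    gi = {v: i for i, v in enumerate(genos)}
    c1[[ri[v] for v in wide["plotrep"]], [gi[v] for v in wide["genotype"]]] = wide[
        "value_1"
    ].to_numpy()
    c2[[ri[v] for v in wide["plotrep"]], [gi[v] for v in wide["genotype"]]] = wide[
        "value_2"
    ].to_numpy()
    if np.isnan(c1).any() or np.isnan(c2).any():
        return None
    return c1, c2


def fit_bivariate(
    data: pd.DataFrame,
    trait1: str,
    trait2: str,
    independent: bool = False,
    genotype_covariates: np.ndarray | None = None,
) -> BivariateFit:
    """Bivariate REML via log-Cholesky parameterization.

    Only plots with records for both traits enter and no location effect is
    fitted.  ``independent=True`` constrains the genotype and residual
    cross-covariances to zero (the model then decouples into two univariate
    fits).  ``genotype_covariates`` (plots x k) adds trait-specific fixed
    marker effects — used for explained-genetic-covariance calculations.
    """
    wide = _paired_plots(data, trait1, trait2)
    p_plots = len(wide)
    g_codes = pd.factorize(wide["genotype"])[0]
    r_codes = pd.factorize(
        wide["location"].astype(str) + "/" + wide["replicate"].astype(str)
    )[0]
    same_g = (g_codes[:, None] == g_codes[None, :]).astype(float)
    same_r = (r_codes[:, None] == r_codes[None, :]).astype(float)
    y = np.concatenate([wide["value_1"].to_numpy(), wide["value_2"].to_numpy()])
    ones = np.ones((p_plots, 1))
    if genotype_covariates is None:
        x = np.block(
            [[ones, np.zeros((p_plots, 1))], [np.zeros((p_plots, 1)), ones]]
        )
    else:
        c = np.atleast_2d(np.asarray(genotype_covariates, dtype=float))
        if c.shape[0] != p_plots:
            raise ValueError("genotype_covariates must have one row per paired plot")
        k = c.shape[1]
        zero = np.zeros((p_plots, 1 + k))
        x = np.block([[np.hstack([ones, c]), zero], [zero, np.hstack([ones, c])]])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")

    cubes = _paired_cubes(wide) if genotype_covariates is None else None
    if cubes is not None:
        nll, unpack, nll_natural = _bivariate_balanced_nll_factory(
            cubes[0], cubes[1], independent
        )
    else:
        nll, unpack, nll_natural = _bivariate_nll_factory(
            y, same_g, same_r, x, independent
        )

    # moment starts per trait
    def _mom(vals: np.ndarray) -> tuple[float, float]:
        df = pd.DataFrame({"g": g_codes, "y": vals})
        means = df.groupby("g")["y"].mean()
        within = df.groupby("g")["y"].var(ddof=1).dropna()
        msw = float(within.mean()) if len(within) else float(np.var(vals))
        r = p_plots / max(means.size, 1)
        gvar = max(float(means.var(ddof=1)) - msw / max(r, 1.0), 0.05 * float(np.var(vals)))
        return gvar, max(msw, 0.05 * float(np.var(vals)))

    g1, e1 = _mom(wide["value_1"].to_numpy())
    g2, e2 = _mom(wide["value_2"].to_numpy())
    d0 = 0.05 * (e1 + e2) / 2.0
    if independent:
        x0 = np.array(
            [0.5 * np.log(g1), 0.5 * np.log(g2), 0.5 * np.log(e1), 0.5 * np.log(e2),
             np.log(d0), np.log(d0)]
        )
    else:
        x0 = np.array(
            [0.5 * np.log(g1), 0.0, 0.5 * np.log(g2), 0.5 * np.log(e1), 0.0,
             0.5 * np.log(e2), np.log(d0), np.log(d0)]
        )
    # parameters are log/Cholesky scaled, so the surface is safe unbounded
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", options={"maxiter": 1000, "ftol": 1e-12}
    )
    if not res.success or not np.isfinite(res.fun):
        retry = optimize.minimize(
            nll, np.zeros_like(x0), method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-12},
        )
        if retry.fun < res.fun:
            res = retry
    if cubes is not None:  # cheap likelihood: high-precision simplex polish
        pol = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
        )
        if pol.fun <= res.fun:
            res = pol
    gcov, rcov, d = unpack(res.x)
    corr = float(gcov[0, 1] / np.sqrt(gcov[0, 0] * gcov[1, 1]))

    # SE of the genetic covariance from the curvature in the natural
    # (covariance-element) parameterization; the replicate variances are
    # held at their estimates (they are weakly coupled and often boundary)
    se_g12 = float("nan")
    if not independent:
        p0 = np.array(
            [gcov[0, 0], gcov[0, 1], gcov[1, 1], rcov[0, 0], rcov[0, 1],
             rcov[1, 1], d[0], d[1]]
        )
        free = [0, 1, 2, 3, 4, 5]
        scale = np.maximum(np.abs(p0), 1e-3)
        eps = 1e-3 * scale
        k = len(free)
        hess = np.zeros((k, k))

        def f_at(delta: dict[int, float]) -> float:
            q = p0.copy()
            for idx, dv in delta.items():
                q[idx] += dv
            return nll_natural(q)

        f0 = f_at({})
        try:
            for a in range(k):
                ia = free[a]
                hess[a, a] = (
                    f_at({ia: eps[ia]}) - 2 * f0 + f_at({ia: -eps[ia]})
                ) / eps[ia] ** 2
                for b in range(a + 1, k):
                    ib = free[b]
                    hess[a, b] = hess[b, a] = (
                        f_at({ia: eps[ia], ib: eps[ib]})
                        - f_at({ia: eps[ia], ib: -eps[ib]})
                        - f_at({ia: -eps[ia], ib: eps[ib]})
                        + f_at({ia: -eps[ia], ib: -eps[ib]})
                    ) / (4 * eps[ia] * eps[ib])
            cov_nat = np.linalg.pinv(hess)
            var = float(cov_nat[1, 1])
            if var <= 0 and hess[1, 1] > 0:
                var = 1.0 / hess[1, 1]  # profile curvature fallback
            se_g12 = float(np.sqrt(var)) if var > 0 else float("nan")
        except np.linalg.LinAlgError:
            pass
    return BivariateFit(
        traits=(trait1, trait2),
        genetic_cov=gcov,
        residual_cov=rcov,
        replicate_vars=d,
        genetic_correlation=corr,
        genetic_cov_se=se_g12,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_plots=p_plots,
        n_genotypes=int(wide["genotype"].nunique()),
    )
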