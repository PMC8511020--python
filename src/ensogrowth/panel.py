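"""Weighted fixed-effects panel estimation with two-way clustered errors.

The estimating equation regresses a child anthropometric outcome on the
tropical-year ENSO exposure, its interaction with the admin-level
positive-precipitation indicator, country-specific mother covariates,
region-specific month-of-interview effects and linear survey-year trends,
and country×urban fixed-effect cells:

    Y_ict = α + β_n·NINO_t + β_p·[NINO_t · I(PosPrecip_i)] + γ·X_ic
            + f(t_region) + FE_cr + ε_ict

Estimation is weighted least squares.  The fixed-effect cells can be
absorbed by weighted within-cell demeaning or included as explicit dummy
columns; the two routes give identical estimates (the demeaned regression
is the partialled-out form of the dummy regression).

Variances are cluster-robust in two dimensions — tropical year (a common
global ENSO shock) and subnational admin1 unit (serial/spatial correlation)
— combined by inclusion–exclusion:

    V = V_year + V_admin1 − V_year×admin1,

each term a CR sandwich over the corresponding grouping of score sums, with
a CR1-style small-sample multiplier G/(G−1)·(N−1)/(N−K) per dimension.
Confidence intervals use the normal ±1.96 critical value by default (a
t(G_min−1) option exists).

The module also provides the Frisch–Waugh–Lovell machinery: exact
partialled-out slopes (used for fast placebo permutation refits) and the
Epanechnikov local-polynomial residual-on-residual curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "ModelSpec",
    "Design",
    "EstimationResult",
    "build_design",
    "fit_fe_wls",
    "fit_model",
    "twoway_cluster_vcov",
    "partial_out",
    "fwl_residual_curve",
    "placebo_randomization",
    "subsample_effects",
    "CurveResult",
    "PlaceboResult",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification toggles for the estimating equation."""

    outcome: str = "waz"
    exposure: str = "nino"
    include_interaction: bool = True
    interaction_flag: str = "pos_precip"
    controls: tuple = ("mother_edu", "mother_age")
    control_by: str = "country"  # controls enter with country-specific slopes
    fe_cells: tuple = ("country", "urban")
    month_by_region: bool = True
    trend: str = "region_linear"  # 'region_linear' | 'decade_fe' | 'none'
    clusters: tuple = ("tropical_year", "admin1")
    weight_col: str | None = "w"
    lagged_exposures: int = 0  # expects columns nino_lag1, ...
    age_interaction: bool = False  # adds exposure × 1(age ≥ 24 months)


@dataclass
class Design:
    """Assembled regression inputs."""

    y: np.ndarray
    X: np.ndarray
    names: list
    w: np.ndarray
    fe_codes: np.ndarray
    n_cells: int
    cell_labels: list
    clusters: dict  # name -> integer codes
    spec: ModelSpec
    info: dict = field(default_factory=dict)


@dataclass
class EstimationResult:
    """Point estimates with two-way clustered inference."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    vcov: pd.DataFrame
    r2: float
    nobs: int
    k_params: int
    n_clusters: dict
    weighted_mean: float
    dropped: list
    crit: float
    meat_components: dict | None = None
    negative_variance_terms: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "p": self.pvalues,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def __getitem__(self, term: str) -> float:
        return float(self.params[term])


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Expand the model specification into a numeric design matrix.

    Exposure first, then (optionally) its interaction, country-specific
    control slopes, region-specific month indicators (first month of each
    region is the reference), and region trend columns.  Fixed-effect cells
    are returned as integer codes, not columns; the fit stage absorbs them
    or expands them to dummies.  Reference-category and column bookkeeping
    lands in ``design.info``.
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty estimation table")
    cols: list[np.ndarray] = []
    names: list[str] = []

    x = table[spec.exposure].to_numpy(dtype=float)
    cols.append(x)
    names.append(spec.exposure)
    if spec.include_interaction:
        flag = table[spec.interaction_flag].to_numpy(dtype=float)
        cols.append(x * flag)
        names.append(f"{spec.exposure}_x_{spec.interaction_flag}")
    for k in range(1, spec.lagged_exposures + 1):
        cols.append(table[f"{spec.exposure}_lag{k}"].to_numpy(dtype=float))
        names.append(f"{spec.exposure}_lag{k}")
    if spec.age_interaction:
        older = (table["child_age_months"].to_numpy() >= 24).astype(float)
        cols.append(x * older)
        names.append(f"{spec.exposure}_x_age24plus")
    exposure_block = list(names)

    by = table[spec.control_by].to_numpy()
    groups = np.unique(by)
    for ctrl in spec.controls:
        v = table[ctrl].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"control {ctrl!r} contains missing values")
        for g in groups:
            cols.append(v * (by == g))
            names.append(f"{ctrl}:{g}")

    months = table["int_month"].to_numpy()
    if spec.month_by_region:
        regions = table["region"].to_numpy()
        ref_months = {}
        for r in np.unique(regions):
            present = np.unique(months[regions == r])
            ref_months[r] = present[0]
            for m in present[1:]:
                cols.append(((regions == r) & (months == m)).astype(float))
                names.append(f"month{m}:{r}")
    else:
        present = np.unique(months)
        ref_months = {"all": present[0]}
        for m in present[1:]:
            cols.append((months == m).astype(float))
            names.append(f"month{m}")

    info = {"reference_months": ref_months, "exposure_block": exposure_block}
    if spec.trend == "region_linear":
        yr = table["int_year"].to_numpy(dtype=float)
        y0 = yr.min()
        regions = table["region"].to_numpy()
        for r in np.unique(regions):
            cols.append(np.where(regions == r, yr - y0, 0.0))
            names.append(f"trend:{r}")
        info["trend_origin"] = float(y0)
    elif spec.trend == "decade_fe":
        dec = (table["int_year"].to_numpy() // 10) * 10
        regions = table["region"].to_numpy()
        ref_dec = {}
        for r in np.unique(regions):
            present = np.unique(dec[regions == r])
            ref_dec[r] = int(present[0])
            for d in present[1:]:
                cols.append(((regions == r) & (dec == d)).astype(float))
                names.append(f"decade{d}:{r}")
        info["reference_decades"] = ref_dec
    elif spec.trend != "none":
        raise ValueError(f"unknown trend mode {spec.trend!r}")

    keys = table[list(spec.fe_cells)].astype(str).agg("|".join, axis=1)
    fe_codes, cell_labels = pd.factorize(keys, sort=True)

    y = table[spec.outcome].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError(f"outcome {spec.outcome!r} contains missing values")
    if spec.weight_col is None:
        w = np.ones(n)
    else:
        w = table[spec.weight_col].to_numpy(dtype=float)
        if (w <= 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be strictly positive and finite")

    clusters = {}
    for cname in spec.clusters:
        codes, uniq = pd.factorize(table[cname], sort=True)
        if (codes < 0).any():
            raise ValueError(f"cluster variable {cname!r} has missing values")
        if len(uniq) < 2:
            raise ValueError(f"cluster dimension {cname!r} has a single cluster")
        clusters[cname] = codes

    X = np.column_stack(cols)
    return Design(
        y=y,
        X=X,
        names=names,
        w=w,
        fe_codes=fe_codes,
        n_cells=len(cell_labels),
        cell_labels=list(cell_labels),
        clusters=clusters,
        spec=spec,
        info=info,
    )


def _group_weighted_demean(M: np.ndarray, codes: np.ndarray, w: np.ndarray, n_groups: int):
    """Subtract the weighted within-group mean from each column of ``M``."""
    if M.ndim == 1:
        M = M[:, None]
        squeeze = True
    else:
        squeeze = False
    sw = np.bincount(codes, weights=w, minlength=n_groups)
    sums = np.zeros((n_groups, M.shape[1]))
    np.add.at(sums, codes, w[:, None] * M)
    means = sums / sw[:, None]
    out = M - means[codes]
    return out[:, 0] if squeeze else out


def _pivoted_qr_solve(Xw: np.ndarray, yw: np.ndarray, names: list, rcond: float = 1e-10):
    """Rank-revealing WLS solve; returns (beta_full, kept, dropped, XtX_inv).

    Columns that are numerically collinear are pruned (coefficient 0, noted
    in ``dropped``); ``XtX_inv`` covers the retained columns.
    """
    Q, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = (d[0] if d.size else 0.0) * max(Xw.shape) * rcond
    rank = int(np.sum(d > tol)) if d.size else 0
    if rank == 0:
        raise ValueError("design matrix has rank zero")
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in np.sort(piv[rank:])]
    Xk = Xw[:, keep]
    Q2, R2 = np.linalg.qr(Xk)
    beta_k = linalg.solve_triangular(R2, Q2.T @ yw)
    Rinv = linalg.solve_triangular(R2, np.eye(R2.shape[0]))
    XtX_inv = Rinv @ Rinv.T
    beta = np.zeros(Xw.shape[1])
    beta[keep] = beta_k
    return beta, keep, dropped, XtX_inv


def twoway_cluster_vcov(
    X: np.ndarray,
    resid: np.ndarray,
    w: np.ndarray,
    bread: np.ndarray,
    clusters: dict,
    k_total: int,
    small_sample: bool = True,
    require_positive: list | None = None,
    spectral_fix: bool = False,
):
    """Two-way cluster-robust covariance by inclusion–exclusion.

    ``X`` are the (possibly demeaned) retained regressor columns, ``bread``
    is (X'WX)^{-1}, ``clusters`` maps the two dimension names to integer
    codes, and ``k_total`` counts every estimated parameter including
    absorbed fixed effects.  Returns ``(V, components, counts)`` where
    components holds the three meat matrices keyed by dimension name and
    ``"intersection"``.

    The inclusion–exclusion difference is not guaranteed positive
    semi-definite; sparse nuisance dummies can come out with non-positive
    variance.  Positions listed in ``require_positive`` (default: all)
    raise on a non-positive diagonal; other offending positions are left
    for the caller to flag.
    """
    if len(clusters) != 2:
        raise ValueError("exactly two cluster dimensions are required")
    n = X.shape[0]
    S = X * (w * resid)[:, None]

    def meat(codes):
        G = int(codes.max()) + 1
        U = np.zeros((G, X.shape[1]))
        np.add.at(U, codes, S)
        return U.T @ U, G

    (name1, codes1), (name2, codes2) = clusters.items()
    m1, g1 = meat(codes1)
    m2, g2 = meat(codes2)
    inter = codes1.astype(np.int64) * (int(codes2.max()) + 1) + codes2
    inter = pd.factorize(inter)[0]
    m12, g12 = meat(inter)

    def corr(G):
        if not small_sample:
            return 1.0
        return (G / (G - 1)) * ((n - 1) / (n - k_total))

    M = corr(g1) * m1 + corr(g2) * m2 - corr(g12) * m12
    if spectral_fix:
        # the inclusion–exclusion difference can be indefinite; project onto
        # the PSD cone by zeroing negative eigenvalues (standard practice in
        # multi-way cluster implementations)
        M = 0.5 * (M + M.T)
        lam, U = np.linalg.eigh(M)
        M = (U * np.maximum(lam, 0.0)) @ U.T
    V = bread @ M @ bread
    diag = np.diag(V)
    must = range(len(diag)) if require_positive is None else require_positive
    bad_required = [i for i in must if diag[i] <= 0]
    if bad_required:
        raise ValueError(
            "two-way combined covariance has non-positive variance for "
            f"required coefficients at positions {bad_required}; the "
            "inclusion–exclusion combination failed on this sample"
        )
    components = {name1: m1, name2: m2, "intersection": m12}
    counts = {name1: g1, name2: g2, "intersection": g12}
    return V, components, counts


def fit_fe_wls(
    design: Design,
    absorb: bool = True,
    small_sample: bool = True,
    crit: str = "normal",
    keep_meat: bool = False,
    spectral_fix: bool = False,
) -> EstimationResult:
    """Weighted least squares with fixed-effect cells and two-way clustering.

    ``absorb=True`` demeans outcome and regressors within fixed-effect cells
    (weighted) — numerically identical to ``absorb=False``, which appends
    one dummy column per cell (no global intercept).  R² and the weighted
    outcome mean refer to the full model including the fixed effects.
    """
    y, X, w = design.y, design.X, design.w
    n = len(y)
    names = list(design.names)
    if absorb:
        Xd = _group_weighted_demean(X, design.fe_codes, w, design.n_cells)
        yd = _group_weighted_demean(y, design.fe_codes, w, design.n_cells)
        k_absorbed = design.n_cells
    else:
        dummies = np.zeros((n, design.n_cells))
        dummies[np.arange(n), design.fe_codes] = 1.0
        Xd = np.column_stack([X, dummies])
        yd = y
        names = names + [f"fe:{c}" for c in design.cell_labels]
        k_absorbed = 0

    sw = np.sqrt(w / w.mean())
    Xw = Xd * sw[:, None]
    yw = yd * sw
    beta, keep, dropped, XtX_inv = _pivoted_qr_solve(Xw, yw, names)
    # rescale bread to the unscaled-weight metric: XtX_inv above is
    # (X' W̃ X)^{-1} with W̃ = W/mean(w); scores below use raw w, so convert.
    bread = XtX_inv / w.mean()

    resid = yd - Xd @ beta
    k_total = len(keep) + k_absorbed
    if n <= k_total:
        raise ValueError(f"n = {n} observations but {k_total} parameters")

    kept_names = [names[j] for j in keep]
    required = [
        i
        for i, nm in enumerate(kept_names)
        if nm in design.info.get("exposure_block", [])
    ]
    V, components, counts = twoway_cluster_vcov(
        Xd[:, keep],
        resid,
        w,
        bread,
        design.clusters,
        k_total,
        small_sample,
        require_positive=required,
        spectral_fix=spectral_fix,
    )

    params = pd.Series(beta[keep], index=kept_names)
    diag = np.diag(V).copy()
    negative_terms = [kept_names[i] for i in np.flatnonzero(diag <= 0)]
    diag[diag <= 0] = np.nan  # nuisance terms only; exposure block is checked
    se = pd.Series(np.sqrt(diag), index=kept_names)
    if crit == "normal":
        cv = 1.959963984540054
        pvals = 2 * stats.norm.sf(np.abs(params / se))
    elif crit == "t":
        g_min = min(counts[c] for c in design.spec.clusters)
        cv = float(stats.t.ppf(0.975, g_min - 1))
        pvals = 2 * stats.t.sf(np.abs(params / se), g_min - 1)
    else:
        raise ValueError("crit must be 'normal' or 't'")

    wmean = float(np.average(y, weights=w))
    tss = float(np.sum(w * (y - wmean) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    return EstimationResult(
        params=params,
        se=se,
        pvalues=pd.Series(np.asarray(pvals), index=kept_names),
        ci_lower=params - cv * se,
        ci_upper=params + cv * se,
        vcov=pd.DataFrame(V, index=kept_names, columns=kept_names),
        r2=r2,
        nobs=n,
        k_params=k_total,
        n_clusters=dict(counts),
        weighted_mean=wmean,
        dropped=dropped,
        crit=cv,
        meat_components=components if keep_meat else None,
        negative_variance_terms=negative_terms,
    )


def fit_model(table: pd.DataFrame, spec: ModelSpec, **fit_kwargs) -> EstimationResult:
    """Convenience: build the design and fit in one call."""
    return fit_fe_wls(build_design(table, spec), **fit_kwargs)


# ---------------------------------------------------------------------------
# Frisch–Waugh–Lovell machinery
# ---------------------------------------------------------------------------


def _residualizer(design: Design, target_names: list):
    """Split the design into target and control blocks, both FE-demeaned and
    weight-scaled, and return (targets_resid, y_resid, resid_fn, sw)."""
    names = design.names
    t_idx = [names.index(t) for t in target_names]
    c_idx = [j for j in range(len(names)) if j not in t_idx]
    Xd = _group_weighted_demean(design.X, design.fe_codes, design.w, design.n_cells)
    yd = _group_weighted_demean(design.y, design.fe_codes, design.w, design.n_cells)
    sw = np.sqrt(design.w / design.w.mean())
    Cw = Xd[:, c_idx] * sw[:, None]
    Q, R, piv = linalg.qr(Cw, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = (d[0] if d.size else 0.0) * max(Cw.shape) * 1e-10
    rank = int(np.sum(d > tol))
    Qk = Q[:, :rank]

    def resid(v_w: np.ndarray) -> np.ndarray:
        return v_w - Qk @ (Qk.T @ v_w)

    Tw = Xd[:, t_idx] * sw[:, None]
    return resid(Tw), resid(yd * sw), resid, sw


def partial_out(table: pd.DataFrame, spec: ModelSpec, target: str | None = None):
    """Exact FWL slope of the target regressor.

    Residualizes the outcome and the full exposure block on everything else
    (controls, month effects, trends, fixed effects) under the estimation
    weights, then regresses residual on residual.  The returned coefficient
    for ``target`` equals the joint-fit estimate to machine precision.

    Returns ``(coef, x_resid, y_resid)`` where the residuals are on the
    sqrt-weight scale (a plain OLS of y_resid on x_resid reproduces the
    weighted slope).
    """
    design = build_design(table, spec)
    target = target or spec.exposure
    block = [design.names[0]]
    if spec.include_interaction:
        block.append(design.names[1])
    Tres, yres, _, _ = _residualizer(design, block)
    G = Tres.T @ Tres
    coefs = np.linalg.solve(G, Tres.T @ yres)
    j = block.index(target)
    return float(coefs[j]), Tres[:, j], yres


@dataclass
class CurveResult:
    """Local-polynomial fit of outcome residuals on exposure residuals."""

    grid: np.ndarray
    fit: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    slope: float  # global weighted residual-on-residual slope
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "fit": self.fit,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def epanechnikov(u: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel 0.75(1 − u²) on |u| < 1, zero outside."""
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u**2), 0.0)


def local_polynomial(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    degree: int = 1,
):
    """Kernel-weighted local polynomial fit with pointwise standard errors.

    At each grid point the polynomial is fit by WLS with weights
    ``w · K((x − x0)/h)``; the reported value and variance are those of the
    local intercept.  Grid points with too little kernel mass return NaN.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    fit = np.full(len(grid), np.nan)
    se = np.full(len(grid), np.nan)
    for i, x0 in enumerate(grid):
        u = (x - x0) / bandwidth
        k = epanechnikov(u)
        mask = k > 0
        if mask.sum() < degree + 2:
            continue
        wl = (k * w)[mask]
        Z = np.vander(x[mask] - x0, degree + 1, increasing=True)
        WZ = Z * wl[:, None]
        G = Z.T @ WZ
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            continue
        b = Ginv @ (WZ.T @ y[mask])
        e = y[mask] - Z @ b
        sigma2 = float(np.sum(wl * e**2) / np.sum(wl))
        mid = Z.T @ (Z * (wl**2)[:, None])
        Vb = Ginv @ mid @ Ginv * sigma2
        fit[i] = b[0]
        se[i] = np.sqrt(max(Vb[0, 0], 0.0))
    return fit, se


def fwl_residual_curve(
    table: pd.DataFrame,
    spec: ModelSpec,
    bandwidth: float = 0.7,
    degree: int = 1,
    n_grid: int = 50,
    n_bins: int = 30,
) -> dict:
    """Residual-on-residual curves, separately by precipitation regime.

    For each subsample (negative/neutral vs positive precipitation
    teleconnection) the outcome and the exposure are residualized on the
    controls-only model (no exposure terms), then a local polynomial with an
    Epanechnikov kernel of the given bandwidth — in exposure-residual units
    — is fit with pointwise 95% bands.  Histogram counts of the exposure
    residuals accompany each curve.  Keys: ``"neg_neutral"``, ``"positive"``.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    out = {}
    flag = table[spec.interaction_flag].astype(bool)
    sub_spec = replace(spec, include_interaction=False)
    for label, mask in (("neg_neutral", ~flag), ("positive", flag)):
        sub = table.loc[mask]
        if len(sub) == 0:
            continue
        design = build_design(sub, sub_spec)
        Tres, yres, _, sw = _residualizer(design, [design.names[0]])
        # back to unscaled residual units; observation weights enter the
        # kernel fit directly, so the bandwidth is in exposure-residual °C
        xr = Tres[:, 0] / sw
        yr = yres / sw
        slope = float((Tres[:, 0] @ yres) / (Tres[:, 0] @ Tres[:, 0]))
        grid = np.linspace(xr.min(), xr.max(), n_grid)
        fit, se = local_polynomial(xr, yr, design.w, grid, bandwidth, degree)
        counts, edges = np.histogram(xr, bins=n_bins)
        out[label] = CurveResult(
            grid=grid,
            fit=fit,
            se=se,
            ci_lower=fit - 1.96 * se,
            ci_upper=fit + 1.96 * se,
            hist_edges=edges,
            hist_counts=counts,
            slope=slope,
            n=len(sub),
        )
    return out


@dataclass
class PlaceboResult:
    observed: float
    draws: np.ndarray
    p_value: float


def placebo_randomization(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int = 200,
    seed: int = 0,
    include_identity: bool = False,
) -> PlaceboResult:
    """Permutation test shuffling exposure values across tropical years.

    Within-year structure is untouched: each tropical year's exposure value
    is reassigned wholesale to another year.  The model is re-fit per
    permutation via the exact FWL shortcut (residualize the permuted
    exposure block on the fixed controls), and the two-sided rank-based
    p-value of the observed β_n is returned:
    p = (1 + #{|β*| ≥ |β̂|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    years, year_codes = np.unique(table["tropical_year"].to_numpy(), return_inverse=True)
    if len(years) < 5:
        raise ValueError("placebo needs at least 5 distinct tropical years")
    design = build_design(table, spec)
    block = [design.names[0]] + ([design.names[1]] if spec.include_interaction else [])
    # residualize y and the control complement once
    names = design.names
    t_idx = [names.index(b) for b in block]
    Xd = _group_weighted_demean(design.X, design.fe_codes, design.w, design.n_cells)
    yd = _group_weighted_demean(design.y, design.fe_codes, design.w, design.n_cells)
    sw = np.sqrt(design.w / design.w.mean())
    c_idx = [j for j in range(len(names)) if j not in t_idx]
    Cw = Xd[:, c_idx] * sw[:, None]
    Q, R, piv = linalg.qr(Cw, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    rank = int(np.sum(d > (d[0] if d.size else 0) * max(Cw.shape) * 1e-10))
    Qk = Q[:, :rank]

    def resid(vw):
        return vw - Qk @ (Qk.T @ vw)

    yres = resid(yd * sw)
    pos = (
        table[spec.interaction_flag].to_numpy(dtype=float)
        if spec.include_interaction
        else None
    )
    value_by_year = (
        table.groupby("tropical_year")[spec.exposure].first().loc[years].to_numpy()
    )

    # Any permuted exposure column is a linear combination of per-year
    # indicator columns, and demeaning/projection are linear maps, so
    # residualize the indicator basis once and each permutation refit
    # reduces to quadratic forms in the per-year values.
    n_years = len(years)
    I_y = np.zeros((len(table), n_years))
    I_y[np.arange(len(table)), year_codes] = 1.0
    blocks = [I_y] if pos is None else [I_y, I_y * pos[:, None]]
    basis = []
    for Bk in blocks:
        Bd = _group_weighted_demean(Bk, design.fe_codes, design.w, design.n_cells)
        basis.append(resid(Bd * sw[:, None]))
    nb = len(basis)
    G = np.empty((nb, nb, n_years, n_years))
    b = np.empty((nb, n_years))
    for i in range(nb):
        b[i] = basis[i].T @ yres
        for j in range(nb):
            G[i, j] = basis[i].T @ basis[j]

    def beta_for(v: np.ndarray) -> float:
        EtE = np.array([[v @ G[i, j] @ v for j in range(nb)] for i in range(nb)])
        Ety = np.array([b[i] @ v for i in range(nb)])
        coefs = np.linalg.solve(EtE, Ety)
        return float(coefs[0])

    observed = beta_for(value_by_year)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for i in range(n_perm):
        if include_identity and i == 0:
            perm = np.arange(len(years))
        else:
            perm = rng.permutation(len(years))
        draws[i] = beta_for(value_by_year[perm])
    p = (1.0 + np.sum(np.abs(draws) >= np.abs(observed))) / (n_perm + 1.0)
    return PlaceboResult(observed=observed, draws=draws, p_value=p)


def subsample_effects(
    table: pd.DataFrame,
    spec: ModelSpec,
    by: str = "decade",
    restrict_nonpositive: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Re-fit the model within decades or regions.

    Follows the heterogeneity-analysis convention: the sample is restricted
    to locations with non-positive precipitation teleconnection and the
    interaction term is dropped (it is identically zero there).  Returns a
    frame with one row per stratum: estimate, SE, CI, N.
    """
    if by not in ("decade", "region"):
        raise ValueError("by must be 'decade' or 'region'")
    sub = table.loc[~table[spec.interaction_flag].astype(bool)].copy()
    if sub.empty:
        raise ValueError("no observations outside positive-precip areas")
    sub_spec = replace(spec, include_interaction=False)
    if by == "decade":
        strata = (sub["tropical_year"].to_numpy() // 10) * 10
    else:
        strata = sub["region"].to_numpy()
    fit_kwargs.setdefault("spectral_fix", True)  # small strata need the PSD fix
    rows = []
    for s in np.unique(strata):
        part = sub.loc[strata == s]
        if part[spec.exposure].nunique() < 2:
            raise ValueError(f"stratum {s!r} has no exposure variation")
        res = fit_model(part, sub_spec, **fit_kwargs)
        rows.append(
            {
                "stratum": s,
                "estimate": res.params[spec.exposure],
                "se": res.se[spec.exposure],
                "ci_lower": res.ci_lower[spec.exposure],
                "ci_upper": res.ci_upper[spec.exposure],
                "n": res.nobs,
            }
        )
    return pd.DataFrame(rows)
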