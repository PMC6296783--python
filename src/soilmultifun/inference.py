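"""Statistical layer: split-plot Type III ANOVA, Pearson correlations,
recursive path models, and top-performing-monoculture summaries.

The ANOVA reproduces the general-linear-model structure of a split-plot
biodiversity experiment: CO2 is applied at the ring (whole-plot) level,
so its F statistic is formed against the mean square of ring nested
within CO2, while N, the log-linear richness term, and all interactions
are tested against the plot-level residual. Type III sums of squares are
computed with sum-to-zero coding by comparing the full model with the
model lacking each term's columns.

The path model is a recursive system of observed variables fitted to the
sample covariance matrix by maximum likelihood; for recursive models
with uncorrelated errors the equation-wise least-squares solution is the
ML optimum, which is optionally polished (and, in the tests,
cross-checked) against direct minimisation of the covariance
discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    AliasingError,
    DataError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "ModelSpec",
    "AnovaTable",
    "type3_anova",
    "pearson_matrix",
    "PathFit",
    "DEFAULT_PATHS",
    "fit_path_model",
    "compare_paths",
    "top_monoculture",
]

#: Fig-style default path set: richness acts on multifunctionality only
#: through functional dispersion and the evenness of functions.
DEFAULT_PATHS = (
    ("ln_psr", "fdis"),
    ("ln_psr", "evenness_func"),
    ("fdis", "avg_multifunctionality"),
    ("evenness_func", "avg_multifunctionality"),
)


@dataclass
class ModelSpec:
    """Configuration of the split-plot GLM.

    ``richness_col`` may be swapped for a realized-richness column; with
    ``log_richness`` the regressor is its natural log (plots with
    non-positive richness are dropped). ``exclude_monocultures`` refits
    on sown richness levels > 1 only.
    """

    response: str
    richness_col: str = "sown_richness"
    log_richness: bool = True
    exclude_monocultures: bool = False
    satterthwaite: bool = False


@dataclass
class AnovaTable:
    """Type III ANOVA with split-plot error strata.

    ``table`` has one row per term (SS, df, MS, F, p, denominator
    stratum and df). ``model_df_caption``/``residual_df_caption`` follow
    the bookkeeping that counts the 6-ring block as 6 model df (so
    residual df = n - 1 - 13 for the full model); per-term dfs in
    ``table`` are the conventional nested ones (ring(CO2) = 4).
    """

    table: pd.DataFrame
    n: int
    model_df: int
    residual_df: int
    model_df_caption: int
    residual_df_caption: int
    residual_ss: float


def _design_columns(data: pd.DataFrame, spec: ModelSpec):
    """Sum-to-zero coded columns per term for the full split-plot model."""
    co2 = np.where(data["co2"].astype(str) == "elevated", 1.0, -1.0)
    nn = np.where(data["n"].astype(str) == "enriched", 1.0, -1.0)
    r = data[spec.richness_col].to_numpy(dtype=float)
    x = np.log(r) if spec.log_richness else r
    # centring the covariate makes the factor main effects orthogonal to
    # the factor x richness interactions in balanced designs, so their
    # Type III tests refer to the average richness rather than richness 1
    x = x - x.mean()

    ring_cols = []
    for level in ("ambient", "elevated"):
        rings = sorted(data.loc[data["co2"].astype(str) == level, "ring"].unique())
        for rid in rings[:-1]:
            col = np.zeros(len(data))
            col[(data["ring"] == rid).to_numpy()] = 1.0
            col[(data["ring"] == rings[-1]).to_numpy()] = -1.0
            ring_cols.append(col)
    terms = {
        "co2": np.column_stack([co2]),
        "ring(co2)": np.column_stack(ring_cols),
        "n": np.column_stack([nn]),
        "psr": np.column_stack([x]),
        "co2:n": np.column_stack([co2 * nn]),
        "co2:psr": np.column_stack([co2 * x]),
        "n:psr": np.column_stack([nn * x]),
        "co2:n:psr": np.column_stack([co2 * nn * x]),
    }
    return terms


def _rss(xmat: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(xmat, y, rcond=None)
    fitted = xmat @ beta
    return float(np.sum((y - fitted) ** 2))


def type3_anova(data: pd.DataFrame, spec: ModelSpec) -> AnovaTable:
    """Split-plot Type III ANOVA of one response.

    ``data`` needs columns ``co2``, ``n``, ``ring``, the richness column
    and the response; incomplete rows for the response are dropped.
    """
    d = data.dropna(subset=[spec.response]).copy()
    if spec.exclude_monocultures:
        d = d[d["sown_richness"] > 1]
    r = d[spec.richness_col].to_numpy(dtype=float)
    if spec.log_richness and np.any(r <= 0):
        d = d[d[spec.richness_col] > 0]
    if d[spec.richness_col].nunique() < 2:
        raise DegenerateDesignError("need >= 2 distinct richness levels")
    y = d[spec.response].to_numpy(dtype=float)
    n = len(d)

    terms = _design_columns(d, spec)
    intercept = np.ones((n, 1))
    full = np.hstack([intercept] + [terms[t] for t in terms])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        raise AliasingError(
            "rank-deficient design: confounding among terms "
            + ", ".join(terms)
        )
    rss_full = _rss(full, y)
    df_resid = n - rank
    if df_resid <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid

    rows = []
    ss = {}
    for name in terms:
        reduced = np.hstack(
            [intercept] + [terms[t] for t in terms if t != name]
        )
        ss[name] = _rss(reduced, y) - rss_full
    df_ring = terms["ring(co2)"].shape[1]
    ms_ring = ss["ring(co2)"] / df_ring

    for name in terms:
        df_t = terms[name].shape[1]
        ms_t = ss[name] / df_t
        if name == "co2":
            if spec.satterthwaite:
                denom_ms, denom_df, stratum = _satterthwaite_denominator(
                    full, terms, d, ss, df_ring, ms_resid, df_resid, y
                )
            else:
                denom_ms, denom_df, stratum = ms_ring, df_ring, "ring(co2)"
        else:
            denom_ms, denom_df, stratum = ms_resid, df_resid, "residual"
        f = ms_t / denom_ms if denom_ms > 0 else np.nan
        p = float(stats.f.sf(f, df_t, denom_df)) if np.isfinite(f) else np.nan
        rows.append((name, ss[name], df_t, ms_t, f, p, stratum, denom_df))

    table = pd.DataFrame(
        rows, columns=["term", "SS", "df", "MS", "F", "p", "denominator", "den_df"]
    ).set_index("term")
    model_df = rank - 1
    caption_model_df = model_df + 2  # block counted as 6 df instead of 4
    return AnovaTable(
        table=table,
        n=n,
        model_df=model_df,
        residual_df=df_resid,
        model_df_caption=caption_model_df,
        residual_df_caption=n - 1 - caption_model_df,
        residual_ss=rss_full,
    )


def _satterthwaite_denominator(full, terms, d, ss, df_ring, ms_resid, df_resid, y):
    """Denominator for the whole-plot (CO2) test in unbalanced designs.

    Matches the expected-mean-square coefficient of the ring variance
    component in the CO2 quadratic form with a linear combination of the
    ring and residual mean squares, then applies the Satterthwaite df
    approximation to that combination. The coefficients come from
    tr(Z'AZ) where A is each Type III quadratic form and Z the ring
    incidence matrix; in a balanced design this reduces exactly to the
    classical MS[ring(CO2)] denominator.
    """
    n = full.shape[0]
    rings = sorted(d["ring"].unique())
    z = np.zeros((n, len(rings)))
    for j, rid in enumerate(rings):
        z[(d["ring"] == rid).to_numpy(), j] = 1.0

    def projector(xmat):
        q, _ = np.linalg.qr(xmat)
        return q @ q.T

    p_full = projector(full)

    def quad_form(term):
        cols = [t for t in terms if t != term]
        reduced = np.hstack([np.ones((n, 1))] + [terms[t] for t in cols])
        return p_full - projector(reduced)

    a_co2 = quad_form("co2")
    a_ring = quad_form("ring(co2)")
    k0 = np.trace(z.T @ a_co2 @ z) / 1.0
    k1 = np.trace(z.T @ a_ring @ z) / df_ring
    ms_ring = ss["ring(co2)"] / df_ring
    c1 = k0 / k1
    c2 = 1.0 - c1
    denom_ms = c1 * ms_ring + c2 * ms_resid
    denom_df = denom_ms**2 / (
        (c1 * ms_ring) ** 2 / df_ring + (c2 * ms_resid) ** 2 / df_resid
    )
    return denom_ms, float(denom_df), "satterthwaite"


def pearson_matrix(functions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among function columns.

    Pairwise-complete observations; returns a long table with columns
    ``var1``, ``var2``, ``r``, ``r2``, ``p``, ``n``. Zero-variance
    columns yield NaN (undefined-correlation marker).
    """
    rows = []
    for a, b in combinations(functions.columns, 2):
        pair = functions[[a, b]].dropna()
        if len(pair) < 3:
            raise InsufficientDataError(f"fewer than 3 complete pairs for {a}/{b}")
        xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            rows.append((a, b, np.nan, np.nan, np.nan, len(pair)))
            continue
        r, p = stats.pearsonr(xa, xb)
        rows.append((a, b, float(r), float(r) ** 2, float(p), len(pair)))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "r2", "p", "n"])


@dataclass
class PathFit:
    """A fitted recursive path model.

    ``coefficients``/``standardized`` map (source, target) to raw and
    standardized path coefficients; ``chi2`` is (n-1) times the ML
    discrepancy against the saturated model, with ``df`` = number of
    non-redundant covariance moments minus free parameters, and
    ``aic = chi2 + 2 * n_params``.
    """

    variables: list[str]
    paths: list[tuple[str, str]]
    coefficients: dict[tuple[str, str], float]
    standardized: dict[tuple[str, str], float]
    residual_variances: dict[str, float]
    r2: dict[str, float]
    chi2: float
    df: int
    p: float
    aic: float
    n: int
    n_params: int
    implied_cov: pd.DataFrame


def _implied_cov(variables, paths, coeffs, psi, exog_cov):
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    b = np.zeros((p, p))
    for (src, dst), val in coeffs.items():
        b[idx[dst], idx[src]] = val
    psi_mat = np.zeros((p, p))
    for v, val in psi.items():
        psi_mat[idx[v], idx[v]] = val
    for (v1, v2), val in exog_cov.items():
        psi_mat[idx[v1], idx[v2]] = val
        psi_mat[idx[v2], idx[v1]] = val
    inv = np.linalg.inv(np.eye(p) - b)
    return inv @ psi_mat @ inv.T


def fit_path_model(
    data: pd.DataFrame,
    paths=DEFAULT_PATHS,
    polish: bool = True,
) -> PathFit:
    """Maximum-likelihood fit of a recursive path model.

    Parameters
    ----------
    data
        Complete-case rows; every variable named in ``paths`` must be a
        column. Unreferenced columns are ignored.
    paths
        Directed (source, target) pairs. Variables never appearing as a
        target are exogenous; their (co)variances are free parameters.
        Residuals are assumed mutually uncorrelated.
    polish
        Refine the closed-form (equation-wise) solution by numerically
        minimising the ML discrepancy; the refinement is a no-op up to
        tolerance for recursive models and serves as a safeguard.
    """
    paths = [tuple(p) for p in paths]
    variables = []
    for src, dst in paths:
        for v in (src, dst):
            if v not in variables:
                variables.append(v)
    d = data[variables].dropna()
    nobs = len(d)
    targets = {dst for _, dst in paths}
    exog = [v for v in variables if v not in targets]
    n_exog_moments = len(exog) * (len(exog) + 1) // 2
    n_params = len(paths) + len(targets) + n_exog_moments
    if nobs <= n_params:
        raise InsufficientDataError(f"{nobs} rows for {n_params} parameters")
    s = pd.DataFrame(
        np.cov(d.to_numpy().T, ddof=1), index=variables, columns=variables
    )
    if np.linalg.eigvalsh(s.to_numpy()).min() <= 0:
        raise DataError("sample covariance matrix is not positive definite")

    # equation-wise GLS on S: the ML solution for recursive systems
    coeffs: dict[tuple[str, str], float] = {}
    psi: dict[str, float] = {}
    for v in variables:
        parents = [src for src, dst in paths if dst == v]
        if not parents:
            continue
        spp = s.loc[parents, parents].to_numpy()
        spv = s.loc[parents, v].to_numpy()
        beta = np.linalg.solve(spp, spv)
        for src, bval in zip(parents, beta):
            coeffs[(src, v)] = float(bval)
        psi[v] = float(s.loc[v, v] - spv @ beta)
    exog_cov = {
        (a, b): float(s.loc[a, b]) for i, a in enumerate(exog) for b in exog[i:]
    }

    nmoments = len(variables) * (len(variables) + 1) // 2
    dof = nmoments - n_params
    smat = s.to_numpy()
    _, logdet_s = np.linalg.slogdet(smat)

    def discrepancy(theta):
        c = dict(zip(paths, theta[: len(paths)]))
        ps = dict(zip(sorted(targets, key=variables.index), theta[len(paths):len(paths) + len(targets)]))
        ex = dict(zip(sorted(exog_cov), theta[len(paths) + len(targets):]))
        sigma = _implied_cov(variables, paths, c, ps, ex)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return (
            logdet - logdet_s + np.trace(smat @ np.linalg.inv(sigma)) - len(variables)
        )

    target_order = sorted(targets, key=variables.index)
    theta0 = np.concatenate(
        [
            [coeffs[p] for p in paths],
            [psi[v] for v in target_order],
            [exog_cov[k] for k in sorted(exog_cov)],
        ]
    )
    if polish:
        res = optimize.minimize(discrepancy, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if res.fun < discrepancy(theta0):
            theta0 = res.x
            coeffs = dict(zip(paths, theta0[: len(paths)]))
            psi = dict(zip(target_order, theta0[len(paths):len(paths) + len(targets)]))
            exog_cov = dict(zip(sorted(exog_cov), theta0[len(paths) + len(targets):]))

    f_ml = float(discrepancy(theta0))
    chi2 = max((nobs - 1) * f_ml, 0.0)
    p_value = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    sds = {v: float(np.sqrt(s.loc[v, v])) for v in variables}
    standardized = {
        (src, dst): val * sds[src] / sds[dst] for (src, dst), val in coeffs.items()
    }
    r2 = {v: 1.0 - psi[v] / float(s.loc[v, v]) for v in target_order}
    sigma = _implied_cov(variables, paths, coeffs, psi, exog_cov)
    return PathFit(
        variables=variables,
        paths=paths,
        coefficients=coeffs,
        standardized=standardized,
        residual_variances=psi,
        r2=r2,
        chi2=chi2,
        df=dof,
        p=p_value,
        aic=chi2 + 2 * n_params,
        n=nobs,
        n_params=n_params,
        implied_cov=pd.DataFrame(sigma, index=variables, columns=variables),
    )


def compare_paths(data: pd.DataFrame, base_paths, candidate_path) -> float:
    """AIC difference (candidate model minus base) from adding one path.

    Positive values mean the extra path is not supported.
    """
    candidate_path = tuple(candidate_path)
    if candidate_path in {tuple(p) for p in base_paths}:
        raise InvalidInputError(f"path {candidate_path} already in base model")
    base = fit_path_model(data, base_paths)
    extended = fit_path_model(data, list(base_paths) + [candidate_path])
    return extended.aic - base.aic


def top_monoculture(
    functions: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Best-performing monoculture species per function and CO2 x N cell.

    Means are taken over a species' monoculture plots within the cell;
    ties are broken lexicographically and flagged. Cells with no
    monoculture yield a missing-species row.
    """
    mono = design[design["sown_richness"] == 1].copy()
    mono["species"] = mono["sown_species"].map(lambda s: s[0])
    merged = mono.join(functions, how="inner")
    rows = []
    cells = [(c, n) for c in sorted(design["co2"].unique())
             for n in sorted(design["n"].unique())]
    for func in functions.columns:
        for co2, n_level in cells:
            cell = merged[(merged["co2"] == co2) & (merged["n"] == n_level)]
            cell = cell.dropna(subset=[func])
            if cell.empty:
                rows.append((func, co2, n_level, None, np.nan, False))
                continue
            means = cell.groupby("species")[func].mean().sort_index()
            best = means.max()
            winners = means[means == best].index
            rows.append(
                (func, co2, n_level, winners[0], float(best), len(winners) > 1)
            )
    return pd.DataFrame(
        rows, columns=["function", "co2", "n", "species", "mean", "tie"]
    )
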