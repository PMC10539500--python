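"""Random-intercept linear mixed models for imaging-genomic association.

Biopsies from the same patient are correlated, so every association between
an imaging feature (rCBV, nK2, MD, T2W, ...) and a genotype or subtype
signature is modeled as

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

with patient identity i as a categorical random intercept. Estimation is
REML, profiled over the variance ratio lambda = sigma_b^2 / sigma_e^2: for a
given lambda the fixed effects have a closed-form GLS solution (the
random-intercept structure makes V block diagonal and invertible per patient
via a rank-one update), and the 1-D profile is optimized to tight tolerance.

On top of the fit: sequential (Type-I style) percent-variance decomposition
of the fixed terms, estimated marginal means with Tukey-adjusted pairwise
contrasts (Satterthwaite degrees of freedom, residual-df fallback), a
correlation/LMM screen of imaging features against continuous subtype
signatures with z-scoring, and median high/low binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _encode_base(df: pd.DataFrame, col: str) -> tuple[list[str], np.ndarray, list]:
    """Treatment-coded dummies for categoricals, identity for numerics."""
    s = df[col]
    if pd.api.types.is_numeric_dtype(s):
        return [col], s.to_numpy(float).reshape(-1, 1), []
    levels = sorted(s.astype(str).unique())
    mats = [(s.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
    names = [f"{col}[{lev}]" for lev in levels[1:]]
    return names, np.column_stack(mats) if mats else np.empty((len(df), 0)), levels


def expand_terms(fixed: list[str]) -> list[str]:
    """'A*B' -> A, B, A:B; other terms pass through, duplicates dropped."""
    out: list[str] = []
    for term in fixed:
        if "*" in term:
            parts = [p.strip() for p in term.split("*")]
            out.extend(parts)
            out.append(":".join(parts))
        else:
            out.append(term.strip())
    seen: set[str] = set()
    return [t for t in out if not (t in seen or seen.add(t))]


def build_design(
    df: pd.DataFrame, fixed: list[str]
) -> tuple[np.ndarray, list[str], dict[str, slice], dict[str, list]]:
    """Design matrix with intercept; returns (X, colnames, term->slice, levels)."""
    terms = expand_terms(fixed)
    cols = [np.ones((len(df), 1))]
    names = ["Intercept"]
    term_slices: dict[str, slice] = {}
    levels: dict[str, list] = {}
    start = 1
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            sub_names: list[str] = [""]
            sub_mat = np.ones((len(df), 1))
            for p in parts:
                nm, m, lev = _encode_base(df, p)
                if lev:
                    levels.setdefault(p, lev)
                new_cols, new_names = [], []
                for j, nmj in enumerate(sub_names):
                    for k, nk in enumerate(nm):
                        new_cols.append(sub_mat[:, j] * m[:, k])
                        new_names.append(f"{nmj}:{nk}" if nmj else nk)
                sub_mat = np.column_stack(new_cols) if new_cols else np.empty((len(df), 0))
                sub_names = new_names
            mat, nm = sub_mat, sub_names
        else:
            nm, mat, lev = _encode_base(df, term)
            if lev:
                levels.setdefault(term, lev)
        cols.append(mat)
        names.extend(nm)
        term_slices[term] = slice(start, start + mat.shape[1])
        start += mat.shape[1]
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        u, s, _ = np.linalg.svd(x)
        aliased = [names[i] for i in range(x.shape[1]) if s[min(i, len(s) - 1)] < 1e-8]
        raise ValueError(f"singular fixed design; aliased terms near {aliased or names}")
    return x, names, term_slices, levels


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def _gls(x, y, idx, lam):
    """GLS quantities for V = I + lam Z Z' (random intercept, block diagonal)."""
    xtvx = x.T @ x
    xtvy = x.T @ y
    ytvy = float(y @ y)
    logdet_v = 0.0
    for g in idx:
        ng = len(g)
        w = lam / (1.0 + lam * ng)
        sx = x[g].sum(axis=0)
        sy = float(y[g].sum())
        xtvx -= w * np.outer(sx, sx)
        xtvy -= w * sx * sy
        ytvy -= w * sy * sy
        logdet_v += np.log1p(lam * ng)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - float(xtvy @ beta)  # r' V^-1 r at the GLS solution
    return beta, xtvx, rss, logdet_v


def _reml_m2ll(x, y, idx, lam):
    n, p = x.shape
    beta, xtvx, rss, logdet_v = _gls(x, y, idx, lam)
    # floor keeps the likelihood finite on noise-free (exact-fit) data
    sigma2_e = max(rss / (n - p), 1e-30)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    m2ll = (
        (n - p) * (1.0 + np.log(2 * np.pi * sigma2_e))
        + logdet_v
        + logdet_xtvx
    )
    return m2ll, beta, xtvx, sigma2_e


@dataclass
class LMMFit:
    response: str
    fixed: list[str]
    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_patient: float
    sigma2_resid: float
    lam: float
    reml_loglik: float
    fitted: np.ndarray
    resid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    group_idx: list[np.ndarray]
    term_slices: dict[str, slice]
    levels: dict[str, list]
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_idx)

    def cov_beta(self) -> np.ndarray:
        _, xtvx, _, _ = _gls(self.x, self.y, self.group_idx, self.lam)
        return self.sigma2_resid * np.linalg.inv(xtvx)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se}, index=self.coef_names
        )


def fit_random_intercept_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    groups: str = "patient_id",
    zscore: bool = False,
) -> LMMFit:
    """REML fit of ``response ~ fixed + (1 | groups)``.

    ``fixed`` terms may be numeric or categorical column names, 'A:B'
    interactions, or 'A*B' shorthand (both mains plus interaction).
    The profile over lambda = sigma_b^2/sigma_e^2 is optimized on a log grid
    refined by bounded scalar minimization; the lambda = 0 boundary (ordinary
    least squares) is always considered, so one-sample-per-patient data
    degrade gracefully to OLS.
    """
    df = data.dropna(subset=[response]).copy()
    y = df[response].to_numpy(float)
    if zscore:
        y = (y - y.mean()) / y.std(ddof=1)
    x, names, term_slices, levels = build_design(df, fixed)
    idx = _group_indices(df[groups].to_numpy())
    n, p = x.shape
    if n <= p:
        raise ValueError("more parameters than observations")

    def obj(log_lam: float) -> float:
        return _reml_m2ll(x, y, idx, 10.0**log_lam)[0]

    grid = np.linspace(-8, 8, 49)
    vals = [obj(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    lam = float(10.0**res.x)
    m2ll, beta, xtvx, sigma2_e = _reml_m2ll(x, y, idx, lam)
    m2ll0, beta0, xtvx0, sigma2_e0 = _reml_m2ll(x, y, idx, 0.0)
    # prefer the lambda = 0 boundary (plain OLS) unless positive lambda is a
    # real improvement; with one sample per group the profile is exactly flat
    if m2ll0 <= m2ll + 1e-7 * (1.0 + abs(m2ll)):
        lam, m2ll, beta, xtvx, sigma2_e = 0.0, m2ll0, beta0, xtvx0, sigma2_e0
    cov = sigma2_e * np.linalg.inv(xtvx)
    fitted = x @ beta
    return LMMFit(
        response=response,
        fixed=list(fixed),
        coef_names=names,
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma2_patient=lam * sigma2_e,
        sigma2_resid=sigma2_e,
        lam=lam,
        reml_loglik=-0.5 * m2ll,
        fitted=fitted,
        resid=y - fitted,
        x=x,
        y=y,
        group_idx=idx,
        term_slices=term_slices,
        levels=levels,
        data=df,
    )


def reml_profile(fit: LMMFit, log_lambdas: np.ndarray) -> np.ndarray:
    """REML log-likelihood along a lambda grid (for profile diagnostics)."""
    return np.array(
        [-0.5 * _reml_m2ll(fit.x, fit.y, fit.group_idx, 10.0**g)[0] for g in log_lambdas]
    )


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------


def variance_decomposition(fit: LMMFit) -> pd.DataFrame:
    """Sequential percent-variance attribution of each fixed term.

    Terms are added in their model order; each term's contribution is the
    variance of the change in GLS fitted values (at the full-model lambda)
    when that term enters, as a percentage of total response variance.
    Patient (random-intercept) and residual shares are appended.
    """
    total_var = float(np.var(fit.y, ddof=1))
    rows = []
    cols = [0]  # intercept
    prev_fit = np.full(fit.n, fit.y.mean())
    xs = fit.x[:, cols]
    beta, _, _, _ = _gls(xs, fit.y, fit.group_idx, fit.lam)
    prev_fit = xs @ beta
    for term, sl in fit.term_slices.items():
        cols = cols + list(range(sl.start, sl.stop))
        xs = fit.x[:, cols]
        beta, _, _, _ = _gls(xs, fit.y, fit.group_idx, fit.lam)
        cur_fit = xs @ beta
        contrib = cur_fit - prev_fit
        rows.append(
            {
                "term": term,
                "df": sl.stop - sl.start,
                "percent_variance": 100.0 * float(np.var(contrib, ddof=1)) / total_var,
            }
        )
        prev_fit = cur_fit
    rows.append(
        {
            "term": "patient (random)",
            "df": fit.n_groups,
            "percent_variance": 100.0 * fit.sigma2_patient / total_var,
        }
    )
    rows.append(
        {
            "term": "residual",
            "df": fit.n - fit.p,
            "percent_variance": 100.0 * fit.sigma2_resid / total_var,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimated marginal means
# ---------------------------------------------------------------------------


def _design_row(fit: LMMFit, assignment: dict[str, str]) -> np.ndarray:
    """Design vector for one cell of the factor grid (numerics at their mean)."""
    row = np.zeros(fit.p)
    row[0] = 1.0
    for term, sl in fit.term_slices.items():
        parts = term.split(":")
        vals = []
        for pcol in parts:
            if pcol in fit.levels:
                lev = assignment[pcol]
                base = fit.levels[pcol][1:]
                vals.append(np.array([1.0 if lev == b else 0.0 for b in base]))
            else:
                vals.append(np.array([float(fit.data[pcol].mean())]))
        block = vals[0]
        for v in vals[1:]:
            block = np.outer(block, v).ravel()
        row[sl] = block
    return row


def _satterthwaite_df(fit: LMMFit, c: np.ndarray) -> float:
    """Satterthwaite df for the variance of c'beta; residual-df fallback."""
    fallback = float(fit.n - fit.p - max(fit.n_groups - 1, 0))
    if fallback <= 0:
        fallback = float(fit.n - fit.p)

    def var_c(sb2: float, se2: float) -> float:
        lam = sb2 / se2 if se2 > 0 else 0.0
        _, xtvx, _, _ = _gls(fit.x, fit.y, fit.group_idx, lam)
        return se2 * float(c @ np.linalg.solve(xtvx, c))

    sb2, se2 = fit.sigma2_patient, fit.sigma2_resid
    if sb2 <= 0:
        return float(fit.n - fit.p)

    def m2ll(sb2_: float, se2_: float) -> float:
        # unprofiled -2 REML loglik at (sigma_b^2, sigma_e^2), constants dropped
        lam = sb2_ / se2_
        n, p = fit.n, fit.p
        _, xtvx, rss, logdet_v = _gls(fit.x, fit.y, fit.group_idx, lam)
        _, logdet_x = np.linalg.slogdet(xtvx)
        return (n - p) * np.log(se2_) + logdet_v + logdet_x + rss / se2_

    try:
        theta = np.array([sb2, se2])
        step = 1e-4 * np.maximum(theta, 1e-8)
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * step[i]
                ej = np.eye(2)[j] * step[j]
                hess[i, j] = (
                    m2ll(*(theta + ei + ej)) - m2ll(*(theta + ei - ej))
                    - m2ll(*(theta - ei + ej)) + m2ll(*(theta - ei - ej))
                ) / (4 * step[i] * step[j])
        cov_theta = np.linalg.inv(hess / 2.0)  # info = Hessian of -loglik
        grad = np.array(
            [
                (var_c(*(theta + np.eye(2)[i] * step[i]))
                 - var_c(*(theta - np.eye(2)[i] * step[i]))) / (2 * step[i])
                for i in range(2)
            ]
        )
        v = var_c(sb2, se2)
        var_v = float(grad @ cov_theta @ grad)
        if var_v <= 0 or not np.isfinite(var_v):
            return fallback
        df = 2.0 * v**2 / var_v
        if not np.isfinite(df) or df <= 1:
            return fallback
        return float(min(df, fit.n - fit.p))
    except (np.linalg.LinAlgError, FloatingPointError, ZeroDivisionError):
        return fallback


def estimated_marginal_means(fit: LMMFit, factor: str) -> dict:
    """EMMs of one categorical fixed factor with Tukey-adjusted contrasts.

    Marginal means average the model predictions over the full grid of the
    other categorical factors with equal cell weights (numeric covariates at
    their mean); in balanced one-factor designs they coincide with raw group
    means. Pairwise contrasts use the studentized-range (Tukey) adjustment.
    """
    if factor not in fit.levels:
        raise ValueError(f"{factor!r} is not a categorical fixed factor of the fit")
    observed = set(fit.data[factor].astype(str))
    levels = [l for l in fit.levels[factor] if l in observed]
    dropped = [l for l in fit.levels[factor] if l not in observed]
    if dropped:
        logger.warning("factor levels with no observations dropped: %s", dropped)
    other = [f for f in fit.levels if f != factor]
    other_grids = [fit.levels[f] for f in other]
    cov = fit.cov_beta()

    rows_c: dict[str, np.ndarray] = {}
    for lev in levels:
        grid_rows = []
        for combo in product(*other_grids) if other else [()]:
            assignment = {factor: lev, **dict(zip(other, combo))}
            grid_rows.append(_design_row(fit, assignment))
        rows_c[lev] = np.mean(grid_rows, axis=0)

    k = len(levels)
    table = []
    for lev in levels:
        c = rows_c[lev]
        mean = float(c @ fit.beta)
        se = float(np.sqrt(c @ cov @ c))
        df = _satterthwaite_df(fit, c)
        tcrit = stats.t.ppf(0.975, df)
        table.append(
            {
                "level": lev,
                "emmean": mean,
                "se": se,
                "df": df,
                "ci_low": mean - tcrit * se,
                "ci_high": mean + tcrit * se,
            }
        )
    contrasts = []
    for l1, l2 in combinations(levels, 2):
        c = rows_c[l1] - rows_c[l2]
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ cov @ c))
        df = _satterthwaite_df(fit, c)
        tval = est / se if se > 0 else np.inf
        p_tukey = float(stats.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df))
        contrasts.append(
            {
                "contrast": f"{l1} - {l2}",
                "estimate": est,
                "se": se,
                "df": df,
                "t": tval,
                "p_tukey": min(1.0, p_tukey),
            }
        )
    return {"emmeans": pd.DataFrame(table), "contrasts": pd.DataFrame(contrasts)}


# ---------------------------------------------------------------------------
# screens and binning
# ---------------------------------------------------------------------------


def zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    return (v - v.mean()) / v.std(ddof=1)


def signature_screen(
    data: pd.DataFrame,
    imaging_features: list[str],
    signatures: list[str],
    stratum: str = "all",
    region_col: str = "region",
    groups: str = "patient_id",
) -> pd.DataFrame:
    """Correlation + random-intercept LMM screen, feature x signature.

    Both variables are z-scored within the stratum before modeling. Reported
    per pair: Pearson r and p, LMM slope with SE, slope p (t on residual df),
    and marginal R^2 (variance of the fixed-effect prediction over total).
    A Benjamini-Hochberg column over the slope p-values is appended as a
    convenience beyond the original screen outputs.
    """
    if stratum != "all":
        data = data[data[region_col] == stratum]
    rows = []
    for feat in imaging_features:
        for sig in signatures:
            sub = data.dropna(subset=[feat, sig])
            if len(sub) < 3:
                logger.warning("stratum %s: <3 samples for %s~%s; skipped", stratum, feat, sig)
                continue
            yz = zscore(sub[feat].to_numpy())
            xz = zscore(sub[sig].to_numpy())
            r, p_r = stats.pearsonr(xz, yz)
            d = pd.DataFrame({groups: sub[groups].to_numpy(), "sig": xz, "y": yz})
            fit = fit_random_intercept_lmm(d, "y", ["sig"], groups=groups)
            slope = float(fit.beta[1])
            se = float(fit.se[1])
            dfree = fit.n - fit.p
            p_slope = 2.0 * stats.t.sf(abs(slope) / se, dfree) if se > 0 else 0.0
            r2 = float(np.var(fit.x @ fit.beta, ddof=1) / np.var(fit.y, ddof=1))
            rows.append(
                {
                    "imaging_feature": feat,
                    "signature": sig,
                    "stratum": stratum,
                    "n": len(sub),
                    "pearson_r": float(r),
                    "pearson_p": float(p_r),
                    "lmm_slope": slope,
                    "lmm_slope_se": se,
                    "lmm_slope_p": float(p_slope),
                    "lmm_r2": r2,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_q"] = _benjamini_hochberg(out["lmm_slope_p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def median_bin(values) -> pd.Series:
    """High/low labels about the median; exact-median ties go to 'low'."""
    v = pd.Series(values).astype(float)
    if v.nunique() < 2:
        raise ValueError("all values identical; median binning undefined")
    med = float(v.median())
    return pd.Series(np.where(v > med, "high", "low"), index=v.index, name="bin")
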