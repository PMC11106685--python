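"""Estimation of uncollected-resource fractions from the paired design.

The analysis mirrors the field study's statistical pipeline:

1. Per-flower sugar accumulation rates are averaged into one cell mean per
   (study day, period, location, treatment) — the Gaussian model is fitted
   to these cell means, not to raw flowers.
2. A Gaussian linear mixed model with random intercepts for year and
   site-within-year is fitted by this package's own REML (profiled
   variance-ratio optimisation with closed-form GLS for the fixed effects).
3. Pollen counts are fitted with a log-link negative-binomial regression
   (IRLS with ML dispersion); insect transect counts with Poisson
   quasi-likelihood (Pearson-dispersion scaled SEs).
4. Treatment contrasts are expressed as estimated marginal means (EMMs,
   equal weights over off-target factors) and the wastage statistic is the
   percentage ratio of EMMs: accessible/inaccessible for nectar,
   end/begin of anthesis for pollen.
5. Uncertainty comes from a cluster bootstrap over study days; model
   simplification uses likelihood-ratio tests on ML fits.

Count models deliberately omit the random intercepts: with a balanced
two-level design the EMM ratio is unchanged, and uncertainty is carried by
the day-level cluster bootstrap instead of a Laplace-approximate GLMM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .units import SugarDensityTable, accumulation_rate, nectar_sugar_mass

__all__ = [
    "AggregatedRate",
    "LmmFit",
    "CountFit",
    "WastageEstimate",
    "nectar_sugar_rates",
    "aggregate_means",
    "fit_lmm",
    "fit_count_model",
    "lrt",
    "wastage_ratio",
    "cluster_bootstrap",
    "summarize_residual_nectar",
]

AGG_KEYS = ["year", "site", "day", "period", "location", "treatment"]


class FitError(RuntimeError):
    """The requested model cannot be fitted on the given design."""


class EstimateError(ValueError):
    """A ratio estimate is undefined (non-positive reference mean)."""


# ---------------------------------------------------------------------------
# aggregation


def nectar_sugar_rates(
    nectar: pd.DataFrame, table: SugarDensityTable | None = None
) -> pd.DataFrame:
    """Append per-sample sugar mass (ug) and per-hour rates to a nectar table.

    Rows with zero volume carry zero sugar regardless of (possibly missing)
    Brix; rows with positive volume but missing Brix cannot be converted and
    raise.
    """
    if table is None:
        table = SugarDensityTable.packaged()
    df = nectar.copy()
    sugar = np.empty(len(df))
    for i, (vol, brix) in enumerate(zip(df["volume_uL"], df["brix_pct"])):
        if vol == 0:
            sugar[i] = 0.0
        elif pd.isna(brix):
            raise FitError(f"row {i}: positive volume with missing Brix")
        else:
            sugar[i] = nectar_sugar_mass(float(vol), float(brix), table)
    df["sugar_ug"] = sugar
    df["sugar_rate_ug_h"] = [
        accumulation_rate(s, t) for s, t in zip(df["sugar_ug"], df["interval_min"])
    ]
    df["volume_rate_uL_h"] = [
        accumulation_rate(v, t) for v, t in zip(df["volume_uL"], df["interval_min"])
    ]
    return df


@dataclass(frozen=True)
class AggregatedRate:
    """Cell means of sugar accumulation rate, one row per design cell."""

    data: pd.DataFrame  # columns AGG_KEYS + [mean_rate, n]


def aggregate_means(
    samples: pd.DataFrame, response: str = "sugar_rate_ug_h"
) -> pd.DataFrame:
    """Arithmetic mean of ``response`` per (day, period, location, treatment).

    Year and site are carried through (each study day belongs to exactly one
    site and year).  Empty cells are simply absent.  The weighted mean of
    cell means, with cell n as weights, equals the grand sample mean.
    """
    missing = [k for k in AGG_KEYS + [response] if k not in samples.columns]
    if missing:
        raise FitError(f"samples missing required columns: {missing}")
    if samples[AGG_KEYS].isna().any().any():
        bad = samples.index[samples[AGG_KEYS].isna().any(axis=1)].tolist()
        raise FitError(f"rows with missing design labels: {bad[:5]}")
    out = (
        samples.groupby(AGG_KEYS, sort=True, observed=True)[response]
        .agg(mean_rate="mean", n="size")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# design-matrix helpers (treatment coding, first level as reference)


def _levels(df: pd.DataFrame, col: str) -> list:
    return sorted(df[col].unique().tolist())


def _term_columns(df: pd.DataFrame, term: str, levels: Mapping[str, list]):
    """Dummy columns for a main effect 'a' or an interaction 'a:b'."""
    factors = term.split(":")
    blocks: list[tuple[str, np.ndarray]] = [("", np.ones(len(df)))]
    for f in factors:
        new: list[tuple[str, np.ndarray]] = []
        for name, col in blocks:
            for lvl in levels[f][1:]:
                ind = (df[f] == lvl).to_numpy(dtype=float)
                label = f"{name}:{f}[{lvl}]" if name else f"{f}[{lvl}]"
                new.append((label, col * ind))
        blocks = new
    return blocks


def _design(df: pd.DataFrame, terms: Sequence[str], levels: Mapping[str, list]):
    names = ["Intercept"]
    cols = [np.ones(len(df))]
    for term in terms:
        for name, col in _term_columns(df, term, levels):
            names.append(name)
            cols.append(col)
    return names, np.column_stack(cols)


def _factors_in(terms: Sequence[str]) -> list[str]:
    seen: list[str] = []
    for t in terms:
        for f in t.split(":"):
            if f not in seen:
                seen.append(f)
    return seen


# ---------------------------------------------------------------------------
# Gaussian linear mixed model, own REML


def _grouping_matrix(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels, sort=True)
    Z = np.zeros((len(labels), codes.max() + 1))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z


def _neg2_restricted_ll(gamma, y, X, Zs):
    """-2 x (restricted or profile) log-likelihood at variance ratios gamma.

    Returns (-2ll_reml, -2ll_ml, beta, sigma2_reml, sigma2_ml, XtVinvX).
    V = sigma2 * V0 with V0 = I + sum_g gamma_g Z_g Z_g'.
    """
    n, p = X.shape
    V0 = np.eye(n)
    for g, Z in zip(gamma, Zs):
        V0 += g * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return np.inf, np.inf, None, None, None, None
    logdetV0 = 2.0 * np.sum(np.log(np.diag(L)))
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtVX = Xw.T @ Xw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2_reml = rss / max(n - p, 1)
    sigma2_ml = rss / n
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf, np.inf, None, None, None, None
    n2r = (n - p) * np.log(2 * np.pi * sigma2_reml) + logdetV0 + logdetXtVX + (n - p)
    n2m = n * np.log(2 * np.pi * sigma2_ml) + logdetV0 + n
    return n2r, n2m, beta, sigma2_reml, sigma2_ml, XtVX


@dataclass
class LmmFit:
    """A fitted Gaussian random-intercept mixed model."""

    beta: np.ndarray
    beta_names: list[str]
    varcomps: dict[str, float]  # variance per random factor
    sigma2: float  # residual variance
    loglik: float  # REML or ML log-likelihood, per `reml`
    reml: bool
    n: int
    n_params: int  # fixed effects + variance parameters (for LRT bookkeeping)
    terms: list[str]
    levels: dict[str, list]
    cov_beta: np.ndarray
    data: pd.DataFrame = field(repr=False)
    response: str = "mean_rate"

    def _grid(self, factors: list[str]) -> pd.DataFrame:
        combos = list(itertools.product(*[self.levels[f] for f in factors]))
        return pd.DataFrame(combos, columns=factors)

    def emmeans(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means for ``factor``.

        Model-predicted cell means on the full grid of fixed factors,
        averaged over the other factors with equal weights; SEs via the
        GLS covariance of the fixed effects.
        """
        factors = _factors_in(self.terms)
        if factor not in factors:
            raise FitError(f"{factor!r} is not a fixed factor of this model")
        grid = self._grid(factors)
        _, Xg = _design(grid, self.terms, self.levels)
        rows = []
        for lvl in self.levels[factor]:
            mask = (grid[factor] == lvl).to_numpy()
            L = Xg[mask].mean(axis=0)
            est = float(L @ self.beta)
            se = float(np.sqrt(L @ self.cov_beta @ L))
            rows.append({factor: lvl, "emmean": est, "se": se})
        return pd.DataFrame(rows)


def fit_lmm(
    aggregated: pd.DataFrame,
    fixed: Sequence[str] = ("treatment",),
    random: Sequence[str] = ("year", "site_in_year"),
    response: str = "mean_rate",
    reml: bool = True,
) -> LmmFit:
    """Fit a Gaussian random-intercept model to aggregated cell means.

    ``random`` entries are either column names or the special label
    ``"site_in_year"`` (site nested within year, i.e. the year x site
    combination).  Variance components are estimated by maximising the
    restricted likelihood over non-negative variance ratios; boundary
    (zero) estimates are allowed and simply reported.  With ``reml=False``
    the profile (ML) likelihood is maximised instead, which is the fit to
    use inside likelihood-ratio tests.
    """
    df = aggregated.reset_index(drop=True)
    for f in _factors_in(fixed):
        if f not in df.columns:
            raise FitError(f"fixed factor {f!r} not in data")
        if df[f].nunique() < 2:
            raise FitError(f"fixed factor {f!r} needs >= 2 observed levels")
    levels = {f: _levels(df, f) for f in _factors_in(fixed)}
    names, X = _design(df, list(fixed), levels)
    y = df[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise FitError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("non-identifiable fixed-effect design (rank-deficient)")

    Zs, rnames = [], []
    for r in random:
        if r == "site_in_year":
            lab = df["year"].astype(str) + "/" + df["site"].astype(str)
        else:
            lab = df[r]
        if lab.nunique() < 2:
            continue  # a single group is indistinguishable from the intercept
        Zs.append(_grouping_matrix(lab))
        rnames.append(r)

    idx = 0 if reml else 1

    def objective(g):
        if np.any(np.asarray(g) < 0):
            return np.inf
        return _neg2_restricted_ll(g, y, X, Zs)[idx]

    if Zs:
        # coarse grid over variance ratios, then Nelder-Mead polish
        grid_pts = [0.0, 0.05, 0.25, 1.0, 4.0, 16.0]
        best = min(
            itertools.product(grid_pts, repeat=len(Zs)), key=lambda g: objective(g)
        )
        res = optimize.minimize(
            objective,
            np.asarray(best, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        gamma = np.clip(res.x, 0.0, None)
        if objective(gamma) > objective(best):
            gamma = np.asarray(best, dtype=float)
    else:
        gamma = np.array([])

    n2r, n2m, beta, s2r, s2m, XtVX = _neg2_restricted_ll(gamma, y, X, Zs)
    sigma2 = s2r if reml else s2m
    loglik = -0.5 * (n2r if reml else n2m)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    varcomps = {rn: float(g * sigma2) for rn, g in zip(rnames, gamma)}
    for r in random:
        varcomps.setdefault(r, 0.0)
    return LmmFit(
        beta=beta,
        beta_names=names,
        varcomps=varcomps,
        sigma2=float(sigma2),
        loglik=float(loglik),
        reml=reml,
        n=n,
        n_params=p + len(Zs) + 1,
        terms=list(fixed),
        levels=levels,
        cov_beta=cov_beta,
        data=df,
        response=response,
    )


# ---------------------------------------------------------------------------
# count models: negative binomial (ML dispersion) and quasi-Poisson


def _irls_log_link(y, X, var_fun, max_iter=100, tol=1e-10):
    """IRLS for a log-link mean model with variance function ``var_fun(mu)``."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu**2 / var_fun(mu)
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as e:
            raise FitError(f"IRLS normal equations singular: {e}") from None
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def _nb_loglik(y, mu, alpha):
    """Log-likelihood of NB2: var = mu + alpha mu^2 (alpha = 1/size)."""
    size = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + size)
            - special.gammaln(size)
            - special.gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


@dataclass
class CountFit:
    """A fitted log-link count regression (NB2 or quasi-Poisson)."""

    beta: np.ndarray
    beta_names: list[str]
    family: str  # "negbin" | "quasipoisson"
    dispersion: float  # NB: alpha (var = mu + alpha mu^2); QP: Pearson phi
    loglik: float | None  # None for quasi-likelihood fits
    n: int
    n_params: int
    terms: list[str]
    levels: dict[str, list]
    cov_beta: np.ndarray
    data: pd.DataFrame = field(repr=False)
    response: str = "count"

    def emmeans(self, factor: str) -> pd.DataFrame:
        """EMMs on the response scale: link-scale cell means, equal weights
        over off-target factors, then exponentiated (delta-method SEs)."""
        factors = _factors_in(self.terms)
        if factor not in factors:
            raise FitError(f"{factor!r} is not a fixed factor of this model")
        combos = list(itertools.product(*[self.levels[f] for f in factors]))
        grid = pd.DataFrame(combos, columns=factors)
        _, Xg = _design(grid, self.terms, self.levels)
        rows = []
        for lvl in self.levels[factor]:
            mask = (grid[factor] == lvl).to_numpy()
            L = Xg[mask].mean(axis=0)
            eta = float(L @ self.beta)
            se_eta = float(np.sqrt(L @ self.cov_beta @ L))
            rows.append(
                {factor: lvl, "emmean": np.exp(eta), "se": np.exp(eta) * se_eta}
            )
        return pd.DataFrame(rows)


def fit_count_model(
    counts: pd.DataFrame,
    fixed: Sequence[str] = ("stage",),
    response: str = "count",
    family: str = "negbin",
) -> CountFit:
    """Log-link count regression with the package's own IRLS.

    ``family="negbin"`` fits NB2 with the dispersion alpha estimated by
    profile maximum likelihood (alpha -> 0 recovers Poisson);``family=
    "quasipoisson"`` fits a Poisson mean model and scales the coefficient
    covariance by the Pearson dispersion, leaving no true likelihood.
    """
    df = counts.reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise FitError("counts must be non-negative integers")
    for f in _factors_in(fixed):
        if df[f].nunique() < 2:
            raise FitError(f"fixed factor {f!r} needs >= 2 observed levels")
        zero_level = df.groupby(f, observed=True)[response].sum()
        if (zero_level == 0).any():
            bad = zero_level.index[zero_level == 0].tolist()
            raise FitError(
                f"level(s) {bad} of {f!r} have all-zero counts: the log-link "
                "effect is at the boundary (-inf)"
            )
    levels = {f: _levels(df, f) for f in _factors_in(fixed)}
    names, X = _design(df, list(fixed), levels)
    n, p = X.shape

    if family == "quasipoisson":
        beta = _irls_log_link(y, X, lambda mu: mu)
        mu = np.exp(X @ beta)
        phi = float(np.sum((y - mu) ** 2 / mu) / max(n - p, 1))
        W = mu  # Poisson working weights at the solution
        cov = phi * np.linalg.inv(X.T @ (X * W[:, None]))
        return CountFit(beta, names, "quasipoisson", phi, None, n, p, list(fixed),
                        levels, cov, df, response)

    if family != "negbin":
        raise FitError(f"unknown family {family!r}")

    def profile_beta(alpha):
        return _irls_log_link(y, X, lambda mu: mu + alpha * mu**2)

    def neg_profile_ll(log_alpha):
        alpha = np.exp(log_alpha)
        b = profile_beta(alpha)
        mu = np.exp(np.clip(X @ b, -30, 30))
        return -_nb_loglik(y, mu, alpha)

    res = optimize.minimize_scalar(
        neg_profile_ll, bounds=(np.log(1e-6), np.log(1e3)), method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(np.exp(res.x))
    beta = profile_beta(alpha)
    mu = np.exp(X @ beta)
    loglik = _nb_loglik(y, mu, alpha)
    W = mu**2 / (mu + alpha * mu**2)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return CountFit(beta, names, "negbin", alpha, loglik, n, p + 1, list(fixed),
                    levels, cov, df, response)


# ---------------------------------------------------------------------------
# inference


def lrt(full, reduced) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Both fits must expose a true (ML) log-likelihood; REML likelihoods of
    models with different fixed effects are not comparable and are
    rejected.  Returns (chi-square statistic, df, p).
    """
    for m in (full, reduced):
        if getattr(m, "loglik", None) is None:
            raise FitError("both models need a true log-likelihood (not quasi)")
        if getattr(m, "reml", False):
            raise FitError("refit with reml=False (ML) before a likelihood-ratio test")
    df_diff = full.n_params - reduced.n_params
    if df_diff < 0:
        raise FitError("'reduced' must not have more parameters than 'full'")
    if not set(reduced.terms) <= set(full.terms):
        raise FitError("'reduced' terms are not a subset of 'full' terms")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df_diff == 0:  # identical models: no evidence either way
        return stat, 0, 1.0
    p = float(sps.chi2.sf(stat, df_diff)) if stat > 0 else 1.0
    return stat, df_diff, p


@dataclass(frozen=True)
class WastageEstimate:
    """Percentage of a resource left uncollected, with optional bootstrap CI."""

    percent: float
    ci_low: float | None
    ci_high: float | None
    comparison: str
    method: str
    n_boot: int = 0
    seed: int | None = None
    n_failed: int = 0

    def __post_init__(self):
        if self.percent < 0:
            raise EstimateError("percent uncollected cannot be negative")
        if self.ci_low is not None and not (
            self.ci_low <= self.percent <= self.ci_high
        ):
            raise EstimateError("CI must contain the point estimate")

    def rounded(self) -> int:
        """Reporting convention: percentages to the nearest integer."""
        return int(round(self.percent))


def wastage_ratio(
    target_mean: float,
    reference_mean: float,
    comparison: str = "accessible/inaccessible",
    method: str = "emm-ratio",
) -> WastageEstimate:
    """Percent uncollected as 100 x target EMM / reference EMM.

    For nectar the target is the accessible-flower EMM and the reference the
    inaccessible (bagged) EMM; for pollen, end vs beginning of anthesis.
    """
    if reference_mean <= 0:
        raise EstimateError("reference marginal mean must be positive")
    if target_mean < 0:
        raise EstimateError("target marginal mean cannot be negative")
    return WastageEstimate(
        percent=100.0 * target_mean / reference_mean,
        ci_low=None,
        ci_high=None,
        comparison=comparison,
        method=method,
    )


def cluster_bootstrap(
    data: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    cluster: str = "day",
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Percentile CI by resampling whole clusters (study days) with replacement.

    Replicates on which ``statistic`` raises are dropped with a warning and
    counted in the result.  Deterministic for a given seed.
    """
    clusters = np.asarray(sorted(pd.unique(data[cluster])))
    if len(clusters) < 2:
        raise FitError("need >= 2 clusters to bootstrap")
    if B < 1:
        raise FitError("B must be >= 1")
    rng = np.random.default_rng(seed)
    groups = {c: g for c, g in data.groupby(cluster, observed=True)}
    point = float(statistic(data))
    reps = []
    failed = 0
    for _ in range(B):
        chosen = rng.choice(clusters, size=len(clusters), replace=True)
        frames = []
        for j, c in enumerate(chosen):
            g = groups[c].copy()
            g[cluster] = f"{c}#{j}"  # resampled copies are distinct clusters
            frames.append(g)
        rep = pd.concat(frames, ignore_index=True)
        try:
            reps.append(float(statistic(rep)))
        except Exception:  # noqa: BLE001 - any statistic failure drops the rep
            failed += 1
    if failed:
        warnings.warn(f"{failed}/{B} bootstrap replicates failed and were dropped")
    if not reps:
        raise FitError("all bootstrap replicates failed")
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return {
        "point": point,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "B": B,
        "n_failed": failed,
        "alpha": alpha,
        "replicates": np.asarray(reps),
    }


def summarize_residual_nectar(volumes_uL: Sequence[float]) -> dict:
    """Share of post-visit flowers with no detectable nectar, and mean residue.

    Quantifies how completely a visiting insect empties a flower: the
    fraction of exact-zero volumes and the arithmetic mean residual volume
    (zeros included).  Empty input yields absent (None) values.
    """
    v = np.asarray(list(volumes_uL), dtype=float)
    if v.size == 0:
        return {"n": 0, "proportion_zero": None, "mean_volume_uL": None}
    if np.any(v < 0):
        raise EstimateError("residual volumes cannot be negative")
    return {
        "n": int(v.size),
        "proportion_zero": float(np.mean(v == 0)),
        "mean_volume_uL": float(np.mean(v)),
    }
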