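"""Functional-group trajectory models with time x environment structure.

Richness and abundance are counts with strong aggregation and are
modelled with a negative-binomial (NB2) error distribution; gain and
loss rates are modelled with Gaussian errors.  In both cases time
(years 1..T, or intervals for rates) and environment (sun-exposed vs
shaded) enter as categorical fixed effects with their interaction, and
landscape enters additively.  The scientific question is carried by the
time x environment interaction: it is tested with a likelihood-ratio
test between the full model and the additive reduction, and per-time
exposed-vs-shaded differences are assessed with unadjusted Wald z
contrasts on the link scale.

Random-effect structure: Gaussian rate models carry a per-trap random
intercept (restricted to ML estimation so that likelihood-ratio tests
on fixed effects are valid); landscape, having only two levels, is
treated as a fixed covariate.  Count models use a fixed-effects NB2
maximum-likelihood fit with a cluster-robust (by trap) covariance for
Wald inference, which targets the same cell means as a trap-intercept
mixed model.  The structure actually used is recorded on the result.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .datamodel import GroupSeries, SiteTable

FAMILIES = ("negative_binomial", "gaussian")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, error family and time coding."""

    response: str  # richness | abundance | Gp | Lp
    family: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        count = self.response in ("richness", "abundance")
        if count != (self.family == "negative_binomial"):
            raise ValueError(
                "negative_binomial is for richness/abundance, "
                "gaussian for Gp/Lp"
            )

    @classmethod
    def for_response(cls, response: str) -> "ModelSpec":
        fam = (
            "negative_binomial"
            if response in ("richness", "abundance")
            else "gaussian"
        )
        return cls(response=response, family=fam)


class FactorialDesign:
    """Treatment-coded design: full factorial over ``factors`` plus an
    additive covariate factor (landscape).  Reference level is the first
    level of each factor."""

    def __init__(self, factors: dict, covariate_levels=(), interaction=True):
        self.factors = {k: list(v) for k, v in factors.items()}
        self.covariate_levels = list(covariate_levels)
        self.interaction = interaction
        names = list(self.factors)
        subsets = [(f,) for f in names]
        if interaction:
            for r in range(2, len(names) + 1):
                subsets.extend(itertools.combinations(names, r))
        self.subsets = subsets
        self.columns = ["Intercept"]
        for sub in subsets:
            for combo in itertools.product(
                *[self.factors[f][1:] for f in sub]
            ):
                self.columns.append(
                    ":".join(f"{f}[{l}]" for f, l in zip(sub, combo))
                )
        for l in self.covariate_levels[1:]:
            self.columns.append(f"landscape[{l}]")

    def row(self, assign: dict, landscape_weights=None) -> np.ndarray:
        """Design row for one factor-level cell.

        ``landscape_weights`` maps landscape level -> weight; default is
        equal weights (prediction at the balanced landscape mix)."""
        x = [1.0]
        for sub in self.subsets:
            for combo in itertools.product(
                *[self.factors[f][1:] for f in sub]
            ):
                x.append(
                    float(all(assign[f] == l for f, l in zip(sub, combo)))
                )
        if self.covariate_levels:
            if landscape_weights is None:
                w = 1.0 / len(self.covariate_levels)
                landscape_weights = {l: w for l in self.covariate_levels}
            for l in self.covariate_levels[1:]:
                x.append(float(landscape_weights.get(l, 0.0)))
        return np.asarray(x)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        rows = np.empty((len(df), len(self.columns)))
        dummies = {}
        for f, levels in self.factors.items():
            vals = df[f].to_numpy()
            dummies[f] = {l: (vals == l).astype(float) for l in levels[1:]}
        j = 0
        rows[:, j] = 1.0
        j += 1
        for sub in self.subsets:
            for combo in itertools.product(
                *[self.factors[f][1:] for f in sub]
            ):
                col = np.ones(len(df))
                for f, l in zip(sub, combo):
                    col = col * dummies[f][l]
                rows[:, j] = col
                j += 1
        if self.covariate_levels:
            vals = df["landscape"].to_numpy()
            for l in self.covariate_levels[1:]:
                rows[:, j] = (vals == l).astype(float)
                j += 1
        return rows

    def cells(self):
        names = list(self.factors)
        for combo in itertools.product(*[self.factors[f] for f in names]):
            yield dict(zip(names, combo))


@dataclass
class FitResult:
    """A fitted trajectory model."""

    spec: ModelSpec
    design: FactorialDesign
    params: pd.Series  # fixed effects, link scale
    cov: pd.DataFrame  # covariance of the fixed effects
    llf: float
    n_obs: int
    data: pd.DataFrame  # rows used, with 'fitted' and 'resid' columns
    predictions: pd.DataFrame  # per-cell response-scale predictions + 95% CI
    structure: str  # which estimator/random structure was used
    dispersion: float | None = None  # NB2 alpha (1/theta) or residual var
    messages: list = field(default_factory=list)

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def df_fixed(self) -> int:
        return len(self.params)

    def _linpred(self, x: np.ndarray) -> tuple[float, float]:
        est = float(x @ self.params.to_numpy())
        # quadratic form can dip below 0 at machine precision for
        # boundary variance components
        se = float(np.sqrt(max(x @ self.cov.to_numpy() @ x, 0.0)))
        return est, se

    def predict_cell(self, assign: dict) -> tuple[float, float, float]:
        """Response-scale prediction and 95% CI for one factor cell."""
        eta, se = self._linpred(self.design.row(assign))
        lo, hi = eta - 1.96 * se, eta + 1.96 * se
        if self.family == "negative_binomial":
            return np.exp(eta), np.exp(lo), np.exp(hi)
        return eta, lo, hi


@dataclass(frozen=True)
class ContrastResult:
    """Wald contrast between environments at one time level."""

    time: object
    estimate: float  # exposed minus shaded, link scale
    se: float
    z: float
    p: float


def prepare_model_frame(
    series: GroupSeries | pd.DataFrame,
    sites: SiteTable,
    response: str,
) -> pd.DataFrame:
    """Join a richness/abundance series or turnover records with site
    covariates into a model frame with columns trap, time, environment,
    landscape, y.  Undefined turnover rates are dropped listwise."""
    if isinstance(series, GroupSeries):
        df = series.data.copy()
        df["time"] = df["year"]
        df["y"] = df[response].astype(float)
    else:
        df = series.copy()
        if response not in df.columns:
            raise KeyError(f"column {response!r} not in records")
        df["time"] = df["t1"].astype(str) + "-" + df["t2"].astype(str)
        df["y"] = df[response].astype(float)
        df = df[df["y"].notna()]
    env = sites.environment()
    lsc = sites.landscape()
    df["environment"] = df["trap"].map(env)
    df["landscape"] = df["trap"].map(lsc).astype(str)
    if df["environment"].isna().any():
        missing = sorted(df.loc[df["environment"].isna(), "trap"].unique())
        raise ValueError(f"traps missing from site table: {missing}")
    return df[["trap", "time", "environment", "landscape", "y"]].reset_index(
        drop=True
    )


def _fit_nb(y, X, colnames, trap_codes, messages):
    """NB2 ML fit with Poisson warm start and cluster-robust covariance.

    Falls back to a Poisson GLM when the overdispersion parameter is not
    identified (boundary or non-convergence)."""
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    start = np.r_[pois.params, 0.1]
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "newton", "nm"):
            try:
                cand = NegativeBinomial(y, X).fit(
                    start_params=start, method=method, maxiter=500, disp=0,
                    cov_type="cluster", cov_kwds={"groups": trap_codes},
                )
            except Exception:
                continue
            ok = np.all(np.isfinite(cand.params)) and np.isfinite(cand.llf)
            if ok and cand.mle_retvals.get("converged", True):
                res = cand
                break
            if ok and res is None:
                res = cand
    alpha_ok = res is not None and res.params[-1] > 1e-6
    if res is None or not alpha_ok:
        messages.append(
            "NB dispersion not identified; using Poisson fixed-effects fit"
        )
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
            cov_type="cluster", cov_kwds={"groups": trap_codes}
        )
        params = pd.Series(res.params, index=colnames)
        cov = pd.DataFrame(
            np.asarray(res.cov_params()), index=colnames, columns=colnames
        )
        return params, cov, float(res.llf), 0.0, res.fittedvalues
    k = len(colnames)
    params = pd.Series(res.params[:k], index=colnames)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=colnames, columns=colnames
    )
    fitted = np.exp(X @ params.to_numpy())
    return params, cov, float(res.llf), float(res.params[-1]), fitted


def _fit_gaussian(y, X, colnames, trap_codes, messages):
    """Gaussian fit with trap random intercept (ML); OLS with
    cluster-robust covariance when the mixed fit is degenerate."""
    k = len(colnames)
    if np.var(y) > 1e-12:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=trap_codes).fit(reml=False)
            if np.all(np.isfinite(res.fe_params)) and np.isfinite(res.llf):
                params = pd.Series(np.asarray(res.fe_params), index=colnames)
                cov = pd.DataFrame(
                    np.asarray(res.cov_params())[:k, :k],
                    index=colnames,
                    columns=colnames,
                )
                fitted = X @ params.to_numpy()
                return (
                    params, cov, float(res.llf), float(res.scale), fitted,
                    "mixed: trap random intercept + landscape fixed",
                )
        except Exception as exc:  # singular/non-converged mixed fit
            messages.append(f"mixed fit failed ({exc}); OLS fallback")
    res = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": trap_codes}
    )
    params = pd.Series(np.asarray(res.params), index=colnames)
    cov = pd.DataFrame(
        np.asarray(res.cov_params()), index=colnames, columns=colnames
    )
    messages.append("Gaussian fit used OLS with cluster-robust covariance")
    return (
        params, cov, float(res.llf), float(res.scale),
        np.asarray(res.fittedvalues),
        "fixed effects + cluster-robust (by trap) covariance",
    )


def fit_trajectory(
    frame: pd.DataFrame,
    spec: ModelSpec,
    interaction: bool = True,
    extra_factor: str | None = None,
) -> FitResult:
    """Fit the trajectory model for one model frame.

    ``frame`` comes from :func:`prepare_model_frame`.  ``interaction``
    False drops the time x environment (and any higher) interaction,
    giving the reduced model for the likelihood-ratio test.
    ``extra_factor`` names an additional categorical column (used for
    the specialist-vs-generalist three-way model).
    """
    times = sorted(frame["time"].unique(), key=str)
    envs = [e for e in ("exposed", "shaded") if e in set(frame["environment"])]
    if len(times) < 2:
        raise ValueError("need at least 2 time levels")
    if len(envs) < 2:
        raise ValueError("both environments must be present")
    factors = {"time": times, "environment": envs}
    if extra_factor is not None:
        levels = sorted(frame[extra_factor].unique())
        if len(levels) < 2:
            raise ValueError(f"factor {extra_factor!r} needs 2 levels")
        factors[extra_factor] = levels
    landscapes = sorted(frame["landscape"].unique())
    cov_levels = landscapes if len(landscapes) > 1 else []
    design = FactorialDesign(factors, cov_levels, interaction=interaction)
    X = design.matrix(frame)
    y = frame["y"].to_numpy(dtype=float)
    trap_codes = pd.Categorical(frame["trap"]).codes
    messages: list = []

    if spec.family == "negative_binomial":
        params, cov, llf, disp, fitted = _fit_nb(
            y, X, design.columns, trap_codes, messages
        )
        structure = "NB2 fixed effects + cluster-robust (by trap) covariance"
        if messages and "Poisson" in messages[-1]:
            structure = "Poisson fixed effects + cluster-robust covariance"
    else:
        params, cov, llf, disp, fitted, structure = _fit_gaussian(
            y, X, design.columns, trap_codes, messages
        )

    data = frame.copy()
    data["fitted"] = fitted
    if spec.family == "negative_binomial":
        var = fitted * (1.0 + disp * fitted)
        data["resid"] = (y - fitted) / np.sqrt(np.maximum(var, 1e-12))
    else:
        data["resid"] = y - fitted

    preds = []
    lw = frame["landscape"].value_counts(normalize=True).to_dict()
    fit = FitResult(
        spec=spec, design=design, params=params, cov=cov, llf=llf,
        n_obs=len(frame), data=data, predictions=pd.DataFrame(),
        structure=structure, dispersion=disp, messages=messages,
    )
    for cell in design.cells():
        eta, se = fit._linpred(design.row(cell, landscape_weights=lw))
        lo, hi = eta - 1.96 * se, eta + 1.96 * se
        if spec.family == "negative_binomial":
            pred, lo, hi = np.exp(eta), np.exp(lo), np.exp(hi)
        else:
            pred = eta
        preds.append({**cell, "predicted": pred, "ci_lo": lo, "ci_hi": hi})
    fit.predictions = pd.DataFrame(preds)
    return fit


def interaction_lrt(full: FitResult, reduced: FitResult):
    """Likelihood-ratio test of the interaction term.

    Returns (chi2, df, p).  The reduced model must drop the interaction
    from the same spec fitted to the same data."""
    if full.spec != reduced.spec:
        raise ValueError("models do not share a spec; not nested")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted to different data; not nested")
    names_full, names_red = set(full.params.index), set(reduced.params.index)
    if not names_red.issubset(names_full):
        raise ValueError("reduced model is not nested in the full model")
    df = full.df_fixed - reduced.df_fixed
    if df <= 0:
        raise ValueError("reduced model is not a proper reduction")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(st.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def within_time_contrasts(fit: FitResult, adjust: str | None = None):
    """Exposed-vs-shaded Wald contrast at each time level.

    Unadjusted two-sided z tests by default; ``adjust='holm'`` applies a
    Holm correction across time levels."""
    times = fit.design.factors["time"]
    out = []
    for t in times:
        base = {"time": t}
        extra = {
            f: fit.design.factors[f][0]
            for f in fit.design.factors
            if f not in ("time", "environment")
        }
        xe = fit.design.row({**base, **extra, "environment": "exposed"})
        xs = fit.design.row({**base, **extra, "environment": "shaded"})
        c = xe - xs
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ fit.cov.to_numpy() @ c))
        z = est / se if se > 0 else 0.0
        p = float(2 * st.norm.sf(abs(z)))
        out.append(ContrastResult(time=t, estimate=est, se=se, z=z, p=max(p, np.finfo(float).tiny)))
    if adjust == "holm":
        ps = np.array([c.p for c in out])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        out = [
            ContrastResult(c.time, c.estimate, c.se, c.z, float(a))
            for c, a in zip(out, adj)
        ]
    return out


def specialist_generalist_model(
    frames: dict,
    response: str = "abundance",
    years: tuple = (1, 2),
):
    """Three-way model comparing specialist and generalist trajectories
    over the first two years.

    ``frames`` maps group name ('specialist'/'generalist') to a model
    frame.  Returns (fit, three_way, fold_changes) where ``three_way``
    is the Wald test of the environment x year x group interaction and
    ``fold_changes`` gives each group's predicted year-2 / year-1 ratio
    per environment with a 95% CI.
    """
    for g in ("specialist", "generalist"):
        if g not in frames:
            raise ValueError(f"missing group {g!r}")
    parts = []
    for g, df in frames.items():
        part = df[df["time"].isin(years)].copy()
        part["group"] = g
        parts.append(part)
    frame = pd.concat(parts, ignore_index=True)
    spec = ModelSpec.for_response(response)
    fit = fit_trajectory(frame, spec, interaction=True, extra_factor="group")

    # single-df three-way coefficient (2 levels per factor after years 1-2)
    col = [
        c for c in fit.params.index
        if c.count(":") == 2 and "time[" in c and "environment[" in c
        and "group[" in c
    ]
    if len(col) != 1:
        raise RuntimeError(f"expected one three-way column, got {col}")
    est = float(fit.params[col[0]])
    se = float(np.sqrt(fit.cov.loc[col[0], col[0]]))
    z = est / se if se > 0 else 0.0
    three_way = ContrastResult(
        time=col[0], estimate=est, se=se, z=z, p=float(2 * st.norm.sf(abs(z)))
    )

    rows = []
    y1, y2 = years
    for g in ("specialist", "generalist"):
        for env in fit.design.factors["environment"]:
            x2 = fit.design.row({"time": y2, "environment": env, "group": g})
            x1 = fit.design.row({"time": y1, "environment": env, "group": g})
            c = x2 - x1
            d = float(c @ fit.params.to_numpy())
            se_d = float(np.sqrt(c @ fit.cov.to_numpy() @ c))
            if fit.family == "negative_binomial":
                fold = np.exp(d)
                lo, hi = np.exp(d - 1.96 * se_d), np.exp(d + 1.96 * se_d)
            else:
                fold, lo, hi = d, d - 1.96 * se_d, d + 1.96 * se_d
            rows.append(
                dict(group=g, environment=env, fold=fold, ci_lo=lo, ci_hi=hi)
            )
    return fit, three_way, pd.DataFrame(rows)


def residual_time_diagnostics(fit: FitResult):
    """Residual-vs-time table and lag-1 autocorrelation summary.

    Returns (table, summary): ``table`` has one row per observation
    ordered by trap and time with the model residual; ``summary`` holds
    the pooled lag-1 correlation over all within-trap consecutive pairs
    (the headline temporal-autocorrelation statistic) and the per-trap
    correlations (noisy at T=4; reported for completeness).
    """
    times = fit.design.factors["time"]
    if len(times) < 3:
        raise ValueError("residual diagnostics need at least 3 time points")
    order = {t: i for i, t in enumerate(times)}
    tab = fit.data[["trap", "time", "resid"]].copy()
    tab["time_order"] = tab["time"].map(order)
    tab = tab.sort_values(["trap", "time_order"]).reset_index(drop=True)

    firsts, seconds, per_trap = [], [], {}
    for trap, sub in tab.groupby("trap", sort=False):
        r = sub["resid"].to_numpy()
        if len(r) >= 2:
            firsts.append(r[:-1])
            seconds.append(r[1:])
        if len(r) >= 3 and np.std(r[:-1]) > 0 and np.std(r[1:]) > 0:
            per_trap[trap] = float(np.corrcoef(r[:-1], r[1:])[0, 1])
    a = np.concatenate(firsts)
    b = np.concatenate(seconds)
    pooled = float(np.corrcoef(a, b)[0, 1]) if len(a) > 2 else np.nan
    summary = {
        "lag1_pooled": pooled,
        "lag1_per_trap": pd.Series(per_trap),
        "n_pairs": int(len(a)),
    }
    return tab.drop(columns="time_order"), summary
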