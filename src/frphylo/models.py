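"""Comparative inference on log-transformed functional-response parameters.

Two frameworks, mirroring the split-plot structure of the experiment:

* Split-plot linear mixed models (REML, random tank intercept) of
  log a / log h / log max on temperature × origin, or — for the five
  familiar species — temperature × phylogenetic distance. Temperature is a
  whole-plot factor (one temperature per tank), so its F test uses the
  whole-plot error stratum; origin/phylo and the interactions are subplot
  terms. Denominator degrees of freedom follow the classical split-plot
  rule and depend only on the design shape:

      whole-plot terms:  n_tanks − 1 − (number of whole-plot terms)
      subplot terms:     N_obs − n_tanks − (number of subplot terms)

* Phylogenetic generalized least squares (PGLS) under Brownian motion,
  fitted per temperature level (one observation per species) and on
  temperature-averaged values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SpeciesInfo
from .phylo import PhyloTree, brownian_covariance, cophenetic_matrix, mean_distance_to_set

__all__ = [
    "TermTest",
    "SplitPlotFitResult",
    "PGLSResult",
    "build_parameter_table",
    "phylo_covariate",
    "fit_splitplot_lmm",
    "splitplot_denominator_dfs",
    "fit_pgls",
    "pgls_by_temperature",
    "average_over_temperature",
    "RESPONSES",
]

RESPONSES = ("log_a", "log_h", "log_max")


@dataclass
class TermTest:
    term: str
    estimate: float
    se: float
    t: float
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class SplitPlotFitResult:
    response: str
    fixed: str  # "temp_origin" | "temp_phylo"
    terms: list[TermTest]
    contrasts: list[TermTest]
    tank_variance: float
    residual_variance: float
    boundary_fit: bool  # tank variance estimated at (or fell back to) zero
    params: np.ndarray = field(default_factory=lambda: np.empty(0))
    cov_params: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def contrast(self, name: str) -> TermTest:
        for t in self.contrasts:
            if t.term == name:
                return t
        raise KeyError(name)

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"response": self.response, "term": t.term, "df_num": t.df_num,
                 "df_den": t.df_den, "F": t.F, "p": t.p}
                for t in self.terms
            ]
        )

    def contrast_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"response": self.response, "contrast": t.term,
                 "estimate": t.estimate, "t": t.t, "p": t.p}
                for t in self.contrasts
            ]
        )


@dataclass
class PGLSResult:
    response: str
    level: str  # temperature level as string, or "mean"
    covariate: str
    coefficients: pd.DataFrame  # term, estimate, se, t, p
    df_resid: int
    covariance_model: str = "Brownian"

    def coef(self, term: str) -> pd.Series:
        row = self.coefficients[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def build_parameter_table(
    params,
    species_info: dict[str, SpeciesInfo] | list[SpeciesInfo],
    phylo_covariates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the modelling table: one row per species × tank.

    Columns: species, temperature_C, tank, origin, dist_to_novel (familiar
    species only), log_a, log_h, log_max (natural logs; log_max = −log_h
    since max feeding rate = 1/h). The study shape gives 50 rows, 25 of
    them familiar.
    """
    from .frfit import params_to_frame

    if not isinstance(params, pd.DataFrame):
        params = params_to_frame(params)
    if isinstance(species_info, list):
        species_info = {s.name: s for s in species_info}
    df = params.copy()
    if (df["a"] <= 0).any() or (df["h"] <= 0).any():
        raise ValueError("non-positive FR parameter: cannot log-transform")
    df["origin"] = df["species"].map(
        lambda s: species_info[s].familiarity if s in species_info else None
    )
    if df["origin"].isna().any():
        missing = sorted(df.loc[df["origin"].isna(), "species"].unique())
        raise KeyError(f"species missing from metadata: {missing}")
    temps = sorted(df["temperature_C"].unique())
    tank_of = {t: f"tank{i + 1}" for i, t in enumerate(temps)}
    df["tank"] = df["temperature_C"].map(tank_of)
    df["dist_to_novel"] = df["species"].map(phylo_covariates or {})
    df["log_a"] = np.log(df["a"])
    df["log_h"] = np.log(df["h"])
    df["log_max"] = -df["log_h"]
    cols = ["species", "temperature_C", "tank", "origin", "dist_to_novel",
            "log_a", "log_h", "log_max"]
    return df[cols].sort_values(["temperature_C", "species"]).reset_index(drop=True)


def phylo_covariate(tree: PhyloTree, familiar: list[str], novel: list[str]) -> dict[str, float]:
    """Mean cophenetic distance of each familiar species to the novel set."""
    matrix = cophenetic_matrix(tree)
    return {f: mean_distance_to_set(matrix, f, novel) for f in familiar}


def splitplot_denominator_dfs(
    n_obs: int, n_tanks: int, n_wholeplot_terms: int, n_subplot_terms: int
) -> tuple[int, int]:
    """(whole-plot, subplot) denominator dfs from the design shape alone."""
    return (
        n_tanks - 1 - n_wholeplot_terms,
        n_obs - n_tanks - n_subplot_terms,
    )


def _design_matrix(table: pd.DataFrame, fixed: str) -> tuple[np.ndarray, list[str], str]:
    temp = table["temperature_C"].to_numpy(dtype=float)
    if fixed == "temp_origin":
        z = (table["origin"] == "novel").to_numpy(dtype=float)
        names = ["Intercept", "Temp", "Origin", "Temp:Origin"]
        covariate = "origin"
    elif fixed == "temp_phylo":
        if table["dist_to_novel"].isna().any():
            raise ValueError("dist_to_novel missing for some rows (temp_phylo model)")
        z = table["dist_to_novel"].to_numpy(dtype=float)
        names = ["Intercept", "Temp", "Phylo", "Temp:Phylo"]
        covariate = "phylo"
    else:
        raise ValueError(f"unknown fixed-effect structure: {fixed!r}")
    X = np.column_stack([np.ones_like(temp), temp, z, temp * z])
    return X, names, covariate


def fit_splitplot_lmm(
    table: pd.DataFrame, response: str, fixed: str = "temp_origin"
) -> SplitPlotFitResult:
    """REML split-plot mixed model with a random tank intercept.

    Marginal (Wald) F tests per fixed term use the stratum denominator dfs
    described in the module docstring; per-origin temperature slopes (or
    per-temperature phylogeny slopes) are reported as linear-combination
    contrasts, tested in the stratum of their narrowest term.
    """
    import statsmodels.api as sm

    if response not in table.columns:
        raise KeyError(f"unknown response: {response!r}")
    sub = table if fixed == "temp_origin" else table[table["origin"] == "familiar"]
    sub = sub.reset_index(drop=True)
    y = sub[response].to_numpy(dtype=float)
    X, names, covariate = _design_matrix(sub, fixed)
    if np.ptp(X[:, 2]) == 0:
        raise ValueError("covariate is degenerate (constant)")
    tanks = sub["tank"].to_numpy()
    n_tanks = len(np.unique(tanks))
    if n_tanks < 2:
        raise ValueError("need >= 2 tanks")
    n_obs = len(y)

    boundary = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=tanks)
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        params = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[: X.shape[1], : X.shape[1]]
        tank_var = float(fit.cov_re.iloc[0, 0])
        resid_var = float(fit.scale)
        if tank_var <= 1e-8 * max(resid_var, 1.0):
            boundary = True
    except Exception:
        # singular / failed REML: fall back to the boundary (OLS) estimate
        boundary = True
        params, cov, resid_var = _ols(y, X)
        tank_var = 0.0

    df_wp, df_sp = splitplot_denominator_dfs(n_obs, n_tanks, 1, 2)
    strata = {"Temp": df_wp, names[2]: df_sp, f"Temp:{names[2]}": df_sp,
              "Intercept": df_sp}
    terms = []
    for i, name in enumerate(names):
        est = float(params[i])
        se = float(np.sqrt(cov[i, i]))
        tval = est / se
        dfd = strata[name]
        F = tval**2
        terms.append(
            TermTest(name, est, se, tval, F, 1, dfd,
                     float(stats.f.sf(F, 1, dfd)))
        )

    contrasts = []
    if covariate == "origin":
        combos = [("Familiar: Temp", np.array([0.0, 1.0, 0.0, 0.0])),
                  ("Novel: Temp", np.array([0.0, 1.0, 0.0, 1.0]))]
    else:
        combos = [
            (f"{temp:g}: Phylo", np.array([0.0, 0.0, 1.0, float(temp)]))
            for temp in sorted(sub["temperature_C"].unique())
        ]
    for name, c in combos:
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se
        contrasts.append(
            TermTest(name, est, se, tval, tval**2, 1, df_sp,
                     float(2 * stats.t.sf(abs(tval), df_sp)))
        )

    return SplitPlotFitResult(
        response=response, fixed=fixed, terms=terms, contrasts=contrasts,
        tank_variance=tank_var, residual_variance=resid_var,
        boundary_fit=boundary, params=params, cov_params=cov,
    )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (len(y) - X.shape[1])
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, cov, s2


def fit_pgls(
    values: pd.Series,
    covariate: pd.Series,
    tree: PhyloTree,
    response: str = "y",
    covariate_name: str = "x",
    level: str = "mean",
) -> PGLSResult:
    """GLS regression with Brownian-motion error covariance from the tree.

    ``values`` and ``covariate`` are indexed by species (exactly one value
    per tip). β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with V the shared path-length matrix;
    t statistics use the GLS coefficient covariance with n − p residual df.
    Estimates and t statistics are invariant to rescaling V by any c > 0.
    """
    V = brownian_covariance(tree)
    taxa = V.taxa
    missing = [t for t in taxa if t not in values.index or t not in covariate.index]
    if missing:
        raise ValueError(f"missing trait values for: {missing}")
    y = values.loc[taxa].to_numpy(dtype=float)
    x = covariate.loc[taxa].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    Vm = V.values
    if np.linalg.matrix_rank(Vm) < len(taxa):
        zero = [taxa[i] for i in range(len(taxa)) if Vm[i, i] == 0]
        raise np.linalg.LinAlgError(
            f"singular Brownian covariance (zero root-to-tip length for {zero})"
        )
    Vinv = np.linalg.inv(Vm)
    XtVi = X.T @ Vinv
    cov_unscaled = np.linalg.inv(XtVi @ X)
    beta = cov_unscaled @ (XtVi @ y)
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    s2 = float(resid @ Vinv @ resid) / df_resid
    cov = s2 * cov_unscaled
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    coef = pd.DataFrame(
        {"term": ["Intercept", covariate_name], "estimate": beta,
         "se": se, "t": tvals, "p": pvals}
    )
    return PGLSResult(response, level, covariate_name, coef, df_resid)


def pgls_by_temperature(
    table: pd.DataFrame, tree: PhyloTree, response: str
) -> list[PGLSResult]:
    """PGLS of a log FR parameter on origin (novel = 1): one fit per
    temperature level plus one on temperature-averaged values."""
    results = []
    origin = (
        table.drop_duplicates("species").set_index("species")["origin"] == "novel"
    ).astype(float)
    for temp, cell in table.groupby("temperature_C", sort=True):
        vals = cell.set_index("species")[response]
        results.append(
            fit_pgls(vals, origin, tree, response=response,
                     covariate_name="origin", level=f"{temp:g}")
        )
    means = average_over_temperature(table)[response]
    results.append(
        fit_pgls(means, origin, tree, response=response,
                 covariate_name="origin", level="mean")
    )
    return results


def average_over_temperature(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species arithmetic means of the log parameters across temperatures.

    Every species must be observed at every temperature level.
    """
    counts = table.groupby("species")["temperature_C"].nunique()
    n_temps = table["temperature_C"].nunique()
    incomplete = counts[counts < n_temps]
    if len(incomplete):
        raise ValueError(f"missing temperature cells for: {list(incomplete.index)}")
    return table.groupby("species")[list(RESPONSES)].mean()
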