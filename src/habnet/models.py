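"""Regression layer on the computed network indices.

The fits mirror the study's analysis plan:

* ordinary least squares of observed and standardized modularity on
  landscape Shannon diversity;
* linear mixed-effects models (landscape random intercept) of observed and
  standardized robustness on extinction scenario × landscape diversity, and
  variants replacing diversity with modularity;
* a linear model of log(per-location species loss + 0.01) on habitat,
  scenario and diversity, with back-transformed per-habitat predictions;
* Pearson correlations of richness, completeness and network size with
  landscape diversity.

Backward model selection removes the least significant term (interaction
before main effects) until all remaining terms are significant at α = 0.05,
using likelihood-ratio chi-squared tests for mixed models and F-tests for
the species-loss linear model. Term order is fixed, so selection is
deterministic given the input table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .survey import SurveyDataError

ALPHA = 0.05


@dataclass
class ModelResult:
    """A fitted model: formula, coefficient table, selection path, n."""

    name: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    dropped_terms: list[str] = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)


def _check_variation(df: pd.DataFrame, col: str, flags: list[str]) -> bool:
    vals = df[col].dropna()
    if vals.nunique() <= 1:
        flags.append(f"{col} is constant; slope undefined")
        return False
    return True


def _ols(name: str, formula: str, data: pd.DataFrame) -> ModelResult:
    flags: list[str] = []
    fit = smf.ols(formula, data=data).fit()
    return ModelResult(
        name=name, formula=formula, params=fit.params, bse=fit.bse,
        pvalues=fit.pvalues, n=int(fit.nobs), flags=flags,
    )


def fit_modularity_models(indices: pd.DataFrame) -> dict[str, ModelResult]:
    """OLS of mod_obs and mod_z on Shannon diversity (z rows with NaN dropped)."""
    out: dict[str, ModelResult] = {}
    dat = indices.dropna(subset=["q_obs", "shannon_h"])
    if len(dat) < 3:
        raise SurveyDataError("need at least 3 landscapes for modularity models")
    res = _ols("mod_obs~H", "q_obs ~ shannon_h", dat)
    if not _check_variation(dat, "shannon_h", res.flags):
        res.params[:] = np.nan
    out["mod_obs~H"] = res

    dz = indices.dropna(subset=["mod_z", "shannon_h"])
    if len(dz) >= 3:
        out["mod_z~H"] = _ols("mod_z~H", "mod_z ~ shannon_h", dz)
    return out


def _make_fitter(data: pd.DataFrame, response: str, groups: str, terms: list[str]):
    """Return (fit_fn, mixed_used): mixed model if it fits cleanly, else OLS.

    A landscape random intercept whose variance collapses to zero makes the
    MixedLM Hessian singular; in that case the grouping carries no
    information and the whole selection path for that response falls back to
    ordinary least squares (flagged downstream)."""

    def fit_mixed(term_list):
        rhs = " + ".join(term_list) if term_list else "1"
        model = smf.mixedlm(f"{response} ~ {rhs}", data=data, groups=data[groups])
        return model.fit(reml=False, method="lbfgs")

    def fit_ols(term_list):
        rhs = " + ".join(term_list) if term_list else "1"
        return smf.ols(f"{response} ~ {rhs}", data=data).fit()

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = fit_mixed(terms)
        if np.isfinite(full.llf) and np.all(np.isfinite(np.asarray(full.bse))):
            def fit_quiet(term_list):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return fit_mixed(term_list)
            return fit_quiet, True
    except (np.linalg.LinAlgError, ValueError):
        pass
    return fit_ols, False


def _lrt_backward(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    groups: str,
    alpha: float = ALPHA,
) -> tuple[list[str], list[str], bool]:
    """Backward selection by likelihood-ratio chi-squared tests (ML fits).

    Interaction terms are eligible for removal before the main effects they
    contain. Returns (kept_terms, dropped_terms, mixed_used)."""
    fit, mixed_used = _make_fitter(data, response, groups, terms)

    def select(fit_fn):
        kept = list(terms)
        dropped: list[str] = []
        while kept:
            current = fit_fn(kept)
            candidates = [
                t for t in kept
                if ":" in t or not any(":" in o and t in o.split(":") for o in kept)
            ]
            worst, worst_p = None, -1.0
            for t in candidates:
                reduced = fit_fn([u for u in kept if u != t])
                lr = 2 * (current.llf - reduced.llf)
                df_diff = max(1, len(current.params) - len(reduced.params))
                p = stats.chi2.sf(max(lr, 0.0), df=df_diff)
                if p > worst_p:
                    worst, worst_p = t, p
            if worst is not None and worst_p > alpha:
                kept.remove(worst)
                dropped.append(worst)
            else:
                break
        return kept, dropped

    if mixed_used:
        try:
            kept, dropped = select(fit)
            return kept, dropped, True
        except (np.linalg.LinAlgError, ValueError):
            pass  # singular reduced fit: retry the whole path with OLS

    def ols_fit(term_list):
        rhs = " + ".join(term_list) if term_list else "1"
        return smf.ols(f"{response} ~ {rhs}", data=data).fit()

    kept, dropped = select(ols_fit)
    return kept, dropped, False


def fit_robustness_models(
    robustness: pd.DataFrame, indices: pd.DataFrame
) -> dict[str, ModelResult]:
    """Mixed models of rob_obs and rob_z on scenario × diversity (and on
    modularity), landscape random intercept, LRT backward selection."""
    dat = robustness.merge(
        indices[["landscape_id", "shannon_h", "q_obs", "mod_z"]],
        on="landscape_id", how="left",
    )
    out: dict[str, ModelResult] = {}
    specs = {
        "rob_obs~scenario*H": ("rob_obs",
                               ["scenario", "shannon_h", "scenario:shannon_h"]),
        "rob_z~scenario*H": ("rob_z",
                             ["scenario", "shannon_h", "scenario:shannon_h"]),
        "rob_obs~scenario*mod_obs": ("rob_obs",
                                     ["scenario", "q_obs", "scenario:q_obs"]),
        "rob_z~scenario*mod_z": ("rob_z",
                                 ["scenario", "mod_z", "scenario:mod_z"]),
    }
    for name, (resp, terms) in specs.items():
        sub = dat.dropna(subset=[resp] + [t for t in terms if ":" not in t
                                          if t != "scenario"])
        if sub["landscape_id"].nunique() < 3:
            continue
        kept, dropped, mixed_used = _lrt_backward(sub, resp, terms,
                                                  groups="landscape_id")
        rhs = " + ".join(kept) if kept else "1"
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            if mixed_used:
                fit = smf.mixedlm(f"{resp} ~ {rhs}", data=sub,
                                  groups=sub["landscape_id"]).fit(
                    reml=False, method="lbfgs")
                formula = f"{resp} ~ {rhs} + (1|landscape_id)"
                flags = []
            else:
                fit = smf.ols(f"{resp} ~ {rhs}", data=sub).fit()
                formula = f"{resp} ~ {rhs}"
                flags = ["random intercept variance singular; OLS fallback"]
        out[name] = ModelResult(
            name=name, formula=formula,
            params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
            n=int(fit.nobs), dropped_terms=dropped, flags=flags,
        )
    return out


def fit_species_loss_model(
    losses: pd.DataFrame, indices: pd.DataFrame
) -> ModelResult:
    """Linear model of log(mean per-location species loss + 0.01).

    Response rows are location × scenario means from the extinction runs;
    explanatory terms are habitat, scenario and landscape diversity, reduced
    backward by F-tests. Per-habitat predictions are back-transformed to the
    proportion scale (exp(fit) − 0.01) with 95% CIs.
    """
    dat = losses.merge(indices[["landscape_id", "shannon_h"]],
                       on="landscape_id", how="left")
    if dat["habitat"].nunique() < 2:
        raise SurveyDataError("species-loss model needs at least two habitats")
    dat = dat.assign(log_loss=np.log(dat["mean_prop_loss"] + 0.01))

    terms = ["C(habitat)", "C(scenario)", "shannon_h"]
    dropped: list[str] = []
    while len(terms) > 1:
        fit = smf.ols("log_loss ~ " + " + ".join(terms), data=dat).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        pvals = anova["PR(>F)"].drop(index="Residual", errors="ignore")
        if pvals.max() <= ALPHA:
            break
        worst = pvals.idxmax()
        terms.remove(worst)
        dropped.append(worst)
    fit = smf.ols("log_loss ~ " + " + ".join(terms), data=dat).fit()

    # per-habitat predictions at reference levels / mean diversity
    grid = pd.DataFrame({"habitat": sorted(dat["habitat"].unique())})
    if "C(scenario)" in terms:
        grid["scenario"] = sorted(dat["scenario"].unique())[0]
    if "shannon_h" in terms:
        grid["shannon_h"] = dat["shannon_h"].mean()
    pred = fit.get_prediction(grid).summary_frame(alpha=1 - 0.95)
    predictions = pd.DataFrame(
        {
            "habitat": grid["habitat"],
            "pred_loss": np.exp(pred["mean"]) - 0.01,
            "ci_low": np.exp(pred["mean_ci_lower"]) - 0.01,
            "ci_high": np.exp(pred["mean_ci_upper"]) - 0.01,
        }
    )
    return ModelResult(
        name="species_loss", formula=fit.model.formula,
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        n=int(fit.nobs), dropped_terms=dropped, predictions=predictions,
    )


def correlations(indices: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of per-landscape indices with Shannon diversity."""
    if len(indices) < 3:
        raise SurveyDataError("correlations need at least 3 landscapes")
    pairs = [
        ("species_richness", "shannon_h"),
        ("species_completeness", "shannon_h"),
        ("interaction_completeness", "shannon_h"),
        ("network_size", "shannon_h"),
    ]
    rows = []
    for a, b in pairs:
        if a not in indices.columns:
            continue
        sub = indices[[a, b]].dropna()
        if sub[a].nunique() <= 1 or sub[b].nunique() <= 1:
            rows.append({"x": a, "y": b, "r": np.nan, "p": np.nan,
                         "n": len(sub), "flag": "constant column"})
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"x": a, "y": b, "r": float(r), "p": float(p),
                     "n": len(sub), "flag": ""})
    return pd.DataFrame(rows)
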