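"""Dyadic mixed-effects regression of edge strength on network topology.

The unit of observation is a dyad: one unordered node pair in one
subject-state network. Edge strength (the truncated positive correlation)
is regressed on the endpoint-averaged clustering coefficient and global
efficiency, drinking state (0 = normal drinking, 1 = abstinent), resting
cardiac vagal tone (PB_RSA), their two- and three-way interactions, plus
degree difference, network modularity, age, sex, and BMI as adjustments.
Subject-level dependence is absorbed by a random intercept per subject and
(optionally) per subject-state. Fixed-effect p-values (Wald z) are adjusted
with the adaptive Benjamini-Hochberg false discovery rate procedure.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .connectome import ConnectivityMatrix, NodalMetrics

__all__ = [
    "FIXED_EFFECT_TERMS",
    "TERM_LABELS",
    "ModelFit",
    "build_dyad_table",
    "fit_strength_model",
    "adaptive_fdr",
    "report_results",
]

#: fixed-effect design terms, in reporting order
FIXED_EFFECT_TERMS = [
    "intercept",
    "state",
    "rsa",
    "state_rsa",
    "clustering",
    "efficiency",
    "clustering_state",
    "efficiency_state",
    "clustering_rsa",
    "efficiency_rsa",
    "clustering_state_rsa",
    "efficiency_state_rsa",
    "degree_diff",
    "modularity",
    "age",
    "sex",
    "bmi",
]

#: human-readable effect labels for report tables
TERM_LABELS = {
    "intercept": "Intercept",
    "state": "Drinking State",
    "rsa": "PB_RSA-rest",
    "state_rsa": "Drinking State*PB_RSA-rest",
    "clustering": "Clustering Coefficient",
    "efficiency": "Global Efficiency",
    "clustering_state": "Clustering Coefficient*Drinking State",
    "efficiency_state": "Global Efficiency*Drinking State",
    "clustering_rsa": "Clustering Coefficient*PB_RSA-rest",
    "efficiency_rsa": "Global Efficiency*PB_RSA-rest",
    "clustering_state_rsa": "Clustering Coefficient*Drinking State*PB_RSA-rest",
    "efficiency_state_rsa": "Global Efficiency*Drinking State*PB_RSA-rest",
    "degree_diff": "Degree Difference",
    "modularity": "Modularity",
    "age": "Age",
    "sex": "Sex",
    "bmi": "BMI",
}

#: dyad-table covariates standardized (z-scored) across all rows
CONTINUOUS_COVARIATES = [
    "clust_avg", "eff_avg", "degree_diff", "modularity_q", "rsa", "age", "bmi",
]


@dataclasses.dataclass
class ModelFit:
    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    fdr_adjusted_p: np.ndarray
    variance_components: dict  # subject, subject_state, residual (SD scale)
    converged: bool
    method: str  # "reml", "ml", or "ols" fallback chain outcome
    fe_cov: np.ndarray  # fixed-effect covariance (for derived slopes)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Effect": [TERM_LABELS[t] for t in self.terms],
                "Estimate": self.estimates,
                "Standard Error": self.std_errors,
                "p-Value": self.p_values,
                "Adaptive FDR p-Value": self.fdr_adjusted_p,
            }
        )


def build_dyad_table(
    networks: Mapping[tuple, ConnectivityMatrix],
    metrics: Mapping[tuple, NodalMetrics],
    covariates: pd.DataFrame,
    state_labels: Sequence = (0, 1),
    degree_mode: str = "binary",
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble the long-format dyad table from per-(subject, state) networks.

    ``networks`` and ``metrics`` are keyed by (subject, state); every subject
    must appear in both states. ``covariates`` must carry one row per subject
    with columns rsa, age, sex, bmi (indexed by subject). Edge strength is
    the raw truncated correlation; clustering/efficiency are endpoint
    averages; degree difference is the absolute difference (binary degree by
    default, nodal strength when ``degree_mode="strength"``). Continuous
    covariates are z-scored over all rows; state and sex stay as indicators.
    """
    if degree_mode not in ("binary", "strength"):
        raise ValueError("degree_mode must be 'binary' or 'strength'")
    subjects = sorted({k[0] for k in networks})
    cov = covariates.set_index("subject") if "subject" in covariates.columns else covariates
    chunks = []
    for subj in subjects:
        for col in ("rsa", "age", "sex", "bmi"):
            if subj not in cov.index or pd.isna(cov.loc[subj, col]):
                raise ValueError(f"missing covariate '{col}' for subject {subj!r}")
        for code, label in enumerate(state_labels):
            key = (subj, label)
            if key not in networks or key not in metrics:
                raise ValueError(f"missing state {label!r} for subject {subj!r}")
            w = networks[key].weights
            m = metrics[key]
            iu, ju = np.triu_indices(w.shape[0], k=1)
            deg = m.degree.astype(float) if degree_mode == "binary" else m.strength
            chunks.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "state": code,
                        "node_i": iu,
                        "node_j": ju,
                        "strength": w[iu, ju],
                        "clust_avg": (m.clustering[iu] + m.clustering[ju]) / 2.0,
                        "eff_avg": (m.efficiency[iu] + m.efficiency[ju]) / 2.0,
                        "degree_diff": np.abs(deg[iu] - deg[ju]),
                        "modularity_q": m.modularity_q,
                        "rsa": float(cov.loc[subj, "rsa"]),
                        "age": float(cov.loc[subj, "age"]),
                        "sex": float(cov.loc[subj, "sex"]),
                        "bmi": float(cov.loc[subj, "bmi"]),
                    }
                )
            )
    table = pd.concat(chunks, ignore_index=True)
    if standardize:
        table = standardize_covariates(table)
    return table


def standardize_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score the continuous covariates over all rows (ddof=0).

    A covariate with zero spread (e.g. modularity identical everywhere)
    is centered to 0 rather than divided by zero.
    """
    out = table.copy()
    for col in CONTINUOUS_COVARIATES:
        x = out[col].to_numpy(float)
        sd = x.std()
        out[col] = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    return out


def _design_frame(d: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "strength": d["strength"].to_numpy(float),
            "subject": d["subject"].to_numpy(),
            "state": d["state"].to_numpy(float),
            "rsa": d["rsa"].to_numpy(float),
            "clustering": d["clust_avg"].to_numpy(float),
            "efficiency": d["eff_avg"].to_numpy(float),
            "degree_diff": d["degree_diff"].to_numpy(float),
            "modularity": d["modularity_q"].to_numpy(float),
            "age": d["age"].to_numpy(float),
            "sex": d["sex"].to_numpy(float),
            "bmi": d["bmi"].to_numpy(float),
        }
    )
    df["state_rsa"] = df["state"] * df["rsa"]
    df["clustering_state"] = df["clustering"] * df["state"]
    df["efficiency_state"] = df["efficiency"] * df["state"]
    df["clustering_rsa"] = df["clustering"] * df["rsa"]
    df["efficiency_rsa"] = df["efficiency"] * df["rsa"]
    df["clustering_state_rsa"] = df["clustering"] * df["state"] * df["rsa"]
    df["efficiency_state_rsa"] = df["efficiency"] * df["state"] * df["rsa"]
    return df


_FORMULA = "strength ~ " + " + ".join(t for t in FIXED_EFFECT_TERMS if t != "intercept")


def fit_strength_model(
    d: pd.DataFrame,
    include_random_state: bool = True,
    fdr_q: float = 0.05,
) -> ModelFit:
    """Fit the mixed-effects edge-strength regression (REML, Wald z).

    Random effects: intercept per subject plus, when ``include_random_state``
    is set, an intercept per subject-state cell (a variance component on the
    state indicator within subject). Falls back to maximum likelihood if REML
    does not converge, and to OLS if the random-effect structure is
    degenerate (e.g. noiseless simulated data). With millions of dyads per
    model, Wald z inference is used throughout.
    """
    if d["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    df = _design_frame(d)
    vc = {"subject_state": "0 + C(state)"} if include_random_state else None
    converged, method, result = False, "reml", None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for use_reml in (True, False):
            try:
                md = smf.mixedlm(_FORMULA, df, groups=df["subject"], re_formula="1", vc_formula=vc)
                res = md.fit(reml=use_reml, method="lbfgs", maxiter=200)
                if np.all(np.isfinite(res.bse_fe)):
                    result, converged = res, bool(res.converged)
                    method = "reml" if use_reml else "ml"
                    if converged:
                        break
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                continue
    if result is None:
        # degenerate covariance (e.g. zero residual variance): OLS limit
        exog = sm.add_constant(
            df[[t for t in FIXED_EFFECT_TERMS if t != "intercept"]], has_constant="add"
        )
        ols = sm.OLS(df["strength"], exog).fit()
        est = ols.params.to_numpy()
        se = ols.bse.to_numpy()
        pvals = 2 * stats.norm.sf(np.abs(np.divide(est, se, out=np.zeros_like(est), where=se > 0)))
        pvals[se == 0] = np.where(est[se == 0] != 0, 0.0, 1.0)
        adj, _ = adaptive_fdr(pvals, q=fdr_q)
        return ModelFit(
            terms=list(FIXED_EFFECT_TERMS),
            estimates=est,
            std_errors=se,
            p_values=pvals,
            fdr_adjusted_p=adj,
            variance_components={"subject": 0.0, "subject_state": 0.0,
                                 "residual": float(np.sqrt(ols.scale))},
            converged=True,
            method="ols",
            fe_cov=np.asarray(ols.cov_params()),
        )
    names = ["Intercept"] + [t for t in FIXED_EFFECT_TERMS if t != "intercept"]
    est = result.fe_params.reindex(names).to_numpy()
    se = result.bse_fe.reindex(names).to_numpy()
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    adj, _ = adaptive_fdr(pvals, q=fdr_q)
    vcomp = {
        "subject": float(np.sqrt(max(result.cov_re.iloc[0, 0], 0.0))),
        "subject_state": float(np.sqrt(max(result.vcomp[0], 0.0))) if include_random_state else 0.0,
        "residual": float(np.sqrt(result.scale)),
    }
    k = len(names)
    fe_cov = np.asarray(result.cov_params())[:k, :k]
    return ModelFit(
        terms=list(FIXED_EFFECT_TERMS),
        estimates=est,
        std_errors=se,
        p_values=pvals,
        fdr_adjusted_p=adj,
        variance_components=vcomp,
        converged=converged,
        method=method,
        fe_cov=fe_cov,
    )


def adaptive_fdr(
    p: Sequence[float], q: float = 0.05, m0: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive Benjamini-Hochberg step-up FDR adjustment.

    The number of true nulls m0 is estimated by the lowest-slope rule:
    for sorted p-values compute l_i = (m + 1 - i) / (1 - p_(i)) and take the
    first i where l_i exceeds l_{i-1}; then m0 = min(floor(l_i) + 1, m).
    The step-up procedure then runs at level q * m / m0, equivalently the
    classical BH adjusted p-values are multiplied by m0 / m. Passing
    ``m0=len(p)`` reproduces classical BH exactly; the adaptive rejection
    set always contains the classical one.

    Returns (adjusted p-values, rejection flags at level q), in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    if m0 is None:
        with np.errstate(divide="ignore"):
            l = (m + 1 - np.arange(1, m + 1)) / (1.0 - ps)
        m0 = m
        for i in range(1, m):
            if l[i] > l[i - 1]:
                m0 = min(int(math.floor(l[i])) + 1, m)
                break
    if not (1 <= m0 <= m):
        raise ValueError("m0 must lie in [1, len(p)]")
    ranks = np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate((m0 * ps / ranks)[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def report_results(
    fit: ModelFit, rsa_levels: tuple[float, float] = (-1.0, 1.0)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Report table (one row per fixed effect) plus implied metric slopes.

    The slope of strength on a metric at a given state and RSA level is the
    linear combination beta_metric + beta_metric*state * state +
    beta_metric*rsa * rsa + beta_3way * state * rsa; its standard error comes
    from the fixed-effect covariance. With standardized covariates the
    default levels -1/+1 correspond to one SD below/above the mean PB_RSA.
    """
    table = fit.summary_frame()
    idx = {t: i for i, t in enumerate(fit.terms)}
    rows = []
    for metric in ("clustering", "efficiency"):
        for state in (0, 1):
            for rsa in rsa_levels:
                c = np.zeros(len(fit.terms))
                c[idx[metric]] = 1.0
                c[idx[f"{metric}_state"]] = state
                c[idx[f"{metric}_rsa"]] = rsa
                c[idx[f"{metric}_state_rsa"]] = state * rsa
                slope = float(c @ fit.estimates)
                se = float(np.sqrt(c @ fit.fe_cov @ c))
                rows.append(
                    {
                        "metric": metric,
                        "state": state,
                        "rsa_level": rsa,
                        "slope": slope,
                        "se": se,
                    }
                )
    return table, pd.DataFrame(rows)
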