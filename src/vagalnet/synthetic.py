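"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* R-R interval series whose heart period carries a sinusoidal respiratory
  modulation of amplitude A inside the adult band, so the band-limited
  variance — and hence the PB_RSA value — is known analytically: ln(A^2/2).
* Multi-subject, two-state cohorts of region time series drawn from a
  zero-mean multivariate normal with block-structured correlation, giving
  correlation networks whose population adjacency is known.
* Dyad-level datasets drawn directly from the mixed-effects strength model
  (fixed effects + subject and subject-state random intercepts + residual),
  for coefficient-recovery and inference-calibration tests.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import RegionTimeSeriesMatrix
from .netmodel import FIXED_EFFECT_TERMS
from .rsa import RRSeries

__all__ = [
    "RRSimParams",
    "SimulatedRR",
    "CohortSpec",
    "GeneratorModelSpec",
    "simulate_rr_series",
    "simulate_region_timeseries",
    "simulate_dyad_dataset",
    "write_rr_csv",
    "write_truth_csv",
]


@dataclasses.dataclass(frozen=True)
class RRSimParams:
    """Heart-period simulation parameters (additive, in milliseconds).

    h(t) = mean_period + mod_amplitude * sin(2*pi*mod_freq*t)
         + trend_amplitude * sin(2*pi*trend_freq*t) + N(0, noise_sd^2)

    mod_freq should sit inside the adult respiratory band (0.12-0.40 Hz);
    trend_freq models slow non-respiratory drift (typically < 0.03 Hz).
    """

    mean_period: float = 800.0  # ms
    mod_amplitude: float = 20.0  # ms, peak respiratory modulation (A)
    mod_freq: float = 0.25  # Hz
    trend_amplitude: float = 0.0  # ms
    trend_freq: float = 0.01  # Hz
    noise_sd: float = 0.0  # ms
    duration: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_period <= 0 or self.duration < 60:
            raise ValueError("mean_period must be positive and duration >= 60 s")
        if min(self.mod_amplitude, self.trend_amplitude, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")
        if self.mean_period <= self.mod_amplitude + self.trend_amplitude:
            raise ValueError("mean_period must exceed combined modulation amplitude")


@dataclasses.dataclass(frozen=True)
class SimulatedRR:
    rr: RRSeries
    params: RRSimParams
    #: analytic band-limited ln-variance target, ln(A^2/2); NaN when A = 0
    rsa_target: float


def simulate_rr_series(params: RRSimParams) -> SimulatedRR:
    """Generate beats by stepping through the heart-period function.

    Beat k+1 occurs one instantaneous heart period after beat k:
    t_{k+1} = t_k + h(t_k). Since h varies slowly relative to a single beat
    this tracks the modulation accurately. The analytic PB_RSA target is
    ln(A^2/2), the log variance of the respiratory sinusoid.
    """
    rng = np.random.default_rng(params.seed)
    t = 0.0
    intervals: list[float] = []
    while t < params.duration:
        h = (
            params.mean_period
            + params.mod_amplitude * math.sin(2 * math.pi * params.mod_freq * t)
            + params.trend_amplitude * math.sin(2 * math.pi * params.trend_freq * t)
        )
        if params.noise_sd > 0:
            h += rng.normal(0.0, params.noise_sd)
        if h <= 0:
            raise ValueError(
                "parameters generated a non-positive heart period; "
                "reduce noise_sd relative to mean_period"
            )
        intervals.append(h)
        t += h / 1000.0
    target = (
        math.log(params.mod_amplitude**2 / 2.0) if params.mod_amplitude > 0 else float("nan")
    )
    return SimulatedRR(rr=RRSeries(intervals=np.array(intervals)), params=params, rsa_target=target)


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Two-state cohort of block-correlated region time series.

    Within-block pairs share correlation ``rho_within``, across-block pairs
    ``rho_between`` (<= rho_within so the matrix is positive definite for
    moderate values). Defaults are desk-scale; a 268-region cohort is a
    configuration choice, not the default.
    """

    n_subjects: int = 30
    n_nodes: int = 50
    n_timepoints: int = 177
    tr: float = 2.0  # seconds
    n_blocks: int = 5
    rho_within: float = 0.4
    rho_between: float = 0.1
    state_labels: tuple = (0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_nodes, self.n_timepoints, self.n_blocks) < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError("need 0 <= rho_between <= rho_within < 1")
        if len(self.state_labels) != 2:
            raise ValueError("exactly two state labels required")

    def block_assignment(self) -> np.ndarray:
        """Node -> block index; remainder nodes go to the last block."""
        size = max(self.n_nodes // self.n_blocks, 1)
        blocks = np.minimum(np.arange(self.n_nodes) // size, self.n_blocks - 1)
        return blocks

    def population_correlation(self) -> np.ndarray:
        blocks = self.block_assignment()
        same = blocks[:, None] == blocks[None, :]
        r = np.where(same, self.rho_within, self.rho_between)
        np.fill_diagonal(r, 1.0)
        return r


def simulate_region_timeseries(
    spec: CohortSpec,
) -> tuple[dict, np.ndarray]:
    """Draw per-(subject, state) time x node matrices from the block model.

    Returns (data, population_correlation) where data maps
    (subject_index, state_label) to a RegionTimeSeriesMatrix and the
    population matrix serves as the oracle for sample correlations.
    """
    r = spec.population_correlation()
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(spec.seed)
    region_ids = [f"r{i:03d}" for i in range(spec.n_nodes)]
    data: dict = {}
    for subj in range(spec.n_subjects):
        for label in spec.state_labels:
            z = rng.standard_normal((spec.n_timepoints, spec.n_nodes))
            data[(subj, label)] = RegionTimeSeriesMatrix(
                values=z @ chol.T, tr=spec.tr, region_ids=list(region_ids)
            )
    return data, r


@dataclasses.dataclass(frozen=True)
class GeneratorModelSpec:
    """Forward model for dyad-level outcomes with known coefficients.

    ``beta`` maps every fixed-effect design term to its true coefficient.
    Subject-level covariates (rsa, age, bmi) are i.i.d. standard normal, sex
    is Bernoulli(1/2), and the dyad-level topology covariates (clustering,
    efficiency, degree difference) are i.i.d. standard normal per row —
    deliberately ignoring the coupling real networks induce among them;
    full-pipeline tests use the region-time-series route instead.
    """

    beta: Mapping[str, float]
    sigma_subject: float = 0.05
    sigma_subject_state: float = 0.03
    sigma_resid: float = 0.10
    n_subjects: int = 30
    n_nodes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.beta) != set(FIXED_EFFECT_TERMS):
            missing = set(FIXED_EFFECT_TERMS) - set(self.beta)
            extra = set(self.beta) - set(FIXED_EFFECT_TERMS)
            raise ValueError(f"beta keys must match design terms (missing={missing}, extra={extra})")
        if min(self.sigma_subject, self.sigma_subject_state, self.sigma_resid) < 0:
            raise ValueError("all SDs must be nonnegative")
        if self.n_subjects < 2 or self.n_nodes < 2:
            raise ValueError("need >= 2 subjects and >= 2 nodes")


def default_beta(**overrides: float) -> dict[str, float]:
    """All-zero coefficient map with selected terms overridden."""
    beta = {t: 0.0 for t in FIXED_EFFECT_TERMS}
    for k, v in overrides.items():
        if k not in beta:
            raise KeyError(f"unknown design term {k!r}")
        beta[k] = v
    return beta


def simulate_dyad_dataset(spec: GeneratorModelSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a dyad table from y = X beta + b_subject + b_subject_state + eps.

    Returns (table, truth) where the table has the same columns that
    build_dyad_table produces (already on the standardized scale by
    construction) and truth records the generating coefficients, SDs, and
    the realized random-effect draws for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_nodes * (spec.n_nodes - 1) // 2
    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    n_rows = 2 * spec.n_subjects * n_pairs

    subj = np.repeat(np.arange(spec.n_subjects), 2 * n_pairs)
    state = np.tile(np.repeat([0, 1], n_pairs), spec.n_subjects)
    rsa_s = rng.standard_normal(spec.n_subjects)
    age_s = rng.standard_normal(spec.n_subjects)
    bmi_s = rng.standard_normal(spec.n_subjects)
    sex_s = rng.integers(0, 2, spec.n_subjects).astype(float)
    clust = rng.standard_normal(n_rows)
    eff = rng.standard_normal(n_rows)
    degd = rng.standard_normal(n_rows)
    modq = rng.standard_normal((spec.n_subjects, 2))[subj, state]

    cols = {
        "intercept": np.ones(n_rows),
        "state": state.astype(float),
        "rsa": rsa_s[subj],
        "clustering": clust,
        "efficiency": eff,
        "degree_diff": degd,
        "modularity": modq,
        "age": age_s[subj],
        "sex": sex_s[subj],
        "bmi": bmi_s[subj],
    }
    cols["state_rsa"] = cols["state"] * cols["rsa"]
    cols["clustering_state"] = cols["clustering"] * cols["state"]
    cols["efficiency_state"] = cols["efficiency"] * cols["state"]
    cols["clustering_rsa"] = cols["clustering"] * cols["rsa"]
    cols["efficiency_rsa"] = cols["efficiency"] * cols["rsa"]
    cols["clustering_state_rsa"] = cols["clustering"] * cols["state"] * cols["rsa"]
    cols["efficiency_state_rsa"] = cols["efficiency"] * cols["state"] * cols["rsa"]

    y = np.zeros(n_rows)
    for term in FIXED_EFFECT_TERMS:
        y += spec.beta[term] * cols[term]
    b_subj = rng.normal(0.0, spec.sigma_subject, spec.n_subjects) if spec.sigma_subject > 0 else np.zeros(spec.n_subjects)
    b_ss = (
        rng.normal(0.0, spec.sigma_subject_state, (spec.n_subjects, 2))
        if spec.sigma_subject_state > 0
        else np.zeros((spec.n_subjects, 2))
    )
    eps = rng.normal(0.0, spec.sigma_resid, n_rows) if spec.sigma_resid > 0 else np.zeros(n_rows)
    y = y + b_subj[subj] + b_ss[subj, state] + eps

    table = pd.DataFrame(
        {
            "subject": subj,
            "state": state,
            "node_i": np.tile(iu, 2 * spec.n_subjects),
            "node_j": np.tile(ju, 2 * spec.n_subjects),
            "strength": y,
            "clust_avg": clust,
            "eff_avg": eff,
            "degree_diff": degd,
            "modularity_q": modq,
            "rsa": cols["rsa"],
            "age": cols["age"],
            "sex": cols["sex"],
            "bmi": cols["bmi"],
        }
    )
    truth = {
        "beta": dict(spec.beta),
        "sigma_subject": spec.sigma_subject,
        "sigma_subject_state": spec.sigma_subject_state,
        "sigma_resid": spec.sigma_resid,
        "b_subject": b_subj,
        "b_subject_state": b_ss,
    }
    return table, truth


# -- I/O -----------------------------------------------------------------------

def write_rr_csv(rr: RRSeries, path) -> None:
    pd.DataFrame({"rr_ms": rr.intervals}).to_csv(path, index=False)


def write_truth_csv(truth: dict, path) -> None:
    """Flatten a truth record to key-value CSV (arrays are summarized)."""
    rows = []
    for k, v in truth.items():
        if isinstance(v, dict):
            rows.extend({"key": f"{k}.{kk}", "value": vv} for kk, vv in v.items())
        elif isinstance(v, np.ndarray):
            rows.append({"key": f"{k}.sd", "value": float(np.std(v))})
        else:
            rows.append({"key": k, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)
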