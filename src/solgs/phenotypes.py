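"""Trial-level linear mixed models: variance components, heritability, BLUPs.

Continuous traits observed across trials are reduced to per-(accession,
trial) replicate means and fitted with

    y_ij = mu + g_i + t_j + e_ij,

where the intercept mu is fixed and genotype g and trial t are independent
random effects.  Variance components are estimated by EM-REML on Henderson's
mixed-model equations, which handles unbalanced accession x trial tables
natively and keeps every component non-negative.  The genetic value used as
the genomic-selection response is mu_hat + BLUP(g_i); heritability is
var_g over the sum of fitted components (a flag drops the trial component
from the denominator, since "total variance" admits either convention).

Ordinal descriptor traits bypass the Gaussian model: their per-accession
label is the modal label across records (ties -> lower category).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TraitSummary:
    """Fitted variance components and genetic values for one trait."""

    trait: str
    mu_hat: float
    var_g: float
    var_t: float
    var_e: float
    h2: float
    genetic_value: pd.Series  # per-accession mu_hat + BLUP(g)
    converged: bool = True
    n_iter: int = 0


REQUIRED_COLUMNS = ("accession", "trial", "replicate", "trait", "value")


def validate_phenotypes(tbl: pd.DataFrame) -> None:
    """Check the long-format phenotype schema and key uniqueness."""
    missing = [c for c in REQUIRED_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    keys = tbl[["accession", "trial", "replicate", "trait"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (accession, trial, replicate, trait) records")


def trial_means(tbl: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Accession x trial matrix of replicate means for one continuous trait.

    Cells with no observation stay NaN (unbalanced designs are allowed).
    """
    sub = tbl[tbl["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from table")
    return sub.pivot_table(index="accession", columns="trial", values="value",
                           aggfunc="mean")


def fit_trial_lmm(means: pd.DataFrame, trait: str = "trait",
                  include_trial_in_h2: bool = True,
                  tol: float = 1e-8, max_iter: int = 500) -> TraitSummary:
    """EM-REML fit of the two-random-effect trial model on replicate means.

    Iterates Henderson's mixed-model equations, updating each variance
    component from the squared BLUPs plus the trace of the corresponding
    block of the inverse coefficient matrix, until the maximum relative
    change falls below ``tol``.  The restricted likelihood is non-decreasing
    across EM iterations.
    """
    acc = means.index.to_numpy()
    trials = means.columns.to_numpy()
    q_g, q_t = len(acc), len(trials)
    if q_g < 2 or q_t < 2:
        raise ValueError("need at least 2 accessions and 2 trials")
    arr = means.to_numpy(dtype=float)
    obs = ~np.isnan(arr)
    rows, cols = np.nonzero(obs)
    y = arr[rows, cols]
    N = y.size
    if N <= q_g + q_t:
        warnings.warn("very few observations relative to effect levels")

    X = np.ones((N, 1))
    Zg = np.zeros((N, q_g))
    Zg[np.arange(N), rows] = 1.0
    Zt = np.zeros((N, q_t))
    Zt[np.arange(N), cols] = 1.0
    W = np.hstack([X, Zg, Zt])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    vtot = max(float(np.var(y)), 1e-12)
    var_g = var_t = var_e = vtot / 3.0
    floor = 1e-10 * vtot
    sl_g = slice(1, 1 + q_g)
    sl_t = slice(1 + q_g, 1 + q_g + q_t)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        C[sl_g, sl_g] += np.eye(q_g) * (var_e / var_g)
        C[sl_t, sl_t] += np.eye(q_t) * (var_e / var_t)
        Cinv = np.linalg.inv(C)
        sol = Cinv @ Wty
        u_g = sol[sl_g]
        u_t = sol[sl_t]
        new_e = (yty - float(sol @ Wty)) / (N - 1)  # rank(X) = 1
        new_g = (float(u_g @ u_g) + new_e * float(np.trace(Cinv[sl_g, sl_g]))) / q_g
        new_t = (float(u_t @ u_t) + new_e * float(np.trace(Cinv[sl_t, sl_t]))) / q_t
        new_g, new_t, new_e = (max(v, floor) for v in (new_g, new_t, new_e))
        rel = max(
            abs(new_g - var_g) / max(var_g, floor),
            abs(new_t - var_t) / max(var_t, floor),
            abs(new_e - var_e) / max(var_e, floor),
        )
        var_g, var_t, var_e = new_g, new_t, new_e
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM-REML did not converge in {max_iter} iterations "
                      f"(last relative change {rel:.2e})")

    # BLUPs at converged components
    C = WtW.copy()
    C[sl_g, sl_g] += np.eye(q_g) * (var_e / var_g)
    C[sl_t, sl_t] += np.eye(q_t) * (var_e / var_t)
    sol = np.linalg.solve(C, Wty)
    mu_hat = float(sol[0])
    blup_g = sol[sl_g]

    h2 = heritability(var_g, var_t, var_e, include_trial=include_trial_in_h2)
    return TraitSummary(
        trait=trait,
        mu_hat=mu_hat,
        var_g=var_g,
        var_t=var_t,
        var_e=var_e,
        h2=h2,
        genetic_value=pd.Series(mu_hat + blup_g, index=pd.Index(acc, name="accession")),
        converged=converged,
        n_iter=it,
    )


def heritability(var_g: float, var_t: float, var_e: float,
                 include_trial: bool = True) -> float:
    """Broad-sense heritability: var_g over the total fitted variance."""
    denom = var_g + var_e + (var_t if include_trial else 0.0)
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return var_g / denom


def restricted_loglik(means: pd.DataFrame, var_g: float, var_t: float,
                      var_e: float) -> float:
    """Restricted log-likelihood of the trial model at given components.

    Used to monitor the EM iterations (the objective must not decrease).
    """
    arr = means.to_numpy(dtype=float)
    rows, cols = np.nonzero(~np.isnan(arr))
    y = arr[rows, cols]
    N = y.size
    Zg = np.zeros((N, arr.shape[0]))
    Zg[np.arange(N), rows] = 1.0
    Zt = np.zeros((N, arr.shape[1]))
    Zt[np.arange(N), cols] = 1.0
    V = var_g * (Zg @ Zg.T) + var_t * (Zt @ Zt.T) + var_e * np.eye(N)
    X = np.ones((N, 1))
    sign, logdetV = np.linalg.slogdet(V)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = (X.T @ Vinv_X).item()
    beta = (X.T @ Vinv_y).item() / XtVinvX
    r = y - beta
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (logdetV + np.log(XtVinvX) + quad)


def fit_all_traits(tbl: pd.DataFrame, traits: list[str] | None = None,
                   include_trial_in_h2: bool = True) -> dict[str, TraitSummary]:
    """Fit the trial model for each continuous trait in the table."""
    validate_phenotypes(tbl)
    if traits is None:
        traits = sorted(tbl["trait"].unique())
    out = {}
    for tr in traits:
        out[tr] = fit_trial_lmm(trial_means(tbl, tr), trait=tr,
                                include_trial_in_h2=include_trial_in_h2)
    return out


def modal_labels(tbl: pd.DataFrame, trait: str) -> pd.Series:
    """Per-accession modal ordinal label across records (ties -> lower)."""
    sub = tbl[tbl["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from table")

    def _mode(s: pd.Series):
        counts = s.value_counts()
        top = counts[counts == counts.max()]
        return sorted(top.index)[0]

    return sub.groupby("accession")["value"].agg(_mode)


def summaries_to_frame(summaries: dict[str, TraitSummary]) -> pd.DataFrame:
    """One row per trait: components, heritability, convergence."""
    return pd.DataFrame(
        [
            {
                "trait": s.trait,
                "mu_hat": s.mu_hat,
                "var_g": s.var_g,
                "var_t": s.var_t,
                "var_e": s.var_e,
                "h2": s.h2,
                "converged": s.converged,
                "n_iter": s.n_iter,
            }
            for s in summaries.values()
        ]
    ).set_index("trait")


def genetic_values_matrix(summaries: dict[str, TraitSummary]) -> pd.DataFrame:
    """Accession x trait matrix of genetic values (GS responses)."""
    return pd.DataFrame({t: s.genetic_value for t, s in summaries.items()})
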