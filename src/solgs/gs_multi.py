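"""Multi-trait genomic prediction via a kernel (kinship) mixed model.

Model: for t traits stacked as vec(Y),

    vec(Y) = (I_t  kron  1) B + g + e,
    cov(g) = Sigma_g kron K,   cov(e) = Sigma_e kron I_n,

with K the genomic relationship matrix of the training accessions.  The
genetic and residual trait covariances are estimated by EM-REML on error
contrasts: projecting onto the orthogonal complement of the intercept and
rotating by the eigenvectors of the projected kernel leaves independent
t-variate rows with covariance d_i Sigma_g + Sigma_e, so the E-step is a
closed-form per-row conditioning and the M-step averages expected
cross-products of genetic BLUPs and residuals.  The restricted likelihood
is non-decreasing across iterations and is recorded for monitoring.

Prediction for unseen accessions uses the conditional-mean identity
G_test = K_cross K_train^+ G_blup (per trait column).  With a single trait
the model collapses exactly to single-trait rrBLUP/GBLUP, for which the
variance ratio is refined by the exact profiled REML search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gs_core import _contrast_basis, kernel_reml

#: Named trait groups used for grouped multi-trait runs: four pairs (fruit
#: size, width/height, external shape indices, pericarp) and three triples
#: (RGB color, CIELab color, height profile).
TRAIT_GROUP_PRESETS: dict[str, list[str]] = {
    "size": ["perimeter", "area"],
    "width_height": ["width_mid_height", "maximum_height"],
    "shape_index": ["fruit_shape_index_ext_1", "fruit_shape_index_ext_2"],
    "pericarp": ["pericarp_area", "pericarp_thickness"],
    "rgb": ["average_red", "average_green", "average_blue"],
    "cielab": ["average_l", "average_a", "average_b"],
    "heights": ["maximum_height", "height_mid_width", "curved_height"],
}


@dataclass
class MultiTraitModel:
    """Fitted multivariate mixed-model state."""

    trait_names: list[str]
    B_hat: np.ndarray             # t intercepts
    Sigma_g: np.ndarray           # t x t genetic covariance
    Sigma_e: np.ndarray           # t x t residual covariance
    blup_matrix: np.ndarray       # n x t genetic BLUPs of training accessions
    kinship: np.ndarray           # training kinship used for the fit
    converged: bool = True
    n_iter: int = 0
    loglik_history: list = field(default_factory=list)


def _stabilize(S: np.ndarray) -> np.ndarray:
    """Ridge-stabilize a near-singular covariance estimate."""
    t = S.shape[0]
    w = np.linalg.eigvalsh(S)
    if w.min() < 1e-10 * max(w.max(), 1.0):
        warnings.warn("near-singular covariance estimate; ridge-stabilized")
        S = S + 1e-8 * (np.trace(S) / t) * np.eye(t)
    return S


def _row_covs(d: np.ndarray, Sg: np.ndarray, Se: np.ndarray) -> np.ndarray:
    """Stacked per-row covariances W_i = d_i Sigma_g + Sigma_e."""
    return d[:, None, None] * Sg[None] + Se[None]


def _restricted_ll(d: np.ndarray, Ystar: np.ndarray, Sg: np.ndarray,
                   Se: np.ndarray) -> float:
    W = _row_covs(d, Sg, Se)
    _, logdet = np.linalg.slogdet(W)
    Winv = np.linalg.inv(W)
    quad = np.einsum("ia,iab,ib->", Ystar, Winv, Ystar)
    return -0.5 * (float(logdet.sum()) + float(quad))


def fit_multitrait(K: np.ndarray, Y: np.ndarray,
                   trait_names: list[str] | None = None,
                   tol: float = 1e-6, max_iter: int = 500) -> MultiTraitModel:
    """EM-REML fit of the multivariate kernel model.

    ``K`` is the training kinship (PSD, n x n) and ``Y`` the complete
    accession x trait genetic-value matrix.  Convergence is declared when
    the maximum relative change of any covariance entry drops below
    ``tol``; non-convergence is reported with the last iterate.
    """
    K = np.asarray(K, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == K.shape[0]:
        pass
    else:
        raise ValueError("Y must be n x t aligned with K")
    if np.any(np.isnan(Y)):
        raise ValueError("Y must be complete")
    n, t = Y.shape
    if trait_names is None:
        trait_names = [f"trait_{a + 1}" for a in range(t)]

    H = _contrast_basis(n)
    Kc = H @ K @ H.T
    d, U = np.linalg.eigh(Kc)
    d = np.clip(d, 0.0, None)
    Ystar = U.T @ (H @ Y)           # (n-1) x t independent rows

    if t == 1:
        var_u, var_e, _ = kernel_reml(K, Y[:, 0])
        Sg = np.array([[var_u]])
        Se = np.array([[var_e]])
        hist = [_restricted_ll(d, Ystar, Sg, Se)]
        conv, it = True, 0
    else:
        S0 = np.cov(Y.T)
        Sg = S0 / 2.0 + 1e-8 * np.eye(t)
        Se = S0 / 2.0 + 1e-8 * np.eye(t)
        pos = d > 1e-12
        n_pos = int(pos.sum())
        hist = []
        conv = False
        it = 0
        for it in range(1, max_iter + 1):
            hist.append(_restricted_ll(d, Ystar, Sg, Se))
            Winv = np.linalg.inv(_row_covs(d, Sg, Se))
            SgWinv = np.einsum("ab,ibc->iac", Sg, Winv)
            G = d[:, None] * np.einsum("iab,ib->ia", SgWinv, Ystar)
            E = Ystar - G
            # E[a a'] with g = sqrt(d) a, a ~ N(0, Sg)
            cov_a = Sg[None] - d[:, None, None] * (SgWinv @ Sg)
            Gp = G[pos]
            acc_g = (
                np.einsum("ia,ib->ab", Gp / d[pos, None], Gp)
                + cov_a[pos].sum(axis=0)
            )
            SeWinv = np.einsum("ab,ibc->iac", Se, Winv)
            acc_e = (
                np.einsum("ia,ib->ab", E, E)
                + (n - 1) * Se - (SeWinv @ Se).sum(axis=0)
            )
            Sg_new = _stabilize(acc_g / max(n_pos, 1))
            Se_new = _stabilize(acc_e / (n - 1))
            denom = max(np.abs(Sg).max(), np.abs(Se).max(), 1e-12)
            rel = max(np.abs(Sg_new - Sg).max(), np.abs(Se_new - Se).max()) / denom
            Sg, Se = Sg_new, Se_new
            if rel < tol:
                conv = True
                break
        if not conv:
            warnings.warn(f"multi-trait EM-REML did not converge in {max_iter} "
                          f"iterations (last relative change {rel:.2e})")
        hist.append(_restricted_ll(d, Ystar, Sg, Se))

    # GLS intercepts and training BLUPs on the full (uncontrasted) rotation
    df, Uf = np.linalg.eigh(K)
    df = np.clip(df, 0.0, None)
    Yr = Uf.T @ Y
    xr = Uf.T @ np.ones(n)
    Winv = np.linalg.inv(_row_covs(df, Sg, Se))
    lhs = np.einsum("i,iab->ab", xr**2, Winv)
    rhs = np.einsum("i,iab,ib->a", xr, Winv, Yr)
    B_hat = np.linalg.solve(lhs, rhs)
    R = Yr - np.outer(xr, B_hat)
    Gr = df[:, None] * np.einsum("ab,ibc,ic->ia", Sg, Winv, R)
    blup = Uf @ Gr
    return MultiTraitModel(trait_names=list(trait_names), B_hat=B_hat,
                           Sigma_g=Sg, Sigma_e=Se, blup_matrix=blup,
                           kinship=K, converged=conv, n_iter=it,
                           loglik_history=hist)


def predict_multitrait(model: MultiTraitModel, K_cross: np.ndarray) -> np.ndarray:
    """Conditional-mean prediction for unseen accessions.

    ``K_cross`` is the test x train kinship block built on the combined
    accessions with training-mean centering (see
    :func:`solgs.gs_core.kinship_pair`).  Returns the test x t prediction
    matrix B_hat + K_cross K_train^+ G_blup.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    n = model.kinship.shape[0]
    if K_cross.shape[1] != n:
        raise ValueError("K_cross column count must match training size")
    d, U = np.linalg.eigh(model.kinship)
    keep = d > 1e-10 * max(d.max(), 1.0)
    Kpinv = (U[:, keep] / d[keep]) @ U[:, keep].T
    return model.B_hat[None, :] + K_cross @ (Kpinv @ model.blup_matrix)


def rv_coefficient(Xm: np.ndarray, Ym: np.ndarray) -> float:
    """Rv matrix correlation between two column-centered data matrices.

    RV = trace(X X' Y Y') / sqrt(trace((X X')^2) trace((Y Y')^2)); computed
    through cross-product Frobenius norms so no n x n matrix is formed.
    """
    X = np.atleast_2d(np.asarray(Xm, dtype=float))
    Y = np.atleast_2d(np.asarray(Ym, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrices must have the same number of rows")
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    num = float(np.sum((X.T @ Y) ** 2))
    dx = float(np.sum((X.T @ X) ** 2))
    dy = float(np.sum((Y.T @ Y) ** 2))
    if dx == 0 or dy == 0:
        raise ValueError("Rv undefined for a zero matrix")
    return num / np.sqrt(dx * dy)


def serialize_model(model: MultiTraitModel, prefix: str) -> None:
    """Write Sigma matrices and the BLUP matrix as delimited files."""
    import pandas as pd

    names = model.trait_names
    pd.DataFrame(model.Sigma_g, index=names, columns=names).to_csv(
        f"{prefix}.sigma_g.tsv", sep="\t")
    pd.DataFrame(model.Sigma_e, index=names, columns=names).to_csv(
        f"{prefix}.sigma_e.tsv", sep="\t")
    blup = pd.DataFrame(model.blup_matrix, columns=names)
    blup.insert(0, "intercept_added", False)
    blup.to_csv(f"{prefix}.blup.tsv", sep="\t", index=False)
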