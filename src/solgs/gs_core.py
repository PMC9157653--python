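"""Single-trait ridge-regression BLUP (rrBLUP) genomic prediction.

Model: y = 1 b + Z u + e with i.i.d. marker effects u ~ N(0, var_u I) and
residuals e ~ N(0, var_e I); the fixed part is the intercept only.  The
variance-component ratio delta = var_e / var_u is estimated by restricted
maximum likelihood: the marker kernel K = Zc Zc' is eigendecomposed once on
the error-contrast space (orthogonal complement of the intercept), after
which every evaluation of the profiled restricted log-likelihood is O(n)
and the ratio is found by bounded scalar search in log-space.

Marker effects follow from the kernel-form identity
u_hat = Zc' (Zc Zc' + delta I)^(-1) (y - b_hat 1), the dual of the dense
ridge solve (Zc'Zc + delta I)^(-1) Zc'(y - b_hat 1); predictions for new
accessions center their dosages by the training means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import helmert
from scipy.optimize import brentq, minimize_scalar

_LOG_RATIO_BOUNDS = (np.log(1e-6), np.log(1e6))


@dataclass
class RRBlupModel:
    """Fitted rrBLUP state."""

    b_hat: float
    u_hat: np.ndarray
    lam: float                    # ridge ratio var_e / var_u
    var_u: float
    var_e: float
    train_mean_dosage: np.ndarray
    marker_ids: np.ndarray | None = None
    mean_diag_k: float = np.nan   # mean diagonal of Zc Zc' (genomic scaling)

    @property
    def estimated_h2(self) -> float:
        """Genomic heritability var_u * c / (var_u * c + var_e), with c the
        mean diagonal of the training marker kernel."""
        vg = self.var_u * self.mean_diag_k
        return vg / (vg + self.var_e)


def _contrast_basis(n: int) -> np.ndarray:
    """(n-1) x n orthonormal error contrasts (rows orthogonal to 1)."""
    return helmert(n)


def kernel_reml(K: np.ndarray, y: np.ndarray,
                xatol: float = 1e-12) -> tuple[float, float, float]:
    """REML variance components for y = 1b + g + e, g ~ N(0, var_u K).

    Returns ``(var_u, var_e, delta)`` with delta = var_e / var_u found by
    bounded search on the profiled restricted log-likelihood over log-delta.
    Emits a warning when the optimum sits at a search boundary.
    """
    n = len(y)
    H = _contrast_basis(n)
    M = H @ K @ H.T
    xi, V = np.linalg.eigh(M)
    xi = np.clip(xi, 0.0, None)
    eta2 = (V.T @ (H @ y)) ** 2

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = xi + d
        s = float(np.sum(eta2 / denom))
        return 0.5 * (float(np.sum(np.log(denom))) + (n - 1) * np.log(s))

    def grad(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = xi + d
        s1 = float(np.sum(eta2 / denom))
        s2 = float(np.sum(eta2 / denom**2))
        return 0.5 * d * (float(np.sum(1.0 / denom)) - (n - 1) * s2 / s1)

    res = minimize_scalar(neg_restricted_ll, bounds=_LOG_RATIO_BOUNDS,
                          method="bounded", options={"xatol": xatol})
    log_delta = float(res.x)
    lo, hi = _LOG_RATIO_BOUNDS
    # polish interior optima by a gradient root-find: makes the estimate
    # invariant to kernel rescaling to machine precision
    a, b = log_delta - 0.05, log_delta + 0.05
    if a > lo and b < hi and grad(a) < 0 < grad(b):
        log_delta = float(brentq(grad, a, b, xtol=1e-14))
    if log_delta < lo + 1e-4 or log_delta > hi - 1e-4:
        warnings.warn("REML ratio search hit its boundary; treat the fit as "
                      "a boundary estimate", stacklevel=2)
    delta = float(np.exp(log_delta))
    var_u = float(np.sum(eta2 / (xi + delta)) / (n - 1))
    var_e = delta * var_u
    return var_u, var_e, delta


def fit_rrblup(Z: np.ndarray, y: np.ndarray, lam: float | None = None,
               marker_ids: np.ndarray | None = None) -> RRBlupModel:
    """Fit rrBLUP on a complete dosage matrix and genetic-value response.

    When ``lam`` is given the variance-ratio is fixed and only the GLS
    intercept and marker BLUPs are computed; otherwise the ratio is
    estimated by spectral REML.  A response with no variance returns the
    degenerate all-shrunk model with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    if n < 3:
        raise ValueError("need at least 3 training accessions")
    if len(y) != n:
        raise ValueError("response length mismatch")
    if np.any(np.isnan(Z)) or np.any(np.isnan(y)):
        raise ValueError("missing entries not allowed")
    center = Z.mean(axis=0)
    Zc = Z - center
    K = Zc @ Zc.T
    mean_diag = float(np.mean(np.diag(K)))

    if np.all(y == y[0]):
        warnings.warn("constant response: returning zero-effect model")
        return RRBlupModel(b_hat=float(y[0]), u_hat=np.zeros(m), lam=np.inf,
                           var_u=0.0, var_e=0.0, train_mean_dosage=center,
                           marker_ids=marker_ids, mean_diag_k=mean_diag)

    if lam is None:
        var_u, var_e, delta = kernel_reml(K, y)
    else:
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        delta = float(lam)
        var_u, var_e = np.nan, np.nan

    A = K + delta * np.eye(n)
    ones = np.ones(n)
    Ainv_y = np.linalg.solve(A, y)
    Ainv_1 = np.linalg.solve(A, ones)
    b_hat = float(ones @ Ainv_y) / float(ones @ Ainv_1)
    u_hat = Zc.T @ np.linalg.solve(A, y - b_hat)

    if lam is not None:
        r = y - b_hat - Zc @ u_hat
        var_e = float(r @ r) / max(n - 1, 1)
        var_u = var_e / delta if delta > 0 else np.nan
    return RRBlupModel(b_hat=b_hat, u_hat=u_hat, lam=delta, var_u=var_u,
                       var_e=var_e, train_mean_dosage=center,
                       marker_ids=marker_ids, mean_diag_k=mean_diag)


def predict(model: RRBlupModel, Z_new: np.ndarray,
            marker_ids: np.ndarray | None = None) -> np.ndarray:
    """Predicted genetic values b_hat + (Z_new - train means) . u_hat.

    When both the model and the call carry marker ids they must match
    exactly; no silent reordering is attempted.
    """
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    if Z_new.shape[1] != len(model.u_hat):
        raise ValueError("marker dimension mismatch")
    if marker_ids is not None and model.marker_ids is not None:
        if not np.array_equal(np.asarray(marker_ids), np.asarray(model.marker_ids)):
            raise ValueError("marker ids do not match the training order")
    return model.b_hat + (Z_new - model.train_mean_dosage) @ model.u_hat


def kinship(Z: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix K = Zc Zc' / m (column-centered)."""
    Z = np.asarray(Z, dtype=float)
    if np.any(np.isnan(Z)):
        raise ValueError("missing entries not allowed")
    Zc = Z - Z.mean(axis=0)
    return (Zc @ Zc.T) / Z.shape[1]


def kinship_pair(Z_train: np.ndarray, Z_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training kinship and new-vs-training cross-kinship, both centered by
    the training marker means and scaled by the marker count."""
    Z_train = np.asarray(Z_train, dtype=float)
    Z_new = np.asarray(Z_new, dtype=float)
    center = Z_train.mean(axis=0)
    m = Z_train.shape[1]
    Zc = Z_train - center
    Nc = Z_new - center
    return (Zc @ Zc.T) / m, (Nc @ Zc.T) / m


def serialize_model(model: RRBlupModel, path: str) -> None:
    """Write the effects file: header lines then (marker_id, effect) rows."""
    ids = model.marker_ids if model.marker_ids is not None else [
        f"m{j}" for j in range(len(model.u_hat))
    ]
    with open(path, "w") as fh:
        fh.write(f"#b_hat\t{model.b_hat!r}\n")
        fh.write(f"#lambda\t{model.lam!r}\n")
        fh.write(f"#var_u\t{model.var_u!r}\n")
        fh.write(f"#var_e\t{model.var_e!r}\n")
        fh.write("marker_id\teffect\ttrain_mean\n")
        for mid, u, c in zip(ids, model.u_hat, model.train_mean_dosage):
            fh.write(f"{mid}\t{u!r}\t{c!r}\n")
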