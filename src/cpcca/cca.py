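"""Canonical correlation analysis between two multivariate time series.

Rows are variables, columns are time samples.  Given ``X`` (p x i) and
``Y`` (q x i), CCA finds weight vectors ``w_x``, ``w_y`` maximizing the
Pearson correlation between the projected variates ``w_x @ X`` and
``w_y @ Y``.  The solver whitens each set through an SVD of the centered
data rather than inverting covariance matrices, which keeps short or
near-collinear windows stable; an optional trace-scaled ridge inflates the
within-set covariance diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SingularityError, ValidationError

__all__ = ["CCAResult", "cca"]

#: Default relative ridge: within-set covariances get ``ridge * mean
#: squared singular value`` added to the diagonal before whitening.
DEFAULT_RIDGE = 1e-8


@dataclass(frozen=True)
class CCAResult:
    """Outcome of one CCA fit.

    Attributes
    ----------
    rho : float
        Maximal canonical correlation, clipped to [0, 1].
    w_x, w_y : ndarray
        Weight vectors for the first / second input (lengths p and q).
    x_hat, y_hat : ndarray
        Projected canonical variates (length i), centered and scaled to
        unit sample variance.
    all_rhos : ndarray
        All canonical correlations, nonincreasing, length min(p, q);
        correlations beyond the numerical rank are zero.
    """

    rho: float
    w_x: np.ndarray = field(repr=False)
    w_y: np.ndarray = field(repr=False)
    x_hat: np.ndarray = field(repr=False)
    y_hat: np.ndarray = field(repr=False)
    all_rhos: np.ndarray = field(repr=False)


def _whiten(Z: np.ndarray, ridge: float):
    """SVD-based whitening of centered data rows.

    Returns (U, d, back, Vt) where the whitened data is ``U @ diag(d) @ Vt``
    and a weight ``u`` in the whitened basis maps back to the variable
    space as ``U @ (back * u)``.
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    s2 = s**2
    if ridge > 0:
        eps = ridge * s2.mean()
        back = 1.0 / np.sqrt(s2 + eps)
        d = s * back
    else:
        tol = max(Z.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        keep = s > tol
        back = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
        d = keep.astype(float)
    return U, d, back, Vt


def cca(X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> CCAResult:
    """Maximal canonical correlation between ``X`` (p x i) and ``Y`` (q x i).

    Each row is mean-centered before covariances are formed.  ``ridge``
    is relative: the within-set covariance diagonal is inflated by
    ``ridge`` times its mean eigenvalue.  With ``ridge=0`` a zero-variance
    row raises :class:`SingularityError`; rank-deficient inputs are
    otherwise handled by pseudo-inverse whitening.

    Sign convention: ``w_y``'s first nonzero entry is positive, and
    ``w_x`` is flipped so that corr(x_hat, y_hat) is nonnegative, making
    the output deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2:
        raise ValidationError("cca inputs must be 2-D (variables x samples)")
    if X.shape[1] != Y.shape[1]:
        raise ValidationError(
            f"sample-count mismatch: X has {X.shape[1]} columns, Y has {Y.shape[1]}"
        )
    i = X.shape[1]
    if i < 2:
        raise ValidationError("need at least 2 samples per variable")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValidationError("inputs must be finite")
    if ridge < 0:
        raise ValidationError("ridge must be nonnegative")

    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if ridge == 0:
        for name, Z in (("X", Xc), ("Y", Yc)):
            if np.any((Z**2).sum(axis=1) == 0):
                raise SingularityError(
                    f"{name} has a constant (zero-variance) row and ridge=0; "
                    "set ridge > 0 to regularize"
                )

    Ux, dx, bx, Vtx = _whiten(Xc, ridge)
    Uy, dy, by, Vty = _whiten(Yc, ridge)

    # Whitened cross-covariance in the (Ux, Uy) bases.
    M = (dx[:, None] * (Vtx @ Vty.T)) * dy[None, :]
    U, s, Vt = np.linalg.svd(M)
    n_pairs = min(X.shape[0], Y.shape[0])
    all_rhos = np.zeros(n_pairs)
    k = min(s.size, n_pairs)
    all_rhos[:k] = np.clip(s[:k], 0.0, 1.0)

    w_x = Ux @ (bx * U[:, 0])
    w_y = Uy @ (by * Vt[0, :])

    nz = np.nonzero(np.abs(w_y) > 1e-12 * (np.abs(w_y).max() or 1.0))[0]
    if nz.size and w_y[nz[0]] < 0:
        w_y = -w_y
    x_hat = w_x @ Xc
    y_hat = w_y @ Yc
    c = float(x_hat @ y_hat)
    if c < 0:
        w_x = -w_x
        x_hat = -x_hat

    def _unitvar(v):
        sd = v.std(ddof=1)
        return v / sd if sd > 0 else v

    return CCAResult(
        rho=float(all_rhos[0]),
        w_x=w_x,
        w_y=w_y,
        x_hat=_unitvar(x_hat),
        y_hat=_unitvar(y_hat),
        all_rhos=all_rhos,
    )
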