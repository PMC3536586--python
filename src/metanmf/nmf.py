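"""Nonnegative matrix factorization by alternating nonnegative least squares.

Factors a nonnegative expression matrix ``V`` (genes x samples) into
``V ~ W @ H`` with ``W >= 0`` (genes x k, the metagene loadings) and
``H >= 0`` (k x samples, the encoding coefficients).  Each alternating
subproblem -- least squares in one factor with the other held fixed -- is
solved by projected gradient descent with an Armijo step-size search along
the projection arc (Lin's method), which guarantees the reconstruction
objective never increases across accepted steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Factorization", "pg_nnls", "factorize", "reconstruction_error"]

# Armijo search parameters: step-size shrink factor and sufficient-decrease
# coefficient, with a cap on step-size trials per gradient step.
_BETA = 0.1
_SIGMA = 0.01
_MAX_STEP_TRIALS = 20


@dataclass
class Factorization:
    """Result of a single NMF run.

    Attributes
    ----------
    W : ndarray, shape (n_genes, k)
        Nonnegative loading matrix; column j is metagene j, entry ``W[i, j]``
        the coefficient of gene i in metagene j.
    H : ndarray, shape (k, n_samples)
        Nonnegative encoding matrix; ``H[i, j]`` is the activity of
        metagene i in sample j.
    objective : float
        Final squared Frobenius reconstruction error ``||V - W H||_F^2``.
    n_iter : int
        Outer (alternating) iterations performed.
    seed : int
        Seed used for the random-uniform initialization.
    objective_trace : list of float
        Objective after each outer iteration (nonincreasing).
    """

    W: np.ndarray
    H: np.ndarray
    objective: float
    n_iter: int
    seed: int
    objective_trace: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return self.W.shape[1]


def reconstruction_error(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Frobenius norm ``||V - W @ H||_F`` of the reconstruction residual."""
    V = np.asarray(V, dtype=float)
    return float(np.linalg.norm(V - np.asarray(W) @ np.asarray(H), "fro"))


def _nls_subproblem(
    AtA: np.ndarray,
    AtV: np.ndarray,
    X0: np.ndarray,
    tol: float,
    max_inner: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Minimize 0.5||V - A X||_F^2 over X >= 0 by projected gradient.

    Works entirely from the Gram matrix ``A'A`` and cross product ``A'V``.
    Returns (X, gradient at X, iterations used).  Terminates when the norm
    of the projected gradient falls below ``tol``.
    """
    X = X0.copy()
    alpha = 1.0
    grad = AtA @ X - AtV
    n_iter = 0
    for n_iter in range(1, max_inner + 1):
        grad = AtA @ X - AtV
        proj_norm = np.linalg.norm(grad[(grad < 0) | (X > 0)])
        if proj_norm <= tol:
            break
        # Armijo search along the projection arc: find a step size whose
        # projected point achieves sufficient decrease of the quadratic.
        Xp = X
        decrease_alpha = False
        for trial in range(_MAX_STEP_TRIALS):
            Xn = np.maximum(X - alpha * grad, 0.0)
            d = Xn - X
            gradd = float(np.sum(grad * d))
            dQd = float(np.sum((AtA @ d) * d))
            sufficient = (1.0 - _SIGMA) * gradd + 0.5 * dQd <= 0.0
            if trial == 0:
                decrease_alpha = not sufficient
                Xp = X
            if decrease_alpha:
                if sufficient:
                    X = Xn
                    break
                alpha *= _BETA
            else:
                if (not sufficient) or np.array_equal(Xn, Xp):
                    X = Xp
                    break
                alpha /= _BETA
                Xp = Xn
        else:
            X = Xp
    return X, grad, n_iter


def pg_nnls(
    A: np.ndarray,
    V_block: np.ndarray,
    X0: np.ndarray,
    tol: float = 1e-8,
    max_inner: int = 1000,
) -> np.ndarray:
    """Nonnegative least squares: minimize ``0.5 ||V_block - A X||_F^2``, X >= 0.

    Projected-gradient solve with Armijo step-size search along the
    projection arc.  The objective never increases across accepted steps.

    Parameters
    ----------
    A : (m, r) fixed factor matrix.
    V_block : (m, c) target matrix.
    X0 : (r, c) nonnegative starting point.
    tol : termination threshold on the projected-gradient norm.
    max_inner : iteration cap.
    """
    A = np.asarray(A, dtype=float)
    V_block = np.asarray(V_block, dtype=float)
    X0 = np.asarray(X0, dtype=float)
    for name, M in (("A", A), ("V_block", V_block), ("X0", X0)):
        if not np.all(np.isfinite(M)):
            raise ValueError(f"non-finite values in {name}")
    if X0.min(initial=0.0) < 0:
        raise ValueError("X0 must be nonnegative")
    if A.shape[0] != V_block.shape[0] or A.shape[1] != X0.shape[0]:
        raise ValueError(
            f"incompatible shapes: A {A.shape}, V_block {V_block.shape}, X0 {X0.shape}"
        )
    X, _, _ = _nls_subproblem(A.T @ A, A.T @ V_block, X0, tol, max_inner)
    return X


def _projected_gradient_norm(gradW, W, gradH, H) -> float:
    gw = gradW[(gradW < 0) | (W > 0)]
    gh = gradH[(gradH < 0) | (H > 0)]
    return float(np.sqrt(np.sum(gw**2) + np.sum(gh**2)))


def factorize(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_outer: int = 500,
    max_inner: int = 1000,
    W0: np.ndarray | None = None,
    H0: np.ndarray | None = None,
) -> Factorization:
    """Factor a nonnegative matrix as ``V ~ W @ H`` at rank ``k``.

    W and H are initialized Uniform(0, 1] scaled by ``sqrt(mean(V) / k)``
    (or taken from ``W0``/``H0`` when given, e.g. for warm starts)
    and refined by alternating projected-gradient nonnegative least squares.
    The run stops when the total projected-gradient norm drops below
    ``tol`` times its initial value, or after ``max_outer`` alternations.
    A fixed seed reproduces the result bit-for-bit.

    Raises
    ------
    ValueError
        If ``V`` has negative entries (the offending minimum is named) or
        ``k`` is not in ``[1, min(V.shape))``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    vmin = float(V.min())
    if vmin < 0:
        raise ValueError(f"V must be nonnegative; minimum entry is {vmin}")
    n, p = V.shape
    if not 1 <= k < min(n, p):
        raise ValueError(f"k={k} must satisfy 1 <= k < min{(n, p)}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    if (W0 is None) != (H0 is None):
        raise ValueError("provide both W0 and H0 or neither")
    if W0 is not None:
        W = np.array(W0, dtype=float)
        H = np.array(H0, dtype=float)
        if W.shape != (n, k) or H.shape != (k, p):
            raise ValueError("W0/H0 shapes do not match V and k")
        if W.min() < 0 or H.min() < 0:
            raise ValueError("W0 and H0 must be nonnegative")
    else:
        # Uniform(0, 1]: avoids exactly-zero entries at initialization.
        W = (1.0 - rng.random((n, k))) * scale
        H = (1.0 - rng.random((k, p))) * scale

    gradW = W @ (H @ H.T) - V @ H.T
    gradH = (W.T @ W) @ H - W.T @ V
    init_grad = float(np.sqrt(np.sum(gradW**2) + np.sum(gradH**2)))
    tolW = max(1e-3, tol) * init_grad
    tolH = tolW

    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        proj_norm = _projected_gradient_norm(gradW, W, gradH, H)
        if proj_norm <= tol * init_grad:
            n_iter -= 1
            break
        # W-subproblem: min ||V' - H' W'||^2 over W' >= 0.
        Wt, gradWt, iterW = _nls_subproblem(H @ H.T, H @ V.T, W.T, tolW, max_inner)
        W, gradW = Wt.T, gradWt.T
        if iterW == 1:
            tolW *= 0.1
        # H-subproblem.
        H, gradH, iterH = _nls_subproblem(W.T @ W, W.T @ V, H, tolH, max_inner)
        if iterH == 1:
            tolH *= 0.1

        # Dead metagenes (all-zero column/row) are re-seeded with a trace of
        # uniform noise so they can re-enter the fit on degenerate inputs.
        dead_cols = ~W.any(axis=0)
        if dead_cols.any():
            warnings.warn(f"re-seeding {int(dead_cols.sum())} zero column(s) of W")
            W[:, dead_cols] = rng.random((n, int(dead_cols.sum()))) * (1e-6 * scale)
        dead_rows = ~H.any(axis=1)
        if dead_rows.any():
            warnings.warn(f"re-seeding {int(dead_rows.sum())} zero row(s) of H")
            H[dead_rows, :] = rng.random((int(dead_rows.sum()), p)) * (1e-6 * scale)

        trace.append(reconstruction_error(V, W, H) ** 2)

    objective = reconstruction_error(V, W, H) ** 2
    return Factorization(
        W=W, H=H, objective=objective, n_iter=n_iter, seed=seed, objective_trace=trace
    )
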