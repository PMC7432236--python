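"""Low-rank tensor-approximation surrogate of indoor SAR.

A multivariate response Y(X), X in R^M, is approximated as a finite sum of
rank-one functions,

    Y(X) ~ sum_{l=1..R} b_l * prod_{i=1..M} v_l^(i)(X_i),

each univariate factor v_l^(i) expanded on orthonormal Legendre polynomials
of the input scaled to [-1, 1].  Coefficients are estimated greedily rank by
rank: each rank-one term is fitted to the current residual by alternating
least squares over the input dimensions (holding all but one dimension
fixed turns the problem into an ordinary linear LS), and after each new
term the normalizing constants b_l are re-estimated jointly by a final LS
on the accumulated rank-one terms.

The class follows the model/results convention:
``LowRankSurrogate(X0, Y0, rank=5, degree=4).fit()`` returns an
:class:`LraResults` carrying coefficients, training diagnostics,
``predict`` and a portable JSON serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .exceptions import UnderdeterminedDesignError

__all__ = ["LowRankSurrogate", "LraResults"]


def _scale(X: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Affine map of each input column from [lo, hi] to [-1, 1]."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    return 2.0 * (X - lo) / (hi - lo) - 1.0


def _basis(u: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal Legendre design matrix, shape (n, degree + 1).

    phi_k = sqrt(2k + 1) P_k, orthonormal for the uniform measure on
    [-1, 1] (density 1/2).
    """
    n = len(u)
    out = np.empty((n, degree + 1))
    for k in range(degree + 1):
        c = np.zeros(k + 1)
        c[k] = np.sqrt(2.0 * k + 1.0)
        out[:, k] = legendre.legval(u, c)
    return out


class LowRankSurrogate:
    """Greedy-ALS low-rank surrogate model of an experimental set (X0, Y0).

    Parameters
    ----------
    X : (N, M) array
        Experimental designs.
    Y : (N,) array
        Responses (e.g. whole-body SAR, mW/kg).
    rank : int
        Number R of rank-one terms.
    degree : int
        Legendre degree per univariate factor (default 4).
    bounds : (M, 2) array, optional
        Input-domain bounds; defaults to the per-column min/max of X.
    """

    def __init__(self, X, Y, rank: int, degree: int = 4, bounds=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float).ravel()
        if rank < 1:
            raise ValueError("rank must be >= 1")
        n, m = X.shape
        n_coef = m * (degree + 1)
        if n < n_coef:
            raise UnderdeterminedDesignError(
                f"N={n} designs cannot determine {n_coef} coefficients per rank-one term"
            )
        if bounds is None:
            bounds = np.column_stack([X.min(axis=0), X.max(axis=0)])
        self.X, self.Y = X, Y
        self.rank, self.degree = rank, degree
        self.bounds = np.asarray(bounds, dtype=float)

    @staticmethod
    def _als_term(Phi, resid, c, max_sweeps, tol, y_scale):
        """Fit one rank-one term to the residual by alternating LS.

        Returns (relative error, coefficients, rank-one values, converged).
        """
        m = len(Phi)
        v = np.column_stack([Phi[i] @ c[i] for i in range(m)])
        last = np.inf
        err = np.inf
        ok = False
        for _ in range(max_sweeps):
            for i in range(m):
                partial = np.prod(np.delete(v, i, axis=1), axis=1)
                A = Phi[i] * partial[:, None]
                ci, *_ = np.linalg.lstsq(A, resid, rcond=None)
                nrm = np.linalg.norm(ci)
                if nrm > 0:
                    ci /= nrm
                c[i] = ci
                v[:, i] = Phi[i] @ ci
            w = np.prod(v, axis=1)
            ww = float(w @ w)
            beta = float(w @ resid) / ww if ww > 0 else 0.0
            err = float(np.sqrt(np.mean((resid - w * beta) ** 2))) / y_scale
            # converged when the error stalls or hits machine precision
            if err < 1e-14 or abs(last - err) <= tol * max(err, 1e-300):
                ok = True
                break
            last = err
        return err, c, np.prod(v, axis=1), ok

    def fit(
        self,
        tol: float = 1e-8,
        max_sweeps: int = 100,
        n_starts: int = 7,
        correction_sweeps: int = 5,
    ) -> "LraResults":
        """Estimate all coefficients; returns the fitted results object.

        Each rank-one term is fitted to the running residual by alternating
        LS from ``n_starts`` deterministic initializations (the constant
        function plus seeded random coefficient vectors), keeping the start
        with the lowest training error; sweeps stop when the relative
        change of the training RMSE drops below ``tol`` or after
        ``max_sweeps`` sweeps, and a non-converged term keeps its best
        iterate with the warning flag set.  After the greedy pass,
        ``correction_sweeps`` rounds re-optimize every term against the
        residual of the others (with a joint re-estimate of the b_l after
        each), which removes most of the greedy suboptimality.
        """
        X, Y = self.X, self.Y
        n, m = X.shape
        p1 = self.degree + 1
        U = _scale(X, self.bounds)
        Phi = [_basis(U[:, i], self.degree) for i in range(m)]

        coefs = np.zeros((self.rank, m, p1))
        b = np.zeros(self.rank)
        W = np.empty((n, self.rank))
        resid = Y.copy()
        converged = []
        y_scale = float(np.sqrt(np.mean(Y**2))) or 1.0
        for l in range(self.rank):
            best = None
            for start in range(n_starts):
                c = np.zeros((m, p1))
                if start == 0:
                    c[:, 0] = 1.0  # the constant function
                else:
                    rs = np.random.default_rng(1000 * l + start)
                    c[:] = rs.standard_normal((m, p1))
                    c /= np.linalg.norm(c, axis=1, keepdims=True)
                err, cc, w, ok = self._als_term(
                    Phi, resid, c, max_sweeps, tol, y_scale
                )
                if best is None or err < best[0]:
                    best = (err, cc, w, ok)
            if not best[3]:
                warnings.warn(
                    f"rank-one term {l + 1} did not converge in {max_sweeps} sweeps",
                    stacklevel=2,
                )
            converged.append(best[3])
            coefs[l] = best[1]
            W[:, l] = best[2]
            # joint re-estimation of the normalizing constants
            b[: l + 1], *_ = np.linalg.lstsq(W[:, : l + 1], Y, rcond=None)
            resid = Y - W[:, : l + 1] @ b[: l + 1]

        for _ in range(correction_sweeps):
            for l in range(self.rank):
                resid_l = Y - W @ b + b[l] * W[:, l]
                _, cc, w, _ = self._als_term(
                    Phi, resid_l, coefs[l].copy(), 20, tol, y_scale
                )
                coefs[l] = cc
                W[:, l] = w
                b, *_ = np.linalg.lstsq(W, Y, rcond=None)
        resid = Y - W @ b

        train_rmse = float(np.sqrt(np.mean(resid**2)))
        return LraResults(
            rank=self.rank,
            degree=self.degree,
            bounds=self.bounds,
            coefs=coefs,
            b=b,
            train_rel_rmse=train_rmse / y_scale,
            converged=converged,
            model=self,
        )


@dataclass
class LraResults:
    """Fitted low-rank surrogate: coefficients plus prediction machinery."""

    rank: int
    degree: int
    bounds: np.ndarray
    coefs: np.ndarray  # (rank, M, degree + 1)
    b: np.ndarray  # (rank,)
    train_rel_rmse: float
    converged: list[bool]
    model: LowRankSurrogate | None = None

    @property
    def n_inputs(self) -> int:
        return self.coefs.shape[1]

    def predict(self, X, check_domain: bool = True) -> np.ndarray:
        """Evaluate the finite sum of rank-one terms at X ((n, M) or (M,)).

        Points outside the training domain are evaluated anyway but trigger
        an extrapolation warning when ``check_domain`` is true.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} input columns, got {X.shape[1]}"
            )
        if check_domain and (
            np.any(X < self.bounds[:, 0] - 1e-12)
            or np.any(X > self.bounds[:, 1] + 1e-12)
        ):
            warnings.warn("surrogate evaluated outside its training domain",
                          stacklevel=2)
        U = _scale(X, self.bounds)
        out = np.zeros(len(X))
        for l in range(self.rank):
            w = np.ones(len(X))
            for i in range(self.n_inputs):
                w *= _basis(U[:, i], self.degree) @ self.coefs[l, i]
            out += self.b[l] * w
        return out

    def summary(self) -> str:
        lines = [
            "Low-rank tensor-approximation surrogate",
            "=" * 40,
            f"inputs M             : {self.n_inputs}",
            f"rank R               : {self.rank}",
            f"Legendre degree      : {self.degree}",
            f"training rel. RMSE   : {self.train_rel_rmse:.3e}",
            f"terms converged      : {sum(self.converged)}/{self.rank}",
            f"normalizing b        : {np.array2string(self.b, precision=4)}",
        ]
        return "\n".join(lines)

    # -- portable text serialization -------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "lra_surrogate",
            "rank": self.rank,
            "degree": self.degree,
            "basis": "legendre_orthonormal",
            "bounds": self.bounds.tolist(),
            "coefs": self.coefs.tolist(),
            "b": self.b.tolist(),
            "train_rel_rmse": self.train_rel_rmse,
            "converged": list(map(bool, self.converged)),
        }

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "LraResults":
        return cls(
            rank=int(d["rank"]),
            degree=int(d["degree"]),
            bounds=np.asarray(d["bounds"], dtype=float),
            coefs=np.asarray(d["coefs"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            train_rel_rmse=float(d["train_rel_rmse"]),
            converged=list(d["converged"]),
        )

    @classmethod
    def load(cls, path) -> "LraResults":
        with open(path) as f:
            return cls.from_dict(json.load(f))
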