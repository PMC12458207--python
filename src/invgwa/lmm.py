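"""Gaussian linear mixed model with a relatedness kernel, fitted by REML.

The model is ``y = X b + u + e`` with ``u ~ N(0, sg2 K)`` for a line x line
relatedness kernel ``K`` and ``e ~ N(0, se2 I)``. A single eigendecomposition
of ``K`` reduces every restricted-likelihood evaluation to O(n) in the
variance ratio ``lambda = sg2/se2``, which is profiled on a log grid and then
refined by bounded scalar optimization. Per-variant association uses the score
test at the null fit: ``U = g'Py``, ``Vs = g'Pg``, ``chi2 = U^2/Vs`` with one
degree of freedom, where ``P`` is the REML projection
``Vinv - Vinv X (X'Vinv X)^-1 X'Vinv``.

The module follows the Model/Results convention: construct a :class:`MixedLMM`
from data, call :meth:`~MixedLMM.fit`, and use the returned
:class:`MixedLMMResults` for projections, score scans and the summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .datatypes import GRM, DataValidationError

__all__ = ["MixedLMM", "MixedLMMResults", "score_scan"]


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the likelihood trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


class MixedLMM:
    """Linear mixed model ``y ~ X + kernel`` for one trait.

    Parameters
    ----------
    endog:
        Trait values per line (no missing entries; drop them first).
    exog:
        Fixed-effect design, including the intercept column.
    kernel:
        Relatedness kernel: a :class:`~invgwa.datatypes.GRM` (its cached
        eigendecomposition is reused) or a plain symmetric matrix.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        kernel: GRM | np.ndarray,
        exog_names: list[str] | None = None,
    ):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != len(self.y):
            raise DataValidationError("endog/exog length mismatch")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise DataValidationError("missing values in endog/exog; drop lines first")
        n, p = self.X.shape
        if np.linalg.matrix_rank(self.X) < p:
            raise DataValidationError("fixed-effect design is rank deficient")
        if isinstance(kernel, GRM):
            if kernel.matrix.shape[0] != n:
                raise DataValidationError("kernel size does not match endog")
            self.eigvals, self.eigvecs = kernel.eigendecomposition()
        else:
            K = np.asarray(kernel, dtype=float)
            if K.shape != (n, n):
                raise DataValidationError("kernel size does not match endog")
            self.eigvals, self.eigvecs = np.linalg.eigh(K)
        self.eigvals = np.maximum(self.eigvals, 0.0)
        self.exog_names = exog_names or [f"x{j}" for j in range(p)]
        self.y_rot = self.eigvecs.T @ self.y
        self.X_rot = self.eigvecs.T @ self.X
        # kernel proportional to identity => variance components confounded
        spread = self.eigvals.max() - self.eigvals.min() if n else 0.0
        self.confounded = spread <= 1e-10 * max(self.eigvals.max(), 1.0)

    # -- restricted likelihood profiled over the variance ratio ------------

    def _profile(self, lamb: float) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Restricted log-likelihood and GLS quantities at a variance ratio."""
        n, p = self.X.shape
        w = lamb * self.eigvals + 1.0
        wi = 1.0 / w
        XtWX = self.X_rot.T @ (wi[:, None] * self.X_rot)
        XtWy = self.X_rot.T @ (wi * self.y_rot)
        ytWy = float(self.y_rot @ (wi * self.y_rot))
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - float(beta @ XtWy)
        rss = max(rss, 1e-300)
        se2 = rss / (n - p)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        llf = -0.5 * (
            (n - p) * np.log(se2)
            + np.log(w).sum()
            + logdet_XtWX
            + (n - p)
        )
        return llf, se2, beta, XtWX

    def fit(
        self,
        lamb: float | None = None,
        grid: np.ndarray | None = None,
        tol: float = 1e-8,
    ) -> "MixedLMMResults":
        """REML fit. ``lamb`` fixes the variance ratio (e.g. 0 for pure OLS);
        otherwise it is profiled on ``grid`` (default ``0`` plus a log grid
        over 1e-4..1e4) and refined with bounded Brent search."""
        trace: list[tuple[float, float]] = []
        if self.confounded and lamb is None:
            lamb = 0.0
        if lamb is None:
            if grid is None:
                grid = np.concatenate([[0.0], np.logspace(-4, 4, 17)])
            lls = []
            for lv in grid:
                ll = self._profile(lv)[0]
                lls.append(ll)
                trace.append((float(lv), float(ll)))
            best = int(np.argmax(lls))
            if not np.isfinite(lls[best]):
                raise ConvergenceError("restricted likelihood not finite on grid", trace)
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, len(grid) - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda lv: -self._profile(lv)[0],
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": tol * max(1.0, grid[best])},
                )
                lamb_hat = float(res.x)
                if -res.fun >= lls[best]:
                    lamb = lamb_hat
                else:
                    lamb = float(grid[best])
            else:
                lamb = float(grid[best])
        lamb = max(float(lamb), 0.0)
        llf, se2, beta, XtWX = self._profile(lamb)
        cov_beta = se2 * np.linalg.inv(XtWX)
        return MixedLMMResults(
            model=self,
            lamb=lamb,
            sigma_g2=lamb * se2,
            sigma_e2=se2,
            params=beta,
            cov_params=cov_beta,
            llf=llf,
            boundary=(lamb == 0.0),
            confounded=self.confounded,
        )


@dataclass
class MixedLMMResults:
    """REML fit of a :class:`MixedLMM`; exposes the projection operator and
    vectorized score tests."""

    model: MixedLMM
    lamb: float
    sigma_g2: float
    sigma_e2: float
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    boundary: bool
    confounded: bool
    _py: np.ndarray | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def _weights(self) -> np.ndarray:
        """Inverse marginal variance in the eigenbasis: 1/(se2 (lamb d + 1))."""
        return 1.0 / (self.sigma_e2 * (self.lamb * self.model.eigvals + 1.0))

    def apply_P(self, v: np.ndarray) -> np.ndarray:
        """Apply the REML projection P to a line-indexed vector."""
        m = self.model
        wr = self._weights()
        v_rot = m.eigvecs.T @ np.asarray(v, dtype=float)
        Wv = wr * v_rot
        XtWX = m.X_rot.T @ (wr[:, None] * m.X_rot)
        XtWv = m.X_rot.T @ Wv
        corr = (wr[:, None] * m.X_rot) @ np.linalg.solve(XtWX, XtWv)
        return m.eigvecs @ (Wv - corr)

    @property
    def Py(self) -> np.ndarray:
        if self._py is None:
            self._py = self.apply_P(self.model.y)
        return self._py

    def score_tests(
        self, G: np.ndarray, G_rot: np.ndarray | None = None
    ) -> pd.DataFrame:
        """Score test of every column of ``G`` against this null fit.

        ``G`` must already be aligned to the model's lines with missing
        dosages imputed; pass ``G_rot = eigvecs.T @ G`` to reuse a cached
        rotation across traits and permutations. Columns with non-positive
        score variance are flagged ``skipped``.
        """
        m = self.model
        if G_rot is None:
            G_rot = m.eigvecs.T @ np.asarray(G, dtype=float)
        wr = self._weights()
        resid_rot = m.y_rot - m.X_rot @ self.params
        U = G_rot.T @ (wr * resid_rot)
        WG = wr[:, None] * G_rot
        gVg = np.einsum("ij,ij->j", G_rot, WG)
        A = m.X_rot.T @ WG  # p x m
        XtWX = m.X_rot.T @ (wr[:, None] * m.X_rot)
        MA = np.linalg.solve(XtWX, A)
        Vs = gVg - np.einsum("ij,ij->j", A, MA)
        ok = Vs > 1e-12
        chi2 = np.full(len(Vs), np.nan)
        chi2[ok] = U[ok] ** 2 / Vs[ok]
        p = np.full(len(Vs), np.nan)
        # chi2_1 upper tail: sf(x) = erfc(sqrt(x/2)) (faster than stats.chi2.sf)
        p[ok] = special.erfc(np.sqrt(chi2[ok] / 2.0))
        beta = np.full(len(Vs), np.nan)
        se = np.full(len(Vs), np.nan)
        beta[ok] = U[ok] / Vs[ok]
        se[ok] = 1.0 / np.sqrt(Vs[ok])
        return pd.DataFrame(
            {"score": U, "variance": Vs, "chi2": chi2, "p": p, "beta": beta,
             "se": se, "skipped": ~ok}
        )

    def summary(self) -> str:
        """Plain-text summary of the variance components and fixed effects."""
        lines = [
            "Mixed LMM (REML)",
            "=" * 44,
            f"n obs            {len(self.model.y):>10d}",
            f"sigma_g^2        {self.sigma_g2:>10.4f}",
            f"sigma_e^2        {self.sigma_e2:>10.4f}",
            f"lambda (sg2/se2) {self.lamb:>10.4f}",
            f"REML loglik      {self.llf:>10.3f}",
        ]
        if self.boundary:
            lines.append("note: sigma_g^2 at the zero boundary")
        if self.confounded:
            lines.append("note: kernel ~ identity; variance components confounded")
        lines.append("-" * 44)
        lines.append(f"{'effect':<16}{'coef':>10}{'se':>10}")
        for name, b, s in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"{name:<16}{b:>10.4f}{s:>10.4f}")
        return "\n".join(lines)


def score_scan(results: MixedLMMResults, G: np.ndarray, G_rot: np.ndarray | None = None) -> pd.DataFrame:
    """Module-level convenience wrapper around ``results.score_tests``."""
    return results.score_tests(G, G_rot=G_rot)
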