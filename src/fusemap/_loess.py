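"""Local polynomial regression (LOESS) with tricube weights.

Degree-1 or degree-2 fits with a span given as the fraction of points
entering each local neighbourhood — the classic Cleveland smoother,
without robustness iterations; degree 2 (the R ``loess`` default) is
the package default since it tracks the sharp genotype transitions of
backcross data far better than local lines.  Unlike library one-shot
smoothers this keeps the fit re-usable: it predicts at arbitrary
positions (needed to interpolate windows with no data) and exposes
pointwise standard errors for confidence ribbons.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LoessFit", "loess_fit"]


class LoessFit:
    """A fitted local-linear smoother.

    Parameters
    ----------
    x, y : arrays of the training points (finite values only).
    span : fraction of points in each local neighbourhood, in (0, 1].
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, span: float, degree: int = 2, weights: np.ndarray | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        w_obs = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        if w_obs.shape != x.shape or np.any(w_obs < 0):
            raise ValueError("weights must be non-negative and match x")
        keep = np.isfinite(x) & np.isfinite(y) & (w_obs > 0)
        x, y, w_obs = x[keep], y[keep], w_obs[keep]
        if x.size < 3:
            raise ValueError("need at least 3 finite points to fit a LOESS curve")
        if not (0.0 < span <= 1.0):
            raise ValueError(f"span must be in (0, 1], got {span}")
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]
        self.w_obs = w_obs[order]
        self.span = span
        self.degree = degree
        # residual scale for standard errors, estimated from the fit itself
        fitted, _ = self._predict_raw(self.x)
        resid = self.y - fitted
        dof = max(self.x.size - 2.0, 1.0)
        self._sigma2 = float(np.sum(resid**2) / dof)

    # number of points per neighbourhood, >= 2 for a linear fit
    @property
    def _q(self) -> int:
        return max(2, int(np.ceil(self.span * self.x.size)))

    def _predict_raw(self, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fitted value and the squared norm of the equivalent kernel at x0."""
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        q = self._q
        n = self.x.size
        out = np.empty(x0.size)
        lnorm2 = np.empty(x0.size)
        for i, xi in enumerate(x0):
            d = np.abs(self.x - xi)
            # q-nearest-neighbour bandwidth, as in Cleveland's tracking window
            h = np.partition(d, q - 1)[q - 1]
            if h == 0.0:
                # all q nearest points coincide with xi: average them
                sel = d == 0.0
                out[i] = float(np.mean(self.y[sel]))
                lnorm2[i] = 1.0 / np.count_nonzero(sel)
                continue
            u = np.clip(d / h, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
            if q < n:
                w[d / h >= 1.0] = 0.0
            w = w * self.w_obs
            xc = self.x - xi
            # weighted polynomial fit; the fitted value at xi is the
            # intercept, and its equivalent kernel gives the variance
            cols = [np.ones_like(xc), xc] if self.degree == 1 else [np.ones_like(xc), xc, xc**2]
            X = np.column_stack(cols)
            XtW = X.T * w
            A = XtW @ X
            try:
                first_row = np.linalg.solve(A, np.eye(self.degree + 1))[0]
            except np.linalg.LinAlgError:
                first_row = np.linalg.pinv(A)[0]
            l_i = first_row @ XtW
            out[i] = float(np.dot(l_i, self.y))
            lnorm2[i] = float(np.dot(l_i, l_i))
        return out, lnorm2

    def predict(self, x0) -> np.ndarray:
        """Smoothed values at positions ``x0``."""
        fitted, _ = self._predict_raw(x0)
        return fitted if np.ndim(x0) else float(fitted[0])

    def predict_with_se(self, x0) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed values and pointwise standard errors at ``x0``."""
        fitted, lnorm2 = self._predict_raw(x0)
        se = np.sqrt(self._sigma2 * lnorm2)
        return fitted, se


def loess_fit(x, y, span: float, degree: int = 2, weights=None) -> LoessFit:
    """Fit a tricube local-polynomial smoother; see :class:`LoessFit`."""
    return LoessFit(np.asarray(x), np.asarray(y), span, degree=degree, weights=weights)
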