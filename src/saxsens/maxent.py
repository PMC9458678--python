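"""Maximum-entropy ensemble reweighting with a θ-controlled KL penalty.

Starting from reference weights w⁰ (uniform for an unbiased simulation
ensemble), the refined weights minimise the negative log-posterior

    L(w) = θ S_KL(w ‖ w⁰) + χ²(w) / 2,
    S_KL = Σₖ wₖ ln(wₖ / wₖ⁰),

where χ²(w) compares the ensemble-average profile c·Σ wₖ Iₖ(q) with the
experimental curve on its error bars and c is a nuisance scale re-estimated
between optimisation rounds.  θ expresses confidence in the reference
ensemble: θ → ∞ returns w⁰, θ → 0 gives the unregularised least-squares
ensemble.  A θ-scan traces the (S_KL, χ²_red) L-curve whose
maximum-curvature elbow balances fit quality against perturbation; any
constant factor convention inside χ² only rescales θ.

The minimisation runs unconstrained in log-weight coordinates
(w = softmax(a)) with the analytic gradient and L-BFGS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .saxs_forward import ScatteringCurve, optimal_scale

__all__ = [
    "MaxEntModel",
    "MaxEntResults",
    "LCurve",
    "kl_divergence",
    "neg_log_posterior",
    "optimize_weights",
    "theta_scan",
    "select_elbow",
    "significant_conformers",
]


def kl_divergence(w, w0) -> float:
    """Relative entropy S_KL = Σ wₖ ln(wₖ/wₖ⁰); 0·ln 0 = 0.

    Infinite divergence (support of w outside that of w⁰) is an error.
    """
    w = np.asarray(w, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if w.shape != w0.shape:
        raise ValueError("weight vectors differ in length")
    for v, name in ((w, "w"), (w0, "w0")):
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not on the probability simplex")
    if np.any((w0 <= 0) & (w > 0)):
        raise ValueError("infinite divergence: w has mass where w0 is zero")
    pos = w > 0
    return float(np.sum(w[pos] * np.log(w[pos] / w0[pos])))


class MaxEntModel:
    """KL-regularised weight refinement of a conformer ensemble.

    Parameters
    ----------
    profiles
        Per-conformer scattering profiles on the experimental grid: list of
        ScatteringCurve or a (K, n_q) intensity matrix.
    experiment
        Experimental curve with errors.
    w0
        Reference weights (uniform by default).
    """

    def __init__(self, profiles, experiment: ScatteringCurve, w0=None):
        if isinstance(profiles, (list, tuple)):
            for p in profiles:
                if not p.same_grid(experiment):
                    raise ValueError("profile grid differs from experiment")
            self.B = np.stack([p.I for p in profiles])
        else:
            self.B = np.atleast_2d(np.asarray(profiles, dtype=float))
        if experiment.sigma is None:
            raise ValueError("experimental curve lacks error estimates")
        if self.B.shape[1] != len(experiment):
            raise ValueError("profiles and experiment are on different q grids")
        self.experiment = experiment
        k = self.B.shape[0]
        self.w0 = np.full(k, 1.0 / k) if w0 is None else np.asarray(w0, dtype=float)
        if len(self.w0) != k:
            raise ValueError("w0 length mismatch")
        if np.any(self.w0 <= 0) or abs(self.w0.sum() - 1.0) > 1e-6:
            raise ValueError("w0 must be strictly positive and sum to 1")

    @property
    def k(self) -> int:
        return self.B.shape[0]

    def chi2(self, w, c: float | None = None) -> float:
        I_comp = np.asarray(w, float) @ self.B
        exp = self.experiment
        if c is None:
            c = optimal_scale(I_comp, exp.I, exp.sigma)
        r = (exp.I - c * I_comp) / exp.sigma
        return float((r ** 2).sum())

    def neg_log_posterior(self, w, theta: float, c: float | None = None) -> float:
        """L = θ·S_KL + χ²/2 at fixed (or re-estimated) nuisance scale c."""
        return theta * kl_divergence(w, self.w0) + 0.5 * self.chi2(w, c=c)

    # -- inner optimisation in log-weight coordinates -----------------------

    def _objective(self, a, theta, c=None):
        """L and its gradient in log-weight coordinates.

        With ``c=None`` the nuisance scale is profiled out analytically at
        every evaluation; by the envelope theorem the gradient formula with
        c at its optimum remains exact.
        """
        a = a - a.max()
        e = np.exp(a)
        w = e / e.sum()
        I_comp = w @ self.B
        exp = self.experiment
        if c is None:
            c = optimal_scale(I_comp, exp.I, exp.sigma)
        r = (exp.I - c * I_comp) / exp.sigma
        skl_terms = w * (np.log(np.maximum(w, 1e-300)) - np.log(self.w0))
        L = theta * skl_terms.sum() + 0.5 * (r ** 2).sum()
        # dL/dw_k = theta (ln(w_k/w0_k) + 1) - c Σ_q r_q I_k(q)/σ_q
        g_w = theta * (np.log(np.maximum(w, 1e-300)) - np.log(self.w0) + 1.0) \
            - c * (self.B @ (r / exp.sigma))
        g_a = w * (g_w - float(g_w @ w))
        return L, g_a

    def fit(self, theta: float, outer_iterations: int = 10, w_init=None,
            tol: float = 1e-10) -> "MaxEntResults":
        """Minimise L at one θ, alternating with nuisance-scale re-estimation.

        Convergence is declared when the relative change of L between outer
        rounds falls below ``tol``; otherwise the best iterate is returned
        with ``converged = False``.
        """
        if theta < 0:
            raise ValueError("theta must be non-negative")
        if self.k < 2:
            raise ValueError("ensemble refinement needs at least two conformers")
        w = self.w0.copy() if w_init is None else np.asarray(w_init, dtype=float)
        w = np.clip(w, 1e-12, None)
        w /= w.sum()
        a = np.log(w)
        L_prev, n_it, converged = np.inf, 0, False
        for _ in range(outer_iterations):
            res = minimize(self._objective, a, args=(theta, None), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
            a = res.x - res.x.max()
            e = np.exp(a)
            w = e / e.sum()
            n_it += res.nit
            L = self.neg_log_posterior(w, theta)
            if np.isfinite(L_prev) and abs(L_prev - L) <= tol * max(abs(L_prev), 1.0):
                converged = True
                L_prev = L
                break
            L_prev = L
        chi2 = self.chi2(w)
        n = len(self.experiment)
        return MaxEntResults(
            model=self, theta=float(theta), weights=w, w0=self.w0.copy(),
            s_kl=kl_divergence(w, self.w0), chi2=chi2, chi2_red=chi2 / n,
            iterations=n_it, converged=converged,
        )

    def fit_theta_scan(self, thetas=None, outer_iterations: int = 10,
                       selected_theta: float | None = None,
                       elbow_method: str = "plateau") -> "LCurve":
        """Fit along a θ grid (warm-started) and pick the L-curve elbow.

        The grid is traversed from the largest θ (solution near w⁰) downward,
        each fit warm-started from the previous one.  The elbow is picked by
        :func:`select_elbow` (``elbow_method``) unless ``selected_theta``
        overrides it explicitly.
        """
        thetas = np.logspace(-2, 6, 13) if thetas is None else np.asarray(thetas, float)
        if np.any(thetas <= 0):
            raise ValueError("theta grid must be positive")
        order = np.argsort(thetas)[::-1]
        results: list[MaxEntResults | None] = [None] * len(thetas)
        w = None
        for idx in order:
            res = self.fit(thetas[idx], outer_iterations=outer_iterations, w_init=w)
            results[idx] = res
            w = res.weights
        results = [r for _, r in sorted(zip(thetas, results), key=lambda t: t[0])]
        if selected_theta is not None:
            best = min(results, key=lambda r: abs(np.log(r.theta / selected_theta)))
        else:
            i = select_elbow([r.s_kl for r in results], [r.chi2_red for r in results],
                             method=elbow_method)
            best = results[i]
        return LCurve(results=results, selected=best)


@dataclass
class MaxEntResults:
    """One converged (θ, w) point of the maximum-entropy refinement."""

    model: MaxEntModel
    theta: float
    weights: np.ndarray
    w0: np.ndarray
    s_kl: float
    chi2: float
    chi2_red: float
    iterations: int
    converged: bool

    def significant_conformers(self) -> np.ndarray:
        return significant_conformers(self.weights)

    def summary(self) -> str:
        sig = self.significant_conformers()
        return "\n".join([
            "Maximum-entropy ensemble refinement",
            f"  K = {self.model.k} conformers, theta = {self.theta:g}",
            f"  S_KL = {self.s_kl:.6g}",
            f"  chi2 = {self.chi2:.6g}, chi2_red = {self.chi2_red:.4g}",
            f"  iterations = {self.iterations}, converged = {self.converged}",
            f"  significant conformers (w > mean + std): {len(sig)}",
        ])

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "weights": self.weights.tolist(),
            "s_kl": self.s_kl,
            "chi2": self.chi2,
            "chi2_red": self.chi2_red,
            "iterations": self.iterations,
            "converged": self.converged,
        }


@dataclass
class LCurve:
    """θ-scan trace (θ, S_KL, χ²_red) with the selected compromise point."""

    results: list
    selected: MaxEntResults
    points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.array([[r.theta, r.s_kl, r.chi2_red] for r in self.results])

    def __len__(self) -> int:
        return len(self.results)

    @property
    def selected_theta(self) -> float:
        return self.selected.theta

    def to_dict(self) -> dict:
        return {
            "points": [
                {"theta": r.theta, "s_kl": r.s_kl, "chi2_red": r.chi2_red}
                for r in self.results
            ],
            "selected_theta": self.selected_theta,
        }


def select_elbow(s_kl, chi2_red, method: str = "plateau",
                 margin: float = 1.01, floor: float = 1e-12) -> int:
    """Index of the L-curve corner balancing fit quality and perturbation.

    ``method="plateau"`` (default) reads the corner along the residual
    branch: the largest-θ point whose χ²_red still lies within ``margin``
    (relative) of the scan minimum, i.e. the departure point of the
    minimal-χ² plateau.  This is stable even when the low-θ branch is
    nearly degenerate in χ².  The inputs must be ordered by increasing θ.

    ``method="curvature"`` takes the discrete maximum-curvature point of
    the (log χ²_red, log S_KL) polyline (central differences; S_KL values
    below ``floor`` are clipped before the log).  Sharp single-corner
    curves give the same answer for both methods.
    """
    c2 = np.asarray(chi2_red, float)
    n = len(c2)
    if n < 3:
        return n - 1
    if method == "plateau":
        within = np.flatnonzero(c2 <= c2.min() * margin)
        return int(within.max())
    if method != "curvature":
        raise ValueError(f"unknown elbow method {method!r}")
    x = np.log(np.maximum(c2, floor))
    y = np.log(np.maximum(np.asarray(s_kl, float), floor))
    curvature = np.full(n, -np.inf)
    for i in range(1, n - 1):
        dx1, dy1 = x[i] - x[i - 1], y[i] - y[i - 1]
        dx2, dy2 = x[i + 1] - x[i], y[i + 1] - y[i]
        cross = dx1 * dy2 - dy1 * dx2
        denom = (np.hypot(dx1, dy1) * np.hypot(dx2, dy2)
                 * np.hypot(dx1 + dx2, dy1 + dy2))
        if denom > 0:
            curvature[i] = abs(cross) / denom
    return int(np.argmax(curvature))


def significant_conformers(w) -> np.ndarray:
    """Indices with weight above mean + one (population) standard deviation.

    Uniform weights have zero spread and therefore no significant members
    (strict inequality).
    """
    w = np.asarray(w, dtype=float)
    if len(w) < 2:
        raise ValueError("need at least two weights")
    return np.flatnonzero(w > w.mean() + w.std())


# ---------------------------------------------------------------------------
# Functional front-ends


def neg_log_posterior(w, theta, profiles, exp: ScatteringCurve, w0=None) -> float:
    return MaxEntModel(profiles, exp, w0=w0).neg_log_posterior(w, theta)


def optimize_weights(theta, w0, profiles, exp: ScatteringCurve,
                     outer_iterations: int = 10) -> MaxEntResults:
    return MaxEntModel(profiles, exp, w0=w0).fit(theta, outer_iterations=outer_iterations)


def theta_scan(thetas, profiles, exp: ScatteringCurve, w0=None,
               selected_theta: float | None = None) -> LCurve:
    return MaxEntModel(profiles, exp, w0=w0).fit_theta_scan(
        thetas, selected_theta=selected_theta
    )
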