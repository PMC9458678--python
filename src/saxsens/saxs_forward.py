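"""Forward SAXS calculation and curve fitting.

The orientation-averaged scattering intensity of a rigid particle is computed
with the exact Debye double sum

    I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ) / (q rᵢⱼ),

with the i = j and q = 0 singularities replaced by their analytic limit 1, so
I(0) = (Σᵢ fᵢ(0))².  Computed curves are matched to experiment with a
multiplicative scale c (and optionally an additive constant accounting for
buffer-subtraction mismatch) by weighted least squares, and the quality of
fit is reported as χ² and the per-point reduced χ² = χ²/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .formfactors import scatterers_for

__all__ = [
    "ScatteringCurve",
    "FitResult",
    "debye_curve",
    "weighted_average_profile",
    "fit_to_experiment",
    "chi_square",
    "optimal_scale",
    "load_curve",
    "save_curve",
]

_GRID_TOL = 1e-9


@dataclass
class ScatteringCurve:
    """One-dimensional scattering curve: q (Å⁻¹), I(q), optional σ(q)."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.I.shape != self.q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(self.q < 0):
            raise ValueError("negative q value")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("non-positive sigma")

    def __len__(self) -> int:
        return len(self.q)

    def same_grid(self, other: "ScatteringCurve") -> bool:
        return len(self) == len(other) and np.allclose(
            self.q, other.q, rtol=0.0, atol=_GRID_TOL
        )

    def interpolated(self, q: np.ndarray) -> "ScatteringCurve":
        """Linear interpolation onto a new grid; extrapolation is an error."""
        q = np.asarray(q, dtype=float)
        if q.min() < self.q.min() - _GRID_TOL or q.max() > self.q.max() + _GRID_TOL:
            raise ValueError("requested grid extends beyond the measured range")
        I = np.interp(q, self.q, self.I)
        sig = np.interp(q, self.q, self.sigma) if self.sigma is not None else None
        return ScatteringCurve(q, I, sig, label=self.label)


@dataclass
class FitResult:
    """Scale/offset fit of a computed curve to experiment."""

    c: float
    constant: float
    chi2: float
    chi2_red: float
    n_points: int


def debye_curve(conf, q, form_factor_model: str = "unit",
                chunk: int = 64) -> ScatteringCurve:
    """Exact Debye-sum scattering curve of one conformer.

    ``form_factor_model`` selects unit, residue-bead or atomic (Cromer–Mann)
    form factors; the double sum is evaluated in q-chunks to bound memory.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or len(q) == 0:
        raise ValueError("invalid q grid")
    if np.any(q < 0):
        raise ValueError("negative q value")
    pos, fac = scatterers_for(conf, q, form_factor_model)
    if len(pos) == 0:
        raise ValueError("conformer has no scatterers")
    if len(pos) == 1:
        return ScatteringCurve(q, fac[0] ** 2, label=str(conf.id))

    r = pdist(pos)                      # n(n-1)/2 pair distances
    iu, ju = np.triu_indices(len(pos), k=1)
    I = np.empty_like(q)
    for lo in range(0, len(q), chunk):
        qs = q[lo : lo + chunk]
        # sinc handles the q r -> 0 limit exactly (np.sinc(x) = sin(pi x)/(pi x))
        sinc = np.sinc(np.outer(qs, r) / np.pi)
        fs = fac[:, lo : lo + chunk]
        cross = fs[iu] * fs[ju]         # (npairs, nq_chunk)
        I[lo : lo + chunk] = (fs ** 2).sum(axis=0) + 2.0 * (sinc * cross.T).sum(axis=1)
    return ScatteringCurve(q, I, label=str(conf.id))


def weighted_average_profile(weights, profiles) -> ScatteringCurve:
    """Pointwise convex combination I(w, q) = Σₖ wₖ Iₖ(q) of basis profiles."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(profiles):
        raise ValueError("one weight per profile required")
    if abs(weights.sum() - 1.0) > 1e-8 or np.any(weights < -1e-12):
        raise ValueError("weights must be non-negative and sum to 1")
    ref = profiles[0]
    for p in profiles[1:]:
        if not ref.same_grid(p):
            raise ValueError("profiles are not on a common q grid")
    I = np.sum([w * p.I for w, p in zip(weights, profiles)], axis=0)
    return ScatteringCurve(ref.q.copy(), I, label="ensemble average")


def optimal_scale(I_comp: np.ndarray, I_exp: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form least-squares scale c = (Σ I_exp I_comp/σ²)/(Σ I_comp²/σ²)."""
    w = 1.0 / np.asarray(sigma, float) ** 2
    return float((w * I_exp * I_comp).sum() / (w * I_comp ** 2).sum())


def chi_square(I_comp, I_exp, sigma, c: float = 1.0, constant: float = 0.0) -> float:
    r = (np.asarray(I_exp, float) - c * np.asarray(I_comp, float) - constant) / sigma
    return float((r ** 2).sum())


def fit_to_experiment(
    computed: ScatteringCurve,
    experimental: ScatteringCurve,
    fit_constant: bool = False,
) -> FitResult:
    """Fit a computed curve to experiment by weighted least squares.

    Without the constant the scale has the closed form above; with it, the
    two-parameter (c, constant) problem is solved through its normal
    equations.  χ² is evaluated on the experimental error bars.
    """
    if not computed.same_grid(experimental):
        raise ValueError("computed and experimental curves are on different q grids")
    if experimental.sigma is None:
        raise ValueError("experimental curve lacks error estimates")
    sig = experimental.sigma
    if fit_constant:
        a = np.stack([computed.I / sig, np.ones_like(sig) / sig], axis=1)
        b = experimental.I / sig
        (c, const), *_ = np.linalg.lstsq(a, b, rcond=None)
    else:
        c = optimal_scale(computed.I, experimental.I, sig)
        const = 0.0
    chi2 = chi_square(computed.I, experimental.I, sig, c=c, constant=const)
    n = len(experimental)
    return FitResult(float(c), float(const), chi2, chi2 / n, n)


def load_curve(path) -> ScatteringCurve:
    """Read a 3-column (q, I, σ) — or 2-column (q, I) — text table."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma, label=str(path))


def save_curve(curve: ScatteringCurve, path) -> None:
    cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
    header = "q(1/A) I(q)" + (" sigma" if curve.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header)
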