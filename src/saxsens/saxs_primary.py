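"""Primary SAXS analysis: Guinier fit, dimensionless Kratky plot, model P(r).

At low angle a globular particle obeys the Guinier law
I(q) ≈ I(0) exp(−q² Rg²/3), so ln I is linear in q² with slope −Rg²/3; the
fit range is iterated until q_max·Rg stays below a configurable limit
(1.3 by default, the usual convention for globular particles).  The
dimensionless Kratky transform (qRg)² I/I(0) vs qRg diagnoses globularity
against flexibility, with the globular Gaussian reference peaking at
(√3, 3/e) and the Debye random-coil reference rising to a plateau of 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .formfactors import scatterers_for
from .saxs_forward import ScatteringCurve

__all__ = [
    "GuinierFit",
    "PairDistribution",
    "guinier_fit",
    "kratky_dimensionless",
    "globular_reference",
    "coil_reference",
    "pr_from_model",
    "save_pr",
]


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_min: float
    q_max: float
    n_points: int
    rg_err: float
    i0_err: float

    @property
    def qrg_max(self) -> float:
        return self.q_max * self.rg


def _guinier_regression(q, I, sigma):
    """Weighted linear fit of ln I on q²; returns slope, intercept, errors."""
    x = q ** 2
    y = np.log(I)
    w = (I / sigma) ** 2 if sigma is not None else np.ones_like(y)
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    delta = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / delta
    intercept = (swxx * swy - swx * swxy) / delta
    var_slope = sw / delta
    var_intercept = swxx / delta
    return slope, intercept, np.sqrt(var_slope), np.sqrt(var_intercept)


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3,
                min_points: int = 5, start_points: int = 20) -> GuinierFit:
    """Iterated Guinier fit at low q.

    Starts from the lowest ``start_points`` usable points and expands while
    the constraint q_max·Rg ≤ ``qrg_limit`` holds (shrinking first if the
    initial window already violates it).  The first non-positive intensity
    truncates the usable range.  A non-negative slope anywhere in the final
    window (no Guinier decay) is an error unless the curve is flat, for
    which Rg = 0 is returned.
    """
    nonpos = np.flatnonzero(curve.I <= 0)
    usable = nonpos[0] if len(nonpos) else len(curve)
    q, I = curve.q[:usable], curve.I[:usable]
    sig = curve.sigma[:usable] if curve.sigma is not None else None
    if usable < min_points:
        raise ValueError("too few usable points for a Guinier fit")

    def fit_first(n):
        s = slice(0, n)
        slope, icpt, s_err, i_err = _guinier_regression(
            q[s], I[s], sig[s] if sig is not None else None
        )
        if slope > 1e-12:
            raise ValueError("positive Guinier slope: no Guinier region")
        rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
        return slope, icpt, s_err, i_err, rg

    n = min(start_points, usable)
    slope, icpt, s_err, i_err, rg = fit_first(n)
    # shrink while the window violates the q·Rg constraint
    while n > min_points and q[n - 1] * rg > qrg_limit:
        n -= 1
        slope, icpt, s_err, i_err, rg = fit_first(n)
    # expand while the next point would still satisfy it
    while n < usable and q[n] * rg <= qrg_limit:
        cand = fit_first(n + 1)
        if q[n] * cand[4] > qrg_limit:
            break
        n += 1
        slope, icpt, s_err, i_err, rg = cand
    i0 = float(np.exp(icpt))
    rg_err = float(1.5 * s_err / rg) if rg > 0 else float("nan")
    return GuinierFit(rg, i0, float(q[0]), float(q[n - 1]), n, rg_err, i0 * i_err)


def globular_reference(x):
    """Guinier-law reference for the dimensionless Kratky plot: x² exp(−x²/3)."""
    x = np.asarray(x, dtype=float)
    return x ** 2 * np.exp(-(x ** 2) / 3.0)


def coil_reference(x):
    """Debye random-coil reference 2/x²·[exp(−x²) + x² − 1], with f(0) = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 2.0 / xs ** 2 * (np.exp(-(xs ** 2)) + xs ** 2 - 1.0)
    out[small] = x[small] ** 2  # leading term of the series
    return out


def kratky_dimensionless(curve: ScatteringCurve, fit: GuinierFit):
    """Dimensionless Kratky series (qRg, (qRg)² I/I0) plus reference curves.

    Returns a dict with keys ``x``, ``y``, ``globular``, ``coil``.
    """
    if fit.i0 <= 0:
        raise ValueError("Guinier I(0) must be positive")
    x = curve.q * fit.rg
    y = x ** 2 * curve.I / fit.i0
    return {"x": x, "y": y, "globular": globular_reference(x), "coil": coil_reference(x)}


@dataclass
class PairDistribution:
    """Pair-distance distribution P(r): area-normalised histogram of
    intramolecular distances, vanishing beyond Dmax."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    bin_width: float

    def minmax_normalised(self) -> np.ndarray:
        """Min–max scaled profile (plotting convention only)."""
        lo, hi = self.p.min(), self.p.max()
        return (self.p - lo) / (hi - lo) if hi > lo else np.zeros_like(self.p)


def pr_from_model(conf, bin_width: float = 1.0,
                  form_factor_model: str = "unit") -> PairDistribution:
    """Model-based P(r): f(0)-weighted histogram of pairwise distances.

    Normalised to unit area; Dmax is the maximum pair distance.  The
    P(r)-based radius of gyration is the second moment of the pair-distance
    distribution, Rg² = ⟨r²⟩/2 in the many-scatterer limit; the exact
    finite-N weighting (F² − Σf²)/(2F²) with F = Σf(0) is used so that
    Rg_pr coincides with the geometric radius of gyration for any N
    (a two-point particle gives exactly d/2).
    """
    pos, fac = scatterers_for(conf, np.array([0.0]), form_factor_model)
    if len(pos) < 2:
        raise ValueError("P(r) needs at least two scatterers")
    f0 = fac[:, 0]
    d = pdist(pos)
    iu, ju = np.triu_indices(len(pos), k=1)
    w = f0[iu] * f0[ju]
    dmax = float(d.max())
    nbins = max(int(np.ceil(dmax / bin_width)), 1)
    edges = np.arange(nbins + 1) * bin_width
    if edges[-1] <= dmax:
        edges = np.append(edges, edges[-1] + bin_width)
    hist, edges = np.histogram(d, bins=edges, weights=w)
    p = hist / (hist.sum() * bin_width)
    r = 0.5 * (edges[:-1] + edges[1:])
    ftot = f0.sum()
    mean_r2 = (w * d ** 2).sum() / w.sum()
    rg = float(np.sqrt(mean_r2 * (ftot ** 2 - (f0 ** 2).sum()) / (2.0 * ftot ** 2)))
    return PairDistribution(r, p, dmax, rg, bin_width)


def save_pr(pr: PairDistribution, path) -> None:
    """Write a pair distribution as a 2-column (r, P) text table."""
    np.savetxt(path, np.column_stack([pr.r, pr.p]), header="r(A) P(r)")
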