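"""Maximum-parsimony (basis-set) weight inference by Bayesian Monte Carlo.

Given a small basis set of K experimentally distinguishable scattering
profiles, the ensemble curve is the convex combination
I_comp(w, q) = Σₖ wₖ Iₖ(q).  The posterior over the weight simplex is

    P(w | data) ∝ exp(−χ²(w)) · P(w),

with a uniform prior and χ²(w) evaluated after re-estimating the
least-squares scale c at every step.  The posterior is mapped by plain
Metropolis sampling with a symmetric pairwise-transfer proposal: two
components are picked at random and an amount δ ~ U(−s, s) is moved from
one to the other, rejecting moves that leave the simplex.  The step size s
is tuned during burn-in toward a 25–45% acceptance rate and then frozen.
Reported weights are posterior means with posterior standard deviations as
uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import BasisSet
from .saxs_forward import ScatteringCurve, chi_square, optimal_scale

__all__ = [
    "MaxParsModel",
    "MaxParsResults",
    "chi2_of_weights",
    "sample_posterior",
    "summarize_weights",
]


def _basis_matrix(basis) -> np.ndarray:
    if isinstance(basis, BasisSet):
        return basis.intensity_matrix
    if isinstance(basis, (list, tuple)):
        return np.stack([p.I for p in basis])
    return np.atleast_2d(np.asarray(basis, dtype=float))


class MaxParsModel:
    """Posterior over basis-set weights given an experimental curve.

    Parameters
    ----------
    basis
        BasisSet, list of ScatteringCurve on the experimental grid, or a
        (K, n_q) intensity matrix.
    experiment
        Experimental curve with per-point errors.
    fit_constant
        Also fit an additive constant inside χ² (off by default: the
        posterior uses only the multiplicative scale c).
    """

    def __init__(self, basis, experiment: ScatteringCurve, fit_constant: bool = False):
        self.B = _basis_matrix(basis)
        if experiment.sigma is None:
            raise ValueError("experimental curve lacks error estimates")
        if self.B.shape[1] != len(experiment):
            raise ValueError("basis profiles and experiment are on different q grids")
        if isinstance(basis, (BasisSet, list, tuple)):
            profiles = basis.profiles if isinstance(basis, BasisSet) else basis
            for p in profiles:
                if not p.same_grid(experiment):
                    raise ValueError("basis profile grid differs from experiment")
        self.experiment = experiment
        self.fit_constant = fit_constant

    @property
    def k(self) -> int:
        return self.B.shape[0]

    def chi2(self, w) -> float:
        """χ²(w) with the scale c re-estimated by its closed form."""
        w = np.asarray(w, dtype=float)
        if len(w) != self.k:
            raise ValueError("weight vector length mismatch")
        I_comp = w @ self.B
        exp = self.experiment
        if self.fit_constant:
            sig = exp.sigma
            a = np.stack([I_comp / sig, np.ones_like(sig) / sig], axis=1)
            (c, const), *_ = np.linalg.lstsq(a, exp.I / sig, rcond=None)
        else:
            c = optimal_scale(I_comp, exp.I, exp.sigma)
            const = 0.0
        return chi_square(I_comp, exp.I, exp.sigma, c=c, constant=const)

    def fit(self, steps: int = 51000, burn: int = 1000, seed: int | None = None,
            initial_step: float = 0.1) -> "MaxParsResults":
        """Run the Metropolis chain and summarise the posterior."""
        if steps <= burn:
            raise ValueError("steps must exceed burn-in")
        rng = np.random.default_rng(seed)
        k = self.k
        if k == 1:
            samples = np.ones((steps - burn, 1))
            return MaxParsResults(self, samples, 1.0, burn, seed, [self.chi2([1.0])] * 2)

        w = np.full(k, 1.0 / k)
        chi2 = self.chi2(w)
        if not np.isfinite(chi2):
            raise ValueError("non-finite likelihood at the initial weights")
        s = initial_step
        samples = np.empty((steps - burn, k))
        chi2_trace = []
        accepted = tune_acc = tune_tot = 0
        window = 100
        for step in range(steps):
            i, j = rng.choice(k, size=2, replace=False)
            delta = rng.uniform(-s, s)
            wi, wj = w[i] + delta, w[j] - delta
            inside = 0.0 <= wi <= 1.0 and 0.0 <= wj <= 1.0
            accept = False
            if inside:
                w_new = w.copy()
                w_new[i], w_new[j] = wi, wj
                chi2_new = self.chi2(w_new)
                if chi2_new <= chi2 or rng.random() < np.exp(chi2 - chi2_new):
                    accept = True
            if accept:
                w, chi2 = w_new, chi2_new
            tune_tot += 1
            tune_acc += accept
            if step < burn and tune_tot == window:
                rate = tune_acc / tune_tot
                if rate < 0.25:
                    s = max(s * 0.8, 1e-6)
                elif rate > 0.45:
                    s = min(s * 1.25, 1.0)
                tune_acc = tune_tot = 0
            if step >= burn:
                accepted += accept
                samples[step - burn] = w
                chi2_trace.append(chi2)
        rate = accepted / (steps - burn)
        return MaxParsResults(self, samples, rate, burn, seed, chi2_trace, step_size=s)


@dataclass
class MaxParsResults:
    """Posterior summary of a basis-set weight inference run."""

    model: MaxParsModel
    samples: np.ndarray
    acceptance_rate: float
    burn: int
    seed: int | None
    chi2_trace: list = field(default_factory=list, repr=False)
    step_size: float = float("nan")

    @property
    def weights(self) -> np.ndarray:
        """Posterior-mean weights, renormalised onto the simplex."""
        m = self.samples.mean(axis=0)
        return m / m.sum()

    @property
    def weights_std(self) -> np.ndarray:
        return self.samples.std(axis=0)

    @property
    def chi2(self) -> float:
        return self.model.chi2(self.weights)

    @property
    def chi2_red(self) -> float:
        return self.chi2 / len(self.model.experiment)

    def summary(self) -> str:
        lines = [
            "Maximum-parsimony ensemble weights (Bayesian Monte Carlo)",
            f"  basis size K = {self.model.k}, samples = {len(self.samples)}, "
            f"burn-in = {self.burn}, seed = {self.seed}",
            f"  acceptance rate = {self.acceptance_rate:.3f}",
            f"  chi2 = {self.chi2:.4g}, chi2_red = {self.chi2_red:.4g}",
            "  k    weight     std",
        ]
        for k, (w, s) in enumerate(zip(self.weights, self.weights_std)):
            lines.append(f"  {k:<3d}  {w:8.4f}  {s:7.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "weights_std": self.weights_std.tolist(),
            "acceptance_rate": self.acceptance_rate,
            "chi2": self.chi2,
            "chi2_red": self.chi2_red,
            "n_samples": int(len(self.samples)),
            "burn": self.burn,
            "seed": self.seed,
            "step_size": self.step_size,
        }


# ---------------------------------------------------------------------------
# Functional front-ends


def chi2_of_weights(w, basis, exp: ScatteringCurve, fit_constant: bool = False) -> float:
    """χ²(w) for a weight vector against experiment, scale re-estimated."""
    return MaxParsModel(basis, exp, fit_constant=fit_constant).chi2(w)


def sample_posterior(basis, exp: ScatteringCurve, steps: int = 51000,
                     burn: int = 1000, seed: int | None = None) -> MaxParsResults:
    return MaxParsModel(basis, exp).fit(steps=steps, burn=burn, seed=seed)


def summarize_weights(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise posterior mean (renormalised) and standard deviation."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if len(samples) < 2:
        raise ValueError("need at least two posterior samples")
    mean = samples.mean(axis=0)
    return mean / mean.sum(), samples.std(axis=0)
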