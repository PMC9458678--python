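# saxsens

SAXS-restrained conformational-ensemble reweighting for flexible
multidomain proteins.

Proteins built from rigid domains joined by flexible linkers — the
motivating case is the catalytic RBR module of the E3 ubiquitin ligase
HOIP, three zinc-binding subdomains (RING1, IBR, RING2) connected by two
linkers — do not adopt a single structure in solution. A small-angle X-ray
scattering (SAXS) curve measured on such a protein is an ensemble average,
and a molecular-dynamics ensemble rarely reproduces it with its raw frame
populations. `saxsens` implements the a-posteriori reweighting workflow
that reconciles the two: it computes theoretical scattering for every
conformer, and infers ensemble weights that bring the average curve into
agreement with experiment, by two complementary routes.

## The models

**Forward model.** The orientation-averaged intensity of a conformer is the
exact Debye sum

```
I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q·rᵢⱼ)/(q·rᵢⱼ)
```

with unit, residue-bead, or atomic (Cromer–Mann) form factors. An ensemble
with weights *w* scatters as `I(w, q) = Σₖ wₖ Iₖ(q)`, matched to experiment
through a least-squares scale `c = (Σ I_exp I_comp/σ²)/(Σ I_comp²/σ²)` and
scored by `χ² = Σ[(I_exp − c·I_comp)/σ]²` and `χ²_red = χ²/N`.

**Maximum parsimony (`MaxParsModel`).** Frames are first reduced to a small
basis set of conformationally unique, experimentally distinguishable
states: HDBSCAN clustering on pairwise Cα-distance features picks
structural representatives, then Ward-linkage clustering of their profiles
under the pairwise χ² metric merges states the data cannot tell apart.
Basis weights follow the Bayesian posterior `P(w|data) ∝ exp(−χ²(w))` on
the simplex, mapped by Metropolis Monte Carlo; `fit()` returns posterior
means and standard deviations.

**Maximum entropy (`MaxEntModel`).** All frames are kept and their
reference weights w⁰ minimally perturbed by minimising

```
L(w) = θ·S_KL(w‖w⁰) + χ²(w)/2,   S_KL = Σₖ wₖ ln(wₖ/wₖ⁰)
```

over the simplex. The confidence parameter θ is chosen from an L-curve
scan of (S_KL, χ²_red); conformers with weight above one standard
deviation over the mean are reported as significant.

Primary SAXS analysis (iterated Guinier fit, dimensionless Kratky
transform with globular and random-coil references, model-based P(r)),
weighted free-energy surfaces over inter-domain distances, difference
landscapes, and block-averaging error estimates round out the pipeline. A
synthetic-data module generates three-domain hinge ensembles with known
ground-truth weights so every stage is testable without external data.

## Worked example

Simulate a 12-conformer hinge ensemble in which compact conformer 0 is
over-weighted, then reweight the uniform reference against the synthetic
observation:

```
$ saxsens simulate --n-conformers 12 --seed 3 --weights 4,1,1,1,1,1,1,1,1,1,1,2 --out sim
wrote 12-frame toy ensemble and observation to sim

$ saxsens reweight sim/ensemble.pdb sim/observed.dat --mode maxent --out me
Maximum-entropy ensemble refinement
  K = 12 conformers, theta = 21.5443
  S_KL = 0.060773
  chi2 = 211.091, chi2_red = 1.055
  iterations = 31, converged = True
  significant conformers (w > mean + std): 2

$ saxsens analyze-saxs sim/observed.dat --out analysis
Guinier Rg = 33.04 A (I0 = 1.114e+04, 22 points, qRg_max = 1.272)
```

Reading the output: the θ-scan's L-curve elbow lands at θ ≈ 22, where the
reweighted ensemble matches the observation at χ²_red ≈ 1.06 (a
statistically perfect fit to 1% noise) while moving only S_KL ≈ 0.06 of
relative entropy away from the uniform reference; the two up-weighted
frames are flagged significant. The Guinier radius of 33 Å is the
ensemble-averaged size, between the compact (~27 Å) and extended (~45 Å)
ends of the hinge range. Per-frame weights land in `me/weights.dat`; the
resolved configuration and seeds are stored in each output directory.

The same objects are available as a library:

```python
from saxsens import MaxEntModel, debye_curve, generate_toy_ensemble

ens, features, rg = generate_toy_ensemble(50, seed=1)
```

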