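"""Atomic X-ray form factors for the Debye forward model.

Three levels are supported:

``unit``
    f ≡ 1 per scatterer.  Every intensity then has a closed-form oracle,
    which makes this the default for synthetic bead models.
``residue``
    One bead per residue placed at the residue centre of mass, with a
    q-independent form factor equal to the residue electron count.
``atomic``
    Four-Gaussian Cromer–Mann parameterisation
    f(q) = Σᵢ aᵢ exp(−bᵢ (q/4π)²) + c, in-vacuo (no solvent contrast term).
"""

from __future__ import annotations

import numpy as np

# Cromer-Mann coefficients (a1..a4, b1..b4, c), International Tables Vol. C.
_CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
    "ZN": ([14.0743, 7.03180, 5.16520, 2.41000],
           [3.26550, 0.233300, 10.3163, 58.7097], 1.30410),
    "FE": ([11.7695, 7.35730, 3.52220, 2.30450],
           [4.76110, 0.307200, 15.3535, 76.8805], 1.03690),
    "SE": ([17.0006, 5.81960, 3.97310, 4.35430],
           [2.40980, 0.272600, 15.2372, 43.8163], 2.84090),
}

_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "ZN": 30, "FE": 26, "SE": 34,
}

#: electrons per residue (heavy atoms + hydrogens, neutral side chain)
RESIDUE_ELECTRONS = {
    "GLY": 30, "ALA": 38, "SER": 46, "CYS": 54, "THR": 54, "VAL": 54,
    "PRO": 52, "LEU": 62, "ILE": 62, "ASN": 60, "ASP": 59, "GLN": 68,
    "GLU": 67, "MET": 70, "HIS": 72, "LYS": 71, "ARG": 85, "PHE": 78,
    "TYR": 86, "TRP": 98, "UNK": 62,
}


def atomic_number(element: str) -> int:
    el = element.upper()
    if el not in _ATOMIC_NUMBER:
        raise ValueError(f"no atomic number tabulated for element {element!r}")
    return _ATOMIC_NUMBER[el]


def cromer_mann(element: str, q: np.ndarray) -> np.ndarray:
    """f(q) for one element on a q grid (Å⁻¹)."""
    el = element.upper()
    if el not in _CROMER_MANN:
        raise ValueError(f"no Cromer-Mann coefficients for element {element!r}")
    a, b, c = _CROMER_MANN[el]
    s2 = (np.asarray(q, float) / (4.0 * np.pi)) ** 2
    f = np.full_like(s2, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def scatterers_for(conf, q: np.ndarray, model: str = "unit"):
    """Positions and per-scatterer form factors f(q) for a conformer.

    Returns ``(positions (n, 3), factors (n, nq))``.
    """
    q = np.asarray(q, dtype=float)
    if model == "unit":
        pos = conf.coords
        fac = np.ones((len(pos), len(q)))
    elif model == "atomic":
        pos = conf.coords
        fac = np.stack([cromer_mann(el, q) for el in conf.elements.astype(str)])
    elif model == "residue":
        pos, counts = [], []
        resids = conf.resids
        chains = conf.chains.astype(str)
        keys = list(dict.fromkeys(zip(chains, resids)))
        for ch, ri in keys:
            m = (resids == ri) & (chains == ch)
            w = conf.masses[m]
            pos.append((w[:, None] * conf.coords[m]).sum(axis=0) / w.sum())
            rn = str(conf.resnames[m][0]).upper()
            if rn in RESIDUE_ELECTRONS:
                counts.append(RESIDUE_ELECTRONS[rn])
            else:
                counts.append(sum(atomic_number(e) for e in conf.elements[m].astype(str)))
        pos = np.array(pos)
        fac = np.repeat(np.asarray(counts, float)[:, None], len(q), axis=1)
    else:
        raise ValueError(f"unknown form-factor model {model!r}")
    return np.asarray(pos, float), fac
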