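"""Assembly and metrics of the HOIP RBR crystal-derived reference models.

The HOIP RBR/E2~Ub crystal structure (PDB 5EDV) contains two RBR chains:
an *extended* conformation (a single polypeptide) and a *closed* one formed
by fragments of both chains clamping the same E2~Ub conjugate.  Both chains
have unresolved loops, so the full-length extended model is assembled by
grafting the fully resolved RING2-LDD region of PDB 4LJP (chain A) onto
5EDV chain B after backbone superposition on the shared L2 region, and the
short 751–759 RING1 loop is taken from 5EDV chain A.

These builders operate on locally available PDB files (the entries are not
redistributed here); download 5EDV and 4LJP from the PDB and point the
functions at them.
"""

from __future__ import annotations

import numpy as np

from .structures import (
    Conformer,
    HOIP_DOMAINS,
    domain_distance,
    max_dimension,
    radius_of_gyration,
    read_coordinates,
    superpose_and_graft,
)

__all__ = [
    "extract_chain",
    "build_extended_model",
    "extended_model_metrics",
    "closed_model_d_ibr_ring2",
]


def extract_chain(path, chain: str, resid_range=None) -> Conformer:
    """First-model single-chain (optionally residue-windowed) conformer."""
    conf = read_coordinates(path)[0]
    mask = conf.chains.astype(str) == chain
    if resid_range is not None:
        lo, hi = resid_range
        mask &= (conf.resids >= lo) & (conf.resids <= hi)
    if not mask.any():
        raise ValueError(f"no atoms for chain {chain!r} in {path}")
    return conf.select(mask, id=f"{path}:{chain}")


def build_extended_model(path_5edv, path_4ljp) -> Conformer:
    """Full-length (699–1071) extended HOIP RBR model from 5EDV + 4LJP.

    5EDV chain B supplies 699–867 (RING1–L1–IBR–L2); 4LJP chain A,
    superposed on the shared 860–867 backbone, supplies 868–1071
    (RING2–LDD); the missing 751–759 RING1 loop comes from 5EDV chain A
    superposed on its flanking residues.
    """
    target = extract_chain(path_5edv, "B", (699, 867))
    donor_ring2 = extract_chain(path_4ljp, "A")
    model = superpose_and_graft(target, donor_ring2,
                                align_range=(860, 867), replace_range=(868, 1071))
    # RING1 751-759 loop from chain A, aligned on the flanking backbone
    loop_donor = extract_chain(path_5edv, "A", (699, 800))
    try:
        model = superpose_and_graft(model, loop_donor,
                                    align_range=(745, 750), replace_range=(751, 759))
    except ValueError:
        # flanking backbone incomplete in either chain: keep the gapped model
        pass
    return model


def extended_model_metrics(model: Conformer) -> dict:
    """Rg, inter-domain COM distances and Dmax of an assembled model (Å)."""
    ring1 = HOIP_DOMAINS["RING1"]
    ibr = HOIP_DOMAINS["IBR"]
    ring2 = HOIP_DOMAINS["RING2"]
    return {
        "rg": radius_of_gyration(model),
        "d_ring1_ibr": domain_distance(model, ring1, ibr),
        "d_ibr_ring2": domain_distance(model, ibr, ring2),
        "dmax": max_dimension(model),
    }


def closed_model_d_ibr_ring2(path_5edv) -> float:
    """D_IBR–RING2 of the closed conformation, from fragment superposition.

    The closed RBR arrangement is the composite of 5EDV chain B
    (RING1–IBR–L2, 699–852) and chain A (L2–RING2, 853–936) in the crystal
    frame, so the inter-domain distance follows directly from the two
    fragments' COMs without rebuilding the 852–853 junction.
    """
    ens = read_coordinates(path_5edv)
    conf = ens[0]
    ibr = HOIP_DOMAINS["IBR"]
    ring2 = HOIP_DOMAINS["RING2"]
    chains = conf.chains.astype(str)
    frag_b = conf.select((chains == "B") & (conf.resids >= 699) & (conf.resids <= 852))
    frag_a = conf.select((chains == "A") & (conf.resids >= 853) & (conf.resids <= 936))
    from .structures import center_of_mass

    com_ibr = center_of_mass(frag_b, ibr)
    com_ring2 = center_of_mass(frag_a, ring2)
    return float(np.linalg.norm(com_ibr - com_ring2))
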