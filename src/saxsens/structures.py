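"""Coordinate containers, model assembly and per-conformer structural metrics.

The objects here describe a multidomain protein conformer at atomic (or
coarse-grained bead) resolution: element symbols, masses, author residue
numbering, chain ids and Cartesian coordinates in Å.  Everything downstream —
forward scattering, clustering features, collective variables — consumes these
containers.

Residue numbering follows the author (crystallographic) convention throughout;
for the HOIP RBR catalytic module that is 699–1071, with the zinc-binding
subdomains RING1 699–751, IBR 796–841 and RING2 869–934 joined by the flexible
linkers L1 and L2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import pdist

__all__ = [
    "Conformer",
    "Ensemble",
    "DomainDefinition",
    "FeatureMatrix",
    "HOIP_DOMAINS",
    "read_coordinates",
    "write_pdb",
    "load_domains",
    "superpose_and_graft",
    "kabsch",
    "center_of_mass",
    "domain_distance",
    "radius_of_gyration",
    "max_dimension",
    "ca_distance_features",
]

# Standard atomic masses (Da) for elements common in protein structures;
# anything else is looked up in Biopython's IUPAC table at parse time.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "ZN": 65.38, "FE": 55.845, "SE": 78.971,
}


def _element_mass(element: str) -> float:
    el = element.upper()
    if el in _MASSES:
        return _MASSES[el]
    from Bio.Data.IUPACData import atom_weights

    key = el.capitalize()
    if key not in atom_weights:
        raise ValueError(f"unknown element {element!r}")
    return float(atom_weights[key])


@dataclass
class Conformer:
    """A single structural model: parallel per-atom arrays plus a frame label.

    Invariants: finite coordinates, strictly positive masses, and residue
    indices non-decreasing within each chain.
    """

    elements: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    id: str = "0"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        for name in ("elements", "names", "resnames", "chains"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        n = len(self.coords)
        for name in ("elements", "names", "resids", "resnames", "chains", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch with coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("non-positive atomic mass")
        for ch in np.unique(self.chains.astype(str)):
            r = self.resids[self.chains.astype(str) == ch]
            if np.any(np.diff(r) < 0):
                raise ValueError(f"residue indices decrease within chain {ch!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray, id: str | None = None) -> "Conformer":
        """Sub-conformer from a boolean mask, preserving atom order."""
        mask = np.asarray(mask, dtype=bool)
        return Conformer(
            elements=self.elements[mask],
            names=self.names[mask],
            resids=self.resids[mask],
            resnames=self.resnames[mask],
            chains=self.chains[mask],
            masses=self.masses[mask],
            coords=self.coords[mask],
            id=id if id is not None else self.id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        out = self.select(np.ones(self.n_atoms, dtype=bool))
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass
class Ensemble:
    """Ordered collection of conformers sharing one topology."""

    conformers: list[Conformer]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("empty ensemble")
        n0 = self.conformers[0].n_atoms
        for c in self.conformers:
            if c.n_atoms != n0:
                raise ValueError("conformers differ in atom count")

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    def __iter__(self):
        return iter(self.conformers)

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([c.coords for c in self.conformers])


@dataclass(frozen=True)
class DomainDefinition:
    """Named inclusive residue range in author numbering, optionally per chain."""

    name: str
    start: int
    end: int
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain {self.name}: start > end")

    def mask(self, conf: Conformer) -> np.ndarray:
        m = (conf.resids >= self.start) & (conf.resids <= self.end)
        if self.chain is not None:
            m &= conf.chains.astype(str) == self.chain
        return m


# COM-defining subdomain ranges of the HOIP RBR catalytic module.
HOIP_DOMAINS = {
    "RING1": DomainDefinition("RING1", 699, 751),
    "L1": DomainDefinition("L1", 752, 795),
    "IBR": DomainDefinition("IBR", 796, 841),
    "L2": DomainDefinition("L2", 842, 868),
    "RING2": DomainDefinition("RING2", 869, 934),
    "LDD": DomainDefinition("LDD", 935, 1071),
}


def load_domains(path) -> list[DomainDefinition]:
    """Read domain definitions from a YAML file.

    Expected layout: a list of mappings with keys ``name``, ``start``,
    ``end`` and optional ``chain``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("domain config must be a list of mappings")
    return [
        DomainDefinition(d["name"], int(d["start"]), int(d["end"]), d.get("chain"))
        for d in raw
    ]


# ---------------------------------------------------------------------------
# I/O


def read_coordinates(path, format: str = "pdb") -> Ensemble:
    """Read a (multi-model) PDB or XYZ file into an :class:`Ensemble`.

    One conformer per model, atom order preserved; heteroatoms such as Zn are
    kept as ordinary heavy atoms.  Waters are dropped.
    """
    fmt = format.lower()
    if fmt in ("pdb", "multi-model pdb"):
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown coordinate format {format!r}")


def _read_pdb(path) -> Ensemble:
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure("m", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"malformed PDB record in {path}: {exc}") from exc
    conformers = []
    for model in structure:
        elements, names, resids, resnames, chains, masses, coords = ([] for _ in range(7))
        for chain in model:
            for residue in chain:
                if residue.get_resname().strip() == "HOH":
                    continue
                for atom in residue:
                    el = (atom.element or atom.get_name()[0]).strip()
                    elements.append(el.upper())
                    names.append(atom.get_name())
                    resids.append(residue.get_id()[1])
                    resnames.append(residue.get_resname().strip())
                    chains.append(chain.get_id())
                    masses.append(_element_mass(el))
                    coords.append(atom.get_coord())
        if coords:
            conformers.append(
                Conformer(elements, names, resids, resnames, chains, masses,
                          np.array(coords, dtype=float), id=str(model.get_id()))
            )
    if not conformers:
        raise ValueError(f"no models with atoms found in {path}")
    return Ensemble(conformers, source=str(path))


def _read_xyz(path) -> Ensemble:
    """Plain multi-frame XYZ: count line, comment line, then element x y z."""
    conformers = []
    with open(path) as fh:
        lines = fh.readlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 1}: truncated frame of {n} atoms")
        elements, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: malformed XYZ atom line {ln!r}")
            elements.append(parts[0].upper())
            coords.append([float(x) for x in parts[1:4]])
        conformers.append(
            Conformer(
                elements=elements,
                names=elements,
                resids=np.arange(1, n + 1),
                resnames=["UNK"] * n,
                chains=["A"] * n,
                masses=[_element_mass(e) for e in elements],
                coords=np.array(coords),
                id=comment or str(frame),
            )
        )
        frame += 1
        i += 2 + n
    if not conformers:
        raise ValueError(f"no frames found in {path}")
    return Ensemble(conformers, source=str(path))


def write_pdb(obj: Conformer | Ensemble, path) -> None:
    """Write a conformer or ensemble as a (multi-model) PDB file."""
    conformers = obj.conformers if isinstance(obj, Ensemble) else [obj]
    multi = len(conformers) > 1
    with open(path, "w") as fh:
        for m, conf in enumerate(conformers, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(conf.n_atoms):
                name = str(conf.names[i])[:4]
                el = str(conf.elements[i])[:2]
                record = "HETATM" if el in ("ZN", "FE") else "ATOM  "
                x, y, z = conf.coords[i]
                fh.write(
                    f"{record}{(i + 1) % 100000:5d} {name:<4s}{str(conf.resnames[i])[:3]:>4s} "
                    f"{str(conf.chains[i])[:1]}{int(conf.resids[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Model assembly

_BACKBONE = ("N", "CA", "C")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ R.T + t`` best fits ``target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must share shape (n, 3)")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - r @ mc
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return r, t, rmsd


def _range_tuple(rng) -> tuple[int, int]:
    if isinstance(rng, DomainDefinition):
        return rng.start, rng.end
    start, end = rng
    return int(start), int(end)


def superpose_and_graft(
    target: Conformer,
    donor: Conformer,
    align_range,
    replace_range,
) -> Conformer:
    """Graft a donor fragment onto a target after backbone superposition.

    The donor is rigid-body transformed by Kabsch superposition on the
    backbone atoms (N, CA, C) of ``align_range``; atoms of ``replace_range``
    in the output come from the transformed donor, all other atoms from the
    target.  This is how a full-length model is assembled from overlapping
    crystal fragments (e.g. joining two partially resolved chains at a
    shared linker region).
    """
    a_start, a_end = _range_tuple(align_range)
    r_start, r_end = _range_tuple(replace_range)

    def backbone_sel(conf: Conformer) -> np.ndarray:
        return (
            (conf.resids >= a_start)
            & (conf.resids <= a_end)
            & np.isin(conf.names.astype(str), _BACKBONE)
        )

    tmask, dmask = backbone_sel(target), backbone_sel(donor)
    if not tmask.any() or not dmask.any():
        raise ValueError("empty alignment selection")
    if tmask.sum() != dmask.sum():
        raise ValueError(
            f"alignment selections differ in size ({tmask.sum()} vs {dmask.sum()})"
        )
    t_ids = list(zip(target.resids[tmask], target.names[tmask].astype(str)))
    d_ids = list(zip(donor.resids[dmask], donor.names[dmask].astype(str)))
    if t_ids != d_ids:
        raise ValueError("mismatched residue identities in alignment range")

    rot, trans, _ = kabsch(donor.coords[dmask], target.coords[tmask])
    moved = donor.transformed(rot, trans)

    keep = ~((target.resids >= r_start) & (target.resids <= r_end))
    graft = (moved.resids >= r_start) & (moved.resids <= r_end)
    if not graft.any():
        raise ValueError("replace_range selects no donor atoms")

    kept, grafted = target.select(keep), moved.select(graft)
    fields = {}
    for name in ("elements", "names", "resids", "resnames", "chains", "masses"):
        fields[name] = np.concatenate([getattr(kept, name), getattr(grafted, name)])
    coords = np.concatenate([kept.coords, grafted.coords])
    order = np.argsort(fields["resids"], kind="stable")
    return Conformer(
        elements=fields["elements"][order],
        names=fields["names"][order],
        resids=fields["resids"][order],
        resnames=fields["resnames"][order],
        chains=np.asarray(["A"] * len(coords), dtype=object),
        masses=fields["masses"][order],
        coords=coords[order],
        id=f"{target.id}+{donor.id}",
    )


# ---------------------------------------------------------------------------
# Structural metrics


def _selection_mask(conf: Conformer, selection) -> np.ndarray:
    if selection is None:
        return np.ones(conf.n_atoms, dtype=bool)
    if isinstance(selection, DomainDefinition):
        return selection.mask(conf)
    if isinstance(selection, np.ndarray) and selection.dtype == bool:
        return selection
    start, end = _range_tuple(selection)
    return (conf.resids >= start) & (conf.resids <= end)


def center_of_mass(conf: Conformer, selection=None) -> np.ndarray:
    """Mass-weighted mean position (Å) of the selected atoms."""
    m = _selection_mask(conf, selection)
    if not m.any():
        raise ValueError("empty selection for center of mass")
    w = conf.masses[m]
    return (w[:, None] * conf.coords[m]).sum(axis=0) / w.sum()


def domain_distance(conf: Conformer, a, b) -> float:
    """Euclidean distance between two domain centres of mass (Å)."""
    return float(np.linalg.norm(center_of_mass(conf, a) - center_of_mass(conf, b)))


def radius_of_gyration(conf: Conformer, selection=None) -> float:
    """Mass-weighted radius of gyration (Å) about the selection COM."""
    m = _selection_mask(conf, selection)
    if not m.any():
        raise ValueError("empty selection for radius of gyration")
    w = conf.masses[m]
    x = conf.coords[m]
    com = (w[:, None] * x).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((x - com) ** 2, axis=1)).sum() / w.sum()))


def max_dimension(conf: Conformer, selection=None) -> float:
    """Maximum pairwise inter-atomic distance (Å)."""
    m = _selection_mask(conf, selection)
    x = conf.coords[m]
    if len(x) < 2:
        raise ValueError("max_dimension needs at least two atoms")
    return float(pdist(x).max())


@dataclass
class FeatureMatrix:
    """Per-frame pairwise Cα–Cα distance vectors (Å), frames × n(n−1)/2."""

    values: np.ndarray
    pair_labels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("negative distance feature")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def ca_distance_features(
    ens: Ensemble,
    ranges: Sequence[DomainDefinition],
    inter_domain_only: bool = False,
) -> FeatureMatrix:
    """Pairwise Cα–Cα distances over the union of domain ranges, per frame.

    Used as the rotation/translation-invariant clustering representation of
    relative domain arrangements.  With ``inter_domain_only`` the
    near-constant intra-domain pairs are dropped.
    """
    first = ens[0]
    is_ca = first.names.astype(str) == "CA"
    domain_of = np.full(first.n_atoms, -1)
    for k, rng in enumerate(ranges):
        domain_of[rng.mask(first)] = k
    sel = np.flatnonzero(is_ca & (domain_of >= 0))
    if len(sel) < 2:
        raise ValueError("fewer than two Cα atoms selected")
    for rng in ranges:
        if not np.any(is_ca & rng.mask(first)):
            raise ValueError(f"no Cα atoms in domain {rng.name!r}")

    pairs = list(itertools.combinations(range(len(sel)), 2))
    if inter_domain_only:
        dom = domain_of[sel]
        pairs = [(i, j) for i, j in pairs if dom[i] != dom[j]]
    labels = [(int(first.resids[sel[i]]), int(first.resids[sel[j]])) for i, j in pairs]

    rows = []
    for conf in ens:
        if not np.all(conf.names[sel].astype(str) == "CA"):
            raise ValueError("Cα selection inconsistent across frames")
        x = conf.coords[sel]
        if inter_domain_only:
            d = np.array([np.linalg.norm(x[i] - x[j]) for i, j in pairs])
        else:
            d = pdist(x)
        rows.append(d)
    return FeatureMatrix(np.array(rows), pair_labels=labels)
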