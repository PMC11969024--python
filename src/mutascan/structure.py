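"""Inter-chain contact and binding-site occlusion analysis of complex models.

Binding-site residues are defined residue-level: any heavy-atom pair within
the 5 Å cutoff. Atom-pair interactions are then typed with simplified,
fixed geometric rules (distance thresholds over template-derived atom
classes); ring-centroid (pi) geometry is deliberately out of scope. A
chemokine binding-site residue is "blocked" when it also lies within the
cutoff of a bound peptide in the corresponding peptide-complex model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

BOND_CLASSES = ("aromatic", "carbonyl", "hydrophobic", "hydrogen", "ionic", "polar", "vdw")

# --- residue templates (standard amino acids, heavy atoms, physiological pH)

_AROMATIC_RING = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
# H-bond donors / acceptors (heavy atoms); backbone N donates, backbone O accepts
_DONORS = {
    "*": {"N"},
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_ACCEPTORS = {
    "*": {"O", "OXT"},
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"},
}
# formal charges at physiological pH (His neutral)
_POSITIVE = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}}
_NEGATIVE = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
# side-chain carbons bonded to N/O (not apolar)
_POLARISED_C = {
    "ARG": {"CZ"}, "ASN": {"CG"}, "ASP": {"CG"}, "GLN": {"CD"}, "GLU": {"CD"},
    "SER": {"CB"}, "THR": {"CB"}, "TYR": {"CZ"}, "TRP": set(), "HIS": set(),
}

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    index: int  # author residue number
    name: str
    atoms: tuple[Atom, ...]


@dataclass
class StructureModel:
    model_id: str
    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("structure has no chains with heavy atoms")

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not in model {self.model_id}") from None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for ch in self.chains.values() for r in ch)

    def shortest_chain(self) -> str:
        return min(self.chains, key=lambda c: (len(self.chains[c]), c))


@dataclass(frozen=True)
class ContactRules:
    site_cutoff: float = 5.0
    hydrophobic_cutoff: float = 4.5
    hydrogen_cutoff: float = 3.5
    ionic_cutoff: float = 4.0
    polar_cutoff: float = 3.5
    carbonyl_cutoff: float = 3.6
    aromatic_cutoff: float = 4.0
    vdw_slack: float = 0.5

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class ContactPair:
    chain_a: str
    res_a: int
    name_a: str
    chain_b: str
    res_b: int
    name_b: str
    min_distance: float
    classes: frozenset[str]


@dataclass(frozen=True)
class OcclusionSummary:
    chemokine_id: str
    partner_id: str
    total_site_residues: int
    blocked: int

    def __post_init__(self) -> None:
        if not 0 <= self.blocked <= self.total_site_residues:
            raise ValueError("blocked must lie within [0, total]")


def read_structure(path: str | Path) -> StructureModel:
    """Load an mmCIF or PDB file: heavy atoms only, best-occupancy altlocs."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    st.remove_hydrogens()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            atoms = tuple(
                Atom(a.name, a.element.name.upper(), (a.pos.x, a.pos.y, a.pos.z))
                for a in best.values()
            )
            residues.append(Residue(res.seqid.num, res.name.upper(), atoms))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"{path}: no chains with heavy atoms")
    return StructureModel(model_id=Path(path).stem, chains=chains)


def _chain_coords(residues: list[Residue]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stacked coordinates plus (residue list index, atom index) keys."""
    coords, keys = [], []
    for ri, res in enumerate(residues):
        for ai, atom in enumerate(res.atoms):
            coords.append(atom.xyz)
            keys.append((ri, ai))
    return np.asarray(coords, dtype=float), keys


def _pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))


def contact_residues(
    model: StructureModel, chain_a: str, chain_b: str,
    rules: ContactRules | None = None,
) -> set[int]:
    """Residue numbers of chain_a with any heavy atom within the cutoff of chain_b."""
    rules = rules or ContactRules()
    res_a, res_b = model.chain(chain_a), model.chain(chain_b)
    if not res_a or not res_b:
        warnings.warn("empty chain in contact computation")
        return set()
    ca, keys_a = _chain_coords(res_a)
    cb, _ = _chain_coords(res_b)
    dmat = _pairwise_distances(ca, cb)
    hit_atoms = (dmat <= rules.site_cutoff).any(axis=1)
    return {res_a[keys_a[i][0]].index for i in np.flatnonzero(hit_atoms)}


# --- atom typing helpers


def _named(table: dict[str, set[str]], res: str, atom: str) -> bool:
    return atom in table.get(res, set()) or atom in table.get("*", set())


def _is_apolar_carbon(res: str, atom: Atom) -> bool:
    if atom.element != "C":
        return False
    if atom.name == "C":  # backbone carbonyl carbon
        return False
    if atom.name in _POLARISED_C.get(res, set()):
        return False
    return True


def _is_polar_uncharged(res: str, atom: Atom) -> bool:
    if atom.element not in ("N", "O", "S"):
        return False
    charged = _named(_POSITIVE, res, atom.name) or _named(_NEGATIVE, res, atom.name)
    polar = _named(_DONORS, res, atom.name) or _named(_ACCEPTORS, res, atom.name)
    return polar and not charged


def _atom_pair_classes(
    res_a: str, atom_a: Atom, res_b: str, atom_b: Atom, dist: float, rules: ContactRules
) -> set[str]:
    classes: set[str] = set()
    if (
        dist <= rules.hydrophobic_cutoff
        and _is_apolar_carbon(res_a, atom_a)
        and _is_apolar_carbon(res_b, atom_b)
    ):
        classes.add("hydrophobic")
    if dist <= rules.hydrogen_cutoff and (
        (_named(_DONORS, res_a, atom_a.name) and _named(_ACCEPTORS, res_b, atom_b.name))
        or (_named(_DONORS, res_b, atom_b.name) and _named(_ACCEPTORS, res_a, atom_a.name))
    ):
        classes.add("hydrogen")
    if dist <= rules.ionic_cutoff and (
        (_named(_POSITIVE, res_a, atom_a.name) and _named(_NEGATIVE, res_b, atom_b.name))
        or (_named(_NEGATIVE, res_a, atom_a.name) and _named(_POSITIVE, res_b, atom_b.name))
    ):
        classes.add("ionic")
    if (
        dist <= rules.polar_cutoff
        and _is_polar_uncharged(res_a, atom_a)
        and _is_polar_uncharged(res_b, atom_b)
    ):
        classes.add("polar")
    if dist <= rules.carbonyl_cutoff and (
        (atom_a.name == "C" and atom_b.name == "O")
        or (atom_a.name == "O" and atom_b.name == "C")
    ):
        classes.add("carbonyl")
    if (
        dist <= rules.aromatic_cutoff
        and atom_a.name in _AROMATIC_RING.get(res_a, set())
        and atom_b.name in _AROMATIC_RING.get(res_b, set())
    ):
        classes.add("aromatic")
    r_a = _VDW_RADII.get(atom_a.element, 1.8)
    r_b = _VDW_RADII.get(atom_b.element, 1.8)
    if dist <= r_a + r_b + rules.vdw_slack:
        classes.add("vdw")
    return classes


def classify_contacts(
    model: StructureModel, chain_a: str, chain_b: str,
    rules: ContactRules | None = None,
) -> list[ContactPair]:
    """Type every inter-chain residue pair within the site cutoff.

    Per residue pair, classes are the union over its atom pairs; a pair may
    carry no class (proximity without a typed interaction). Unknown residue
    names fall back to element-only typing (vdw and backbone rules).
    """
    rules = rules or ContactRules()
    res_a, res_b = model.chain(chain_a), model.chain(chain_b)
    pairs: list[ContactPair] = []
    for ra in res_a:
        ca = np.asarray([a.xyz for a in ra.atoms])
        for rb in res_b:
            cb = np.asarray([a.xyz for a in rb.atoms])
            dmat = _pairwise_distances(ca, cb)
            dmin = float(dmat.min())
            if dmin > rules.site_cutoff:
                continue
            classes: set[str] = set()
            for i, atom_a in enumerate(ra.atoms):
                for j, atom_b in enumerate(rb.atoms):
                    classes |= _atom_pair_classes(
                        ra.name, atom_a, rb.name, atom_b, float(dmat[i, j]), rules
                    )
            pairs.append(
                ContactPair(chain_a, ra.index, ra.name, chain_b, rb.index, rb.name,
                            dmin, frozenset(classes))
            )
    return pairs


def summarize_bonds(
    pairs: list[ContactPair], by: str = "model"
) -> pd.DataFrame:
    """Counts of typed residue-pair interactions per class, plus an 'all' total.

    ``by="peptide_residue"`` groups on the second chain's residue numbers
    (the peptide chain in peptide:chemokine complexes).
    """
    if by not in ("model", "peptide_residue"):
        raise ValueError("by must be 'model' or 'peptide_residue'")
    rows = []
    for p in pairs:
        key = p.res_b if by == "peptide_residue" else "all_models"
        rows.append({"key": key, **{c: int(c in p.classes) for c in BOND_CLASSES}})
    if not rows:
        out = pd.DataFrame(columns=["key", *BOND_CLASSES, "all"]).set_index("key")
        return out
    df = pd.DataFrame(rows).groupby("key").sum()
    df["all"] = df.sum(axis=1)
    return df


def occlusion(
    site_model: StructureModel,
    probe_model: StructureModel,
    chemokine_chain: str,
    partner_chain: str,
    peptide_chain: str,
    rules: ContactRules | None = None,
) -> OcclusionSummary:
    """Fraction of partner binding-site residues also covered by the peptide.

    The binding site is computed on the chemokine:partner model; a site
    residue is blocked when the same chemokine residue (same number and
    name) contacts the peptide in the probe model. Residue numbering must
    agree between the two chemokine chains.
    """
    rules = rules or ContactRules()
    site_res = {r.index: r.name for r in site_model.chain(chemokine_chain)}
    probe_res = {r.index: r.name for r in probe_model.chain(chemokine_chain)}
    shared = set(site_res) & set(probe_res)
    mismatched = sorted(i for i in shared if site_res[i] != probe_res[i])
    if mismatched:
        raise ValueError(
            f"chemokine residue numbering mismatch between models at {mismatched}"
        )
    site = contact_residues(site_model, chemokine_chain, partner_chain, rules)
    peptide_side = contact_residues(probe_model, chemokine_chain, peptide_chain, rules)
    blocked = site & peptide_side
    return OcclusionSummary(
        chemokine_id=site_model.model_id,
        partner_id=probe_model.model_id,
        total_site_residues=len(site),
        blocked=len(blocked),
    )


def build_model_manifest(
    chemokines: list[str],
    peptides: list[str],
    receptor_pairs: list[tuple[str, str]] = (),
    dimer_pairs: list[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Task table: chemokine x peptide Cartesian product plus explicit pairs."""
    tasks = [
        {"entity_a": c, "entity_b": p, "kind": "peptide"}
        for c in chemokines for p in peptides
    ]
    tasks += [{"entity_a": a, "entity_b": b, "kind": "receptor"} for a, b in receptor_pairs]
    tasks += [{"entity_a": a, "entity_b": b, "kind": "dimer"} for a, b in dimer_pairs]
    df = pd.DataFrame(tasks, columns=["entity_a", "entity_b", "kind"])
    before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < before:
        warnings.warn(f"{before - len(df)} duplicate modelling task(s) removed")
    return df
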