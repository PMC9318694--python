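"""Molecular data model, descriptors, ligand-side pharmacophore feature perception.

Molecules are thin wrappers around RDKit ``Mol`` objects (heavy-atom graph,
implicit hydrogens).  Conformers store one 3D point per heavy atom, in
Angstrom.  Feature perception assigns the five interaction-feature kinds used
throughout the package:

PI   positively ionizable (protonatable basic nitrogen)
HBA  hydrogen-bond acceptor
HBD  hydrogen-bond donor
HC   hydrophobic contact (centroid of an apolar carbon/halogen patch)
AI   aromatic interaction (ring centroid with ring normal)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors, rdMolAlign

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("PI", "HBA", "HBD", "HC", "AI")

#: elements treated as polar when carving out hydrophobic patches
_POLAR_Z = {7, 8, 15, 16}
#: halogens participate in hydrophobic patches
_HALOGEN_Z = {9, 17, 35, 53}


@dataclass
class Conformer:
    """One 3D geometry of a molecule: one point (Angstrom) per heavy atom."""

    molecule_id: str
    coords: np.ndarray  # (n_heavy, 3)
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("conformer coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coordinates must be finite")


@dataclass
class Molecule:
    """A small molecule: identity, RDKit graph, provenance and conformers."""

    id: str
    rdmol: Chem.Mol
    name: str = ""
    source: str = ""
    conformers: list[Conformer] = field(default_factory=list)

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


@dataclass(frozen=True)
class DescriptorVector:
    """The seven physicochemical descriptors used by the screening filter."""

    mw: float
    clogp: float
    hba_count: int
    hbd_count: int
    rotatable_bonds: int
    ring_count: int
    aromatic_ring_count: int

    #: name of the logP estimator, reported in output metadata
    clogp_method: str = "crippen"


@dataclass
class LigandFeature:
    """A perceived interaction feature of one conformer."""

    kind: str
    atom_indices: tuple[int, ...]
    point: np.ndarray
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.point = np.asarray(self.point, dtype=float)


# ---------------------------------------------------------------------------
# library I/O


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def _prepare(mol: Chem.Mol) -> Chem.Mol | None:
    mol = _largest_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # pragma: no cover - defensive
        return None
    if mol.GetNumHeavyAtoms() < 1:
        return None
    return mol


def read_library(path: str, fmt: str | None = None) -> list[Molecule]:
    """Read a SMILES (.smi, one record per line, optional id column) or SDF file.

    Unparsable records are logged and skipped; parsing zero records is an
    error.  Salts are reduced to their largest covalent fragment.
    """
    fmt = (fmt or ("SDF" if str(path).lower().endswith(("sdf", "sd")) else "SMILES")).upper()
    mols: list[Molecule] = []
    skipped = 0
    if fmt == "SMILES":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                raw = Chem.MolFromSmiles(parts[0])
                mol = _prepare(raw) if raw is not None else None
                if mol is None:
                    skipped += 1
                    logger.warning("skipping unparsable SMILES record on line %d", i + 1)
                    continue
                mid = parts[1] if len(parts) > 1 else f"mol{len(mols)}"
                mols.append(Molecule(id=mid, rdmol=mol, source=str(path)))
    elif fmt == "SDF":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, raw in enumerate(supplier):
            mol = _prepare(raw) if raw is not None else None
            if mol is None:
                skipped += 1
                logger.warning("skipping unparsable SDF record %d", i)
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{len(mols)}"
            m = Molecule(id=mid, rdmol=mol, source=str(path))
            if raw.GetNumConformers() and mol.GetNumConformers():
                m.conformers.append(Conformer(mid, mol.GetConformer().GetPositions()))
            mols.append(m)
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    if not mols:
        raise ValueError(f"no parsable records in {path}")
    if skipped:
        logger.info("read %d molecules from %s (%d records skipped)", len(mols), path, skipped)
    return mols


def write_library(mols: list[Molecule], path: str, with_descriptors: bool = True) -> None:
    """Write molecules to an SDF (V2000), optionally tagged with descriptors."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for m in mols:
            out = Chem.Mol(m.rdmol)
            out.RemoveAllConformers()
            if m.conformers:
                conf = Chem.Conformer(out.GetNumAtoms())
                for i, xyz in enumerate(m.conformers[0].coords):
                    conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
                out.AddConformer(conf, assignId=True)
            out.SetProp("_Name", m.id)
            if with_descriptors:
                d = compute_descriptors(m)
                out.SetProp("MW", f"{d.mw:.2f}")
                out.SetProp("cLogP", f"{d.clogp:.2f}")
                out.SetProp("cLogP_method", d.clogp_method)
                out.SetProp("HBA", str(d.hba_count))
                out.SetProp("HBD", str(d.hbd_count))
                out.SetProp("RotB", str(d.rotatable_bonds))
                out.SetProp("Rings", str(d.ring_count))
                out.SetProp("AromaticRings", str(d.aromatic_ring_count))
            writer.write(out)
    finally:
        writer.close()


def write_smiles(mols: list[Molecule], path: str) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.smiles}\t{m.id}\n")


# ---------------------------------------------------------------------------
# descriptors


def compute_descriptors(mol: Molecule | Chem.Mol) -> DescriptorVector:
    """Compute the seven-descriptor vector used by the physicochemical filter.

    Conventions: molecular weight uses average atomic masses; cLogP is the
    Crippen atom-contribution estimate; acceptor/donor counts follow the
    chemistry-aware heteroatom definitions; rotatable bonds are non-ring
    single bonds between non-terminal heavy atoms with amide C-N excluded;
    rings are counted on the SSSR.
    """
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    return DescriptorVector(
        mw=Descriptors.MolWt(rd),
        clogp=Crippen.MolLogP(rd),
        hba_count=rdMolDescriptors.CalcNumHBA(rd),
        hbd_count=rdMolDescriptors.CalcNumHBD(rd),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(
            rd, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        ring_count=rdMolDescriptors.CalcNumRings(rd),
        aromatic_ring_count=rdMolDescriptors.CalcNumAromaticRings(rd),
    )


# ---------------------------------------------------------------------------
# feature perception

# protonatable basic nitrogens: aliphatic amines, amidines, guanidines.
# Amide/sulfonamide N, anilines, aromatic n and any N double-bonded to a
# heteroatom are excluded.
_PI_PATTERNS = [
    Chem.MolFromSmarts(s)
    for s in (
        # aliphatic amine (incl. protonated): N(sp3) not bonded to aromatic
        # ring, carbonyl/thiocarbonyl/imine carbon, sulfonyl S or heteroatom
        "[NX3,NX4+;!$(N-a);!$(N-C=[O,S,N]);!$(N-S(=O));!$(N-[!#6;!#1])]",
        # amidine / guanidine nitrogens
        "[NX3;$(N-C=[NX2])]",
        "[NX2;$(N=C-[NX3])]",
    )
]

# lone-pair acceptors (PI atoms are removed afterwards: mutual exclusion)
_HBA_PATTERNS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[OX2;+0]",          # hydroxyl / ether / ester oxygen
        "[OX1;+0]",          # carbonyl oxygen
        "[nX2;+0]",          # pyridine-type aromatic nitrogen
        "[NX2;+0;!$(N=C-[NX3])]",  # imine nitrogen (amidine N handled as PI)
        "[NX1;+0]",          # nitrile nitrogen
    )
]

_HBD_PATTERN = Chem.MolFromSmarts("[#7,#8;!H0]")


def _pi_atoms(rd: Chem.Mol) -> set[int]:
    out: set[int] = set()
    for pat in _PI_PATTERNS:
        for match in rd.GetSubstructMatches(pat):
            out.add(match[0])
    return out


def feature_kind_counts(mol: Molecule | Chem.Mol) -> dict[str, int]:
    """Count how many features of each kind a molecule can present at all.

    Purely topological; used by the screening loop to reject molecules that
    lack a required feature kind before any 3D work is done.
    """
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    pi = _pi_atoms(rd)
    hba = {m[0] for p in _HBA_PATTERNS for m in rd.GetSubstructMatches(p)} - pi
    hbd = {m[0] for m in rd.GetSubstructMatches(_HBD_PATTERN)} - pi
    return {
        "PI": len(pi),
        "HBA": len(hba),
        "HBD": len(hbd),
        "AI": len(_aromatic_rings(rd)),
        "HC": len(_hydrophobic_patches(rd)),
    }


def _aromatic_rings(rd: Chem.Mol) -> list[tuple[int, ...]]:
    return [r for r in rd.GetRingInfo().AtomRings() if all(rd.GetAtomWithIdx(i).GetIsAromatic() for i in r)]


def _hydrophobic_patches(rd: Chem.Mol) -> list[list[int]]:
    """Connected fragments of >=3 carbon/halogen atoms with no polar neighbour."""
    eligible = set()
    for atom in rd.GetAtoms():
        z = atom.GetAtomicNum()
        if z != 6 and z not in _HALOGEN_Z:
            continue
        if atom.GetFormalCharge() != 0:
            continue
        if any(nb.GetAtomicNum() in _POLAR_Z for nb in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    patches: list[list[int]] = []
    seen: set[int] = set()
    for start in sorted(eligible):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            idx = stack.pop()
            comp.append(idx)
            for nb in rd.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j in eligible and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= 3:
            patches.append(sorted(comp))
    return patches


def perceive_features(mol: Molecule, conformer: Conformer | int = 0) -> list[LigandFeature]:
    """Perceive the interaction features of one conformer.

    A PI nitrogen is never additionally listed as acceptor or donor, so the
    feature set never double-counts the basic amine.
    """
    conf = mol.conformers[conformer] if isinstance(conformer, int) else conformer
    coords = conf.coords
    rd = mol.rdmol
    if coords.shape[0] != rd.GetNumHeavyAtoms():
        raise ValueError("conformer does not belong to this molecule")

    feats: list[LigandFeature] = []
    pi = _pi_atoms(rd)
    for idx in sorted(pi):
        feats.append(LigandFeature("PI", (idx,), coords[idx]))
    hba = {m[0] for p in _HBA_PATTERNS for m in rd.GetSubstructMatches(p)} - pi
    for idx in sorted(hba):
        feats.append(LigandFeature("HBA", (idx,), coords[idx]))
    hbd = {m[0] for m in rd.GetSubstructMatches(_HBD_PATTERN)} - pi
    for idx in sorted(hbd):
        feats.append(LigandFeature("HBD", (idx,), coords[idx]))
    for ring in _aromatic_rings(rd):
        pts = coords[list(ring)]
        centroid = pts.mean(axis=0)
        # ring normal from the two leading principal directions
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=True)
        feats.append(LigandFeature("AI", tuple(ring), centroid, direction=vt[2]))
    for patch in _hydrophobic_patches(rd):
        feats.append(LigandFeature("HC", tuple(patch), coords[patch].mean(axis=0)))
    return feats


# ---------------------------------------------------------------------------
# conformer generation


def generate_conformers(
    mol: Molecule,
    max_n: int = 200,
    seed: int = 0,
    rms_threshold: float = 0.5,
    optimize: bool = True,
) -> list[Conformer]:
    """Distance-geometry conformer ensemble with force-field relaxation.

    Deterministic for a fixed seed; near-duplicate conformers (heavy-atom
    best RMSD below ``rms_threshold``) are pruned.  The default cap of 200
    conformers per molecule suits flexible drug-like ligands; rigid systems
    yield far fewer.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    molh = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.pruneRmsThresh = rms_threshold
    params.useRandomCoords = False
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=max_n, params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=max_n, params=params)
    if len(ids) == 0:
        raise RuntimeError(f"conformer embedding failed for molecule {mol.id!r}")
    energies: dict[int, float | None] = {}
    if optimize:
        try:
            results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=200)
            for cid, (_, e) in zip(ids, results):
                energies[cid] = float(e)
        except Exception:
            pass
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    noh = Chem.RemoveHs(molh)
    kept: list[int] = []
    for cid in ids:
        dup = False
        for prev in kept:
            if rdMolAlign.GetBestRMS(noh, noh, prbId=cid, refId=prev) < rms_threshold:
                dup = True
                break
        if not dup:
            kept.append(cid)
        if len(kept) >= max_n:
            break
    out = []
    for cid in kept:
        pos = molh.GetConformer(cid).GetPositions()[heavy]
        out.append(Conformer(mol.id, pos, energy=energies.get(cid)))
    return out


def from_smiles(smiles: str, mol_id: str = "mol", **kw) -> Molecule:
    """Convenience constructor from a SMILES string."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return Molecule(id=mol_id, rdmol=_prepare(rd), **kw)
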