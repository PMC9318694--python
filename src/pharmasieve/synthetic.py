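"""Synthetic study inputs: reference pharmacophore models, a matched
actives/inactives/decoys benchmark, and simulated HTRF plates.

The four reference models M1'-M4' reproduce the feature-kind and
exclusion-volume compositions of the published screening models (their true
3D coordinates are proprietary, so the geometry here is derived from
template ligands): two "structure-based style" models built on an
arylpiperazine template and two "ligand-based style" models built on a
phenol/arylpiperidine template, each surrounded by a shell of exclusion
volumes.

Actives are decorated variants of the template whose conformers inherit the
template geometry, so they match their parent model by construction.
Inactives are the same chemotypes with the basic nitrogen carbonized, i.e.
they lack the positively ionizable feature every model requires.  Decoys
are assembled from an amide/ester/ether aryl fragment grammar,
property-matched to their parent active within descriptor bins and kept
topologically dissimilar (ECFP4 Tanimoto below a cap) to every active --
the in-silico benchmark convention for challenging a screening model.
"""

from __future__ import annotations


import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .assay import PlateRead, logistic4, saturation_model
from .chem import Conformer, Molecule, compute_descriptors, from_smiles, perceive_features
from .evaluation import ScreeningDataset
from .pharmacophore import (
    ExclusionVolume,
    ModelFeature,
    PharmacophoreModel,
    match_conformer,
)
from .triage import ecfp4, tanimoto

logger = logging.getLogger(__name__)

# template ligands whose conformers define the reference-model geometry
SB_TEMPLATE = "CC(C)COc1cc(CN2CCN(CCc3ccccn3)CC2)ccc1O"
LB_TEMPLATE = "COc1ccc(CCN2CCC(Cc3ccc(O)cc3)CC2)cc1"

FEATURE_TOLERANCE = 1.5  # Angstrom, default feature tolerance in fixtures
XVOL_RADIUS = 1.2        # Angstrom, default exclusion-volume radius
XVOL_SHELL_MARGIN = 3.5  # shell clearance beyond the farthest template atom

#: printed composition of each reference model: (kind counts, n_xvols)
MODEL_COMPOSITIONS = {
    "M1": ({"PI": 1, "HC": 3, "HBA": 2}, 60, "structure-based", SB_TEMPLATE),
    "M2": ({"PI": 1, "HC": 3, "HBA": 1, "HBD": 1}, 113, "structure-based", SB_TEMPLATE),
    "M3": ({"PI": 1, "HB_XOR": 2, "AI": 1, "HC": 1}, 61, "ligand-based", LB_TEMPLATE),
    "M4": ({"PI": 1, "HBA": 1, "HBD": 1, "AI": 1, "HC": 2}, 122, "ligand-based", LB_TEMPLATE),
}


def _template_conformer(smiles: str, seed: int = 2021) -> tuple[Molecule, Conformer]:
    mol = from_smiles(smiles, mol_id="template")
    molh = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise RuntimeError("template embedding failed")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    conf = Conformer(mol.id, molh.GetConformer().GetPositions()[heavy])
    mol.conformers.append(conf)
    return mol, conf


def _fibonacci_shell(n: int, radius: float, center: np.ndarray, phase: float) -> np.ndarray:
    """n quasi-uniform points on a sphere (deterministic; phase rotates the set)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = math.pi * (1 + 5**0.5)
    theta = golden * i + phase
    pts = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return center + radius * pts


def make_reference_models(seed: int = 2021) -> dict[str, PharmacophoreModel]:
    """Build the four reference models with the published feature compositions."""
    out: dict[str, PharmacophoreModel] = {}
    for mid, (composition, n_xvol, provenance, template) in MODEL_COMPOSITIONS.items():
        mol, conf = _template_conformer(template, seed=seed)
        feats = perceive_features(mol, conf)
        by_kind: dict[str, list] = {}
        for f in feats:
            by_kind.setdefault(f.kind, []).append(f)
        for kind in by_kind:
            by_kind[kind].sort(key=lambda f: f.atom_indices)

        features: list[ModelFeature] = []
        xor_groups: list[list[str]] = []
        for kind, count in composition.items():
            if kind == "HB_XOR":
                # one site accepting either donor or acceptor chemistry:
                # two optional features sharing the hydroxyl-oxygen centre,
                # exactly one of which must match
                donors = [f for f in by_kind.get("HBD", []) if f.kind == "HBD"]
                if not donors:
                    raise RuntimeError("template lacks a donor for the XOR site")
                center = donors[0].point
                features.append(ModelFeature("HBA_s", "HBA", center, FEATURE_TOLERANCE, optional=True))
                features.append(ModelFeature("HBD_s", "HBD", center, FEATURE_TOLERANCE, optional=True))
                xor_groups.append(["HBA_s", "HBD_s"])
                continue
            pool = by_kind.get(kind, [])
            if kind == "HBA":
                # keep the basic-site-independent acceptors; skip the hydroxyl
                # oxygen when the model also uses it as donor site
                if "HBD" in composition:
                    donor_atoms = {f.atom_indices for f in by_kind.get("HBD", [])}
                    pool = [f for f in pool if f.atom_indices not in donor_atoms]
            if len(pool) < count:
                raise RuntimeError(f"template provides {len(pool)} {kind} features, need {count}")
            for i in range(count):
                features.append(
                    ModelFeature(f"{kind}_{i + 1}", kind, pool[i].point, FEATURE_TOLERANCE)
                )

        centroid = conf.coords.mean(axis=0)
        r_max = float(np.max(np.linalg.norm(conf.coords - centroid, axis=1)))
        shell = _fibonacci_shell(n_xvol, r_max + XVOL_SHELL_MARGIN, centroid, phase=0.1 * len(out))
        xvols = [ExclusionVolume(p, XVOL_RADIUS) for p in shell]

        out[mid] = PharmacophoreModel(
            id=mid,
            provenance=provenance,
            features=features,
            xvols=xvols,
            xor_groups=xor_groups,
            metadata={"template_smiles": template, "template_seed": seed},
        )
    return out


# ---------------------------------------------------------------------------
# actives / inactives


_DECORATIONS = ("F", "Cl", "C")  # single-atom aromatic substituents
_BOND_LENGTH = {"F": 1.35, "Cl": 1.74, "C": 1.50}


def _aromatic_ch_positions(rd: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in rd.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def _decorate(template: Molecule, conf: Conformer, positions: list[int], symbols: list[str]) -> Molecule | None:
    """Attach single-atom substituents at aromatic CH positions.

    The new atom is placed along the in-plane exocyclic direction of the ring
    carbon, so the core geometry (and hence all perceived core features) is
    exactly the template conformer's.
    """
    rw = Chem.RWMol(template.rdmol)
    coords = [row for row in conf.coords]
    for pos, sym in zip(positions, symbols):
        atom = rw.GetAtomWithIdx(pos)
        ring_nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
        if len(ring_nbrs) < 2:
            return None
        direction = conf.coords[pos] - np.mean([conf.coords[i] for i in ring_nbrs[:2]], axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            return None
        new_idx = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(pos, new_idx, Chem.BondType.SINGLE)
        coords.append(conf.coords[pos] + direction / norm * _BOND_LENGTH[sym])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    out = Molecule(id="", rdmol=mol)
    out.conformers.append(Conformer("", np.array(coords)))
    return out


def _decoration_stream(rng: np.random.Generator, rd: Chem.Mol):
    """Endless stream of (positions, symbols) decoration choices, no repeats."""
    ch = _aromatic_ch_positions(rd)
    seen = set()
    yield [], []
    while True:
        k = int(rng.integers(1, 4))
        if k > len(ch):
            k = len(ch)
        positions = sorted(rng.choice(len(ch), size=k, replace=False))
        symbols = tuple(rng.choice(_DECORATIONS) for _ in range(k))
        key = (tuple(positions), symbols)
        if key in seen:
            continue
        seen.add(key)
        yield [ch[i] for i in positions], list(symbols)


def generate_actives(
    model: PharmacophoreModel, n: int, seed: int = 0, max_attempts_factor: int = 50
) -> list[Molecule]:
    """n decorated template variants that all match ``model`` (verified)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    template_smiles = model.metadata.get("template_smiles")
    if not template_smiles:
        raise ValueError("model carries no template_smiles metadata")
    tmpl, conf = _template_conformer(template_smiles, seed=int(model.metadata.get("template_seed", 2021)))
    rng = np.random.default_rng(seed)
    stream = _decoration_stream(rng, tmpl.rdmol)
    out: list[Molecule] = []
    seen_smiles: set[str] = set()
    attempts = 0
    for positions, symbols in stream:
        attempts += 1
        if attempts > max_attempts_factor * n:
            raise RuntimeError(f"active generation exhausted its retry budget at {len(out)}/{n}")
        cand = _decorate(tmpl, conf, positions, symbols)
        if cand is None or cand.smiles in seen_smiles:
            continue
        feats = perceive_features(cand, cand.conformers[0])
        res = match_conformer(model, cand.conformers[0], feats)
        if not res.passed:
            continue
        seen_smiles.add(cand.smiles)
        cand.id = f"ACT{len(out) + 1:03d}"
        cand.name = cand.smiles
        cand.source = "synthetic-actives"
        cand.conformers[0].molecule_id = cand.id
        out.append(cand)
        if len(out) == n:
            return out
    raise RuntimeError("unreachable")


# carbonized scaffolds: the ring nitrogen of each template replaced by carbon,
# removing the positively ionizable feature every reference model requires
_INACTIVE_BASES = {
    SB_TEMPLATE: "CC(C)COc1cc(CC2CCC(CCc3ccccn3)CC2)ccc1O",
    LB_TEMPLATE: "COc1ccc(CCC2CCC(Cc3ccc(O)cc3)CC2)cc1",
}


def generate_inactives(model: PharmacophoreModel, n: int, seed: int = 0) -> list[Molecule]:
    """n molecules verified NOT to match ``model`` (no protonatable nitrogen)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    template_smiles = model.metadata.get("template_smiles")
    base = _INACTIVE_BASES.get(template_smiles)
    if base is None:
        raise ValueError("no inactive scaffold registered for this model's template")
    tmpl = from_smiles(base, mol_id="inactive-base")
    rng = np.random.default_rng(seed + 1)
    stream = _decoration_stream(rng, tmpl.rdmol)
    out: list[Molecule] = []
    seen: set[str] = set()
    attempts = 0
    # decoration placement needs coordinates only for actives; for inactives
    # a 2D-consistent dummy conformer suffices because the match is decided
    # by the missing-feature prefilter
    for positions, symbols in stream:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("inactive generation exhausted its retry budget")
        rw = Chem.RWMol(tmpl.rdmol)
        for pos, sym in zip(positions, symbols):
            new_idx = rw.AddAtom(Chem.Atom(sym))
            rw.AddBond(pos, new_idx, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        cand = Molecule(id=f"INA{len(out) + 1:03d}", rdmol=mol, name=smi, source="synthetic-inactives")
        from .pharmacophore import match_molecule

        if match_molecule(model, cand, conformer_cap=1, seed=seed) is not None:
            continue
        seen.add(smi)
        out.append(cand)
        if len(out) == n:
            return out
    raise RuntimeError("unreachable")


# ---------------------------------------------------------------------------
# decoys


@dataclass
class BenchmarkSpec:
    """Benchmark composition and decoy-matching windows.

    Defaults emulate the published benchmark: 68 actives, 68 inactives and
    55 property-matched decoys per active (3740 in total), each decoy inside
    the descriptor bins of its parent active and with ECFP4 Tanimoto below
    0.3 to every active.
    """

    n_actives: int = 68
    n_inactives: int = 68
    decoys_per_active: int = 55
    seed: int = 7
    mw_bin: float = 25.0
    clogp_bin: float = 1.0
    hbd_bin: int = 1
    hba_bin: int = 1
    rot_bin: int = 2
    max_decoy_ts: float = 0.3

    def __post_init__(self) -> None:
        for name in ("mw_bin", "clogp_bin", "hbd_bin", "hba_bin", "rot_bin"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.max_decoy_ts < 1:
            raise ValueError("max_decoy_ts must be in (0, 1)")


# fragment grammar for decoys: aryl terminals, polar linkers, ring middles.
# None of the nitrogens is basic, so no decoy presents a PI feature.
_TERMINALS = [
    "[*]c1ccccc1", "[*]c1ccc(C)cc1", "[*]c1ccc(Cl)cc1", "[*]c1ccc(OC)cc1",
    "[*]c1ccc2ccccc2c1", "[*]c1ccc(F)cc1", "[*]c1ccc(Cl)c(Cl)c1",
    "[*]c1cccnc1", "[*]c1ccc(C(F)(F)F)cc1", "[*]Cc1ccccc1", "[*]CCc1ccccc1",
    "[*]C1CCCCC1", "[*]c1ccc(O)cc1", "[*]c1cccs1", "[*]c1ccc(CC)cc1",
    "[*]c1ccc(OC(F)F)cc1", "[*]Cc1ccc(Cl)cc1", "[*]c1ccc(SC)cc1",
]
_LINKERS = [
    "[*]C(=O)N[*]", "[*]C(=O)O[*]", "[*]O[*]", "[*]CO[*]", "[*]S(=O)(=O)N[*]",
    "[*]C(=O)[*]", "[*]CC[*]", "[*]CCC[*]", "[*]NC(=O)N[*]", "[*]OCC[*]",
    "[*]C(=O)NC[*]", "[*]CNC(=O)[*]",
]
_MIDDLES = [
    "[*]c1ccc([*])cc1", "[*]c1cccc([*])c1", "[*]C1CCC([*])CC1",
    "[*]c1ccc([*])o1", "[*]c1ccc([*])s1", "[*]c1ccc2cc([*])ccc2c1",
]


def _attachment_join(a: Chem.Mol, b: Chem.Mol) -> Chem.Mol:
    """Join two fragments through one ``[*]`` attachment point of each."""
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    dummies = [atom.GetIdx() for atom in combo.GetAtoms() if atom.GetAtomicNum() == 0]
    da = next(i for i in dummies if i < a.GetNumAtoms())
    db = next(i for i in dummies if i >= a.GetNumAtoms())
    na = combo.GetAtomWithIdx(da).GetNeighbors()[0].GetIdx()
    nb = combo.GetAtomWithIdx(db).GetNeighbors()[0].GetIdx()
    combo.AddBond(na, nb, Chem.BondType.SINGLE)
    for idx in sorted((da, db), reverse=True):
        combo.RemoveAtom(idx)
    return combo.GetMol()


def _assemble(parts: list[str]) -> Chem.Mol | None:
    mols = [Chem.MolFromSmiles(p) for p in parts]
    if any(m is None for m in mols):
        return None
    cur = mols[0]
    for nxt in mols[1:]:
        cur = _attachment_join(cur, nxt)
    try:
        Chem.SanitizeMol(cur)
    except Exception:
        return None
    if any(a.GetAtomicNum() == 0 for a in cur.GetAtoms()):
        return None
    return cur


_FRAG_MW = None


def _fragment_mw():
    global _FRAG_MW
    if _FRAG_MW is None:
        from rdkit.Chem import Descriptors

        def mw(smi):
            # dummy atoms are massless and carry no implicit H, so MolWt of a
            # fragment is already its contribution to the assembled molecule
            return Descriptors.MolWt(Chem.MolFromSmiles(smi))

        _FRAG_MW = {
            "T": [mw(s) for s in _TERMINALS],
            "L": [mw(s) for s in _LINKERS],
            "M": [mw(s) for s in _MIDDLES],
        }
    return _FRAG_MW


def _sample_decoy(rng: np.random.Generator, mw_lo: float, mw_hi: float) -> Chem.Mol | None:
    """Draw one candidate whose additive fragment mass falls in [mw_lo, mw_hi]."""
    fw = _fragment_mw()
    for _ in range(200):
        five = rng.random() < 0.8
        ti = rng.integers(0, len(_TERMINALS), size=2)
        li = rng.integers(0, len(_LINKERS), size=2 if five else 1)
        mi = int(rng.integers(0, len(_MIDDLES))) if five else None
        est = fw["T"][ti[0]] + fw["T"][ti[1]] + sum(fw["L"][j] for j in li)
        if five:
            est += fw["M"][mi]
        if not (mw_lo - 5 <= est <= mw_hi + 5):
            continue
        parts = [_TERMINALS[ti[0]]]
        parts.append(_LINKERS[li[0]])
        if five:
            parts.append(_MIDDLES[mi])
            parts.append(_LINKERS[li[1]])
        parts.append(_TERMINALS[ti[1]])
        return _assemble(parts)
    return None


def generate_decoys(actives: list[Molecule], spec: BenchmarkSpec) -> list[Molecule]:
    """Property-matched, topologically dissimilar decoys for each active."""
    if not actives:
        raise ValueError("decoy generation requires at least one active")
    rng = np.random.default_rng(spec.seed + 17)
    parent_desc = {m.id: compute_descriptors(m) for m in actives}
    active_fps = [ecfp4(m) for m in actives]
    need = {m.id: spec.decoys_per_active for m in actives}
    mw_values = sorted(d.mw for d in parent_desc.values())
    out: list[Molecule] = []
    seen: set[str] = set()
    attempts = 0
    budget = 400 * spec.decoys_per_active * len(actives)
    parents = [m.id for m in actives]
    while any(v > 0 for v in need.values()):
        attempts += 1
        if attempts > budget:
            short = {k: v for k, v in need.items() if v > 0}
            raise RuntimeError(f"decoy bins infeasible for parents {sorted(short)[:5]} (and {len(short)} total)")
        # aim at a parent that still needs decoys
        open_parents = [p for p in parents if need[p] > 0]
        target = open_parents[int(rng.integers(0, len(open_parents)))]
        td = parent_desc[target]
        cand = _sample_decoy(rng, td.mw - spec.mw_bin, td.mw + spec.mw_bin)
        if cand is None:
            continue
        smi = Chem.MolToSmiles(cand)
        if smi in seen:
            continue
        d = compute_descriptors(cand)
        # assign to the first open parent whose every bin accepts the candidate
        assigned = None
        for p in open_parents:
            pd = parent_desc[p]
            if (
                abs(d.mw - pd.mw) <= spec.mw_bin
                and abs(d.clogp - pd.clogp) <= spec.clogp_bin
                and abs(d.hbd_count - pd.hbd_count) <= spec.hbd_bin
                and abs(d.hba_count - pd.hba_count) <= spec.hba_bin
                and abs(d.rotatable_bonds - pd.rotatable_bonds) <= spec.rot_bin
            ):
                assigned = p
                break
        if assigned is None:
            continue
        fp = ecfp4(cand)
        if max(tanimoto(fp, afp) for afp in active_fps) >= spec.max_decoy_ts:
            continue
        seen.add(smi)
        need[assigned] -= 1
        out.append(
            Molecule(
                id=f"DEC{len(out) + 1:04d}", rdmol=cand, name=smi,
                source=f"synthetic-decoys parent={assigned}",
            )
        )
    return out


def generate_benchmark(
    model: PharmacophoreModel, spec: BenchmarkSpec | None = None
) -> ScreeningDataset:
    """Full benchmark in the published proportions for one reference model."""
    spec = spec or BenchmarkSpec()
    actives = generate_actives(model, spec.n_actives, seed=spec.seed)
    inactives = generate_inactives(model, spec.n_inactives, seed=spec.seed)
    decoys = generate_decoys(actives, spec)
    return ScreeningDataset(actives=actives, inactives=inactives, decoys=decoys)


# ---------------------------------------------------------------------------
# HTRF plate simulation


@dataclass
class PlateSpec:
    """Ground truth and layout of a simulated HTRF plate.

    Concentrations are mol/L.  Fluorescence noise is multiplicative Gaussian
    with the stated coefficient of variation, matching the proportional error
    of fluorescence counting.  620-nm counts are held at a fixed level so all
    signal variation appears in the 665/620 ratio.
    """

    kd: float = 2e-9
    bmax: float = 6000.0
    r0: float = 800.0
    ns_slope: float = 0.0
    tracer_conc: float = 2e-9
    ki: dict[str, float] = field(default_factory=lambda: {"CMP1": 0.32e-6})
    hill: float = 1.0
    bottom_fraction: float = 0.15  # residual specific signal at full displacement
    concentrations: list[float] | None = None  # per-compound grid override
    n_points: int = 8
    span_decades: float = 5.0
    replicates: int = 3
    noise_cv: float = 0.05
    f620: float = 25000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.concentrations is not None:
            cs = list(self.concentrations)
            if any(c <= 0 for c in cs) or cs != sorted(cs):
                raise ValueError("concentrations must be positive and sorted")


def _noisy_wells(rng, role, compound, concs, ratios, spec, start_index):
    wells = []
    idx = start_index
    for conc, ratio in zip(concs, ratios):
        for rep in range(spec.replicates):
            noise = 1.0 + spec.noise_cv * rng.standard_normal() if spec.noise_cv > 0 else 1.0
            f665 = max(ratio * noise, 0.0) * spec.f620 / 1.0e4
            wells.append(
                PlateRead(
                    well=f"W{idx:03d}", role=role, compound=compound,
                    concentration=conc, f620=spec.f620, f665=f665, replicate=rep,
                )
            )
            idx += 1
    return wells, idx


def simulate_saturation_plate(spec: PlateSpec) -> list[PlateRead]:
    """Tracer titration wells drawn from the one-site saturation model."""
    rng = np.random.default_rng(spec.seed)
    concs = spec.concentrations or list(
        np.geomspace(spec.kd / 30.0, spec.kd * 30.0, spec.n_points)
    )
    ratios = [saturation_model(c, spec.r0, spec.ns_slope, spec.bmax, spec.kd) for c in concs]
    wells, idx = _noisy_wells(rng, "compound", "tracer", concs, ratios, spec, 1)
    blank, _ = _noisy_wells(rng, "background", None, [None] * 2, [spec.r0] * 2, spec, idx)
    return wells + blank


def _competition_top_bottom(spec: PlateSpec) -> tuple[float, float]:
    specific = spec.bmax * spec.tracer_conc / (spec.kd + spec.tracer_conc)
    top = spec.r0 + specific
    bottom = spec.r0 + spec.bottom_fraction * specific
    return top, bottom


def simulate_competition_plate(spec: PlateSpec) -> list[PlateRead]:
    """Displacement curves for each compound in ``spec.ki`` plus reference wells.

    The dilution series is placed around each compound's expected IC50
    (= KI * (1 + L*/KD)), mimicking how working concentrations are chosen
    from expected potency.  Includes tracer-only and control wells so the
    plate also supports DNF analysis.
    """
    rng = np.random.default_rng(spec.seed)
    top, bottom = _competition_top_bottom(spec)
    wells: list[PlateRead] = []
    idx = 1
    # tracer-only: undisplaced signal; control: a known ligand producing a
    # small fixed displacement (the replicate loop supplies the copies)
    w, idx = _noisy_wells(rng, "tracer_only", None, [None], [top], spec, idx)
    wells.extend(w)
    control_ratio = top - 0.05 * (top - bottom)
    w, idx = _noisy_wells(rng, "control", None, [None], [control_ratio], spec, idx)
    wells.extend(w)
    for name in sorted(spec.ki):
        ic50 = spec.ki[name] * (1.0 + spec.tracer_conc / spec.kd)
        if spec.concentrations is not None:
            concs = list(spec.concentrations)
        else:
            half = spec.span_decades / 2.0
            concs = list(np.geomspace(ic50 * 10**-half, ic50 * 10**half, spec.n_points))
        ratios = [logistic4(c, top, bottom, np.log10(ic50), spec.hill) for c in concs]
        w, idx = _noisy_wells(rng, "compound", name, concs, ratios, spec, idx)
        wells.extend(w)
    return wells
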