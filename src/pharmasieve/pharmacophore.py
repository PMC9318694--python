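"""Pharmacophore models: schema, tolerance-sphere matching, scoring, optimization.

A model is a set of labelled feature points with tolerance radii plus
exclusion volumes (XVOLs) representing receptor bulk.  A conformer matches
when an injective, kind-compatible assignment of its perceived features to
the model features exists such that, after least-squares rigid superposition,
every paired ligand feature lies within the tolerance sphere of its model
feature and no heavy atom falls inside an exclusion volume.

Matching is alignment-based, so pass/fail and fit score are invariant under
rigid motion of the input conformer.
"""

from __future__ import annotations

import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import FEATURE_KINDS, Conformer, LigandFeature, Molecule, feature_kind_counts, generate_conformers, perceive_features

logger = logging.getLogger(__name__)


@dataclass
class ModelFeature:
    label: str
    kind: str
    center: np.ndarray
    tolerance: float
    optional: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.label}: unknown kind {self.kind!r}")
        if not self.tolerance > 0:
            raise ValueError(f"feature {self.label}: tolerance must be > 0")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class ExclusionVolume:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("exclusion volume radius must be > 0")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    """A screening query: features, exclusion volumes, optional XOR groups.

    An XOR group is a set of feature labels of which exactly one must be
    matched; it encodes a model position that accepts alternative feature
    kinds (e.g. a site that may act as either H-bond acceptor or donor).
    Features inside an XOR group are marked optional individually.
    """

    id: str
    features: list[ModelFeature]
    xvols: list[ExclusionVolume] = field(default_factory=list)
    provenance: str = "ligand-based"
    xor_groups: list[list[str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError("feature labels must be unique")
        known = set(labels)
        for grp in self.xor_groups:
            unknown = set(grp) - known
            if unknown:
                raise ValueError(f"xor group references unknown labels {sorted(unknown)}")

    @property
    def required_labels(self) -> list[str]:
        return [f.label for f in self.features if not f.optional]

    def feature(self, label: str) -> ModelFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def kind_requirements(self) -> dict[str, int]:
        """Minimum count of ligand features per kind for any chance of a match."""
        req: dict[str, int] = {}
        for f in self.features:
            if not f.optional:
                req[f.kind] = req.get(f.kind, 0) + 1
        return req


@dataclass
class MatchResult:
    model_id: str
    molecule_id: str
    conformer_index: int
    pairs: list[tuple[str, int]]
    rmsd: float
    per_pair_distance: list[float]
    fit_score: float
    passed: bool
    fail_reason: str | None = None  # missing-feature | tolerance | xvol-clash
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    aligned_atoms: np.ndarray | None = None  # heavy atoms in the model frame


@dataclass
class HitRecord:
    molecule_id: str
    match: MatchResult


# ---------------------------------------------------------------------------
# schema I/O


def model_to_dict(model: PharmacophoreModel) -> dict:
    return {
        "id": model.id,
        "provenance": model.provenance,
        "features": [
            {
                "label": f.label,
                "kind": f.kind,
                "center": [float(v) for v in f.center],
                "tolerance": float(f.tolerance),
                "optional": bool(f.optional),
            }
            for f in model.features
        ],
        "xvols": [
            {"center": [float(v) for v in x.center], "radius": float(x.radius)}
            for x in model.xvols
        ],
        "xor_groups": [list(g) for g in model.xor_groups],
        "metadata": dict(model.metadata),
    }


def model_from_dict(doc: dict) -> PharmacophoreModel:
    def _fail(path: str, msg: str):
        raise ValueError(f"model schema error at {path}: {msg}")

    if not isinstance(doc, dict):
        _fail("$", "document must be an object")
    for key in ("id", "features"):
        if key not in doc:
            _fail(f"$.{key}", "missing required field")
    features = []
    for i, fd in enumerate(doc["features"]):
        for key in ("label", "kind", "center", "tolerance"):
            if key not in fd:
                _fail(f"$.features[{i}].{key}", "missing required field")
        if fd["kind"] not in FEATURE_KINDS:
            _fail(f"$.features[{i}].kind", f"must be one of {FEATURE_KINDS}")
        if not isinstance(fd["center"], (list, tuple)) or len(fd["center"]) != 3:
            _fail(f"$.features[{i}].center", "must be a 3-vector")
        if not (isinstance(fd["tolerance"], (int, float)) and fd["tolerance"] > 0):
            _fail(f"$.features[{i}].tolerance", "must be a number > 0")
        features.append(
            ModelFeature(
                label=str(fd["label"]),
                kind=fd["kind"],
                center=fd["center"],
                tolerance=float(fd["tolerance"]),
                optional=bool(fd.get("optional", False)),
            )
        )
    xvols = []
    for i, xd in enumerate(doc.get("xvols", [])):
        if "center" not in xd or "radius" not in xd:
            _fail(f"$.xvols[{i}]", "must have center and radius")
        if not (isinstance(xd["radius"], (int, float)) and xd["radius"] > 0):
            _fail(f"$.xvols[{i}].radius", "must be a number > 0")
        xvols.append(ExclusionVolume(center=xd["center"], radius=float(xd["radius"])))
    try:
        return PharmacophoreModel(
            id=str(doc["id"]),
            provenance=doc.get("provenance", "ligand-based"),
            features=features,
            xvols=xvols,
            xor_groups=[list(g) for g in doc.get("xor_groups", [])],
            metadata=dict(doc.get("metadata", {})),
        )
    except ValueError as exc:
        _fail("$", str(exc))


def save_model(model: PharmacophoreModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def load_model(path: str) -> PharmacophoreModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# geometry


def align_pairs(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of point pairs.

    Returns ``(R, t, rmsd)`` with ``moving @ R.T + t`` approximating
    ``target``.  A single pair degenerates to pure translation.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if moving.shape != target.shape:
        raise ValueError("point sets must have equal shape")
    n = moving.shape[0]
    if n == 0:
        return np.eye(3), np.zeros(3), 0.0
    cm, ct = moving.mean(axis=0), target.mean(axis=0)
    if n == 1:
        return np.eye(3), ct - cm, 0.0
    P, Q = moving - cm, target - ct
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    diff = moving @ R.T + t - target
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ R.T + t


# ---------------------------------------------------------------------------
# mapping enumeration


def enumerate_mappings(
    model: PharmacophoreModel, feats: list[LigandFeature]
) -> list[dict[str, int]]:
    """All injective, kind-compatible assignments surviving distance pruning.

    Every non-optional model feature must be assigned; optional features may
    be left out.  Distance pruning: for every assigned pair of model features
    i, j the inter-feature distances must satisfy
    ``|d_model(i,j) - d_ligand(i,j)| <= tol_i + tol_j``.
    """
    order = sorted(model.features, key=lambda f: (f.optional, f.label))
    lig_by_kind: dict[str, list[int]] = {}
    for idx, lf in enumerate(feats):
        lig_by_kind.setdefault(lf.kind, []).append(idx)

    results: list[dict[str, int]] = []
    assignment: dict[str, int] = {}
    used: set[int] = set()

    def backtrack(pos: int) -> None:
        if pos == len(order):
            results.append(dict(assignment))
            return
        mf = order[pos]
        candidates = lig_by_kind.get(mf.kind, [])
        for lig_idx in candidates:
            if lig_idx in used:
                continue
            ok = True
            for lbl, other_idx in assignment.items():
                other = model.feature(lbl)
                dm = float(np.linalg.norm(mf.center - other.center))
                dl = float(np.linalg.norm(feats[lig_idx].point - feats[other_idx].point))
                if abs(dm - dl) > mf.tolerance + other.tolerance:
                    ok = False
                    break
            if ok:
                assignment[mf.label] = lig_idx
                used.add(lig_idx)
                backtrack(pos + 1)
                used.discard(lig_idx)
                del assignment[mf.label]
        if mf.optional:
            backtrack(pos + 1)

    backtrack(0)
    return results


def _xor_satisfied(model: PharmacophoreModel, assignment: dict[str, int]) -> bool:
    for grp in model.xor_groups:
        if sum(1 for lbl in grp if lbl in assignment) != 1:
            return False
    return True


# ---------------------------------------------------------------------------
# scoring and matching


def fit_score(pairs_distances: list[float], tolerances: list[float]) -> float:
    """S = 10 n + 9 (1 - mean(d_i / tol_i)), geometric term clamped to [0, 9].

    Strictly increasing in the number of matched features and strictly
    decreasing in each pair distance; only the ordering it induces is
    load-bearing downstream.
    """
    n = len(pairs_distances)
    if n == 0:
        return 0.0
    mean_frac = float(np.mean([d / t for d, t in zip(pairs_distances, tolerances)]))
    geom = min(9.0, max(0.0, 9.0 * (1.0 - mean_frac)))
    return 10.0 * n + geom


def match_conformer(
    model: PharmacophoreModel,
    conf: Conformer,
    feats: list[LigandFeature],
    conformer_index: int = 0,
) -> MatchResult:
    """Best pass/fail match of one conformer against a model.

    Evaluates every surviving feature assignment, superposes the paired
    points, and checks tolerance spheres and exclusion volumes.  Among passing
    assignments the highest fit score wins; ties break on the
    lexicographically smallest assignment.
    """
    def _failed(reason: str) -> MatchResult:
        return MatchResult(
            model_id=model.id, molecule_id=conf.molecule_id,
            conformer_index=conformer_index, pairs=[], rmsd=float("nan"),
            per_pair_distance=[], fit_score=0.0, passed=False, fail_reason=reason,
        )

    if not model.features:
        return MatchResult(
            model_id=model.id, molecule_id=conf.molecule_id,
            conformer_index=conformer_index, pairs=[], rmsd=0.0,
            per_pair_distance=[], fit_score=0.0, passed=True,
            rotation=np.eye(3), translation=np.zeros(3),
        )

    have = {}
    for lf in feats:
        have[lf.kind] = have.get(lf.kind, 0) + 1
    for kind, need in model.kind_requirements().items():
        if have.get(kind, 0) < need:
            return _failed("missing-feature")

    assignments = enumerate_mappings(model, feats)
    assignments = [a for a in assignments if _xor_satisfied(model, a)]
    if not assignments:
        return _failed("missing-feature" if not model.xor_groups else "tolerance")

    best: MatchResult | None = None
    best_key: tuple | None = None
    saw_tolerance_ok = False
    for assignment in assignments:
        items = sorted(assignment.items())
        if not items:
            continue
        labels = [lbl for lbl, _ in items]
        lig_pts = np.array([feats[idx].point for _, idx in items])
        mdl_pts = np.array([model.feature(lbl).center for lbl in labels])
        R, t, rmsd = align_pairs(lig_pts, mdl_pts)
        dists = list(np.linalg.norm(lig_pts @ R.T + t - mdl_pts, axis=1))
        tols = [model.feature(lbl).tolerance for lbl in labels]
        if any(d > tol for d, tol in zip(dists, tols)):
            continue
        saw_tolerance_ok = True
        atoms = apply_transform(conf.coords, R, t)
        clash = False
        for xv in model.xvols:
            if np.any(np.linalg.norm(atoms - xv.center, axis=1) < xv.radius):
                clash = True
                break
        if clash:
            continue
        score = fit_score(dists, tols)
        key = (-score, tuple(items))
        if best_key is None or key < best_key:
            best_key = key
            best = MatchResult(
                model_id=model.id, molecule_id=conf.molecule_id,
                conformer_index=conformer_index, pairs=items, rmsd=rmsd,
                per_pair_distance=dists, fit_score=score, passed=True,
                rotation=R, translation=t, aligned_atoms=atoms,
            )
    if best is not None:
        return best
    return _failed("xvol-clash" if saw_tolerance_ok else "tolerance")


def match_molecule(
    model: PharmacophoreModel,
    mol: Molecule,
    conformer_cap: int = 200,
    seed: int = 0,
) -> MatchResult | None:
    """Best passing match over a molecule's conformers (``None`` if none pass).

    Molecules lacking a required feature kind are rejected before any 3D work,
    and existing conformers are used as-is; conformers are generated only when
    the molecule carries none.
    """
    counts = feature_kind_counts(mol)
    for kind, need in model.kind_requirements().items():
        if counts.get(kind, 0) < need:
            return None
    confs = mol.conformers
    if not confs:
        confs = generate_conformers(mol, max_n=conformer_cap, seed=_molecule_seed(seed, mol.id))
    best: MatchResult | None = None
    for ci, conf in enumerate(confs):
        feats = perceive_features(mol, conf)
        res = match_conformer(model, conf, feats, conformer_index=ci)
        if res.passed and (best is None or res.fit_score > best.fit_score):
            best = res
    return best


def _molecule_seed(seed: int, mol_id: str) -> int:
    return (int(seed) * 1000003 + zlib.crc32(mol_id.encode())) % (2**31 - 1)


def screen(
    model: PharmacophoreModel,
    library: list[Molecule],
    conformer_cap: int = 200,
    seed: int = 0,
) -> list[HitRecord]:
    """Screen a library; one record per passing molecule, best conformer first."""
    hits = []
    for mol in library:
        res = match_molecule(model, mol, conformer_cap=conformer_cap, seed=seed)
        if res is not None and res.passed:
            hits.append(HitRecord(molecule_id=mol.id, match=res))
    return hits


# ---------------------------------------------------------------------------
# greedy model optimization


@dataclass
class OptimizerConfig:
    delta: float = 0.1           # Angstrom step for tolerance / XVOL moves
    min_tolerance: float = 0.2   # never shrink a feature below this radius
    new_xvol_radius: float = 1.2
    sensitivity_floor: float | None = None  # default: input model's sensitivity
    move_budget: int = 50
    conformer_cap: int = 30
    seed: int = 0
    max_xvol_candidates: int = 5


def _screen_sets(model, actives, inactives, decoys, cfg):
    hits_a = screen(model, actives, cfg.conformer_cap, cfg.seed)
    hits_i = screen(model, inactives, cfg.conformer_cap, cfg.seed)
    hits_d = screen(model, decoys, cfg.conformer_cap, cfg.seed)
    return hits_a, hits_i, hits_d


def _ef_sens(hits_a, hits_i, hits_d, n_act, n_inact, n_dec):
    tp = len(hits_a)
    fp = len(hits_i) + len(hits_d)
    total = n_act + n_inact + n_dec
    sens = tp / n_act
    yoa = tp / (tp + fp) if tp + fp else 0.0
    ef = yoa / (n_act / total)
    return ef, sens, fp


def optimize_model(
    model: PharmacophoreModel,
    actives: list[Molecule],
    inactives: list[Molecule],
    decoys: list[Molecule],
    config: OptimizerConfig | None = None,
) -> PharmacophoreModel:
    """Greedy restrictiveness optimization of a pharmacophore model.

    Candidate moves: shrink one feature tolerance by delta, enlarge one XVOL
    by delta, add an XVOL at a false-positive atom hotspot, remove one
    feature, or mark one feature optional.  A move is kept only if the
    enrichment factor does not decrease and sensitivity stays at or above the
    configured floor; an added XVOL must eliminate at least one inactive or
    decoy without any loss of sensitivity.  The loop stops when no move
    improves (EF, false-positive count) or the move budget is exhausted, so
    the returned model's EF is never below the input's.
    """
    if not actives:
        raise ValueError("optimization requires at least one active")
    cfg = config or OptimizerConfig()
    n_act, n_inact, n_dec = len(actives), len(inactives), len(decoys)

    cur = model
    hits = _screen_sets(cur, actives, inactives, decoys, cfg)
    cur_ef, cur_sens, cur_fp = _ef_sens(*hits, n_act, n_inact, n_dec)
    floor = cfg.sensitivity_floor if cfg.sensitivity_floor is not None else cur_sens
    trace = [cur_ef]

    for _ in range(cfg.move_budget):
        candidates = list(_moves(cur, hits, actives, cfg))
        best = None
        for cand, is_xvol_add in candidates:
            cand_hits = _screen_sets(cand, actives, inactives, decoys, cfg)
            ef, sens, fp = _ef_sens(*cand_hits, n_act, n_inact, n_dec)
            if sens < floor or ef < cur_ef:
                continue
            if is_xvol_add and (fp >= cur_fp or sens < cur_sens):
                continue  # an added XVOL must eliminate a false positive
            improving = ef > cur_ef or (ef == cur_ef and fp < cur_fp)
            if not improving:
                continue
            key = (ef, -fp)
            if best is None or key > best[0]:
                best = (key, cand, cand_hits, ef, sens, fp)
        if best is None:
            break
        _, cur, hits, cur_ef, cur_sens, cur_fp = best
        trace.append(cur_ef)

    cur = replace(cur, metadata={**cur.metadata, "ef_trace": trace})
    return cur


def _moves(model: PharmacophoreModel, hits, actives, cfg: OptimizerConfig):
    # shrink a tolerance
    for i, f in enumerate(model.features):
        if f.tolerance - cfg.delta >= cfg.min_tolerance:
            feats = list(model.features)
            feats[i] = replace(f, tolerance=f.tolerance - cfg.delta)
            yield replace(model, features=feats), False
    # enlarge an XVOL
    for i, xv in enumerate(model.xvols):
        xvols = list(model.xvols)
        xvols[i] = ExclusionVolume(xv.center, xv.radius + cfg.delta)
        yield replace(model, xvols=xvols), False
    # add an XVOL at a false-positive atom hotspot
    for center in _xvol_hotspots(model, hits, actives, cfg):
        xvols = list(model.xvols) + [ExclusionVolume(center, cfg.new_xvol_radius)]
        yield replace(model, xvols=xvols), True
    # remove a feature / mark one optional (keep >=1 required feature)
    n_required = len(model.required_labels)
    grouped = {lbl for grp in model.xor_groups for lbl in grp}
    for i, f in enumerate(model.features):
        if f.label in grouped:
            continue
        if not f.optional and n_required <= 1:
            continue
        feats = [g for j, g in enumerate(model.features) if j != i]
        yield replace(model, features=feats), False
        if not f.optional:
            feats2 = list(model.features)
            feats2[i] = replace(f, optional=True)
            yield replace(model, features=feats2), False


def _xvol_hotspots(model, hits, actives, cfg: OptimizerConfig):
    """Candidate centres for new XVOLs.

    False-positive heavy-atom positions (in the model frame) that lie clear of
    every aligned true-positive atom; ranked by how many false-positive atoms
    a new sphere there would cover.
    """
    hits_a, hits_i, hits_d = hits
    active_atoms = [h.match.aligned_atoms for h in hits_a if h.match.aligned_atoms is not None]
    active_atoms = np.vstack(active_atoms) if active_atoms else np.zeros((0, 3))
    fp_atoms = [h.match.aligned_atoms for h in itertools.chain(hits_i, hits_d)
                if h.match.aligned_atoms is not None]
    if not fp_atoms:
        return []
    fp_all = np.vstack(fp_atoms)
    scored: list[tuple[int, tuple[float, float, float]]] = []
    for pos in fp_all:
        if active_atoms.size and np.min(np.linalg.norm(active_atoms - pos, axis=1)) <= cfg.new_xvol_radius:
            continue
        coverage = int(np.sum(np.linalg.norm(fp_all - pos, axis=1) < cfg.new_xvol_radius))
        scored.append((coverage, tuple(float(v) for v in pos)))
    scored.sort(key=lambda s: (-s[0], s[1]))
    seen = set()
    out = []
    for _, pos in scored:
        key = tuple(round(v, 2) for v in pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(np.array(pos))
        if len(out) >= cfg.max_xvol_candidates:
            break
    return out
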