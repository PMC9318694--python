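"""Independent oracles and toy-instance generators for matcher validation.

Kept separate from any implementation path they check: exhaustive search over
assignments for pass/fail, and Horn's quaternion method for superposition.
"""

import itertools

import numpy as np

from pharmasieve.chem import Conformer, LigandFeature
from pharmasieve.pharmacophore import (
    ExclusionVolume,
    ModelFeature,
    PharmacophoreModel,
    align_pairs,
)

KINDS = ("PI", "HBA", "HBD", "HC", "AI")


def quaternion_superpose(moving, target):
    """Horn's closed-form quaternion solution; independent of the Kabsch path."""
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    P = moving - moving.mean(axis=0)
    Q = target - target.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]
    a, b, c, d = q
    R = np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )
    rot = P @ R.T
    return float(np.sqrt(np.mean(np.sum((rot - Q) ** 2, axis=1))))


def oracle_match(model: PharmacophoreModel, coords, feats) -> bool:
    """Exhaustive pass/fail matcher: every optional subset, every injective
    kind-compatible assignment, full alignment and tolerance/XVOL checks."""
    if not model.features:
        return True
    required = [f for f in model.features if not f.optional]
    optional = [f for f in model.features if f.optional]
    for r in range(len(optional) + 1):
        for opt_subset in itertools.combinations(optional, r):
            sel = required + list(opt_subset)
            labels = {f.label for f in sel}
            if any(sum(l in labels for l in grp) != 1 for grp in model.xor_groups):
                continue
            if not sel:
                continue
            for perm in itertools.permutations(range(len(feats)), len(sel)):
                if any(feats[j].kind != f.kind for f, j in zip(sel, perm)):
                    continue
                lig = np.array([feats[j].point for j in perm])
                mdl = np.array([f.center for f in sel])
                R, t, _ = align_pairs(lig, mdl)
                d = np.linalg.norm(lig @ R.T + t - mdl, axis=1)
                if any(di > f.tolerance for di, f in zip(d, sel)):
                    continue
                atoms = np.asarray(coords) @ R.T + t
                if any(
                    np.any(np.linalg.norm(atoms - xv.center, axis=1) < xv.radius)
                    for xv in model.xvols
                ):
                    continue
                return True
    return False


def random_instance(rng, max_model=4, max_lig=6, planted=False):
    k = int(rng.integers(0, max_model + 1))
    feats_m = [
        ModelFeature(
            f"F{i}", KINDS[rng.integers(0, 5)], rng.uniform(-4, 4, 3),
            float(rng.uniform(0.8, 1.6)), optional=bool(rng.random() < 0.2),
        )
        for i in range(k)
    ]
    if feats_m and all(f.optional for f in feats_m):
        feats_m[0].optional = False
    xvols = [
        ExclusionVolume(rng.uniform(-5, 5, 3), float(rng.uniform(0.5, 1.5)))
        for _ in range(int(rng.integers(0, 3)))
    ]
    model = PharmacophoreModel("toy", feats_m, xvols=xvols)
    j = int(rng.integers(0, max_lig + 1))
    if planted and feats_m:
        pts = [f.center + rng.normal(scale=0.5, size=3) for f in feats_m]
        kinds = [f.kind for f in feats_m]
        while len(pts) < j:
            pts.append(rng.uniform(-4, 4, 3))
            kinds.append(KINDS[rng.integers(0, 5)])
    else:
        pts = [rng.uniform(-4, 4, 3) for _ in range(j)]
        kinds = [KINDS[rng.integers(0, 5)] for _ in range(j)]
    feats_l = [LigandFeature(kd, (i,), p) for i, (kd, p) in enumerate(zip(kinds, pts))]
    coords = np.array([f.point for f in feats_l]).reshape(-1, 3)
    conf = Conformer("lig", coords) if len(coords) else Conformer("lig", np.zeros((0, 3)))
    return model, conf, feats_l
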