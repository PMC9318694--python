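"""Model schema, alignment, matching (against independent oracles), optimization."""

import itertools
import json

import numpy as np
import pytest

from pharmasieve import chem, pharmacophore as ph
from pharmasieve.chem import Conformer, LigandFeature
from _oracles import oracle_match, quaternion_superpose, random_instance
from pharmasieve.pharmacophore import (
    ExclusionVolume,
    ModelFeature,
    PharmacophoreModel,
    align_pairs,
    enumerate_mappings,
    fit_score,
    match_conformer,
)

# ---------------------------------------------------------------------------
# schema


def _toy_model():
    return PharmacophoreModel(
        "T",
        [
            ModelFeature("PI_1", "PI", [0.0, 0.0, 0.0], 1.5),
            ModelFeature("AI_1", "AI", [4.0, 0.0, 0.0], 1.5),
            ModelFeature("HBA_1", "HBA", [2.0, 2.0, 0.0], 1.2, optional=True),
        ],
        xvols=[ExclusionVolume([0.0, 5.0, 0.0], 1.0)],
        metadata={"note": "toy"},
    )


def test_model_round_trip_is_exact(tmp_path):
    model = _toy_model()
    path = tmp_path / "m.json"
    ph.save_model(model, path)
    back = ph.load_model(path)
    assert ph.model_to_dict(back) == ph.model_to_dict(model)


def test_schema_rejects_nonpositive_tolerance(tmp_path):
    doc = ph.model_to_dict(_toy_model())
    doc["features"][0]["tolerance"] = 0
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match=r"features\[0\].tolerance"):
        ph.load_model(path)


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError, match="unique"):
        PharmacophoreModel(
            "D",
            [ModelFeature("X", "PI", [0, 0, 0], 1.0), ModelFeature("X", "AI", [1, 0, 0], 1.0)],
        )


def test_reference_fixture_file_round_trip(tmp_path, reference_models):
    path = tmp_path / "M3.json"
    ph.save_model(reference_models["M3"], path)
    model = ph.load_model(path)
    assert len(model.xvols) == 61
    assert ph.model_to_dict(model) == ph.model_to_dict(reference_models["M3"])


# ---------------------------------------------------------------------------
# alignment


def test_align_identity():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    R, t, rmsd = align_pairs(pts, pts)
    np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t, 0, atol=1e-12)
    assert rmsd == pytest.approx(0, abs=1e-12)


def test_align_recovers_rotation():
    rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])  # 90 deg about z
    pts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.0]])
    R, t, rmsd = align_pairs(pts, pts @ rot.T)
    assert rmsd == pytest.approx(0, abs=1e-12)
    np.testing.assert_allclose(R, rot, atol=1e-10)


def test_align_matches_quaternion_oracle(rng):
    for _ in range(25):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        _, _, rmsd = align_pairs(a, b)
        assert rmsd == pytest.approx(quaternion_superpose(a, b), abs=1e-9)


# ---------------------------------------------------------------------------
# mapping enumeration


def test_empty_model_single_empty_assignment():
    model = PharmacophoreModel("E", [])
    assert enumerate_mappings(model, []) == [{}]


def test_missing_kind_gives_no_assignment():
    model = PharmacophoreModel("P", [ModelFeature("PI_1", "PI", [0, 0, 0], 1.0)])
    feats = [LigandFeature("AI", (0,), [0, 0, 0])]
    assert enumerate_mappings(model, feats) == []


def test_enumeration_equals_brute_force(rng):
    """Backtracking enumeration equals filtering of all injective maps."""
    for _ in range(40):
        model, _, feats = random_instance(rng, max_model=3, max_lig=4, planted=bool(rng.random() < 0.5))
        model = PharmacophoreModel(model.id, [f for f in model.features], xvols=[])
        got = {tuple(sorted(a.items())) for a in enumerate_mappings(model, feats)}
        required = [f for f in model.features if not f.optional]
        optional = [f for f in model.features if f.optional]
        expected = set()
        for r in range(len(optional) + 1):
            for opt_subset in itertools.combinations(optional, r):
                sel = required + list(opt_subset)
                for perm in itertools.permutations(range(len(feats)), len(sel)):
                    if any(feats[j].kind != f.kind for f, j in zip(sel, perm)):
                        continue
                    ok = True
                    for (fa, ja), (fb, jb) in itertools.combinations(zip(sel, perm), 2):
                        dm = np.linalg.norm(fa.center - fb.center)
                        dl = np.linalg.norm(feats[ja].point - feats[jb].point)
                        if abs(dm - dl) > fa.tolerance + fb.tolerance:
                            ok = False
                            break
                    if ok:
                        expected.add(tuple(sorted((f.label, j) for f, j in zip(sel, perm))))
        assert got == expected


# ---------------------------------------------------------------------------
# matching


def test_empty_model_passes_any_conformer():
    model = PharmacophoreModel("E", [])
    conf = Conformer("x", np.zeros((1, 3)))
    res = match_conformer(model, conf, [])
    assert res.passed and res.fit_score == 0.0


def test_exact_placement_gives_zero_rmsd_max_score():
    model = _toy_model()
    feats = [
        LigandFeature("PI", (0,), [0.0, 0.0, 0.0]),
        LigandFeature("AI", (1,), [4.0, 0.0, 0.0]),
        LigandFeature("HBA", (2,), [2.0, 2.0, 0.0]),
    ]
    conf = Conformer("x", np.array([f.point for f in feats]))
    res = match_conformer(model, conf, feats)
    assert res.passed
    assert res.rmsd == pytest.approx(0, abs=1e-9)
    assert res.fit_score == pytest.approx(39.0)  # 3 pairs, all distances zero


def test_atom_inside_xvol_fails_with_reason():
    model = _toy_model()
    feats = [
        LigandFeature("PI", (0,), [0.0, 0.0, 0.0]),
        LigandFeature("AI", (1,), [4.0, 0.0, 0.0]),
    ]
    coords = np.array([[0, 0, 0], [4, 0, 0], [0, 5, 0.0]])  # atom at the XVOL centre
    res = match_conformer(model, Conformer("x", coords), feats)
    assert not res.passed and res.fail_reason == "xvol-clash"


def test_missing_required_kind_reason():
    model = _toy_model()
    feats = [LigandFeature("AI", (0,), [4.0, 0.0, 0.0])]
    res = match_conformer(model, Conformer("x", np.array([[4.0, 0, 0]])), feats)
    assert not res.passed and res.fail_reason == "missing-feature"


@pytest.mark.parametrize("n, d_frac, expected", [(5, 0.0, 59.0), (5, 1.0, 50.0), (0, 0.0, 0.0)])
def test_fit_score_values(n, d_frac, expected):
    tols = [1.5] * n
    dists = [d_frac * t for t in tols]
    assert fit_score(dists, tols) == pytest.approx(expected)


def test_fit_score_monotonic():
    assert fit_score([0.1, 0.1], [1.0, 1.0]) > fit_score([0.1, 0.2], [1.0, 1.0])
    assert fit_score([0.5, 0.5, 0.5], [1.0] * 3) > fit_score([0.0, 0.0], [1.0] * 2)


def test_matcher_equals_exhaustive_oracle(rng):
    """Spot check on random toy instances (the full 500 run in acceptance)."""
    agree = 0
    for i in range(60):
        model, conf, feats = random_instance(rng, planted=(i % 2 == 0))
        got = match_conformer(model, conf, feats).passed
        assert got == oracle_match(model, conf.coords, feats)
        agree += 1
    assert agree == 60


def test_match_invariant_under_rigid_motion(rng):
    model, conf, feats = random_instance(rng, planted=True)
    base = match_conformer(model, conf, feats)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(size=3) * 10
    feats2 = [LigandFeature(f.kind, f.atom_indices, f.point @ Q.T + t) for f in feats]
    conf2 = Conformer("lig", conf.coords @ Q.T + t)
    moved = match_conformer(model, conf2, feats2)
    assert moved.passed == base.passed
    assert moved.fit_score == pytest.approx(base.fit_score, abs=1e-6)


def test_restrictiveness_monotonicity(rng, reference_models, small_benchmark):
    """Shrinking a tolerance or adding an XVOL never gains hits."""
    (ds, _) = small_benchmark
    model = reference_models["M3"]
    lib = ds.actives
    base_ids = {h.molecule_id for h in ph.screen(model, lib, 5, seed=1)}
    import dataclasses

    shrunk_feats = [dataclasses.replace(f, tolerance=max(f.tolerance - 0.5, 0.2)) for f in model.features]
    shrunk = dataclasses.replace(model, features=shrunk_feats)
    assert {h.molecule_id for h in ph.screen(shrunk, lib, 5, seed=1)} <= base_ids

    extra = dataclasses.replace(
        model, xvols=list(model.xvols) + [ExclusionVolume(rng.uniform(-6, 6, 3), 1.2)]
    )
    assert {h.molecule_id for h in ph.screen(extra, lib, 5, seed=1)} <= base_ids


# ---------------------------------------------------------------------------
# screening


def test_screen_constructed_actives_all_hit(reference_models, small_benchmark):
    (ds, _) = small_benchmark
    hits = ph.screen(reference_models["M3"], ds.actives, 5, seed=3)
    assert len(hits) == len(ds.actives)


def test_screen_empty_library(reference_models):
    assert ph.screen(reference_models["M3"], [], 5, seed=1) == []


def test_screen_deterministic(reference_models, small_benchmark):
    (ds, _) = small_benchmark
    lib = ds.actives + ds.inactives
    h1 = ph.screen(reference_models["M3"], lib, 5, seed=9)
    h2 = ph.screen(reference_models["M3"], lib, 5, seed=9)
    assert [h.molecule_id for h in h1] == [h.molecule_id for h in h2]
    assert [h.match.fit_score for h in h1] == [h.match.fit_score for h in h2]


# ---------------------------------------------------------------------------
# optimization


def _point_molecule(mol_id, smiles, coords):
    mol = chem.from_smiles(smiles, mol_id)
    mol.conformers = [Conformer(mol_id, np.asarray(coords, float))]
    return mol


def _optimizer_instance():
    """Tiny hand-built instance: a 2-feature model, two conforming actives and
    decoys that also conform but extend into a distinctive off-feature locus."""
    model = PharmacophoreModel(
        "opt",
        [
            ModelFeature("PI_1", "PI", [0.0, 0.0, 0.0], 1.5),
            ModelFeature("AI_1", "AI", [4.0, 0.0, 0.0], 1.5),
        ],
    )
    # phenethylamine-like actives: N + aromatic ring, ring centroid near AI_1
    ring = [[3.2 + dx, dy, 0.0] for dx, dy in [(0, 1.4), (1.2, 0.7), (1.2, -0.7), (0, -1.4), (-1.2, -0.7), (-1.2, 0.7)]]
    act_coords = [[0, 0, 0], [1.2, 0, 0], [2.2, 0.6, 0]] + ring
    actives = [
        _point_molecule("a1", "NCCc1ccccc1", act_coords),
        _point_molecule("a2", "NCCc1ccccc1", [[p[0], p[1], p[2] + 0.05] for p in act_coords]),
    ]
    # decoys share the pharmacophore but carry a para tail reaching (8, 0, 0)
    tail = [[5.6, 0.0, 0.0], [7.0, 0.0, 0.0], [8.0, 0.8, 0.0], [8.0, -0.8, 0.0], [9.2, 1.0, 0.0]]
    dec_coords = [[0, 0, 0], [1.2, 0, 0], [2.2, 0.6, 0]] + ring + tail
    decoys = [
        _point_molecule("d1", "NCCc1ccc(CCC(C)C)cc1", dec_coords),
        _point_molecule("d2", "NCCc1ccc(CCC(C)C)cc1", [[p[0], p[1] + 0.05, p[2]] for p in dec_coords]),
    ]
    inactives = [
        _point_molecule(
            "i1", "CCOC(C)=O",
            [[0, 0, 0], [1.4, 0, 0], [2.4, 0.7, 0], [3.6, 0.2, 0], [4.8, 0.9, 0], [3.6, -1.2, 0.0]],
        )
    ]
    return model, actives, inactives, decoys


def test_optimizer_adds_xvol_at_decoy_locus_and_ef_increases():
    model, actives, inactives, decoys = _optimizer_instance()
    cfg = ph.OptimizerConfig(conformer_cap=1, move_budget=10, seed=0)
    before = ph.screen(model, decoys, 1, 0)
    assert len(before) == 2  # decoys conform before optimization
    opt = ph.optimize_model(model, actives, inactives, decoys, cfg)
    assert len(opt.xvols) > len(model.xvols)
    trace = opt.metadata["ef_trace"]
    assert trace == sorted(trace)  # EF never decreases
    assert trace[-1] > trace[0]
    # sensitivity preserved
    assert len(ph.screen(opt, actives, 1, 0)) == 2
    assert len(ph.screen(opt, decoys, 1, 0)) < 2


def test_optimizer_returns_optimal_model_unchanged():
    model, actives, inactives, decoys = _optimizer_instance()
    cfg = ph.OptimizerConfig(conformer_cap=1, move_budget=10, seed=0)
    opt = ph.optimize_model(model, actives, inactives, decoys, cfg)
    again = ph.optimize_model(opt, actives, inactives, decoys, cfg)
    assert ph.model_to_dict(again)["features"] == ph.model_to_dict(opt)["features"]
    assert len(again.xvols) == len(opt.xvols)


def test_optimizer_requires_actives():
    model, _, inactives, decoys = _optimizer_instance()
    with pytest.raises(ValueError):
        ph.optimize_model(model, [], inactives, decoys)
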