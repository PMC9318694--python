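"""Filters, consensus categorization, similarity and diversity selection."""

import numpy as np
import pandas as pd
import pytest
from rdkit import DataStructs

from pharmasieve import chem, triage
from pharmasieve.chem import DescriptorVector
from pharmasieve.triage import ConsensusCategory, HitAnnotation, categorize


def _desc(**kw):
    base = dict(
        mw=350.0, clogp=3.0, hba_count=3, hbd_count=1,
        rotatable_bonds=5, ring_count=3, aromatic_ring_count=2,
    )
    base.update(kw)
    return DescriptorVector(**base)


# ---------------------------------------------------------------------------
# physicochemical filter


def test_all_boundaries_inclusive():
    lo = _desc(mw=200.0, clogp=1.5, hba_count=0, hbd_count=0, rotatable_bonds=0,
               ring_count=2, aromatic_ring_count=1)
    hi = _desc(mw=600.0, clogp=6.0, hba_count=7, hbd_count=3, rotatable_bonds=18,
               ring_count=5, aromatic_ring_count=3)
    assert triage.physchem_filter(lo).physchem_pass
    assert triage.physchem_filter(hi).physchem_pass


@pytest.mark.parametrize(
    "kw, bound",
    [
        (dict(mw=199.99), "mw"),
        (dict(mw=600.01), "mw"),
        (dict(clogp=1.49), "clogp"),
        (dict(clogp=6.01), "clogp"),
        (dict(hba_count=8), "hba"),
        (dict(hbd_count=4), "hbd"),
        (dict(rotatable_bonds=19), "rotatable_bonds"),
        (dict(ring_count=1), "rings"),
        (dict(ring_count=6), "rings"),
        (dict(aromatic_ring_count=0), "aromatic_rings"),
        (dict(aromatic_ring_count=4), "aromatic_rings"),
    ],
)
def test_single_violation_rejected_with_named_bound(kw, bound):
    v = triage.physchem_filter(_desc(**kw))
    assert not v.physchem_pass
    assert v.failed_bounds == [bound]


def test_dopamine_fails_on_molecular_weight():
    d = chem.compute_descriptors(chem.from_smiles("NCCc1ccc(O)c(O)c1"))
    v = triage.physchem_filter(d, "dopamine")
    assert not v.physchem_pass
    assert "mw" in v.failed_bounds


def test_multiple_violations_all_listed():
    v = triage.physchem_filter(_desc(mw=150.0, ring_count=1))
    assert set(v.failed_bounds) == {"mw", "rings"}


# ---------------------------------------------------------------------------
# PAINS


def test_benzene_passes_default_pains():
    v = triage.pains_filter(chem.from_smiles("c1ccccc1", "bz"))
    assert v.pains_pass


def test_toy_catalog_flags_catechol(tmp_path):
    cat = tmp_path / "toy.smarts"
    cat.write_text("c1ccc(O)c(O)c1\tcatechol\n")
    catalogs = triage.load_smarts_catalog(cat, "toy")
    v = triage.pains_filter(chem.from_smiles("NCCc1ccc(O)c(O)c1", "dopa"), catalogs)
    assert not v.pains_pass
    assert ("toy", "catechol") in v.pains_matches
    # empty catalog: same molecule passes
    assert triage.pains_filter(chem.from_smiles("NCCc1ccc(O)c(O)c1"), {"empty": []}).pains_pass


def test_malformed_smarts_reported(tmp_path):
    cat = tmp_path / "bad.smarts"
    cat.write_text("c1ccc(\tbroken\n")
    with pytest.raises(ValueError, match="malformed"):
        triage.load_smarts_catalog(cat)


def test_known_pains_compound_flagged():
    # rhodanine, a canonical pan-assay interference scaffold
    v = triage.pains_filter(chem.from_smiles("O=C1CSC(=S)N1c1ccccc1", "rhod"))
    assert not v.pains_pass and v.pains_matches


# ---------------------------------------------------------------------------
# consensus categories


@pytest.mark.parametrize(
    "found, expected",
    [
        ({"M2", "M4", "M3"}, ConsensusCategory.TRIPLE),
        ({"M2", "M4", "M1"}, ConsensusCategory.TRIPLE),
        ({"M2", "M4"}, ConsensusCategory.DOUBLE_M2_M4),
        ({"M2", "M1"}, ConsensusCategory.DOUBLE_M2_M13),
        ({"M4", "M3"}, ConsensusCategory.DOUBLE_M4_M13),
        ({"M1"}, ConsensusCategory.SINGLE_M1),
        ({"M3"}, ConsensusCategory.SINGLE_M3),
    ],
)
def test_categorize(found, expected):
    assert categorize(found) == expected


def test_categorize_rejects_empty_and_unknown():
    with pytest.raises(ValueError):
        categorize(set())
    with pytest.raises(ValueError):
        categorize({"M9"})


def test_m1_m3_co_retrieval_warns_but_categorizes():
    with pytest.warns(UserWarning, match="M1 and M3"):
        assert categorize({"M1", "M3", "M2", "M4"}) == ConsensusCategory.TRIPLE


def test_categories_partition_all_subsets():
    """Every non-empty model subset maps to exactly one category."""
    import itertools, warnings

    models = ["M1", "M2", "M3", "M4"]
    for r in range(1, 5):
        for combo in itertools.combinations(models, r):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert isinstance(categorize(set(combo)), ConsensusCategory)


def test_priority_order():
    assert ConsensusCategory.TRIPLE.rank < ConsensusCategory.DOUBLE_M2_M4.rank
    assert ConsensusCategory.DOUBLE_M4_M13.rank < ConsensusCategory.SINGLE_M1.rank


# ---------------------------------------------------------------------------
# fingerprints and similarity


def test_tanimoto_identical_and_disjoint():
    a = chem.from_smiles("c1ccccc1CCN")
    b = chem.from_smiles("c1ccccc1CCN")
    assert triage.tanimoto(triage.ecfp4(a), triage.ecfp4(b)) == 1.0
    c = chem.from_smiles("O=S(=O)(O)O")
    assert triage.tanimoto(triage.ecfp4(a), triage.ecfp4(c)) < 0.1


def test_tanimoto_subset_formula():
    fa = DataStructs.ExplicitBitVect(64)
    fb = DataStructs.ExplicitBitVect(64)
    for i in range(10):
        fa.SetBit(i)
    for i in range(20):
        fb.SetBit(i)
    assert triage.tanimoto(fa, fb) == pytest.approx(0.5)


def test_tanimoto_empty_pair_defined_zero():
    fa = DataStructs.ExplicitBitVect(8)
    fb = DataStructs.ExplicitBitVect(8)
    with pytest.warns(UserWarning):
        assert triage.tanimoto(fa, fb) == 0.0


def test_similarity_matrix_properties():
    mols = [chem.from_smiles(s, f"m{i}") for i, s in enumerate(["c1ccccc1", "c1ccccc1C", "CCO"])]
    m = triage.similarity_matrix(mols)
    assert np.allclose(np.diag(m.values), 1.0)
    assert np.allclose(m.values, m.values.T)
    assert ((m.values >= 0) & (m.values <= 1)).all()


# ---------------------------------------------------------------------------
# diversity selection


def _hit(mol_id, found_by, score):
    return HitAnnotation(molecule_id=mol_id, found_by=found_by, best_fit_score=score, best_model=sorted(found_by)[0])


def _matrix(ids, value, diag=1.0):
    m = np.full((len(ids), len(ids)), value, float)
    np.fill_diagonal(m, diag)
    return pd.DataFrame(m, index=ids, columns=ids)


def test_all_similar_hits_collapse_to_best():
    hits = [_hit(f"h{i}", {"M2", "M4"}, 40 + i) for i in range(4)]
    sel = triage.diversity_select(hits, _matrix([h.molecule_id for h in hits], 0.9), 0.6)
    assert [s.molecule_id for s in sel] == ["h3"]  # highest score kept


def test_dissimilar_hits_all_kept():
    hits = [_hit(f"h{i}", {"M2", "M4"}, 40 + i) for i in range(4)]
    sel = triage.diversity_select(hits, _matrix([h.molecule_id for h in hits], 0.1), 0.6)
    assert len(sel) == 4


def test_similarity_not_compared_across_categories():
    """Identical scaffolds in different consensus groups are both kept."""
    hits = [_hit("a", {"M2", "M4"}, 50), _hit("b", {"M2", "M1"}, 45)]
    sel = triage.diversity_select(hits, _matrix(["a", "b"], 1.0), 0.6)
    assert {s.molecule_id for s in sel} == {"a", "b"}


def test_selected_hits_pairwise_dissimilar_within_category(rng):
    ids = [f"h{i}" for i in range(12)]
    vals = rng.uniform(0, 1, size=(12, 12))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    matrix = pd.DataFrame(vals, index=ids, columns=ids)
    hits = [_hit(i, {"M2", "M4"}, float(rng.uniform(30, 60))) for i in ids]
    sel = triage.diversity_select(hits, matrix, 0.6)
    for i, a in enumerate(sel):
        for b in sel[i + 1:]:
            assert matrix.loc[a.molecule_id, b.molecule_id] < 0.6


def test_single_model_quota():
    hits = [_hit(f"s{i}", {"M1"}, 30 + i) for i in range(20)]
    sel = triage.diversity_select(hits, _matrix([h.molecule_id for h in hits], 0.0), 0.6, single_quota=16)
    assert len(sel) == 16


# ---------------------------------------------------------------------------
# selection for testing


def test_triple_ranks_before_double_at_equal_score():
    triple = _hit("t", {"M2", "M4", "M3"}, 50)
    double = _hit("d", {"M2", "M4"}, 50)
    sel = triage.select_for_testing([double, triple])
    assert [h.molecule_id for h in sel] == ["t", "d"]


def test_known_active_excluded_by_id_and_structure():
    hits = [_hit("a", {"M2"}, 50), _hit("b", {"M2"}, 40)]
    table = pd.DataFrame({"id": ["a"], "smiles": [None]})
    sel = triage.select_for_testing(hits, known_actives=table)
    assert [h.molecule_id for h in sel] == ["b"]
    # structural match: same canonical molecule under a different id
    mols = [chem.from_smiles("c1ccccc1CCN", "a"), chem.from_smiles("CCOCC", "b")]
    table = pd.DataFrame({"smiles": ["NCCc1ccccc1"]})
    sel = triage.select_for_testing(hits, known_actives=table, mols=mols)
    assert [h.molecule_id for h in sel] == ["b"]


def test_empty_annotation_table_excludes_nothing():
    hits = [_hit("a", {"M2"}, 50), _hit("b", {"M4"}, 40)]
    sel = triage.select_for_testing(hits, known_actives=pd.DataFrame())
    assert len(sel) == 2
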