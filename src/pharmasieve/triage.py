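"""Hit triage: PAINS and physicochemical filters, consensus categories,
ECFP4/Tanimoto similarity and scaffold-diversity selection.

The physicochemical bounds default to the rule-of-five-derived window used
for dopaminergic screening hits (MW 200-600, cLogP 1.5-6.0, HBA 0-7,
HBD 0-3, rotatable bonds 0-18, rings 2-5, aromatic rings 1-3), all bounds
inclusive.  PAINS filtering uses the three published substructure families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chem import DescriptorVector, Molecule

logger = logging.getLogger(__name__)

#: inclusive [lo, hi] bounds per descriptor
DEFAULT_PHYSCHEM_BOUNDS: dict[str, tuple[float, float]] = {
    "mw": (200.0, 600.0),
    "clogp": (1.5, 6.0),
    "hba": (0, 7),
    "hbd": (0, 3),
    "rotatable_bonds": (0, 18),
    "rings": (2, 5),
    "aromatic_rings": (1, 3),
}

_DESCRIPTOR_FIELD = {
    "mw": "mw",
    "clogp": "clogp",
    "hba": "hba_count",
    "hbd": "hbd_count",
    "rotatable_bonds": "rotatable_bonds",
    "rings": "ring_count",
    "aromatic_rings": "aromatic_ring_count",
}


@dataclass
class FilterVerdict:
    molecule_id: str
    physchem_pass: bool = True
    failed_bounds: list[str] = field(default_factory=list)
    pains_pass: bool = True
    pains_matches: list[tuple[str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.physchem_pass and self.pains_pass


def physchem_filter(
    d: DescriptorVector,
    molecule_id: str = "",
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FilterVerdict:
    """Pass iff every descriptor lies inside its inclusive bound window."""
    bounds = bounds or DEFAULT_PHYSCHEM_BOUNDS
    failed = []
    for name, (lo, hi) in bounds.items():
        value = getattr(d, _DESCRIPTOR_FIELD[name])
        if not (lo <= value <= hi):
            failed.append(name)
    return FilterVerdict(molecule_id=molecule_id, physchem_pass=not failed, failed_bounds=failed)


_PAINS_FAMILIES = (
    ("PAINS1", FilterCatalogParams.FilterCatalogs.PAINS_A),
    ("PAINS2", FilterCatalogParams.FilterCatalogs.PAINS_B),
    ("PAINS3", FilterCatalogParams.FilterCatalogs.PAINS_C),
)


def default_pains_catalogs() -> dict[str, FilterCatalog]:
    """The three PAINS substructure families at default settings."""
    out = {}
    for name, cat in _PAINS_FAMILIES:
        params = FilterCatalogParams()
        params.AddCatalog(cat)
        out[name] = FilterCatalog(params)
    return out


def load_smarts_catalog(path: str, name: str | None = None) -> dict[str, list[tuple[str, Chem.Mol]]]:
    """Load a custom catalog: one ``SMARTS<TAB>pattern_id`` per line."""
    patterns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            patt = Chem.MolFromSmarts(parts[0])
            if patt is None:
                raise ValueError(f"{path}:{lineno}: malformed SMARTS {parts[0]!r}")
            pid = parts[1].strip() if len(parts) > 1 else f"pattern{lineno}"
            patterns.append((pid, patt))
    return {name or str(path): patterns}


def pains_filter(mol: Molecule, catalogs=None) -> FilterVerdict:
    """Fail iff the molecule matches at least one pattern in any catalog.

    ``catalogs`` maps a catalog name either to an RDKit ``FilterCatalog`` or
    to a list of ``(pattern_id, query_mol)`` pairs; default: PAINS 1-3.
    """
    if catalogs is None:
        catalogs = default_pains_catalogs()
    matches: list[tuple[str, str]] = []
    rd = mol.rdmol
    for cat_name, cat in catalogs.items():
        if isinstance(cat, FilterCatalog):
            for entry in cat.GetMatches(rd):
                matches.append((cat_name, entry.GetDescription()))
        else:
            for pid, patt in cat:
                if rd.HasSubstructMatch(patt):
                    matches.append((cat_name, pid))
    return FilterVerdict(molecule_id=mol.id, pains_pass=not matches, pains_matches=matches)


# ---------------------------------------------------------------------------
# consensus categories


class ConsensusCategory(Enum):
    """Hit categories by model agreement; lower rank = higher priority.

    The two models built in the same ligand-based screening environment never
    co-retrieved a hit, so they are pooled into one M1/M3 slot.
    """

    TRIPLE = "M2 + M4 + M1/M3"
    DOUBLE_M2_M4 = "M2 + M4"
    DOUBLE_M2_M13 = "M2 + M1/M3"
    DOUBLE_M4_M13 = "M4 + M1/M3"
    SINGLE_M1 = "M1"
    SINGLE_M2 = "M2"
    SINGLE_M3 = "M3"
    SINGLE_M4 = "M4"

    @property
    def rank(self) -> int:
        order = [
            ConsensusCategory.TRIPLE,
            ConsensusCategory.DOUBLE_M2_M4,
            ConsensusCategory.DOUBLE_M2_M13,
            ConsensusCategory.DOUBLE_M4_M13,
            ConsensusCategory.SINGLE_M1,
            ConsensusCategory.SINGLE_M2,
            ConsensusCategory.SINGLE_M3,
            ConsensusCategory.SINGLE_M4,
        ]
        return order.index(self)


def categorize(found_by: set[str]) -> ConsensusCategory:
    """Consensus category of a hit from the set of models that retrieved it."""
    if not found_by:
        raise ValueError("found_by must be non-empty")
    unknown = found_by - {"M1", "M2", "M3", "M4"}
    if unknown:
        raise ValueError(f"unknown model ids {sorted(unknown)}")
    m13 = bool(found_by & {"M1", "M3"})
    if {"M1", "M3"} <= found_by:
        warnings.warn("hit found by both M1 and M3; pooled into the M1/M3 slot")
    if {"M2", "M4"} <= found_by and m13:
        return ConsensusCategory.TRIPLE
    if {"M2", "M4"} <= found_by:
        return ConsensusCategory.DOUBLE_M2_M4
    if "M2" in found_by and m13:
        return ConsensusCategory.DOUBLE_M2_M13
    if "M4" in found_by and m13:
        return ConsensusCategory.DOUBLE_M4_M13
    return ConsensusCategory[f"SINGLE_{sorted(found_by)[0]}"]


@dataclass
class HitAnnotation:
    molecule_id: str
    found_by: set[str]
    best_fit_score: float
    best_model: str
    category: ConsensusCategory = None  # type: ignore[assignment]
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if self.category is None:
            self.category = categorize(self.found_by)


def annotate_hits(hitlists: dict[str, list]) -> list[HitAnnotation]:
    """Merge per-model hitlists (model id -> list of HitRecord) into annotations."""
    per_mol: dict[str, dict[str, float]] = {}
    for model_id, records in hitlists.items():
        for rec in records:
            per_mol.setdefault(rec.molecule_id, {})[model_id] = rec.match.fit_score
    out = []
    for mol_id in sorted(per_mol):
        scores = per_mol[mol_id]
        best_model = max(sorted(scores), key=lambda m: scores[m])
        out.append(
            HitAnnotation(
                molecule_id=mol_id,
                found_by=set(scores),
                best_fit_score=scores[best_model],
                best_model=best_model,
            )
        )
    return out


# ---------------------------------------------------------------------------
# similarity

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def ecfp4(mol: Molecule | Chem.Mol):
    """Radial fingerprint of radius 2 hashed to 2048 bits (2D structure)."""
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    return _MORGAN.GetFingerprint(rd)


def tanimoto(fp_a, fp_b) -> float:
    """|a & b| / |a | b|; defined as 0 (with a warning) for two empty sets."""
    if fp_a.GetNumOnBits() == 0 and fp_b.GetNumOnBits() == 0:
        warnings.warn("Tanimoto of two empty fingerprints; defining as 0")
        return 0.0
    return float(DataStructs.TanimotoSimilarity(fp_a, fp_b))


def similarity_matrix(mols: list[Molecule]) -> pd.DataFrame:
    """Symmetric pairwise Tanimoto matrix with unit diagonal."""
    fps = [ecfp4(m) for m in mols]
    ids = [m.id for m in mols]
    n = len(mols)
    mat = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            mat[i, i + 1:] = sims
            mat[i + 1:, i] = sims
    return pd.DataFrame(mat, index=ids, columns=ids)


def similarity_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Colour-coded similarity heatmap exported to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(matrix) / 4),) * 2)
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Tanimoto similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# diversity selection


def diversity_select(
    hits: list[HitAnnotation],
    matrix: pd.DataFrame,
    ts_threshold: float = 0.6,
    single_quota: int = 16,
) -> list[HitAnnotation]:
    """Scaffold-diversity pruning within each consensus category.

    Greedy leader clustering: hits are visited by descending fit score; a hit
    joins the first existing cluster whose leader it resembles at
    TS >= threshold, otherwise it founds a new cluster.  Each cluster keeps
    its best-scoring member.  Similarity is never compared across categories.
    Single-model categories are additionally capped at ``single_quota``
    selections per model.
    """
    selected: list[HitAnnotation] = []
    by_cat: dict[ConsensusCategory, list[HitAnnotation]] = {}
    for h in hits:
        by_cat.setdefault(h.category, []).append(h)
    cluster_counter = 0
    for cat in sorted(by_cat, key=lambda c: c.rank):
        members = sorted(by_cat[cat], key=lambda h: (-h.best_fit_score, h.molecule_id))
        leaders: list[HitAnnotation] = []
        for h in members:
            placed = False
            for leader in leaders:
                if matrix.loc[h.molecule_id, leader.molecule_id] >= ts_threshold:
                    h.cluster_id = leader.cluster_id
                    placed = True
                    break
            if not placed:
                h.cluster_id = cluster_counter
                cluster_counter += 1
                leaders.append(h)
        kept = leaders  # leader = best-scoring member by visit order
        if cat.name.startswith("SINGLE"):
            kept = kept[:single_quota]
        selected.extend(kept)
    return selected


def select_for_testing(
    hits: list[HitAnnotation],
    known_actives: pd.DataFrame | None = None,
    cap: int | None = None,
    mols: list[Molecule] | None = None,
) -> list[HitAnnotation]:
    """Rank hits for experimental testing and drop known actives.

    Ranking: consensus-category priority, then best fit score (descending),
    then id.  ``known_actives`` is a user-supplied annotation table (stand-in
    for literature / target-prediction lookups) with columns ``id`` and/or
    ``smiles``; exact structural matches with known target activity are
    excluded.  Deterministic.
    """
    excluded_ids: set[str] = set()
    excluded_smiles: set[str] = set()
    if known_actives is not None and len(known_actives):
        if "id" in known_actives.columns:
            excluded_ids = set(known_actives["id"].astype(str))
        if "smiles" in known_actives.columns:
            for smi in known_actives["smiles"].dropna():
                rd = Chem.MolFromSmiles(str(smi))
                if rd is not None:
                    excluded_smiles.add(Chem.MolToSmiles(rd))
    smiles_of = {}
    if mols is not None:
        smiles_of = {m.id: m.smiles for m in mols}
    ranked = sorted(hits, key=lambda h: (h.category.rank, -h.best_fit_score, h.molecule_id))
    out = []
    for h in ranked:
        if h.molecule_id in excluded_ids:
            continue
        if smiles_of.get(h.molecule_id) in excluded_smiles:
            continue
        out.append(h)
        if cap is not None and len(out) >= cap:
            break
    return out


def hits_table(hits: list[HitAnnotation], verdicts: dict[str, FilterVerdict] | None = None) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {
            "id": h.molecule_id,
            "found_by": "+".join(sorted(h.found_by)),
            "best_model": h.best_model,
            "best_fit_score": h.best_fit_score,
            "category": h.category.value,
            "cluster_id": h.cluster_id,
        }
        if verdicts and h.molecule_id in verdicts:
            v = verdicts[h.molecule_id]
            row["physchem_pass"] = v.physchem_pass
            row["failed_bounds"] = ";".join(v.failed_bounds)
            row["pains_pass"] = v.pains_pass
        rows.append(row)
    return pd.DataFrame(rows)
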