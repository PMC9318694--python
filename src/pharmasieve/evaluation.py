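"""Virtual-screening validation metrics over an actives/inactives/decoys benchmark.

Definitions (with tp/fp/tn/fn the usual confusion counts over the full
database of actives, inactives and decoys):

    sensitivity = tp / n_actives
    specificity = tn / (tn + fp)
    accuracy    = (tp + tn) / N
    YoA         = tp / (tp + fp)            (yield of actives)
    EF          = YoA / (n_actives / N)     (enrichment factor)

where N = n_actives + n_inactives + n_decoys.  The identity
EF = YoA * N / n_actives holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from rdkit import Chem

from .chem import Molecule

_PLACEHOLDER_MOL = Chem.MolFromSmiles("C")


@dataclass
class ScreeningDataset:
    actives: list[Molecule]
    inactives: list[Molecule]
    decoys: list[Molecule]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.actives] + [m.id for m in self.inactives] + [m.id for m in self.decoys]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset classes must have disjoint molecule ids")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.actives), len(self.inactives), len(self.decoys)

    @property
    def total(self) -> int:
        return sum(self.sizes)

    @classmethod
    def from_ids(cls, actives: list[str], inactives: list[str], decoys: list[str]) -> "ScreeningDataset":
        """Build a label-only dataset (ids without structures) for tallying."""
        mk = lambda ids: [Molecule(id=i, rdmol=_PLACEHOLDER_MOL) for i in ids]
        return cls(mk(actives), mk(inactives), mk(decoys))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    active_hits: int
    inactive_hits: int
    decoy_hits: int

    def __post_init__(self) -> None:
        if self.fp != self.inactive_hits + self.decoy_hits:
            raise ValueError("fp must equal inactive_hits + decoy_hits")


@dataclass(frozen=True)
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    yoa: float
    ef: float
    total_hits: int
    yoa_defined: bool = True


def tally(hitlist: list[str], ds: ScreeningDataset) -> ConfusionCounts:
    """Confusion counts for a hitlist of molecule ids against a labelled dataset."""
    act = {m.id for m in ds.actives}
    inact = {m.id for m in ds.inactives}
    dec = {m.id for m in ds.decoys}
    hits = set(hitlist)
    unknown = hits - act - inact - dec
    if unknown:
        raise ValueError(f"hitlist contains ids not in the dataset: {sorted(unknown)[:5]}")
    a_hits = len(hits & act)
    i_hits = len(hits & inact)
    d_hits = len(hits & dec)
    fp = i_hits + d_hits
    return ConfusionCounts(
        tp=a_hits,
        fp=fp,
        tn=len(inact) + len(dec) - fp,
        fn=len(act) - a_hits,
        active_hits=a_hits,
        inactive_hits=i_hits,
        decoy_hits=d_hits,
    )


def compute_metrics(c: ConfusionCounts, sizes: tuple[int, int, int]) -> ScreeningMetrics:
    n_act, n_inact, n_dec = sizes
    if n_act <= 0:
        raise ValueError("metrics require at least one active in the dataset")
    total = n_act + n_inact + n_dec
    hits = c.tp + c.fp
    yoa_defined = hits > 0
    yoa = c.tp / hits if yoa_defined else 0.0
    return ScreeningMetrics(
        sensitivity=c.tp / n_act,
        specificity=c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 1.0,
        accuracy=(c.tp + c.tn) / total,
        yoa=yoa,
        ef=yoa / (n_act / total),
        total_hits=hits,
        yoa_defined=yoa_defined,
    )


def union_evaluate(
    hitlists: dict[str, list[str]], ds: ScreeningDataset
) -> tuple[ConfusionCounts, ScreeningMetrics]:
    """Metrics of the union of several models' hitlists (unique ids)."""
    if not hitlists:
        raise ValueError("union evaluation requires at least one model")
    union: set[str] = set()
    for ids in hitlists.values():
        union |= set(ids)
    counts = tally(sorted(union), ds)
    return counts, compute_metrics(counts, ds.sizes)


def hit_rate(n_confirmed: int, n_tested: int) -> float:
    """Prospective hit rate in percent, reported to one decimal."""
    if n_tested <= 0:
        raise ValueError("hit rate requires n_tested > 0")
    return round_half_up(100.0 * n_confirmed / n_tested, 1)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding used for all displayed metric values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_report(
    per_model: dict[str, tuple[ConfusionCounts, ScreeningMetrics]],
    union_row: tuple[ConfusionCounts, ScreeningMetrics] | None = None,
) -> pd.DataFrame:
    """One row per model plus an all-models union row, display-rounded."""
    rows = []

    def _row(label, counts, metrics):
        return {
            "model": label,
            "active_hits": counts.active_hits,
            "inactive_hits": counts.inactive_hits,
            "decoy_hits": counts.decoy_hits,
            "TP": counts.tp,
            "FP": counts.fp,
            "TN": counts.tn,
            "specificity": round_half_up(metrics.specificity, 2),
            "sensitivity": round_half_up(metrics.sensitivity, 2),
            "accuracy": round_half_up(metrics.accuracy, 2),
            "EF": round_half_up(metrics.ef, 2),
            "YoA": round_half_up(metrics.yoa, 2),
        }

    for label, (counts, metrics) in per_model.items():
        rows.append(_row(label, counts, metrics))
    if union_row is not None:
        rows.append(_row("All models", *union_row))
    return pd.DataFrame(rows)
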