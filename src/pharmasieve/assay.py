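"""HTRF competition-binding plate analysis.

The assay reads each well at 620 nm (donor) and 665 nm (acceptor) and works
on the ratio R = 1e4 * F665 / F620, which cancels well-to-well excitation
differences.  Displacement of the fluorescent tracer by a competitor lowers
R relative to tracer-only wells; the normalized decrease in fluorescence
(DNF) scales that drop so the control ligand scores exactly 1, and a
compound is called active at DNF >= 2.

Curve models:
  saturation   R(L) = R0 + NS*L + Bmax*L / (KD + L)        (one site + linear
                                                            nonspecific term)
  competition  R(c) = bottom + (top - bottom) /
                      (1 + 10^((log10 c - log10 IC50) * h)) (4-param logistic)

Competitor affinity uses the Cheng-Prusoff correction
KI = IC50 / (1 + L*/KD) with L* the tracer concentration.  Confidence
intervals are nonparametric bootstrap percentiles over replicate wells.
Concentrations are handled in mol/L throughout; micromolar appears only at
the report boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_DOWN, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

ROLES = ("tracer_only", "control", "compound", "background")

#: convention for the displayed HTRF ratio
RATIO_SCALE = 1.0e4

#: DNF activity threshold relative to the control
DNF_ACTIVE_THRESHOLD = 2.0


@dataclass(frozen=True)
class PlateRead:
    well: str
    role: str
    f620: float
    f665: float
    compound: str | None = None
    concentration: float | None = None  # mol/L
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if not self.f620 > 0:
            raise ValueError("f620 must be > 0")


def htrf_ratio(p: PlateRead) -> float:
    """R = 1e4 * F665 / F620 (invariant under common rescaling of both channels)."""
    return RATIO_SCALE * p.f665 / p.f620


# ---------------------------------------------------------------------------
# plate CSV I/O (columns: well,role,compound,concentration_M,f620,f665,replicate)


def read_plate_csv(path: str) -> list[PlateRead]:
    df = pd.read_csv(path)
    wells = []
    for _, row in df.iterrows():
        wells.append(
            PlateRead(
                well=str(row["well"]),
                role=str(row["role"]),
                compound=None if pd.isna(row.get("compound")) else str(row["compound"]),
                concentration=None if pd.isna(row.get("concentration_M")) else float(row["concentration_M"]),
                f620=float(row["f620"]),
                f665=float(row["f665"]),
                replicate=int(row.get("replicate", 0)),
            )
        )
    return wells


def write_plate_csv(wells: list[PlateRead], path: str) -> None:
    pd.DataFrame(
        {
            "well": [w.well for w in wells],
            "role": [w.role for w in wells],
            "compound": [w.compound for w in wells],
            "concentration_M": [w.concentration for w in wells],
            "f620": [w.f620 for w in wells],
            "f665": [w.f665 for w in wells],
            "replicate": [w.replicate for w in wells],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DNF


@dataclass
class DnfEntry:
    compound: str
    dnf: float
    sd: float
    active: bool


@dataclass
class DnfTable:
    entries: list[DnfEntry]
    control_delta: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": [e.compound for e in self.entries],
                "dnf": [e.dnf for e in self.entries],
                "sd": [e.sd for e in self.entries],
                "active": [e.active for e in self.entries],
            }
        )


def compute_dnf(plate: list[PlateRead]) -> DnfTable:
    """Normalized decrease in fluorescence per compound.

    Delta_w = mean(R over tracer-only wells) - R_w;
    DNF_i = mean(Delta over compound-i wells) / mean(Delta over control wells),
    so the control scores 1 by construction.  The per-compound sd is the
    replicate spread of Delta scaled by the control mean.
    """
    tracer = [htrf_ratio(w) for w in plate if w.role == "tracer_only"]
    control = [w for w in plate if w.role == "control"]
    if len(tracer) < 2 or len(control) < 2:
        raise ValueError("DNF requires >=2 tracer_only and >=2 control wells")
    r_free = float(np.mean(tracer))
    control_deltas = np.array([r_free - htrf_ratio(w) for w in control])
    d_control = float(np.mean(control_deltas))
    if d_control <= 0:
        raise ValueError("mean control fluorescence decrease is <= 0; DNF undefined")

    entries = [
        DnfEntry(
            "control",
            1.0,
            float(np.std(control_deltas, ddof=1)) / d_control,
            DNF_ACTIVE_THRESHOLD <= 1.0,
        )
    ]
    by_compound: dict[str, list[float]] = {}
    for w in plate:
        if w.role == "compound":
            if w.compound is None:
                raise ValueError(f"compound well {w.well} lacks a compound id")
            by_compound.setdefault(w.compound, []).append(r_free - htrf_ratio(w))
    for name in sorted(by_compound):
        deltas = np.array(by_compound[name])
        dnf = float(np.mean(deltas)) / d_control
        sd = float(np.std(deltas, ddof=1)) / d_control if len(deltas) > 1 else 0.0
        entries.append(DnfEntry(name, dnf, sd, dnf >= DNF_ACTIVE_THRESHOLD))
    return DnfTable(entries=entries, control_delta=d_control)


# ---------------------------------------------------------------------------
# saturation binding


@dataclass
class SaturationResult:
    kd: float  # mol/L
    bmax: float
    r0: float
    ns_slope: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_rms: float = 0.0


def saturation_model(L, r0, ns, bmax, kd):
    return r0 + ns * L + bmax * L / (kd + L)


def fit_kd(wells: list[PlateRead]) -> SaturationResult:
    """One-site saturation fit (with linear nonspecific term) of tracer titration."""
    pts = [(w.concentration, htrf_ratio(w)) for w in wells if w.role == "compound" and w.concentration is not None]
    if len({c for c, _ in pts}) < 5:
        raise ValueError("saturation fit requires >=5 tracer concentrations")
    L = np.array([c for c, _ in pts])
    R = np.array([r for _, r in pts])
    span = R.max() - R.min()
    # KD guess: concentration nearest the half-saturation response
    half = R.min() + span / 2.0
    kd0 = float(L[np.argmin(np.abs(R - half))]) or float(np.median(L))
    p0 = [R.min(), 0.0, max(span, 1e-9), kd0]
    scale = [max(abs(p0[0]), 1.0), 1.0, max(p0[2], 1.0), max(kd0, 1e-12)]
    try:
        popt, _ = curve_fit(
            saturation_model, L, R, p0=p0,
            bounds=([-np.inf, -np.inf, 0, 1e-15], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000, x_scale=scale, xtol=1e-12,
        )
    except RuntimeError as exc:
        resid = f"data range {R.min():.3g}..{R.max():.3g} over L {L.min():.3g}..{L.max():.3g}"
        raise RuntimeError(f"saturation fit did not converge ({resid})") from exc
    resid = R - saturation_model(L, *popt)
    return SaturationResult(
        kd=float(popt[3]), bmax=float(popt[2]), r0=float(popt[0]), ns_slope=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# competition binding


@dataclass
class CompetitionResult:
    ic50: float  # mol/L
    hill: float
    top: float
    bottom: float
    ki: float | None = None  # mol/L, after Cheng-Prusoff correction
    ci95: tuple[float, float] | None = None  # mol/L, on KI
    fold_difference: float | None = None

    def __post_init__(self) -> None:
        if self.ci95 is not None and not self.ci95[0] < self.ci95[1]:
            raise ValueError("CI bounds must satisfy lo < hi")


def logistic4(c, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(c) - log_ic50) * hill))


def fit_competition(wells: list[PlateRead], compound: str | None = None) -> CompetitionResult:
    """Four-parameter logistic fit of a displacement curve (R vs competitor conc)."""
    pts = [
        (w.concentration, htrf_ratio(w))
        for w in wells
        if w.role == "compound"
        and w.concentration is not None
        and (compound is None or w.compound == compound)
    ]
    concs = sorted({c for c, _ in pts})
    if len(concs) < 6:
        raise ValueError("competition fit requires >=6 competitor concentrations")
    c = np.array([x for x, _ in pts])
    R = np.array([r for _, r in pts])
    top0, bot0 = float(R.max()), float(R.min())
    if top0 - bot0 < 1e-12 * max(abs(top0), 1.0):
        logger.warning("competition data look flat/monotone-degenerate; fit may be unstable")
    p0 = [top0, bot0, float(np.log10(np.median(c))), 1.0]
    try:
        popt, _ = curve_fit(
            logistic4, c, R, p0=p0,
            bounds=([-np.inf, -np.inf, np.log10(c.min()) - 3, 0.1],
                    [np.inf, np.inf, np.log10(c.max()) + 3, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError("competition fit did not converge") from exc
    return CompetitionResult(
        ic50=float(10.0 ** popt[2]), hill=float(popt[3]), top=float(popt[0]), bottom=float(popt[1]),
    )


def ki_from_ic50(ic50: float, tracer_conc: float, kd: float) -> float:
    """Cheng-Prusoff correction: KI = IC50 / (1 + L*/KD)."""
    if ic50 <= 0 or tracer_conc < 0 or kd <= 0:
        raise ValueError("ki_from_ic50 requires ic50 > 0, tracer_conc >= 0, kd > 0")
    return ic50 / (1.0 + tracer_conc / kd)


def fold_difference(ki_ref: float, ki: float) -> float:
    """Affinity gain vs a reference ligand: ki_ref / ki.

    Display convention: one decimal below 100, two significant figures above.
    Exact rounding ties resolve downward so 34.75 reports as 34.7.
    """
    if ki <= 0 or ki_ref <= 0:
        raise ValueError("fold difference requires positive KI values")
    ratio = ki_ref / ki
    if ratio < 100:
        return float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_DOWN))
    # two significant figures
    exp = int(np.floor(np.log10(ratio)))
    q = Decimal(1).scaleb(exp - 1)
    return float(Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_DOWN))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(
    fit_func,
    wells: list[PlateRead],
    statistic,
    n_resamples: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI over case-resampled replicate wells.

    Wells are grouped by (compound, concentration); each resample draws
    replicates with replacement within every group, refits with
    ``fit_func`` and records ``statistic(result)``.  Deterministic per seed.
    """
    groups: dict[tuple, list[PlateRead]] = {}
    for w in wells:
        if w.role == "compound":
            groups.setdefault((w.compound, w.concentration), []).append(w)
        else:
            groups.setdefault((w.role, None), []).append(w)
    if any(len(g) < 2 for k, g in groups.items() if k[1] is not None):
        raise ValueError("bootstrap requires >=2 replicates per concentration")
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_resamples):
        resampled: list[PlateRead] = []
        for g in groups.values():
            idx = rng.integers(0, len(g), size=len(g))
            resampled.extend(g[i] for i in idx)
        try:
            stats.append(statistic(fit_func(resampled)))
        except (RuntimeError, ValueError):
            continue
    if not stats:
        raise RuntimeError("all bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# end-to-end per-compound analysis


def analyze_competition(
    wells: list[PlateRead],
    tracer_conc: float,
    kd: float,
    compound: str | None = None,
    ki_ref: float | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> CompetitionResult:
    """Fit a displacement curve and report KI (with bootstrap CI) and fold difference."""
    res = fit_competition(wells, compound=compound)
    ki = ki_from_ic50(res.ic50, tracer_conc, kd)
    lo, hi = bootstrap_ci(
        lambda ws: fit_competition(ws, compound=compound),
        [w for w in wells if compound is None or w.compound in (compound, None) or w.role != "compound"],
        statistic=lambda r: ki_from_ic50(r.ic50, tracer_conc, kd),
        n_resamples=n_resamples,
        seed=seed,
    )
    if hi <= lo:
        hi = lo * (1 + 1e-12) + 1e-300  # degenerate (noise-free) bootstrap
    fold = fold_difference(ki_ref, ki) if ki_ref else None
    return CompetitionResult(
        ic50=res.ic50, hill=res.hill, top=res.top, bottom=res.bottom,
        ki=ki, ci95=(lo, hi), fold_difference=fold,
    )


def results_table(results: dict[str, CompetitionResult]) -> pd.DataFrame:
    """Result rows in micromolar: compound, fold difference, KI, 95% CI."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "compound": name,
                "fold_difference": r.fold_difference,
                "ki_uM": r.ki * 1e6 if r.ki else None,
                "ci95_lo_uM": r.ci95[0] * 1e6 if r.ci95 else None,
                "ci95_hi_uM": r.ci95[1] * 1e6 if r.ci95 else None,
            }
        )
    return pd.DataFrame(rows)
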