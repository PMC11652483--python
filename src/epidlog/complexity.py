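"""Plan-complexity indices and the rank-correlation analysis.

Six aperture-shape indices (SAS, LT, MCSv, LTMCS, AAV, LSV, following the
McNiven/Masi-style definitions) plus six control-point transition metrics
computed directly from MLC travel and MU differences. The rank correlation
against gamma passing rates uses Spearman's rho with average-rank tie
handling and a t-approximation p-value on n-2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epid_io import PlanControlPoint, VmatPlan

_OPEN_EPS = 1e-6


class ComplexityError(ValueError):
    pass


@dataclass
class PlanComplexityReport:
    sas: float
    lt: float
    mcsv: float
    ltmcs: float
    aav: float
    lsv: float
    mlc_mn: float
    mlc_sn: float
    mlc_mx: float
    mlc_sx: float
    mu_mean: float
    mu_std: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def infield_pairs(plan: VmatPlan) -> list[int]:
    """Leaf pairs whose opening exceeds 0 at any control point of the arc."""
    return [
        i
        for i in range(plan.n_leaf_pairs)
        if any(cp.bank_B[i] - cp.bank_A[i] > _OPEN_EPS for cp in plan.control_points)
    ]


def _bank_lsv(positions: np.ndarray) -> float:
    pos_max = float(positions.max() - positions.min())
    if pos_max == 0.0:
        return 1.0
    n = len(positions)
    diffs = np.abs(np.diff(positions))
    return float(np.sum(pos_max - diffs) / ((n - 1) * pos_max))


def leaf_sequence_variability(cp: PlanControlPoint, pairs: list[int] | None = None) -> float:
    """Product of the per-bank leaf-sequence variability terms, each in [0,1]."""
    if pairs is None:
        pairs = list(range(len(cp.bank_A)))
    if len(pairs) < 2:
        warnings.warn("single in-field leaf pair: LSV defaults to 1", stacklevel=2)
        return 1.0
    a = np.asarray([cp.bank_A[i] for i in pairs], dtype=float)
    b = np.asarray([cp.bank_B[i] for i in pairs], dtype=float)
    return _bank_lsv(a) * _bank_lsv(b)


def aperture_area_variability(cp: PlanControlPoint, arc_max_apertures: list[float]) -> float:
    """Aperture openings summed, relative to the arc-wide per-pair maxima."""
    openings = np.asarray(cp.bank_B) - np.asarray(cp.bank_A)
    if np.any(openings < -_OPEN_EPS):
        raise ComplexityError(f"control point {cp.index}: negative leaf opening")
    denom = float(np.sum(arc_max_apertures))
    if denom == 0.0:
        return 0.0
    return float(np.sum(np.clip(openings, 0.0, None)) / denom)


def _arc_max_apertures(plan: VmatPlan, pairs: list[int]) -> list[float]:
    return [
        max(cp.bank_B[i] - cp.bank_A[i] for cp in plan.control_points) for i in pairs
    ]


def _restrict(cp: PlanControlPoint, pairs: list[int]) -> PlanControlPoint:
    return PlanControlPoint(
        index=cp.index,
        gantry_angle=cp.gantry_angle,
        collimator_angle=cp.collimator_angle,
        cumulative_mu=cp.cumulative_mu,
        bank_A=[cp.bank_A[i] for i in pairs],
        bank_B=[cp.bank_B[i] for i in pairs],
    )


def _mu_weights(plan: VmatPlan) -> np.ndarray:
    if plan.total_mu <= 0:
        raise ComplexityError("plan total MU is zero")
    cum = np.asarray([cp.cumulative_mu for cp in plan.control_points], dtype=float)
    return np.diff(cum) / plan.total_mu


def mcsv(plan: VmatPlan) -> float:
    """MU-weighted product of transition-averaged AAV and LSV over the arc."""
    pairs = infield_pairs(plan)
    arc_max = _arc_max_apertures(plan, pairs)
    cps = [_restrict(cp, pairs) for cp in plan.control_points]
    aavs = [aperture_area_variability(cp, arc_max) for cp in cps]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lsvs = [leaf_sequence_variability(cp) for cp in cps]
    w = _mu_weights(plan)
    total = 0.0
    for k in range(len(cps) - 1):
        total += ((aavs[k] + aavs[k + 1]) / 2.0) * ((lsvs[k] + lsvs[k + 1]) / 2.0) * w[k]
    return float(total)


def leaf_travel(plan: VmatPlan) -> float:
    """Mean per-leaf travel (mm) accumulated over control-point transitions,
    averaged over both banks of the in-field pairs."""
    pairs = infield_pairs(plan)
    if not pairs:
        return 0.0
    total = 0.0
    for cp0, cp1 in zip(plan.control_points, plan.control_points[1:]):
        for i in pairs:
            total += abs(cp1.bank_A[i] - cp0.bank_A[i]) + abs(cp1.bank_B[i] - cp0.bank_B[i])
    return float(total / (2 * len(pairs)))


def small_aperture_score(plan: VmatPlan, gap_threshold_mm: float = 10.0) -> float:
    """MU-weighted fraction of open leaf pairs with gap below the threshold."""
    w = _mu_weights(plan)

    def frac(cp: PlanControlPoint) -> float:
        gaps = [b - a for a, b in zip(cp.bank_A, cp.bank_B) if b - a > _OPEN_EPS]
        if not gaps:
            return 0.0
        return sum(1 for g in gaps if g < gap_threshold_mm) / len(gaps)

    fracs = [frac(cp) for cp in plan.control_points]
    return float(
        sum(((fracs[k] + fracs[k + 1]) / 2.0) * w[k] for k in range(len(fracs) - 1))
    )


def ltmcs(plan: VmatPlan, lt_norm_mm: float = 500.0) -> float:
    return mcsv(plan) * max(0.0, 1.0 - leaf_travel(plan) / lt_norm_mm)


def transition_metrics(plan: VmatPlan) -> tuple[float, float, float, float, float, float]:
    """(mlc_mn, mlc_sn, mlc_mx, mlc_sx, mu_mean, mu_std): mean and sample SD,
    across control-point transitions, of the per-transition mean and maximum
    absolute leaf displacement and of the MU difference. A single transition
    reports SDs of 0."""
    if len(plan.control_points) < 2:
        raise ComplexityError("need >= 2 control points")
    pairs = infield_pairs(plan)
    if not pairs:
        raise ComplexityError("no in-field leaf pairs")
    means, maxima, dmus = [], [], []
    for cp0, cp1 in zip(plan.control_points, plan.control_points[1:]):
        moves = np.asarray(
            [abs(cp1.bank_A[i] - cp0.bank_A[i]) for i in pairs]
            + [abs(cp1.bank_B[i] - cp0.bank_B[i]) for i in pairs]
        )
        means.append(float(moves.mean()))
        maxima.append(float(moves.max()))
        dmus.append(cp1.cumulative_mu - cp0.cumulative_mu)

    def sd(v: list[float]) -> float:
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    return (
        float(np.mean(means)),
        sd(means),
        float(np.mean(maxima)),
        sd(maxima),
        float(np.mean(dmus)),
        sd(dmus),
    )


def plan_complexity_report(
    plan: VmatPlan, sas_gap_mm: float = 10.0, lt_norm_mm: float = 500.0
) -> PlanComplexityReport:
    pairs = infield_pairs(plan)
    arc_max = _arc_max_apertures(plan, pairs)
    cps = [_restrict(cp, pairs) for cp in plan.control_points]
    w = _mu_weights(plan)
    aavs = [aperture_area_variability(cp, arc_max) for cp in cps]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lsvs = [leaf_sequence_variability(cp) for cp in cps]
    # MU-weighted arc summaries of the per-CP index values
    aav_plan = float(sum(((aavs[k] + aavs[k + 1]) / 2.0) * w[k] for k in range(len(w))))
    lsv_plan = float(sum(((lsvs[k] + lsvs[k + 1]) / 2.0) * w[k] for k in range(len(w))))
    m = mcsv(plan)
    lt = leaf_travel(plan)
    mn, sn, mx, sx, mu_mean, mu_std = transition_metrics(plan)
    return PlanComplexityReport(
        sas=small_aperture_score(plan, sas_gap_mm),
        lt=lt,
        mcsv=m,
        ltmcs=m * max(0.0, 1.0 - lt / lt_norm_mm),
        aav=aav_plan,
        lsv=lsv_plan,
        mlc_mn=mn,
        mlc_sn=sn,
        mlc_mx=mx,
        mlc_sx=sx,
        mu_mean=mu_mean,
        mu_std=mu_std,
    )


# ------------------------------------------------------------- correlation


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation, average-rank ties, t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ComplexityError("spearman needs two equal-length 1D vectors")
    if len(x) < 4:
        raise ComplexityError(f"need >= 4 observations, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ComplexityError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComplexityError("undefined correlation: constant input vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))


# Indices whose observed correlation direction contradicted the complexity
# interpretation in the source analysis; they are computed but flagged.
SIGN_EXCLUDED = ("sas", "lsv", "lt")

CORRELATION_COLUMNS = (
    "gpr_mach", "sas", "mcsv", "lt", "ltmcs", "aav", "lsv",
    "mlc_mn", "mlc_sn", "mlc_mx", "mlc_sx", "mu_mean", "mu_std",
)


def correlate_table(df: pd.DataFrame, target: str = "gpr_prop") -> pd.DataFrame:
    """Spearman correlation of every complexity column against the target
    GPR column. Returns a tidy frame with rho, p and an ``excluded`` flag for
    the indices whose sign behaviour is known to be unreliable."""
    rows = []
    for col in CORRELATION_COLUMNS:
        res = spearman(df[target].to_numpy(), df[col].to_numpy())
        rows.append(
            {
                "index": col,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "excluded": col in SIGN_EXCLUDED,
            }
        )
    return pd.DataFrame(rows)
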