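"""Incremental cost-effectiveness analysis with bootstrap uncertainty.

Turns per-participant costs and effects into ICERs, cost-effectiveness
plane summaries, acceptability curves (CEAC) and one-way deterministic
sensitivity tables. Effects are oriented so that benefit is positive
(SBP enters as mmHg *reduced*), so the northeast quadrant of the plane
means "costlier and more effective".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import fast_adjusted_delta
from .io import ValidationError

logger = logging.getLogger("clustercea")

QUADRANTS = ("NE", "NW", "SE", "SW")


@dataclass(frozen=True)
class ICERResult:
    """An incremental cost-effectiveness ratio with its plane position.

    ``value`` is d_cost / d_effect; it is only ``interpretable`` as a
    price per unit of benefit in the NE and SW quadrants. A dominant
    strategy (cheaper and more effective, SE) or dominated one (NW)
    is flagged instead; a zero effect difference leaves the ratio
    undefined (``value`` is NaN).
    """

    value: float
    quadrant: str
    interpretable: bool
    dominant: bool = False
    dominated: bool = False


def _quadrant(d_cost: float, d_effect: float) -> str:
    if d_effect > 0:
        return "NE" if d_cost > 0 else "SE"
    if d_effect < 0:
        return "NW" if d_cost > 0 else "SW"
    # zero effect: classify on the cost axis boundary
    return "NW" if d_cost > 0 else "SE"


def icer(d_cost: float, d_effect: float) -> ICERResult:
    """ICER of (incremental cost, incremental effect), benefit-positive."""
    quad = _quadrant(d_cost, d_effect)
    value = d_cost / d_effect if d_effect != 0 else float("nan")
    return ICERResult(
        value=value,
        quadrant=quad,
        interpretable=d_effect > 0,
        dominant=(d_effect > 0 and d_cost <= 0) or (d_effect == 0 and d_cost < 0),
        dominated=(d_effect < 0 and d_cost >= 0) or (d_effect == 0 and d_cost > 0),
    )


@dataclass(frozen=True)
class CEDraws:
    """Bootstrap draws of (incremental cost, incremental effect)."""

    d_cost: np.ndarray
    d_effect: np.ndarray
    point: tuple[float, float]
    seed: int
    B: int

    def __post_init__(self) -> None:
        if len(self.d_cost) != self.B or len(self.d_effect) != self.B:
            raise ValidationError("draw arrays must have length B")
        if not (np.all(np.isfinite(self.d_cost)) and np.all(np.isfinite(self.d_effect))):
            raise ValidationError("draws must be finite")


@dataclass(frozen=True)
class CEACCurve:
    """Probability cost-effective as a function of willingness to pay."""

    wtp: np.ndarray
    p_ce: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wtp) <= 0):
            raise ValidationError("wtp grid must be strictly increasing")
        if np.any((self.p_ce < 0) | (self.p_ce > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")

    def at(self, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.p_ce[i])


def cluster_bootstrap(
    data: pd.DataFrame,
    cost_outcome: str,
    effect_outcome: str,
    B: int,
    seed: int,
    cost_baseline: str | None = None,
    effect_baseline: str | None = None,
) -> CEDraws:
    """Stratified cluster bootstrap of the adjusted (d_cost, d_effect) pair.

    Each replication resamples villages with replacement within
    township x arm strata (respecting the randomization design), then
    re-estimates both covariate-adjusted arm differences. Reproducible
    given ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(seed)

    # pre-split row indices by village within strata
    strata: list[list[np.ndarray]] = []
    for (_, _), g in data.groupby(["township", "arm"], sort=True):
        vils = [idx.to_numpy() for _, idx in g.groupby("village").groups.items()]
        if len(vils) < 2:
            raise ValidationError("need >= 2 villages per (township, arm) stratum")
        strata.append(vils)

    point = (
        fast_adjusted_delta(data, cost_outcome, cost_baseline),
        fast_adjusted_delta(data, effect_outcome, effect_baseline),
    )

    d_cost = np.empty(B)
    d_eff = np.empty(B)
    for b in range(B):
        take: list[np.ndarray] = []
        for vils in strata:
            k = len(vils)
            for i in rng.integers(0, k, k):
                take.append(vils[i])
        rep = data.loc[np.concatenate(take)]
        d_cost[b] = fast_adjusted_delta(rep, cost_outcome, cost_baseline)
        d_eff[b] = fast_adjusted_delta(rep, effect_outcome, effect_baseline)
    logger.info(
        "cluster bootstrap: B=%d seed=%d point=(%.3f, %.4f)", B, seed, *point
    )
    return CEDraws(d_cost=d_cost, d_effect=d_eff, point=point, seed=seed, B=B)


def ceac(draws: CEDraws, grid: Sequence[float]) -> CEACCurve:
    """Acceptability curve: P(net monetary benefit >= 0) along a WTP grid."""
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValidationError("wtp grid must be non-empty")
    if np.any(g < 0):
        raise ValidationError("wtp values must be >= 0")
    nmb = g[:, None] * draws.d_effect[None, :] - draws.d_cost[None, :]
    return CEACCurve(wtp=g, p_ce=(nmb >= 0).mean(axis=1))


def ce_summary(draws: CEDraws) -> dict:
    """Plane-quadrant proportions and percentile 95% CIs.

    The ICER CI is the percentile interval of the draw-wise ratio over
    interpretable draws (NE/SW), with the interpretable fraction
    reported alongside.
    """
    quads = np.array([_quadrant(c, e) for c, e in zip(draws.d_cost, draws.d_effect)])
    props = {q: float((quads == q).mean()) for q in QUADRANTS}
    ci = lambda x: (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))
    interp = np.array(
        [icer(c, e).interpretable for c, e in zip(draws.d_cost, draws.d_effect)]
    )
    ratios = draws.d_cost[interp] / draws.d_effect[interp]
    return {
        "quadrant_proportions": props,
        "d_cost_ci95": ci(draws.d_cost),
        "d_effect_ci95": ci(draws.d_effect),
        "icer_ci95": ci(ratios) if interp.any() else (float("nan"), float("nan")),
        "interpretable_fraction": float(interp.mean()),
    }


@dataclass(frozen=True)
class DSARow:
    """One row of a one-way deterministic sensitivity table."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"{self.parameter}: low must be < high")

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def one_way_dsa(
    base: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]],
    evaluator: Callable[[Mapping[str, float]], float],
) -> list[DSARow]:
    """Vary each parameter to its low/high value, all others at base.

    ``evaluator`` maps a full parameter set to an ICER and must be
    deterministic. Rows come back in tornado order (largest ICER spread
    first).
    """
    rows = []
    for name, (low, high) in ranges.items():
        if name not in base:
            raise KeyError(f"range given for unknown parameter {name!r}")
        out = []
        for v in (low, high):
            params = dict(base)
            params[name] = v
            try:
                out.append(float(evaluator(params)))
            except Exception as exc:  # surface which scenario failed
                raise RuntimeError(f"evaluator failed for {name}={v}: {exc}") from exc
        rows.append(DSARow(name, float(low), float(high), out[0], out[1]))
    return sorted(rows, key=lambda r: r.spread, reverse=True)


def dsa_table(rows: Sequence[DSARow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "icer_low": r.icer_low,
                "icer_high": r.icer_high,
            }
            for r in rows
        ]
    )


@dataclass
class CEResult:
    """Complete result of one cost-effectiveness analysis."""

    effect_name: str
    point_d_cost: float
    point_d_effect: float
    icer: ICERResult
    draws: CEDraws
    ceac_curve: CEACCurve
    summary: dict
    wtp_threshold: float
    p_ce_at_wtp: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effect_name": self.effect_name,
            "point": {"d_cost": self.point_d_cost, "d_effect": self.point_d_effect},
            "icer": {
                "value": self.icer.value,
                "quadrant": self.icer.quadrant,
                "interpretable": self.icer.interpretable,
                "dominant": self.icer.dominant,
                "dominated": self.icer.dominated,
            },
            "draws": {
                "d_cost": self.draws.d_cost.tolist(),
                "d_effect": self.draws.d_effect.tolist(),
                "point": list(self.draws.point),
                "seed": self.draws.seed,
                "B": self.draws.B,
            },
            "ceac": {"wtp": self.ceac_curve.wtp.tolist(), "p_ce": self.ceac_curve.p_ce.tolist()},
            "summary": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in self.summary.items()
            },
            "wtp_threshold": self.wtp_threshold,
            "p_ce_at_wtp": self.p_ce_at_wtp,
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CEResult":
        draws = CEDraws(
            d_cost=np.asarray(d["draws"]["d_cost"], dtype=float),
            d_effect=np.asarray(d["draws"]["d_effect"], dtype=float),
            point=tuple(d["draws"]["point"]),
            seed=int(d["draws"]["seed"]),
            B=int(d["draws"]["B"]),
        )
        summary = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in d["summary"].items()
        }
        summary["quadrant_proportions"] = dict(d["summary"]["quadrant_proportions"])
        return cls(
            effect_name=d["effect_name"],
            point_d_cost=d["point"]["d_cost"],
            point_d_effect=d["point"]["d_effect"],
            icer=ICERResult(**d["icer"]),
            draws=draws,
            ceac_curve=CEACCurve(
                wtp=np.asarray(d["ceac"]["wtp"], dtype=float),
                p_ce=np.asarray(d["ceac"]["p_ce"], dtype=float),
            ),
            summary=summary,
            wtp_threshold=d["wtp_threshold"],
            p_ce_at_wtp=d["p_ce_at_wtp"],
            extras=d.get("extras", {}),
        )
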