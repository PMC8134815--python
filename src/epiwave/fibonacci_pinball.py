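"""Fibonacci retracement/extension levels and scenario projection.

Given the last two (or three) reference levels of a swing, the four
pinball update formulas project the next level :math:`P_{t+1}`:

* uptrend retracement:   ``P_t − (P_t − P_{t−1}) · Fib``
* downtrend retracement: ``P_t + (P_{t−1} − P_t) · Fib``
* uptrend extension:     ``P_t + (P_{t−1} − P_{t−2}) · Fib``
* downtrend extension:   ``P_t − (P_{t−2} − P_{t−1}) · Fib``

Applied over a set of Fibonacci ratios these produce a grid of
support/resistance levels; chaining a retracement with a follow-on
extension sketches best/intermediate/worst-case paths for the daily
new-case curve. All projected levels are clamped at zero — a case
count cannot be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

from epiwave.wave_engine import Pivot, WaveCount

__all__ = [
    "FibLevel",
    "ScenarioProjection",
    "fib_retracement",
    "fib_extension",
    "build_level_grid",
    "project_scenarios",
    "DEFAULT_RETRACEMENT_RATIOS",
    "DEFAULT_SCENARIO_RATIOS",
]

UPTREND = "uptrend"
DOWNTREND = "downtrend"

#: Six ratios used for the default level grid; 23.6 %, 50 %, 61.8 % and
#: 100 % are the ones typically drawn on the charts, 38.2 % and 161.8 %
#: complete the conventional set of six. A 300 % level can be added via
#: the ``ratios`` argument where a deep support is of interest.
DEFAULT_RETRACEMENT_RATIOS: tuple[float, ...] = (0.236, 0.382, 0.5, 0.618, 1.0, 1.618)

#: Correction-depth mapping: a strong correction retraces the whole
#: reference swing (best case for an epidemic), a mild one only half
#: (worst case). No single triple is canonical; this is configuration.
DEFAULT_SCENARIO_RATIOS: dict[str, float] = {"strong": 1.0, "moderate": 0.618, "mild": 0.5}

_SCENARIO_ORDER = ("best", "intermediate", "worst")


@dataclass(frozen=True)
class FibLevel:
    """One projected support/resistance level."""

    ratio: float
    kind: str  # "retracement" | "extension"
    trend: str  # "uptrend" | "downtrend"
    level: float
    role: str  # "support" | "resistance"


@dataclass(frozen=True)
class ScenarioProjection:
    """A best/intermediate/worst-case path for the daily-case curve.

    ``segments`` lists the target levels in order (the correction
    target, optionally followed by a continuation extension), each
    paired with the wave label it would complete.
    """

    scenario: str  # "best" | "intermediate" | "worst"
    correction: str  # "strong" | "moderate" | "mild" (depth name)
    segments: tuple[tuple[FibLevel, str], ...]
    narrative: str

    @property
    def terminal_level(self) -> float:
        return self.segments[-1][0].level


def _check_nonnegative(**values: float) -> None:
    for name, value in values.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def _check_trend(trend: str) -> None:
    if trend not in (UPTREND, DOWNTREND):
        raise ValueError(f"trend must be 'uptrend' or 'downtrend', got {trend!r}")


def fib_retracement(p_t: float, p_t1: float, fib: float, trend: str) -> float:
    """Retracement target from the last two levels, clamped at zero.

    ``p_t`` is the current level, ``p_t1`` the previous one. At
    ``fib=0`` the target is ``p_t``; at ``fib=1`` the swing is fully
    retraced and the target is ``p_t1``.
    """
    _check_nonnegative(p_t=p_t, p_t1=p_t1, fib=fib)
    _check_trend(trend)
    if trend == UPTREND:
        value = p_t - (p_t - p_t1) * fib
    else:
        value = p_t + (p_t1 - p_t) * fib
    return max(value, 0.0)


def fib_extension(p_t: float, p_t1: float, p_t2: float, fib: float, trend: str) -> float:
    """Extension target from the last three levels, clamped at zero."""
    _check_nonnegative(p_t=p_t, p_t1=p_t1, p_t2=p_t2, fib=fib)
    _check_trend(trend)
    if trend == UPTREND:
        value = p_t + (p_t1 - p_t2) * fib
    else:
        value = p_t - (p_t2 - p_t1) * fib
    return max(value, 0.0)


def _to_scale(value: float, scale: str) -> float:
    if scale == "log":
        import math

        return math.log10(value + 1.0)
    return value


def _from_scale(value: float, scale: str) -> float:
    if scale == "log":
        return max(10.0 ** value - 1.0, 0.0)
    return max(value, 0.0)


def build_level_grid(
    reference_swing: tuple[Pivot, Pivot],
    ratios: tuple[float, ...] = DEFAULT_RETRACEMENT_RATIOS,
    trend: str | None = None,
    scale: str = "linear",
    current: float | None = None,
) -> list[FibLevel]:
    """Support/resistance grid from one completed swing.

    For each ratio a retracement level (projected back across the
    swing from its endpoint) and an extension level (projected onward
    past the endpoint by the swing's amplitude times the ratio) are
    emitted — one :class:`FibLevel` per ratio per kind. ``trend``
    defaults to the direction a correction of the swing would take
    (down after an up-swing). Levels below ``current`` (default: the
    swing endpoint) are supports, others resistances. With
    ``scale="log"`` the arithmetic runs on ``log10(value+1)`` and the
    levels are transformed back.
    """
    start, end = reference_swing
    if start.polarity == end.polarity:
        raise ValueError("reference swing pivots must have opposite polarity")
    if not ratios:
        raise ValueError("ratios must be non-empty")
    if trend is None:
        trend = DOWNTREND if end.value >= start.value else UPTREND
    _check_trend(trend)
    a = _to_scale(start.value, scale)
    b = _to_scale(end.value, scale)
    here = end.value if current is None else current

    levels: list[FibLevel] = []
    for kind in ("retracement", "extension"):
        for ratio in ratios:
            if kind == "retracement":
                raw = fib_retracement(b, a, ratio, trend)
            else:
                raw = fib_extension(b, b, a, ratio, trend)
            level = _from_scale(raw, scale)
            role = "support" if level < here else "resistance"
            levels.append(FibLevel(ratio=ratio, kind=kind, trend=trend, level=level, role=role))
    return levels


def _anchor_swing(count: WaveCount) -> tuple[Pivot, Pivot]:
    """Most recent completed swing: the last swing not still forming."""
    pivots = count.pivots
    if len(pivots) < 2:
        raise ValueError("wave count has no swing to project from")
    if count.in_progress and len(pivots) >= 3:
        return pivots[-3], pivots[-2]
    return pivots[-2], pivots[-1]


def project_scenarios(
    count: WaveCount,
    scenario_ratios: dict[str, float] | None = None,
    extension_ratio: float | None = None,
    anchor: tuple[Pivot, Pivot] | None = None,
    scale: str = "linear",
) -> list[ScenarioProjection]:
    """Best/intermediate/worst-case correction targets from a wave count.

    The reference swing (by default the most recent completed swing of
    the count) is retraced at each configured correction depth; the
    deepest retracement is the best case (fewest daily cases), the
    shallowest the worst. With ``extension_ratio`` set, each scenario
    gains a continuation segment extending the reference amplitude
    beyond the correction target — the impulsive follow-on rally that
    may push the curve to unprecedented levels.

    Returned projections are ordered best, intermediate, worst, with
    terminal levels non-decreasing in that order.
    """
    if not count.nodes:
        raise ValueError("empty wave count")
    mapping = dict(DEFAULT_SCENARIO_RATIOS if scenario_ratios is None else scenario_ratios)
    if len(mapping) != 3:
        raise ValueError(f"expected exactly 3 correction depths, got {len(mapping)}")
    start, end = anchor if anchor is not None else _anchor_swing(count)
    if start.polarity == end.polarity:
        raise ValueError("anchor swing pivots must have opposite polarity")
    trend = DOWNTREND if end.value >= start.value else UPTREND
    a = _to_scale(start.value, scale)
    b = _to_scale(end.value, scale)

    completes = count.nodes[-1].label if count.in_progress else "next correction"

    built = []
    for depth, ratio in mapping.items():
        raw = fib_retracement(b, a, ratio, trend)
        level = _from_scale(raw, scale)
        retr = FibLevel(ratio=ratio, kind="retracement", trend=trend, level=level,
                        role="support" if level < end.value else "resistance")
        segments: list[tuple[FibLevel, str]] = [(retr, completes)]
        if extension_ratio is not None:
            cont_trend = UPTREND if trend == DOWNTREND else DOWNTREND
            ext_raw = fib_extension(raw, b, a, extension_ratio, cont_trend)
            ext_level = _from_scale(ext_raw, scale)
            ext = FibLevel(ratio=extension_ratio, kind="extension", trend=cont_trend,
                           level=ext_level,
                           role="support" if ext_level < end.value else "resistance")
            segments.append((ext, "continuation impulse"))
        built.append((depth, tuple(segments)))

    # fewest daily cases is the best outcome: rank by terminal level
    built.sort(key=lambda item: item[1][-1][0].level)
    projections = []
    for scenario, (depth, segments) in zip(_SCENARIO_ORDER, built):
        projections.append(
            ScenarioProjection(
                scenario=scenario,
                correction=depth,
                segments=segments,
                narrative=f"{depth} correction of {completes}",
            )
        )
    return projections
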