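"""Synthetic epidemic curves with known Elliott-wave ground truth.

Builds daily new-case series as geometric interpolations between
pivot levels laid out by an impulse/corrective wave plan, with
per-wave amplitude ratios drawn from the Fibonacci set and optional
multiplicative log-normal day noise. Because the generator knows
exactly where every pivot sits and how every wave is labeled, it
serves as the oracle for the detection and labeling pipeline.

Amplitudes are assigned on the ``log10`` scale: a wave of amplitude
1.0 moves the daily-case level by one order of magnitude, matching
how epidemic waves read on a logarithmic axis. Default ratios are
wave 2 = 50 % of wave 1, wave 3 = 161.8 % of wave 1, wave 4 = 38.2 %
of wave 3, wave 5 = 100 % of wave 1 for impulses and b = 50 %,
c = 100 % of a for correctives — all satisfying the hard wave rules
by construction.

This is a shape generator, not a transmission model: no SIR/SEIR
mechanics, no reporting artifacts beyond the day noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epiwave.series_io import CaseSeries, write_case_series
from epiwave.wave_engine import (
    CORRECTIVE,
    IMPULSE,
    PEAK,
    TROUGH,
    Pivot,
    Violation,
    WaveCount,
    WaveNode,
    _assign_labels,
    validate_wave_count,
)

__all__ = [
    "PlanNode",
    "WaveSpec",
    "generate_elliott_epidemic",
    "write_fixture_suite",
    "plan_textbook5",
    "plan_impulse_correction",
    "plan_super_impulse",
    "plan_in_progress",
]

_IMPULSE_PATTERN = (IMPULSE, CORRECTIVE, IMPULSE, CORRECTIVE, IMPULSE)
_CORRECTIVE_PATTERN = (IMPULSE, CORRECTIVE, IMPULSE)


@dataclass(frozen=True)
class PlanNode:
    """One wave of the plan: a role, optional sub-waves, completeness."""

    role: str
    children: tuple["PlanNode", ...] = ()
    complete: bool = True

    @property
    def degree(self) -> int:
        return 0 if not self.children else 1 + self.children[0].degree


def _impulse(children: tuple[PlanNode, ...] = (), complete: bool = True) -> PlanNode:
    return PlanNode(IMPULSE, children, complete)


def _corrective(children: tuple[PlanNode, ...] = (), complete: bool = True) -> PlanNode:
    return PlanNode(CORRECTIVE, children, complete)


def _leaf_impulse() -> PlanNode:
    return PlanNode(IMPULSE)


def _leaf_corrective() -> PlanNode:
    return PlanNode(CORRECTIVE)


def _subdivided_impulse() -> PlanNode:
    return _impulse(tuple(PlanNode(r) for r in _IMPULSE_PATTERN))


def _subdivided_corrective() -> PlanNode:
    return _corrective(tuple(PlanNode(r) for r in _CORRECTIVE_PATTERN))


@dataclass(frozen=True)
class WaveSpec:
    """Recipe for one synthetic epidemic curve.

    ``degree_plan`` is the nested wave grammar to realize (top-level
    waves in alternating impulse/corrective roles; only the last may
    be incomplete). ``top_amplitude`` is the log10 amplitude of the
    first top-level wave (1.5 = a ~30-fold rise). ``swing_ratios``
    maps role to the per-wave amplitude ratio tuple: for impulses
    (wave2/wave1, wave3/wave1, wave4/wave3, wave5/wave1), for
    correctives (b/a, c/a). ``segment_lengths`` is days per finest
    sub-wave (one int, or one per leaf). ``noise_cv`` is the
    coefficient of variation of the multiplicative log-normal day
    noise. The same seed always reproduces the same series.
    """

    degree_plan: tuple[PlanNode, ...]
    base_level: float = 1000.0
    top_amplitude: float = 1.5
    swing_ratios: dict = field(
        default_factory=lambda: {
            IMPULSE: (0.5, 1.618, 0.382, 1.0),
            CORRECTIVE: (0.5, 1.0),
        }
    )
    segment_lengths: int | tuple[int, ...] = 14
    noise_cv: float = 0.0
    seed: int = 0
    start_date: str = "2020-03-01"
    region: str = "Synthetica"


# ---------------------------------------------------------------------------
# named plans
# ---------------------------------------------------------------------------

def plan_textbook5(seed: int = 0, noise_cv: float = 0.0, **overrides) -> WaveSpec:
    """A single completed five-wave impulse (degree 1, 5 sub-waves)."""
    return WaveSpec(degree_plan=(_subdivided_impulse(),), seed=seed,
                    noise_cv=noise_cv, **overrides)


def plan_impulse_correction(seed: int = 0, noise_cv: float = 0.0, **overrides) -> WaveSpec:
    """A completed impulse followed by a completed a-b-c corrective."""
    return WaveSpec(
        degree_plan=(_subdivided_impulse(), _subdivided_corrective()),
        seed=seed, noise_cv=noise_cv, **overrides,
    )


def plan_super_impulse(seed: int = 0, noise_cv: float = 0.0, **overrides) -> WaveSpec:
    """A degree-2 impulse: five degree-1 waves, each fully subdivided
    (21 finest sub-waves). The default amplitude spans ~2.8 orders of
    magnitude, the scale of a full pandemic year."""
    children = (
        _subdivided_impulse(),
        _subdivided_corrective(),
        _subdivided_impulse(),
        _subdivided_corrective(),
        _subdivided_impulse(),
    )
    overrides.setdefault("top_amplitude", 2.8)
    return WaveSpec(degree_plan=(_impulse(children),), seed=seed,
                    noise_cv=noise_cv, **overrides)


def plan_in_progress(seed: int = 0, noise_cv: float = 0.0, **overrides) -> WaveSpec:
    """A completed impulse with a trailing corrective caught mid-move
    (waves a and b realized, c still to come)."""
    partial = _corrective((_leaf_impulse(), _leaf_corrective()), complete=False)
    return WaveSpec(degree_plan=(_subdivided_impulse(), partial), seed=seed,
                    noise_cv=noise_cv, **overrides)


NAMED_PLANS = {
    "textbook5": plan_textbook5,
    "impulse_correction": plan_impulse_correction,
    "super_impulse": plan_super_impulse,
    "in_progress": plan_in_progress,
}


# ---------------------------------------------------------------------------
# plan validation and amplitude assignment
# ---------------------------------------------------------------------------

def _validate_plan_node(node: PlanNode) -> None:
    if node.role not in (IMPULSE, CORRECTIVE):
        raise ValueError(f"unknown role {node.role!r}")
    if not node.children:
        return
    pattern = _IMPULSE_PATTERN if node.role == IMPULSE else _CORRECTIVE_PATTERN
    roles = tuple(c.role for c in node.children)
    if node.complete:
        if roles != pattern:
            raise ValueError(
                f"complete {node.role} must have children {pattern}, got {roles}"
            )
    else:
        if not roles or roles != pattern[: len(roles)] or len(roles) >= len(pattern):
            raise ValueError(
                f"incomplete {node.role} children must be a proper non-empty prefix of {pattern}"
            )
        for child in node.children[:-1]:
            if not child.complete:
                raise ValueError("only the last child of an incomplete wave may be incomplete")
    degrees = {c.degree for c in node.children}
    if len(degrees) != 1:
        raise ValueError("all children of a wave must have the same degree")
    for k, child in enumerate(node.children):
        if node.complete and not child.complete:
            raise ValueError("a complete wave cannot contain an incomplete child")
        if not node.complete and child is not node.children[-1] and not child.complete:
            raise ValueError("only the trailing child may be incomplete")
        _validate_plan_node(child)


def _validate_ratios(spec: WaveSpec) -> None:
    r2, r3, r4, r5 = spec.swing_ratios[IMPULSE]
    rb, rc = spec.swing_ratios[CORRECTIVE]
    if min(r2, r3, r4, r5, rb, rc) <= 0:
        raise ValueError("all swing ratios must be positive")
    if r2 > 1.0:
        raise ValueError(f"wave-2 ratio {r2} > 1 would retrace beyond wave 1's start (rule R1)")
    if r3 < 1.0 and r3 < r5:
        raise ValueError(f"wave-3 ratio {r3} would make wave 3 the shortest impulse (rule R2)")
    if r3 * (1.0 - r4) <= r2:
        raise ValueError("wave-4 ratio would pull wave 4 into wave 1's territory (rule R3)")
    if 1.0 - r2 + r3 - r3 * r4 + r5 <= 0:
        raise ValueError("impulse ratios produce a non-advancing wave")
    if 1.0 - rb + rc <= 0:
        raise ValueError("corrective ratios produce a non-correcting wave")
    if rb > 1.0:
        raise ValueError(f"b-wave ratio {rb} > 1 would carry b beyond a's origin")


def _leaf_amplitudes(node: PlanNode, amplitude: float, spec: WaveSpec) -> list[float]:
    """Amplitude (log10 units) of every finest sub-wave of ``node``, in order.

    ``amplitude`` is the net start-to-end amplitude the *complete* wave
    would span; incomplete waves realize only their present children.
    """
    if not node.children:
        return [amplitude]
    if node.role == IMPULSE:
        r2, r3, r4, r5 = spec.swing_ratios[IMPULSE]
        w1 = amplitude / (1.0 - r2 + r3 - r3 * r4 + r5)
        child_amps = [w1, r2 * w1, r3 * w1, r4 * r3 * w1, r5 * w1]
    else:
        rb, rc = spec.swing_ratios[CORRECTIVE]
        a = amplitude / (1.0 - rb + rc)
        child_amps = [a, rb * a, rc * a]
    out: list[float] = []
    for child, child_amp in zip(node.children, child_amps):
        out.extend(_leaf_amplitudes(child, child_amp, spec))
    return out


def _count_leaves(node: PlanNode) -> int:
    if not node.children:
        return 1
    return sum(_count_leaves(c) for c in node.children)


def _build_tree(node: PlanNode, start: int) -> WaveNode:
    """Ground-truth WaveNode over pivot-list positions."""
    if not node.children:
        return WaveNode(degree=0, role=node.role, label="", start=start,
                        end=start + 1, complete=True)
    kids = []
    pos = start
    for child in node.children:
        built = _build_tree(child, pos)
        kids.append(built)
        pos = built.end
    return WaveNode(degree=node.degree, role=node.role, label="", start=start,
                    end=pos, children=kids, complete=node.complete)


def generate_elliott_epidemic(spec: WaveSpec) -> tuple[CaseSeries, WaveCount]:
    """Realize a wave plan as a daily case curve plus its ground truth.

    Pivot levels are laid out on the log10 scale by the plan's
    amplitude ratios, days between pivots are geometrically
    interpolated, and each day is multiplied by log-normal noise with
    coefficient of variation ``spec.noise_cv`` (unit mean). The
    returned :class:`WaveCount` holds the exact pivots (noiseless
    levels) and labels, and always passes validation.
    """
    if not spec.degree_plan:
        raise ValueError("degree_plan must contain at least one wave")
    roles = [n.role for n in spec.degree_plan]
    for prev, cur in zip(roles, roles[1:]):
        if prev == cur:
            raise ValueError("top-level waves must alternate impulse/corrective")
    for k, node in enumerate(spec.degree_plan):
        if not node.complete and k != len(spec.degree_plan) - 1:
            raise ValueError("only the final top-level wave may be incomplete")
        _validate_plan_node(node)
    _validate_ratios(spec)
    if spec.base_level <= 0:
        raise ValueError("base_level must be positive")
    if spec.noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    # amplitude of each top-level wave, relative to the first impulse
    amplitudes: list[float] = []
    first = spec.top_amplitude
    for node in spec.degree_plan:
        if node.role == IMPULSE:
            amplitudes.append(first)
        else:
            amplitudes.append(0.618 * first)

    leaf_amps: list[float] = []
    leaf_dirs: list[int] = []
    direction = 1
    for node, amp in zip(spec.degree_plan, amplitudes):
        amps = _leaf_amplitudes(node, amp, spec)
        leaf_amps.extend(amps)
        d = direction if node.role == IMPULSE else -direction
        # sub-wave directions alternate starting with the wave's own
        for k in range(len(amps)):
            leaf_dirs.append(d if k % 2 == 0 else -d)

    n_leaves = len(leaf_amps)
    if isinstance(spec.segment_lengths, int):
        seg = [spec.segment_lengths] * n_leaves
    else:
        seg = list(spec.segment_lengths)
        if len(seg) != n_leaves:
            raise ValueError(
                f"segment_lengths has {len(seg)} entries for {n_leaves} sub-waves"
            )
    if min(seg) < 3:
        raise ValueError("each sub-wave must span at least 3 days")

    levels = [np.log10(spec.base_level)]
    for amp, d in zip(leaf_amps, leaf_dirs):
        levels.append(levels[-1] + d * amp)
    if min(levels) < -6:
        raise ValueError("ratios drive the curve to effectively zero cases")

    # geometric interpolation between pivot levels
    log_curve = []
    for k, days in enumerate(seg):
        ramp = np.linspace(levels[k], levels[k + 1], days + 1)[:-1]
        log_curve.extend(ramp)
    log_curve.append(levels[-1])
    values = 10.0 ** np.asarray(log_curve)

    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv ** 2)))
        rng = np.random.default_rng(spec.seed)
        noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=len(values))
        values = values * noise

    dates = pd.date_range(spec.start_date, periods=len(values), freq="D")
    series = CaseSeries(region=spec.region, dates=dates, raw=values)

    pivot_indices = np.cumsum([0] + seg)
    first_polarity = TROUGH if leaf_dirs[0] > 0 else PEAK
    pivots = []
    for k, (idx, level) in enumerate(zip(pivot_indices, levels)):
        polarity = first_polarity if k % 2 == 0 else (PEAK if first_polarity == TROUGH else TROUGH)
        pivots.append(Pivot(index=int(idx), value=float(10.0 ** level),
                            polarity=polarity, date=dates[int(idx)]))

    nodes = []
    pos = 0
    for node in spec.degree_plan:
        built = _build_tree(node, pos)
        nodes.append(built)
        pos = built.end
    _assign_labels(nodes)
    truth = WaveCount(nodes=nodes, pivots=pivots, score=0.0, scale="log")
    problems: list[Violation] = validate_wave_count(truth)
    if problems:  # construction guarantees validity; guard against regressions
        raise AssertionError(f"generated ground truth violates wave rules: {problems}")
    return series, truth


def write_fixture_suite(directory: str | Path, n_seeds: int) -> None:
    """Write ``n_seeds`` CSV fixtures plus ground-truth JSON files.

    Seeds cycle through a noiseless textbook impulse, a moderate-noise
    (CV 0.15) degree-2 impulse, and a noiseless in-progress corrective,
    so the suite covers the clean, noisy and mid-wave regimes. Files
    are ``fixture_<k>.csv`` / ``fixture_<k>_truth.json``; regeneration
    with the same seeds is byte-identical.
    """
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    variants = [
        lambda s: plan_textbook5(seed=s),
        lambda s: plan_super_impulse(seed=s, noise_cv=0.15),
        lambda s: plan_in_progress(seed=s),
    ]
    for k in range(n_seeds):
        spec = variants[k % len(variants)](k)
        series, truth = generate_elliott_epidemic(spec)
        write_case_series(series, directory / f"fixture_{k:02d}.csv")
        payload = truth.to_dict()
        payload["region"] = series.region
        payload["noise_cv"] = spec.noise_cv
        (directory / f"fixture_{k:02d}_truth.json").write_text(
            json.dumps(payload, indent=1) + "\n"
        )
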