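"""Swing-pivot detection and hierarchical Elliott-wave labeling.

The wave model treats a smoothed epidemic curve as a nested pattern of
*impulses* (five sub-waves in the direction of the prevailing move,
labeled 1-2-3-4-5) and *correctives* (three sub-waves against it,
labeled a-b-c), repeating fractally across *degrees*: five sub-waves
of one degree form a single wave of the next higher degree.

The computational substrate is a percentage-reversal zigzag: the curve
is reduced to alternating peak/trough pivots whose interleaving swings
each exceed a configurable reversal fraction. A dynamic-programming
parser then searches every segmentation of the swing sequence into the
5/3 grammar (waves may be left unsubdivided, and the trailing wave may
be in progress), scoring candidates by hard rule violations plus the
distance of observed swing-amplitude ratios from a Fibonacci ratio
set, and returns the minimum-score labeling.

Hard rules enforced (each switchable):

* **R1** — wave 2 never retraces more than 100 % of wave 1;
* **R2** — wave 3 is never the shortest of impulses 1, 3, 5;
* **R3** — wave 4 does not overlap wave 1's terminal level;

together with the structural grammar **G1** (impulse = 5 children in
roles impulse/corrective/impulse/corrective/impulse) and **G2**
(corrective = 3 children in roles impulse/corrective/impulse).

Amplitudes are measured on ``log10(value + 1)`` by default, matching
how epidemic curves are usually displayed (order-of-magnitude moves on
a logarithmic axis); a linear mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from epiwave.series_io import CaseSeries

__all__ = [
    "Pivot",
    "WaveNode",
    "WaveCount",
    "Violation",
    "detect_pivots",
    "label_waves",
    "validate_wave_count",
    "role_sequence",
    "DEFAULT_RATIO_SET",
    "DEFAULT_REVERSAL_FRACTION",
]

IMPULSE = "impulse"
CORRECTIVE = "corrective"
PEAK = "peak"
TROUGH = "trough"

#: Fibonacci ratios used to score swing-amplitude relationships.
DEFAULT_RATIO_SET: tuple[float, ...] = (0.236, 0.382, 0.5, 0.618, 1.0, 1.618, 2.618)

#: Minimum relative swing size for a reversal to register as a pivot.
DEFAULT_REVERSAL_FRACTION = 0.30

_IMPULSE_CHILD_ROLES = (IMPULSE, CORRECTIVE, IMPULSE, CORRECTIVE, IMPULSE)
_CORRECTIVE_CHILD_ROLES = (IMPULSE, CORRECTIVE, IMPULSE)

# score weights: hard rules dominate, structural shortcuts cost a
# little, Fibonacci proximity breaks the remaining ties
_HARD_PENALTY = 1000.0
_TOP_NODE_PENALTY = 5.0
_LEAF_PENALTY = 3.0  # per degree, for leaving a degree>=1 wave unsubdivided
_MISSING_CHILD_PENALTY = 3.0  # per absent child of an in-progress wave
_TOL = 1e-9
_EPS = 1e-12


@dataclass(frozen=True)
class Pivot:
    """A swing extreme of the smoothed curve.

    ``index`` is the 0-based position in the series, ``value`` the
    smoothed level there, ``polarity`` either ``"peak"`` or
    ``"trough"``. In any pivot list polarities alternate strictly.
    """

    index: int
    value: float
    polarity: str
    date: object | None = None

    def __post_init__(self) -> None:
        if self.polarity not in (PEAK, TROUGH):
            raise ValueError(f"polarity must be 'peak' or 'trough', got {self.polarity!r}")


@dataclass
class WaveNode:
    """One labeled wave spanning ``pivots[start] .. pivots[end]``.

    ``degree`` 0 is the finest sub-wave level (i-v / a-c), degree 1 the
    next (1-5 / A-C), degree 2 the super-wave level (I-V). ``complete``
    is False for an in-progress trailing wave or for a degree>=1 wave
    left unsubdivided.
    """

    degree: int
    role: str
    label: str
    start: int
    end: int
    children: list["WaveNode"] = field(default_factory=list)
    complete: bool = True

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "role": self.role,
            "label": self.label,
            "start": self.start,
            "end": self.end,
            "complete": self.complete,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "WaveNode":
        return cls(
            degree=data["degree"],
            role=data["role"],
            label=data["label"],
            start=data["start"],
            end=data["end"],
            complete=data.get("complete", True),
            children=[cls.from_dict(c) for c in data.get("children", [])],
        )


@dataclass(frozen=True)
class Violation:
    """A wave-grammar rule violation (rule id, node path, message)."""

    rule: str
    path: str
    message: str


@dataclass
class WaveCount:
    """A full labeling: top-degree nodes tiling an alternating pivot list."""

    nodes: list[WaveNode]
    pivots: list[Pivot]
    score: float = 0.0
    violations: list[Violation] = field(default_factory=list)
    scale: str = "log"

    @property
    def in_progress(self) -> bool:
        """True when the final wave has not completed its sub-structure."""
        return bool(self.nodes) and not self.nodes[-1].complete

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "score": self.score,
            "pivots": [
                {"index": p.index, "value": p.value, "polarity": p.polarity,
                 "date": None if p.date is None else str(p.date)}
                for p in self.pivots
            ],
            "nodes": [n.to_dict() for n in self.nodes],
            "violations": [
                {"rule": v.rule, "path": v.path, "message": v.message}
                for v in self.violations
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "WaveCount":
        return cls(
            nodes=[WaveNode.from_dict(n) for n in data["nodes"]],
            pivots=[
                Pivot(index=p["index"], value=p["value"], polarity=p["polarity"],
                      date=p.get("date"))
                for p in data["pivots"]
            ],
            score=data.get("score", 0.0),
            violations=[
                Violation(v["rule"], v["path"], v["message"])
                for v in data.get("violations", [])
            ],
            scale=data.get("scale", "log"),
        )


# ---------------------------------------------------------------------------
# pivot detection
# ---------------------------------------------------------------------------

def detect_pivots(series: CaseSeries, reversal_fraction: float = DEFAULT_REVERSAL_FRACTION) -> list[Pivot]:
    """Reduce a smoothed curve to alternating swing pivots (zigzag).

    A peak (trough) is confirmed once the curve has moved away from the
    running extreme by at least ``reversal_fraction`` of that extreme's
    value. The first and last points of the series are always included,
    so the leading and trailing swings may be smaller than the
    threshold. Detection is scale-invariant: multiplying the series by
    a positive constant leaves the pivot indices unchanged.
    """
    if series.smoothed is None:
        raise ValueError("series has no smoothed values; call moving_average first")
    if not 0.0 < reversal_fraction < 1.0:
        raise ValueError(f"reversal_fraction must be in (0, 1), got {reversal_fraction}")
    v = np.asarray(series.smoothed, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("smoothed values contain missing entries; cannot detect pivots")
    m = len(v)
    if m < 3:
        raise ValueError(f"need at least 3 points to detect pivots, got {m}")

    def _drop(a: float, b: float) -> float:
        return (a - b) / max(a, _EPS)

    def _rise(a: float, b: float) -> float:
        return (b - a) / max(a, _EPS)

    confirmed: list[tuple[int, str]] = []
    hi = lo = 0
    trend = 0
    for i in range(1, m):
        if trend == 0:
            if v[i] > v[hi]:
                hi = i
            if v[i] < v[lo]:
                lo = i
            if hi < i and _drop(v[hi], v[i]) >= reversal_fraction:
                confirmed.append((hi, PEAK))
                trend, lo = -1, i
            elif lo < i and _rise(v[lo], v[i]) >= reversal_fraction:
                confirmed.append((lo, TROUGH))
                trend, hi = 1, i
        elif trend > 0:
            if v[i] > v[hi]:
                hi = i
            elif _drop(v[hi], v[i]) >= reversal_fraction:
                confirmed.append((hi, PEAK))
                trend, lo = -1, i
        else:
            if v[i] < v[lo]:
                lo = i
            elif _rise(v[lo], v[i]) >= reversal_fraction:
                confirmed.append((lo, TROUGH))
                trend, hi = 1, i

    def _opposite(polarity: str) -> str:
        return TROUGH if polarity == PEAK else PEAK

    if not confirmed:
        first = TROUGH if v[m - 1] >= v[0] else PEAK
        marks = [(0, first), (m - 1, _opposite(first))]
    else:
        marks = list(confirmed)
        if marks[0][0] != 0:
            marks.insert(0, (0, _opposite(marks[0][1])))
        if marks[-1][0] != m - 1:
            marks.append((m - 1, _opposite(marks[-1][1])))

    dates = series.dates
    return [
        Pivot(index=i, value=float(v[i]), polarity=pol, date=dates[i])
        for i, pol in marks
    ]


# ---------------------------------------------------------------------------
# labeling search
# ---------------------------------------------------------------------------

def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log":
        return np.log10(np.asarray(values, dtype=float) + 1.0)
    if scale == "linear":
        return np.asarray(values, dtype=float)
    raise ValueError(f"scale must be 'log' or 'linear', got {scale!r}")


def _child_roles(role: str) -> tuple[str, ...]:
    return _IMPULSE_CHILD_ROLES if role == IMPULSE else _CORRECTIVE_CHILD_ROLES


def _roman(n: int, upper: bool) -> str:
    numerals = ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x"]
    text = numerals[n - 1] if 1 <= n <= len(numerals) else str(n)
    return text.upper() if upper else text


def _ordinal_label(position: int, degree: int) -> str:
    if degree == 0:
        return _roman(position, upper=False)
    if degree == 1:
        return str(position)
    return _roman(position, upper=True)


def _letter_label(position: int, degree: int) -> str:
    letters = "abc"
    text = letters[position - 1] if 1 <= position <= 3 else str(position)
    return text if degree == 0 else text.upper()


class _Labeler:
    """Minimum-score parse of a swing sequence into the wave grammar."""

    def __init__(self, tv: np.ndarray, ratio_set: tuple[float, ...],
                 rules: tuple[str, ...]):
        self.tv = tv
        self.n_pivots = len(tv)
        self.last = self.n_pivots - 1  # index of the final pivot
        self.ratio_set = ratio_set
        self.rules = rules
        self._complete_cache: dict = {}
        self._partial_cache: dict = {}

    # -- amplitude helpers --------------------------------------------------

    def _amp(self, node: WaveNode) -> float:
        return abs(self.tv[node.end] - self.tv[node.start])

    def _node_penalty(self, children: list[WaveNode], role: str) -> float:
        return (_HARD_PENALTY * len(self._rule_violations(children, role))
                + self._ratio_penalty(children, role))

    def _rule_violations(self, children: list[WaveNode], role: str) -> list[str]:
        if role != IMPULSE or len(children) < 2:
            return []
        tv = self.tv
        d = 1.0 if tv[children[0].end] >= tv[children[0].start] else -1.0
        out = []
        if "R1" in self.rules and d * (tv[children[1].end] - tv[children[0].start]) < -_TOL:
            out.append("R1")
        if "R2" in self.rules and len(children) == 5:
            a1, a3, a5 = (self._amp(children[k]) for k in (0, 2, 4))
            if a3 < a1 - _TOL and a3 < a5 - _TOL:
                out.append("R2")
        if "R3" in self.rules and len(children) >= 4:
            if d * (tv[children[3].end] - tv[children[0].end]) < -_TOL:
                out.append("R3")
        return out

    def _ratio_penalty(self, children: list[WaveNode], role: str) -> float:
        pairs = ((1, 0), (2, 0), (3, 2), (4, 0)) if role == IMPULSE else ((1, 0), (2, 0))
        penalty = 0.0
        for a, b in pairs:
            if a >= len(children):
                continue
            observed = max(self._amp(children[a]), _EPS) / max(self._amp(children[b]), _EPS)
            penalty += min(abs(math.log(observed / r)) for r in self.ratio_set)
        return penalty

    # -- parsing ------------------------------------------------------------

    def parse_complete(self, start: int, degree: int, role: str) -> dict[int, tuple[float, WaveNode]]:
        """All minimum-score complete parses of a ``(degree, role)`` wave
        beginning at pivot ``start``, keyed by end pivot."""
        key = (start, degree, role)
        if key in self._complete_cache:
            return self._complete_cache[key]
        candidates: dict[int, tuple[float, WaveNode]] = {}
        if start + 1 <= self.last:
            leaf = WaveNode(degree=degree, role=role, label="", start=start,
                            end=start + 1, complete=(degree == 0))
            candidates[start + 1] = (_LEAF_PENALTY * degree, leaf)
        if degree >= 1:
            roles = _child_roles(role)
            states: dict[int, tuple[float, list[WaveNode]]] = {start: (0.0, [])}
            for child_role in roles:
                nxt: dict[int, tuple[float, list[WaveNode]]] = {}
                for pos, (sc, kids) in states.items():
                    for end, (csc, cnode) in self.parse_complete(pos, degree - 1, child_role).items():
                        total = sc + csc
                        if end not in nxt or total < nxt[end][0]:
                            nxt[end] = (total, kids + [cnode])
                states = nxt
                if not states:
                    break
            for end, (sc, kids) in states.items():
                total = sc + self._node_penalty(kids, role)
                if end not in candidates or total < candidates[end][0]:
                    node = WaveNode(degree=degree, role=role, label="", start=start,
                                    end=end, children=kids, complete=True)
                    candidates[end] = (total, node)
        self._complete_cache[key] = candidates
        return candidates

    def parse_partial(self, start: int, degree: int, role: str) -> tuple[float, WaveNode] | None:
        """Best in-progress parse consuming every remaining swing, or None.

        An in-progress wave has a proper prefix of its children, the
        last of which may itself be in progress. Only the trailing wave
        of the whole sequence may be partial (the present moment).
        """
        key = (start, degree, role)
        if key in self._partial_cache:
            return self._partial_cache[key]
        result: tuple[float, WaveNode] | None = None
        if degree >= 1:
            roles = _child_roles(role)
            states: dict[int, tuple[float, list[WaveNode]]] = {start: (0.0, [])}
            for m, child_role in enumerate(roles):
                # option A: children so far are complete and exhaust the swings
                for pos, (sc, kids) in states.items():
                    if pos == self.last and kids:
                        total = (sc + _MISSING_CHILD_PENALTY * (len(roles) - len(kids))
                                 + self._node_penalty(kids, role))
                        if result is None or total < result[0]:
                            node = WaveNode(degree=degree, role=role, label="",
                                            start=start, end=self.last,
                                            children=list(kids), complete=False)
                            result = (total, node)
                # option B: the next child is itself in progress
                for pos, (sc, kids) in states.items():
                    if pos >= self.last:
                        continue
                    partial = self.parse_partial(pos, degree - 1, child_role)
                    if partial is not None:
                        psc, pnode = partial
                        new_kids = kids + [pnode]
                        total = (sc + psc
                                 + _MISSING_CHILD_PENALTY * (len(roles) - len(new_kids))
                                 + self._node_penalty(new_kids, role))
                        if result is None or total < result[0]:
                            node = WaveNode(degree=degree, role=role, label="",
                                            start=start, end=self.last,
                                            children=new_kids, complete=False)
                            result = (total, node)
                # advance: complete this child and move on
                nxt: dict[int, tuple[float, list[WaveNode]]] = {}
                for pos, (sc, kids) in states.items():
                    if pos >= self.last:
                        continue
                    for end, (csc, cnode) in self.parse_complete(pos, degree - 1, child_role).items():
                        total = sc + csc
                        if end not in nxt or total < nxt[end][0]:
                            nxt[end] = (total, kids + [cnode])
                states = nxt
                if not states:
                    break
        self._partial_cache[key] = result
        return result

    def best_sequence(self, top_degree: int) -> tuple[float, list[WaveNode]]:
        """Minimum-score alternating top-level node sequence tiling all swings."""
        memo: dict = {}

        def best(start: int, role: str) -> tuple[float, list[WaveNode]] | None:
            if start == self.last:
                return (0.0, [])
            key = (start, role)
            if key in memo:
                return memo[key]
            memo[key] = None  # cycle guard (nodes consume >=1 swing, so unused)
            other = CORRECTIVE if role == IMPULSE else IMPULSE
            result: tuple[float, list[WaveNode]] | None = None
            for end in sorted(self.parse_complete(start, top_degree, role)):
                sc, node = self.parse_complete(start, top_degree, role)[end]
                rest = best(end, other)
                if rest is None:
                    continue
                total = sc + _TOP_NODE_PENALTY + rest[0]
                if result is None or total < result[0]:
                    result = (total, [node] + rest[1])
            partial = self.parse_partial(start, top_degree, role)
            if partial is not None:
                total = partial[0] + _TOP_NODE_PENALTY
                if result is None or total < result[0]:
                    result = (total, [partial[1]])
            memo[key] = result
            return result

        options = [r for r in (IMPULSE, CORRECTIVE) if best(0, r) is not None]
        if not options:
            raise ValueError("no wave labeling found for the pivot sequence")
        best_role = min(options, key=lambda r: best(0, r)[0])
        return best(0, best_role)


def _assign_labels(nodes: list[WaveNode]) -> None:
    """Label top nodes by sequence position and children by grammar role."""
    for position, node in enumerate(nodes, start=1):
        node.label = _ordinal_label(position, node.degree)
        _label_children(node)


def _label_children(node: WaveNode) -> None:
    for position, child in enumerate(node.children, start=1):
        if node.role == IMPULSE:
            child.label = _ordinal_label(position, child.degree)
        else:
            child.label = _letter_label(position, child.degree)
        _label_children(child)


def _check_alternation(pivots: list[Pivot]) -> None:
    for prev, cur in zip(pivots, pivots[1:]):
        if cur.index <= prev.index:
            raise ValueError("pivot indices must be strictly increasing")
        if cur.polarity == prev.polarity:
            raise ValueError("pivot polarities must strictly alternate")


def label_waves(
    pivots: list[Pivot],
    max_degree: int = 2,
    ratio_set: tuple[float, ...] = DEFAULT_RATIO_SET,
    scale: str = "log",
    rules: tuple[str, ...] = ("R1", "R2", "R3"),
) -> WaveCount:
    """Search for the minimum-score wave labeling of a pivot sequence.

    The swing sequence between consecutive pivots is parsed into the
    impulse/corrective grammar with top-level waves at ``max_degree``.
    The score combines hard rule violations (R1-R3, weighted to
    dominate), small structural penalties for unsubdivided or
    in-progress waves, and the log-distance of observed swing-amplitude
    ratios from the nearest member of ``ratio_set``. The trailing wave
    may be in progress; everything before it must parse completely.

    Elliott counts are not unique: the returned labeling is the best
    under this score, not the only defensible one.
    """
    if len(pivots) < 2:
        raise ValueError(f"need at least 2 pivots to label, got {len(pivots)}")
    if max_degree < 0:
        raise ValueError(f"max_degree must be >= 0, got {max_degree}")
    _check_alternation(pivots)
    if not ratio_set:
        raise ValueError("ratio_set must be non-empty")

    tv = _transform(np.array([p.value for p in pivots], dtype=float), scale)
    labeler = _Labeler(tv, tuple(ratio_set), tuple(rules))
    score, nodes = labeler.best_sequence(max_degree)
    _assign_labels(nodes)
    count = WaveCount(nodes=nodes, pivots=list(pivots), score=score, scale=scale)
    count.violations = validate_wave_count(count)
    return count


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_wave_count(count: WaveCount, rules: tuple[str, ...] = ("R1", "R2", "R3")) -> list[Violation]:
    """Check a wave count against the grammar and the hard wave rules.

    Returns one :class:`Violation` per broken rule (G1/G2 child-count
    grammar, R1 deep wave-2 retrace, R2 shortest wave 3, R3 wave-4 /
    wave-1 overlap). Rules needing absent children of an in-progress
    wave are skipped. Structural malformation — children not tiling the
    parent span, or a child whose degree is not parent degree minus
    one — raises ``ValueError`` naming the node path.
    """
    tv = _transform(np.array([p.value for p in count.pivots], dtype=float), count.scale)

    def amp(node: WaveNode) -> float:
        return abs(tv[node.end] - tv[node.start])

    violations: list[Violation] = []

    def walk(node: WaveNode, path: str) -> None:
        kids = node.children
        if not kids:
            return
        pos = node.start
        for k, child in enumerate(kids):
            if child.degree != node.degree - 1:
                raise ValueError(f"{path}.children[{k}]: degree {child.degree} under degree {node.degree}")
            if child.start != pos:
                raise ValueError(f"{path}.children[{k}]: children do not tile the parent span")
            pos = child.end
        if pos != node.end:
            raise ValueError(f"{path}: children do not reach the parent's end pivot")

        expected = _child_roles(node.role)
        rule_id = "G1" if node.role == IMPULSE else "G2"
        if node.complete and len(kids) != len(expected):
            violations.append(Violation(rule_id, path,
                f"complete {node.role} has {len(kids)} children, expected {len(expected)}"))
        for k, (child, want) in enumerate(zip(kids, expected)):
            if child.role != want:
                violations.append(Violation(rule_id, f"{path}.children[{k}]",
                    f"child role {child.role}, expected {want}"))

        if node.role == IMPULSE:
            d = 1.0 if tv[kids[0].end] >= tv[kids[0].start] else -1.0
            if "R1" in rules and len(kids) >= 2:
                if d * (tv[kids[1].end] - tv[kids[0].start]) < -_TOL:
                    violations.append(Violation("R1", path,
                        "wave 2 retraces more than 100% of wave 1"))
            if "R2" in rules and len(kids) == 5:
                a1, a3, a5 = amp(kids[0]), amp(kids[2]), amp(kids[4])
                if a3 < a1 - _TOL and a3 < a5 - _TOL:
                    violations.append(Violation("R2", path,
                        "wave 3 is the shortest of impulses 1, 3, 5"))
            if "R3" in rules and len(kids) >= 4:
                if d * (tv[kids[3].end] - tv[kids[0].end]) < -_TOL:
                    violations.append(Violation("R3", path,
                        "wave 4 overlaps wave 1's terminal level"))
        for k, child in enumerate(kids):
            walk(child, f"{path}.children[{k}]")

    for idx, node in enumerate(count.nodes):
        walk(node, f"nodes[{idx}]")
    return violations


def role_sequence(count: WaveCount, degree: int) -> list[str]:
    """Roles of all waves at ``degree``, in span order (recovery helper)."""
    out: list[str] = []

    def walk(node: WaveNode) -> None:
        if node.degree == degree:
            out.append(node.role)
            return
        for child in node.children:
            walk(child)

    for node in count.nodes:
        walk(node)
    return out
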