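"""Gate-based marker rescaling, positivity calling, and hierarchical phenotyping.

Raw mean-intensity values are mapped onto [0, 1] with a per-marker
piecewise-linear transform anchored at three intensities: ``low`` (mapped to
0), ``gate`` (mapped to 0.5) and ``high`` (mapped to 1).  A cell is positive
for a marker iff its rescaled value is strictly greater than 0.5, so the gate
intensity itself is negative.  Cell types are then assigned by an ordered
hierarchy of boolean rules over the positivity flags: within each level the
first matching rule wins, child rules apply only to cells carrying the
parent's label, and cells matched by no rule keep the fallback label
``"Other"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

OTHER_LABEL = "Other"
POSITIVITY_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# gates


@dataclass(frozen=True)
class GateEntry:
    """Anchor intensities for one marker: low -> 0, gate -> 0.5, high -> 1."""

    low: float
    gate: float
    high: float

    def __post_init__(self):
        if not (self.low < self.gate < self.high):
            raise ConfigurationError(
                f"gate anchors must satisfy low < gate < high, "
                f"got {self.low} / {self.gate} / {self.high}"
            )


class GateConfig(Mapping[str, GateEntry]):
    """Per-marker gate anchors, behaves as a read-only mapping marker -> GateEntry."""

    def __init__(self, entries: Mapping[str, GateEntry]):
        self._entries = dict(entries)

    def __getitem__(self, marker: str) -> GateEntry:
        return self._entries[marker]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def __repr__(self):
        return f"GateConfig({len(self._entries)} markers)"

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "GateConfig":
        entries = {}
        for marker, spec in d.items():
            try:
                entries[marker] = GateEntry(
                    float(spec["low"]), float(spec["gate"]), float(spec["high"])
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"gate entry for {marker!r} missing key {exc}"
                ) from exc
        return cls(entries)

    def to_dict(self) -> dict:
        return {
            m: {"low": e.low, "gate": e.gate, "high": e.high}
            for m, e in self._entries.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "GateConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_gates(
        cls,
        table: pd.DataFrame,
        gates: Mapping[str, float],
        low_quantile: float = 0.01,
        high_quantile: float = 0.99,
    ) -> "GateConfig":
        """Build a config from gate values only, taking low/high anchors from
        per-marker intensity percentiles (1st/99th by default)."""
        entries = {}
        for marker, gate in gates.items():
            if marker not in table.columns:
                raise ConfigurationError(f"marker {marker!r} not in table")
            vals = np.asarray(table[marker], dtype=float)
            low = float(np.quantile(vals, low_quantile))
            high = float(np.quantile(vals, high_quantile))
            # keep ordering valid when the gate sits outside the percentile span
            low = min(low, gate - abs(gate) * 1e-6 - 1e-12)
            high = max(high, gate + abs(gate) * 1e-6 + 1e-12)
            entries[marker] = GateEntry(low, float(gate), high)
        return cls(entries)


def rescale_marker(raw, gate_entry: GateEntry) -> np.ndarray:
    """Piecewise-linear rescale of raw intensities onto [0, 1].

    [low, gate] maps linearly onto [0, 0.5] and [gate, high] onto [0.5, 1];
    values outside [low, high] are clamped.  Monotone non-decreasing.
    """
    raw = np.asarray(raw, dtype=float)
    xp = [gate_entry.low, gate_entry.gate, gate_entry.high]
    return np.interp(raw, xp, [0.0, 0.5, 1.0])


def call_positivity(scaled) -> np.ndarray:
    """Positive iff rescaled value strictly exceeds 0.5 (exactly 0.5 is negative)."""
    scaled = np.asarray(scaled, dtype=float)
    if np.any((scaled < 0.0) | (scaled > 1.0)):
        raise ValueError("scaled values must lie in [0, 1]")
    return scaled > POSITIVITY_THRESHOLD


def scale_table(
    table: pd.DataFrame, gates: GateConfig, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Append scaled_<marker> and pos_<marker> columns for every gated marker."""
    markers = list(gates) if markers is None else list(markers)
    out = table.copy()
    for marker in markers:
        if marker not in table.columns:
            raise ConfigurationError(f"marker {marker!r} not in table")
        scaled = rescale_marker(table[marker].to_numpy(), gates[marker])
        out[f"scaled_{marker}"] = scaled
        out[f"pos_{marker}"] = call_positivity(scaled)
    return out


def positivity_frame(scaled_table: pd.DataFrame) -> pd.DataFrame:
    """Extract pos_<marker> columns into a boolean frame indexed by marker name."""
    cols = [c for c in scaled_table.columns if c.startswith("pos_")]
    if not cols:
        raise ValueError("table has no pos_<marker> columns; run scale_table first")
    out = scaled_table[cols].copy()
    out.columns = [c[len("pos_"):] for c in cols]
    return out.astype(bool)


# ---------------------------------------------------------------------------
# boolean rule grammar: marker names, AND/OR/NOT, parentheses

_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|([A-Za-z_][A-Za-z0-9_]*))")


class _Expr:
    def evaluate(self, flags: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def markers(self) -> set:  # pragma: no cover
        raise NotImplementedError


@dataclass
class _Name(_Expr):
    name: str

    def evaluate(self, flags):
        return flags[self.name].to_numpy()

    def markers(self):
        return {self.name}


@dataclass
class _Not(_Expr):
    operand: _Expr

    def evaluate(self, flags):
        return ~self.operand.evaluate(flags)

    def markers(self):
        return self.operand.markers()


@dataclass
class _BinOp(_Expr):
    op: str
    operands: list

    def evaluate(self, flags):
        vals = [o.evaluate(flags) for o in self.operands]
        out = vals[0]
        for v in vals[1:]:
            out = (out & v) if self.op == "AND" else (out | v)
        return out

    def markers(self):
        return set().union(*(o.markers() for o in self.operands))


def _tokenize(text: str) -> list:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ConfigurationError(
                    f"cannot tokenize rule expression at {text[pos:]!r}"
                )
            break
        if m.group(1):
            tokens.append("(")
        elif m.group(2):
            tokens.append(")")
        else:
            tokens.append(m.group(3))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> _Expr:
    """Parse a rule expression (markers, AND/OR/NOT, parentheses) into an AST."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or():
        operands = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            take()
            operands.append(parse_and())
        return operands[0] if len(operands) == 1 else _BinOp("OR", operands)

    def parse_and():
        operands = [parse_not()]
        while peek() is not None and peek().upper() == "AND":
            take()
            operands.append(parse_not())
        return operands[0] if len(operands) == 1 else _BinOp("AND", operands)

    def parse_not():
        if peek() is not None and peek().upper() == "NOT":
            take()
            return _Not(parse_not())
        return parse_atom()

    def parse_atom():
        tok = take()
        if tok is None:
            raise ConfigurationError(f"unexpected end of expression in {text!r}")
        if tok == "(":
            inner = parse_or()
            if take() != ")":
                raise ConfigurationError(f"unbalanced parentheses in {text!r}")
            return inner
        if tok in {")"} or tok.upper() in {"AND", "OR", "NOT"}:
            raise ConfigurationError(f"unexpected token {tok!r} in {text!r}")
        return _Name(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise ConfigurationError(f"trailing tokens in expression {text!r}")
    return expr


# ---------------------------------------------------------------------------
# hierarchical rules


@dataclass
class PhenotypeRule:
    """One labeling rule: a boolean expression over positivity flags.

    ``parent`` restricts the rule to cells already carrying that label from
    the previous level; ``None`` means the rule applies at the root.
    """

    label: str
    expression: str
    parent: str | None = None
    _ast: _Expr = field(init=False, repr=False)

    def __post_init__(self):
        self._ast = parse_expression(self.expression)

    def markers(self) -> set:
        return self._ast.markers()

    def evaluate(self, flags: pd.DataFrame) -> np.ndarray:
        return np.asarray(self._ast.evaluate(flags), dtype=bool)


class PhenotypeRuleTree:
    """Ordered levels of ordered rules; document order breaks ties."""

    def __init__(self, levels: Sequence[Sequence[PhenotypeRule]]):
        self.levels = [list(level) for level in levels]

    def markers(self) -> set:
        out: set = set()
        for level in self.levels:
            for rule in level:
                out |= rule.markers()
        return out

    @classmethod
    def from_dict(cls, spec: Iterable) -> "PhenotypeRuleTree":
        levels = []
        for level_spec in spec:
            level = [
                PhenotypeRule(
                    label=r["label"],
                    expression=r["expression"],
                    parent=r.get("parent"),
                )
                for r in level_spec
            ]
            levels.append(level)
        return cls(levels)

    def to_dict(self) -> list:
        return [
            [
                {"label": r.label, "expression": r.expression, "parent": r.parent}
                for r in level
            ]
            for level in self.levels
        ]

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeRuleTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_rule_tree() -> PhenotypeRuleTree:
    """Shipped hierarchy: tumor/immune/endothelial roots, immune lineages,
    and CD8 T-cell functional states ordered most-specific first."""
    return PhenotypeRuleTree(
        [
            [
                PhenotypeRule("Tumor", "SOX10 OR PMEL"),
                PhenotypeRule("Immune", "CD45"),
                PhenotypeRule("Endothelial", "CD31"),
            ],
            [
                PhenotypeRule("CD8 T", "CD3E AND CD8A", parent="Immune"),
                PhenotypeRule("Treg", "CD4 AND FOXP3", parent="Immune"),
                PhenotypeRule("CD4 T", "CD3E AND CD4", parent="Immune"),
                PhenotypeRule("Macrophage", "CD68 OR CD163 OR CD206", parent="Immune"),
                PhenotypeRule("Myeloid", "CD11C", parent="Immune"),
            ],
            [
                PhenotypeRule(
                    "terminally exhausted CD8 T", "PD1 AND LAG3 AND TIM3", parent="CD8 T"
                ),
                PhenotypeRule(
                    "partially exhausted CD8 T",
                    "PD1 AND LAG3 AND NOT TIM3",
                    parent="CD8 T",
                ),
                PhenotypeRule(
                    "proliferative cytotoxic CD8 T", "GZMB AND KI67", parent="CD8 T"
                ),
                PhenotypeRule("cytotoxic CD8 T", "GZMB", parent="CD8 T"),
                PhenotypeRule(
                    "resident memory CD8 T", "CD45RO AND CD103", parent="CD8 T"
                ),
                PhenotypeRule("memory CD8 T", "CD45RO", parent="CD8 T"),
                PhenotypeRule("naive CD8 T", "LEF1 AND CD45RA", parent="CD8 T"),
            ],
        ]
    )


def classify_cells(flags: pd.DataFrame, rules: PhenotypeRuleTree) -> pd.Series:
    """Assign one label per cell from boolean positivity flags.

    Within a level the first matching rule (document order) wins; a child rule
    is only evaluated on cells holding its parent label; cells that match no
    rule retain their parent label or the fallback ``"Other"``.
    """
    missing = rules.markers() - set(flags.columns)
    if missing:
        raise ConfigurationError(
            f"rules reference markers absent from table: {sorted(missing)}"
        )
    n = len(flags)
    labels = np.full(n, OTHER_LABEL, dtype=object)
    for level in rules.levels:
        claimed = np.zeros(n, dtype=bool)
        new_labels = labels.copy()
        for rule in level:
            if rule.parent is None:
                scope = np.ones(n, dtype=bool)
            else:
                scope = labels == rule.parent
            hit = scope & ~claimed & rule.evaluate(flags)
            new_labels[hit] = rule.label
            claimed |= hit
        labels = new_labels
    return pd.Series(labels, index=flags.index, name="phenotype")
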