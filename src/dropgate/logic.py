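"""DNA strand-displacement logic gates over amplification markers.

Five gate primitives — YES, NOT, OR, AND, AND-NOT — combine isothermal
amplification signals into a single fluorescent readout. Each gate is
built from transducers that convert an input (an amplicon, or an upstream
gate's output strand) into a released output strand:

* YES passes its transducer output through;
* NOT displaces an unquenched fluorophore, inverting the signal;
* OR is two transducers releasing identical output strands (levels add);
* AND adds a stoichiometric "threshold strand" that sequesters output, so
  only the excess past the threshold activates the reporter;
* AND-NOT (a primitive, not sugar for AND + NOT) asserts its first input
  and inverts its second.

Circuits are DAGs over named marker inputs, evaluated either at Boolean
level or with a phenomenological equilibrium signal model (levels, leak,
threshold subtraction — no kinetics). In the signal model every gate
reads its inputs through its own transducer stage, which restores the
level to on_level/leak depending on the upstream ON/OFF state — the
digital restoration a released output strand provides in the molecular
implementation. Within a gate the arithmetic is analog, so leaky
parameters can produce false ONs (and are allowed to, for studying
failure modes).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import product

import pandas as pd

__all__ = [
    "Gate",
    "LogicCircuit",
    "SignalParams",
    "eval_boolean",
    "eval_signal",
    "truth_table",
    "parse_expression",
]

GATE_KINDS = ("YES", "NOT", "OR", "AND", "ANDNOT")
_ARITY = {"YES": 1, "NOT": 1, "OR": 2, "AND": 2, "ANDNOT": 2}


@dataclass(frozen=True)
class Gate:
    """One logic gate; inputs name markers or upstream gate labels.

    For AND-NOT the input order matters: the first input is asserted, the
    second inverted.
    """

    label: str
    kind: str
    inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        kind = self.kind.upper().replace("-", "")
        object.__setattr__(self, "kind", kind)
        if kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if len(self.inputs) != _ARITY[kind]:
            raise ValueError(
                f"{kind} gate takes {_ARITY[kind]} input(s), got {len(self.inputs)}"
            )


class LogicCircuit:
    """An acyclic multi-level circuit of gates over named marker inputs."""

    def __init__(
        self,
        gates: list[Gate],
        inputs: list[str] | None = None,
        outputs: list[str] | None = None,
    ):
        self.gates = {g.label: g for g in gates}
        if len(self.gates) != len(gates):
            raise ValueError("duplicate gate labels")
        referenced = {src for g in gates for src in g.inputs}
        inferred_inputs = sorted(referenced - self.gates.keys())
        self.inputs = list(inputs) if inputs is not None else inferred_inputs
        missing = referenced - self.gates.keys() - set(self.inputs)
        if missing:
            raise ValueError(f"unresolved gate input(s): {sorted(missing)}")
        fed = {src for g in gates for src in g.inputs}
        default_out = [g.label for g in gates if g.label not in fed]
        self.outputs = list(outputs) if outputs is not None else default_out
        self.order = self._toposort(gates)

    def _toposort(self, gates: list[Gate]) -> list[str]:
        indeg = {
            g.label: sum(1 for s in g.inputs if s in self.gates) for g in gates
        }
        ready = [lab for lab, d in sorted(indeg.items()) if d == 0]
        order: list[str] = []
        while ready:
            lab = ready.pop(0)
            order.append(lab)
            for g in gates:
                if lab in g.inputs and g.label in indeg:
                    indeg[g.label] -= sum(1 for s in g.inputs if s == lab)
                    if indeg[g.label] == 0 and g.label not in order:
                        ready.append(g.label)
        if len(order) != len(gates):
            raise ValueError("circuit contains a cycle")
        return order


@dataclass(frozen=True)
class SignalParams:
    """Equilibrium signal levels of the strand-displacement components.

    on_level: transducer output when its input fired; leak: residual
    output when it did not; and_threshold: amount of output the AND
    gate's threshold strand sequesters; detect_cutoff: fluorescence level
    counted as ON.
    """

    on_level: float = 1.0
    leak: float = 0.05
    and_threshold: float = 1.2
    detect_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.leak < self.and_threshold < 2 * self.on_level - self.leak):
            raise ValueError("require 0 <= leak < and_threshold < 2*on_level - leak")
        if not (0.0 < self.detect_cutoff < self.on_level):
            raise ValueError("require 0 < detect_cutoff < on_level")
        if self.leak >= self.detect_cutoff:
            # a leaky reporter above the cutoff produces false ONs; allowed
            # deliberately so the failure mode can be studied, not hidden
            warnings.warn(
                "leak >= detect_cutoff: OFF states may read as ON",
                stacklevel=2,
            )


def eval_boolean(circuit: LogicCircuit, assignment: dict[str, int]) -> dict[str, bool]:
    """Evaluate output gate states for one marker assignment.

    YES(x)=x, NOT(x)=!x, OR=x|y, AND=x&y, ANDNOT=x&!y, in topological order.
    """
    missing = [m for m in circuit.inputs if m not in assignment]
    if missing:
        raise ValueError(f"assignment missing marker(s): {missing}")
    value: dict[str, bool] = {m: bool(assignment[m]) for m in circuit.inputs}
    for lab in circuit.order:
        g = circuit.gates[lab]
        a = value[g.inputs[0]]
        if g.kind == "YES":
            value[lab] = a
        elif g.kind == "NOT":
            value[lab] = not a
        else:
            b = value[g.inputs[1]]
            if g.kind == "OR":
                value[lab] = a or b
            elif g.kind == "AND":
                value[lab] = a and b
            else:  # ANDNOT
                value[lab] = a and not b
    return {lab: value[lab] for lab in circuit.outputs}


def eval_signal(
    circuit: LogicCircuit,
    assignment: dict[str, int],
    params: SignalParams = SignalParams(),
) -> tuple[dict[str, float], dict[str, bool]]:
    """Signal-level evaluation: per-gate output levels and ON/OFF calls.

    Each gate's transducer stage reads its source as on_level when the
    source fired (marker present / upstream gate ON) and leak otherwise;
    the gate then combines levels: OR = sum, AND = max(0, sum -
    and_threshold), NOT = max(0, on_level - input), ANDNOT = max(0,
    asserted - inverted). ON iff level > detect_cutoff.
    """
    missing = [m for m in circuit.inputs if m not in assignment]
    if missing:
        raise ValueError(f"assignment missing marker(s): {missing}")
    fired: dict[str, bool] = {m: bool(assignment[m]) for m in circuit.inputs}
    levels: dict[str, float] = {}
    calls: dict[str, bool] = {}

    def transduced(src: str) -> float:
        return params.on_level if fired[src] else params.leak

    for lab in circuit.order:
        g = circuit.gates[lab]
        a = transduced(g.inputs[0])
        if g.kind == "YES":
            lvl = a
        elif g.kind == "NOT":
            lvl = max(0.0, params.on_level - a)
        else:
            b = transduced(g.inputs[1])
            if g.kind == "OR":
                lvl = a + b
            elif g.kind == "AND":
                lvl = max(0.0, a + b - params.and_threshold)
            else:  # ANDNOT
                lvl = max(0.0, a - b)
        levels[lab] = lvl
        calls[lab] = lvl > params.detect_cutoff
        fired[lab] = calls[lab]
    return levels, calls


def truth_table(
    circuit: LogicCircuit,
    params: SignalParams | None = None,
) -> pd.DataFrame:
    """Exhaustive table over all 2^k input assignments (binary-counter order).

    With ``params`` supplied, also reports per-output signal levels and
    signal-model calls.
    """
    k = len(circuit.inputs)
    if k > 20:
        raise ValueError("truth tables limited to 20 inputs")
    rows = []
    for bits in product((0, 1), repeat=k):
        assignment = dict(zip(circuit.inputs, bits))
        out = eval_boolean(circuit, assignment)
        row: dict = {**assignment}
        for lab, v in out.items():
            row[f"out_{lab}"] = bool(v)
        if params is not None:
            levels, calls = eval_signal(circuit, assignment, params)
            for lab in circuit.outputs:
                row[f"level_{lab}"] = levels[lab]
                row[f"signal_on_{lab}"] = calls[lab]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression parser
#
# Grammar (precedence low -> high):
#   expr    := term (OR term)*
#   term    := factor ((AND | AND-NOT) factor)*
#   factor  := NOT factor | YES factor | '(' expr ')' | MARKER
# AND and AND-NOT are left-associative.

_TOKEN = re.compile(r"\s*(AND-NOT|AND|OR|NOT|YES|\(|\)|[A-Za-z_][A-Za-z0-9_]*)")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m:
                if text[pos:].strip() == "":
                    break
                raise ValueError(f"syntax error at position {pos}: {text[pos:]!r}")
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0
        self.counter = 0
        self.gates: list[Gate] = []

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.i >= len(self.tokens):
            raise ValueError(f"syntax error: unexpected end of expression {self.text!r}")
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def _gate(self, kind: str, *inputs: str) -> str:
        self.counter += 1
        label = f"g{self.counter}_{kind.lower()}"
        self.gates.append(Gate(label, kind, tuple(inputs)))
        return label

    def expr(self) -> str:
        node = self.term()
        while self._peek() == "OR":
            self._next()
            node = self._gate("OR", node, self.term())
        return node

    def term(self) -> str:
        node = self.factor()
        while self._peek() in ("AND", "AND-NOT"):
            op, _ = self._next()
            kind = "ANDNOT" if op == "AND-NOT" else "AND"
            node = self._gate(kind, node, self.factor())
        return node

    def factor(self) -> str:
        tok, pos = self._next()
        if tok == "NOT":
            return self._gate("NOT", self.factor())
        if tok == "YES":
            return self._gate("YES", self.factor())
        if tok == "(":
            node = self.expr()
            close, cpos = self._next()
            if close != ")":
                raise ValueError(f"syntax error at position {cpos}: expected ')'")
            return node
        if tok == ")":
            raise ValueError(f"syntax error at position {pos}: unexpected ')'")
        return tok  # marker name


def parse_expression(text: str) -> LogicCircuit:
    """Parse a Boolean expression over marker names into a LogicCircuit.

    Grammar: marker names, parentheses, and the operators OR, AND,
    AND-NOT (binary, left-associative; AND binds tighter than OR) and
    NOT, YES (unary). A bare marker becomes a single YES gate.

    >>> c = parse_expression("(KRT19 OR VIM) AND-NOT PTPRC")
    >>> sorted(c.inputs)
    ['KRT19', 'PTPRC', 'VIM']
    """
    p = _Parser(text)
    root = p.expr()
    if p.i < len(p.tokens):
        tok, pos = p.tokens[p.i]
        raise ValueError(f"syntax error at position {pos}: unexpected {tok!r}")
    if not p.gates or root not in {g.label for g in p.gates}:
        root = p._gate("YES", root)
    return LogicCircuit(p.gates, outputs=[root])
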