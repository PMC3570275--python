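"""Synchronous Boolean network dynamics and exhaustive attractor analysis.

Two update semantics are supported:

* **logic mode** — each node carries a Boolean expression over the current
  state (NOT/AND/OR), all nodes updated simultaneously;
* **threshold mode** — each node carries a signed regulator list and turns
  on iff the signed sum of its regulators' current states is >= 1
  (activation +1, inhibition -1; the threshold is sharp).  A node with no
  regulators holds its state, unless flagged self-degrading, in which case
  it decays to 0.

Clamped nodes (mutant analysis) keep their clamp value regardless of rules.

States are integers whose binary rendering, zero-padded to N digits, lists
node 1 leftmost; the string "0100010100" therefore reads node1=0, node2=1, …
State-string lexicographic order coincides with numeric order, which the
canonical attractor representation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import (
    ConfigurationError,
    ModeError,
    ResourceLimitError,
    RuleStructureError,
)
from .rules import Ast, evaluate, literal_occurrences, parse_statements, regulator_set

#: Default ceiling on N for full state-space enumeration (2^20 ~ 1M states).
DEFAULT_ENUMERATION_CAP = 20

LOGIC = "logic"
THRESHOLD = "threshold"


def state_to_string(state: int, n: int) -> str:
    """Render a state integer as the node1-leftmost binary string."""
    return format(state, f"0{n}b")


def string_to_state(s: str) -> int:
    if not s or any(c not in "01" for c in s):
        raise ConfigurationError(f"state string must be non-empty binary, got {s!r}")
    return int(s, 2)


def state_to_bits(state: int, n: int) -> list[int]:
    """Bit list [S_1, ..., S_N]."""
    return [(state >> (n - j)) & 1 for j in range(1, n + 1)]


def bits_to_state(bits: list[int]) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | (b & 1)
    return out


@dataclass
class BooleanNetwork:
    """A Boolean network in logic or threshold mode.

    ``rules`` maps node index (1-based) to an expression AST; ``regulators``
    maps node index to a list of (regulator index, sign) with sign in
    {+1, -1}.  Exactly one of the two must be provided.
    """

    n: int
    rules: dict[int, Ast] | None = None
    regulators: dict[int, list[tuple[int, int]]] | None = None
    labels: list[str] | None = None
    self_degrading: frozenset[int] = frozenset()
    clamps: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.rules is None) == (self.regulators is None):
            raise ConfigurationError("provide exactly one of rules / regulators")
        if self.n < 1:
            raise ConfigurationError("network needs at least one node")
        if self.labels is not None and len(self.labels) != self.n:
            raise ConfigurationError("labels length must equal node count")
        for idx in self.self_degrading | set(self.clamps):
            if not 1 <= idx <= self.n:
                raise ConfigurationError(f"node index {idx} out of range 1..{self.n}")
        overlap = self.self_degrading & set(self.clamps)
        if overlap:
            raise ConfigurationError(
                f"nodes cannot be both clamped and self-degrading: {sorted(overlap)}"
            )
        if self.rules is not None:
            if set(self.rules) != set(range(1, self.n + 1)):
                raise RuleStructureError("logic mode requires a rule for every node 1..N")
        else:
            for i, regs in self.regulators.items():
                if not 1 <= i <= self.n:
                    raise RuleStructureError(f"regulator target {i} out of range")
                for j, sign in regs:
                    if not 1 <= j <= self.n:
                        raise RuleStructureError(f"regulator index {j} out of range")
                    if sign not in (1, -1):
                        raise RuleStructureError(f"sign must be +1/-1, got {sign}")

    @property
    def mode(self) -> str:
        return LOGIC if self.rules is not None else THRESHOLD

    @property
    def edge_count(self) -> int:
        """Literal occurrences (logic) or regulator entries (threshold).

        Counts describe the parsed rule set; clamps do not alter them.
        """
        if self.rules is not None:
            return sum(len(literal_occurrences(a)) for a in self.rules.values())
        return sum(len(regs) for regs in self.regulators.values())

    def regulator_sets(self) -> dict[int, set[int]]:
        """Distinct regulators per node."""
        if self.rules is not None:
            return {i: regulator_set(a) for i, a in self.rules.items()}
        return {i: {j for j, _ in regs} for i, regs in self.regulators.items()}

    def label_of(self, i: int) -> str:
        if self.labels is not None:
            return self.labels[i - 1]
        return f"node{i}"


def parse_rules(text: str, labels: list[str] | None = None) -> BooleanNetwork:
    """Parse ``$node[i] = expr;`` statements into a logic-mode network."""
    rules = parse_statements(text)
    return BooleanNetwork(n=len(rules), rules=rules, labels=labels)


def step_logic(net: BooleanNetwork, state: int) -> int:
    """One synchronous update in logic mode."""
    if net.mode != LOGIC:
        raise ModeError("step_logic requires a logic-mode network")
    bits = state_to_bits(state, net.n)
    nxt = []
    for i in range(1, net.n + 1):
        if i in net.clamps:
            nxt.append(net.clamps[i])
        else:
            nxt.append(evaluate(net.rules[i], bits))
    return bits_to_state(nxt)


def step_threshold(net: BooleanNetwork, state: int) -> int:
    """One synchronous update by the signed-sum threshold rule."""
    if net.mode != THRESHOLD:
        raise ModeError("step_threshold requires a threshold-mode network")
    bits = state_to_bits(state, net.n)
    nxt = []
    for i in range(1, net.n + 1):
        if i in net.clamps:
            nxt.append(net.clamps[i])
            continue
        regs = net.regulators.get(i, [])
        if not regs:
            nxt.append(0 if i in net.self_degrading else bits[i - 1])
            continue
        total = sum(sign * bits[j - 1] for j, sign in regs)
        nxt.append(1 if total >= 1 else 0)
    return bits_to_state(nxt)


def step(net: BooleanNetwork, state: int) -> int:
    return step_logic(net, state) if net.mode == LOGIC else step_threshold(net, state)


@dataclass
class StateTransitionMap:
    """The total synchronous successor function over all 2^N states."""

    n: int
    successors: list[int]

    def __post_init__(self) -> None:
        if len(self.successors) != 1 << self.n:
            raise ConfigurationError("successor table must cover exactly 2^N states")

    def successor(self, state: int) -> int:
        return self.successors[state]

    @property
    def n_states(self) -> int:
        return 1 << self.n


def enumerate_state_space(
    net: BooleanNetwork,
    mode: str | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> StateTransitionMap:
    """Compute the successor of every one of the 2^N states.

    ``mode`` defaults to the network's own mode and must match it.  Networks
    larger than ``cap`` nodes are refused to guard the 2^N blow-up.
    """
    if mode is not None and mode != net.mode:
        raise ModeError(f"network is {net.mode}-mode; cannot enumerate as {mode}")
    if net.n > cap:
        raise ResourceLimitError(
            f"N={net.n} exceeds the enumeration cap of {cap} nodes "
            f"({1 << net.n} states); raise the cap explicitly to proceed"
        )
    fn = step_logic if net.mode == LOGIC else step_threshold
    return StateTransitionMap(net.n, [fn(net, s) for s in range(1 << net.n)])


@dataclass(frozen=True)
class Attractor:
    """A cycle of the successor function with its basin size.

    ``states`` is the canonical rotation: it starts at the numerically (and
    therefore lexicographically, at fixed width) smallest state.
    """

    states: tuple[int, ...]
    basin_size: int

    @property
    def kind(self) -> str:
        return "singleton" if len(self.states) == 1 else "cyclic"

    @property
    def period(self) -> int:
        return len(self.states)

    def state_strings(self, n: int) -> list[str]:
        return [state_to_string(s, n) for s in self.states]


@dataclass
class AttractorSet:
    n: int
    attractors: list[Attractor]

    @property
    def singletons(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "singleton"]

    @property
    def cycles(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "cyclic"]


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    pivot = cycle.index(min(cycle))
    return tuple(cycle[pivot:] + cycle[:pivot])


def find_attractors(stm: StateTransitionMap) -> AttractorSet:
    """All cycles of the successor function, with basin sizes.

    Iterative orbit-following with path compression onto attractor ids;
    basins (which include the cycle's own states) partition the 2^N states.
    """
    UNSEEN, ON_STACK = -1, -2
    assignment = [UNSEEN] * stm.n_states  # state -> attractor index
    cycles: list[tuple[int, ...]] = []
    basins: list[int] = []
    for start in range(stm.n_states):
        if assignment[start] != UNSEEN:
            continue
        path = []
        s = start
        while assignment[s] == UNSEEN:
            assignment[s] = ON_STACK
            path.append(s)
            s = stm.successors[s]
        if assignment[s] == ON_STACK:
            # new cycle discovered within this path
            cut = path.index(s)
            cycle = path[cut:]
            cycles.append(_canonical_cycle(cycle))
            basins.append(0)
            aidx = len(cycles) - 1
        else:
            aidx = assignment[s]
        for q in path:
            assignment[q] = aidx
        basins[aidx] += len(path)
    attractors = [Attractor(states=c, basin_size=b) for c, b in zip(cycles, basins)]
    attractors.sort(key=lambda a: a.states[0])
    return AttractorSet(n=stm.n, attractors=attractors)


def analyze(net: BooleanNetwork, cap: int = DEFAULT_ENUMERATION_CAP) -> tuple[StateTransitionMap, AttractorSet]:
    """Convenience: enumerate the state space and find its attractors."""
    stm = enumerate_state_space(net, cap=cap)
    return stm, find_attractors(stm)


def apply_perturbation(net: BooleanNetwork, clamps: dict[int, int]) -> BooleanNetwork:
    """Return a copy of ``net`` with additional clamps (mutant network).

    Re-clamping a node to a different value is an error; the input network
    is left untouched.
    """
    merged = dict(net.clamps)
    for idx, value in clamps.items():
        if not 1 <= idx <= net.n:
            raise ConfigurationError(f"clamp index {idx} out of range 1..{net.n}")
        if value not in (0, 1):
            raise ConfigurationError(f"clamp value must be 0 or 1, got {value}")
        if idx in merged and merged[idx] != value:
            raise ConfigurationError(
                f"node {idx} already clamped to {merged[idx]}; cannot re-clamp to {value}"
            )
        merged[idx] = value
    self_deg = net.self_degrading - set(merged)
    return replace(net, clamps=merged, self_degrading=self_deg)


@dataclass
class Trajectory:
    """A synchronous run from a start state.

    ``states`` lists the visited states in order.  If the run entered an
    attractor within the step budget, ``attractor_entry`` is the index in
    ``states`` where the periodic suffix begins and ``period`` its length;
    otherwise both are None (reported, not raised).
    """

    n: int
    states: list[int]
    attractor_entry: int | None
    period: int | None

    @property
    def converged(self) -> bool:
        return self.attractor_entry is not None

    def state_strings(self) -> list[str]:
        return [state_to_string(s, self.n) for s in self.states]


def trajectory(net: BooleanNetwork, start: int, max_steps: int = 1 << 12) -> Trajectory:
    """Follow the synchronous orbit until a state repeats or the budget ends."""
    if max_steps < 1:
        raise ConfigurationError("max_steps must be >= 1")
    seen: dict[int, int] = {}
    states: list[int] = []
    s = start
    for _ in range(max_steps + 1):
        if s in seen:
            entry = seen[s]
            return Trajectory(net.n, states, entry, len(states) - entry)
        seen[s] = len(states)
        states.append(s)
        if len(states) > max_steps:
            break
        s = step(net, s)
    return Trajectory(net.n, states, None, None)


# ---------------------------------------------------------------------------
# text output


def write_transitions(stm: StateTransitionMap, attractors: AttractorSet, path) -> None:
    """Write the full transition table then attractor blocks.

    One ``state<TAB>successor`` line per state in lexicographic order — a
    Cytoscape-loadable edge list — followed by ``#``-prefixed attractor
    blocks (kind, basin size, member states in cycle order).
    """
    from pathlib import Path

    n = stm.n
    lines = [
        f"{state_to_string(s, n)}\t{state_to_string(stm.successors[s], n)}"
        for s in range(stm.n_states)
    ]
    for i, a in enumerate(attractors.attractors, start=1):
        lines.append(f"# attractor {i}\tkind={a.kind}\tperiod={a.period}\tbasin={a.basin_size}")
        for s in a.states:
            lines.append(f"# {state_to_string(s, n)}")
    Path(path).write_text("".join(x + "\n" for x in lines), encoding="utf-8")


def read_transitions(path) -> StateTransitionMap:
    """Re-parse a transition file written by :func:`write_transitions`."""
    from pathlib import Path

    pairs: dict[int, int] = {}
    n = None
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        a, b = raw.split("\t")
        if n is None:
            n = len(a)
        pairs[string_to_state(a)] = string_to_state(b)
    if n is None:
        raise ConfigurationError("transition file contains no transitions")
    return StateTransitionMap(n, [pairs[s] for s in range(1 << n)])
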