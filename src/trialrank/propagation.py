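"""Single-generation value propagation with aging refresh.

A newly published comparison changes the values of its two regimens.  In a
purely pairwise network this penalizes heavily studied standards: every new
challenger that beats the standard drags it down, even though the standard
earned its place by beating the previous generation (the straw-man effect).

Propagation counters this: when a node loses value because of newly
introduced evidence, part of that loss is passed one generation back, to
the regimens the node had previously beaten — restoring some value to the
node itself.  Symmetrically, a node that gains value passes part of the
gain to regimens it had previously lost to.  Each prior edge through which
value is passed is also *refreshed*: its effective age is reduced by one
half-life (doubling its aging coefficient, capped at 1), restoring some
relevance to the older comparison, like decreasing impedance in a circuit.

Propagation is strictly single-generation: no transitive closure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .config import AlgorithmConfig, PropagationConfig, SplitRule
from .trials import TrialComparison, ValidationError
from .valuation import EdgeContribution, NetworkState, evaluate_network

__all__ = [
    "Direction",
    "PropagationEvent",
    "PropagationRecord",
    "find_propagation_targets",
    "refresh_edge",
    "propagate_event",
    "evaluate_with_propagation",
]


class Direction(enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


@dataclass(frozen=True)
class PropagationEvent:
    """A value delta at a node caused by evidence newly introduced in a year.

    All new edges incident to ``node`` in ``year`` are aggregated into one
    event; ``source_trials`` lists their trial ids.
    """

    node: str
    delta: float
    year: int
    source_trials: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValidationError("propagation event requires a nonzero delta")

    @property
    def direction(self) -> Direction:
        return Direction.LOSS if self.delta < 0 else Direction.GAIN


@dataclass(frozen=True)
class PropagationRecord:
    """Audit entry: what one event transferred and which edges it refreshed."""

    event: PropagationEvent
    transfers: tuple[tuple[str, float], ...]  # (target regimen, amount)
    refreshed_trials: tuple[str, ...]


def find_propagation_targets(
    node: str,
    event_year: int,
    edges: Sequence[EdgeContribution],
    direction: Direction,
) -> list[tuple[str, EdgeContribution]]:
    """Find the one-generation-back recipients of a value delta at ``node``.

    LOSS: losers of strictly earlier edges in which ``node`` was the winner.
    GAIN: winners of strictly earlier edges in which ``node`` was the loser.
    An edge published in the event year itself does not qualify —
    "previously" means strictly earlier.
    """
    targets = []
    for edge in edges:
        if edge.year >= event_year or edge.winner is None:
            continue
        if direction is Direction.LOSS and edge.winner == node:
            targets.append((edge.loser, edge))
        elif direction is Direction.GAIN and edge.loser == node:
            targets.append((edge.winner, edge))
    return targets


def refresh_edge(edge: EdgeContribution, half_life: float) -> EdgeContribution:
    """Reduce an edge's effective age by one half-life and revalue it.

    The aging coefficient at most doubles and is capped at 1 (age floors
    at 0); the contribution magnitude is recomputed with the new aging.
    """
    new_age = max(edge.effective_age - half_life, 0.0)
    if new_age == edge.effective_age:
        return edge
    new_aging = 2.0 ** (-new_age / half_life)
    if edge.winner is None:
        new_mag = 0.0
    else:
        new_mag = edge.sig_weight * edge.rv * edge.e_magnitude * edge.log_n * new_aging
    return replace(edge, effective_age=new_age, aging=new_aging, magnitude=new_mag)


def _split(
    delta_transferred: float,
    targets: Sequence[tuple[str, EdgeContribution]],
    rule: SplitRule,
) -> list[tuple[str, float]]:
    if rule is SplitRule.EQUAL:
        share = delta_transferred / len(targets)
        return [(t, share) for t, _ in targets]
    weights = [abs(e.magnitude) for _, e in targets]
    total = sum(weights)
    if total == 0:  # all qualifying edges are draws-by-refresh; fall back
        return _split(delta_transferred, targets, SplitRule.EQUAL)
    return [(t, delta_transferred * w / total) for (t, _), w in zip(targets, weights)]


def propagate_event(
    state: NetworkState,
    event: PropagationEvent,
    targets: Sequence[tuple[str, EdgeContribution]],
    config: PropagationConfig,
    half_life: float = 10.0,
) -> tuple[NetworkState, PropagationRecord]:
    """Apply one propagation event and return the updated state.

    A total of ``fraction * delta`` is transferred, divided among the
    targets by the split rule; the event node's own change shrinks by the
    transferred amount.  With refresh enabled, every qualifying prior edge
    has its effective age reduced by one half-life and its contribution
    revalued in place.  Transfers are zero-sum, and a refreshed edge still
    contributes +c/-c, so the network total is conserved.
    """
    record = PropagationRecord(event=event, transfers=(), refreshed_trials=())
    if not targets:
        return state, record

    adjustments = dict(state.adjustments)
    transfers: list[tuple[str, float]] = []
    if config.fraction > 0:
        transferred = config.fraction * event.delta
        transfers = _split(transferred, targets, config.split_rule)
        adjustments[event.node] = adjustments.get(event.node, 0.0) - transferred
        for target, share in transfers:
            adjustments[target] = adjustments.get(target, 0.0) + share

    edges = list(state.edges)
    refreshed: list[str] = []
    if config.refresh_enabled:
        qualifying = {id(e) for _, e in targets}
        for i, edge in enumerate(edges):
            if id(edge) in qualifying:
                new_edge = refresh_edge(edge, half_life)
                if new_edge is not edge:
                    edges[i] = new_edge
                    refreshed.append(edge.trial_id)

    new_state = state.with_edges(edges).with_adjustments(adjustments)
    record = PropagationRecord(
        event=event,
        transfers=tuple(transfers),
        refreshed_trials=tuple(refreshed),
    )
    return new_state, record


def evaluate_with_propagation(
    trials: Iterable[TrialComparison],
    eval_year: int,
    config: AlgorithmConfig | None = None,
    collect_trace: bool = False,
) -> NetworkState | tuple[NetworkState, list[PropagationRecord]]:
    """Valuation with propagation and refresh replayed over the timeline.

    Publication years are replayed in ascending order.  At each year, every
    node's value delta attributable to that year's new edges (valued as of
    ``eval_year``) becomes a :class:`PropagationEvent`; events within a
    year are processed in node-id order for determinism.  With fraction 0
    and refresh disabled this reduces exactly to
    :func:`trialrank.valuation.evaluate_network`.
    """
    config = config or AlgorithmConfig()
    state = evaluate_network(trials, eval_year, config)
    prop = config.propagation
    trace: list[PropagationRecord] = []

    if prop.fraction == 0 and not prop.refresh_enabled:
        return (state, trace) if collect_trace else state

    years = sorted({e.year for e in state.edges})
    for year in years:
        new_edges = [e for e in state.edges if e.year == year]
        deltas: dict[str, float] = {}
        sources: dict[str, list[str]] = {}
        for e in new_edges:
            if e.winner is None:
                continue
            for node, signed in ((e.winner, e.magnitude), (e.loser, -e.magnitude)):
                deltas[node] = deltas.get(node, 0.0) + signed
                sources.setdefault(node, []).append(e.trial_id)
        for node in sorted(deltas):
            delta = deltas[node]
            if delta == 0:
                continue
            event = PropagationEvent(
                node=node,
                delta=delta,
                year=year,
                source_trials=tuple(sorted(sources[node])),
            )
            targets = find_propagation_targets(
                node, year, state.edges, event.direction
            )
            state, record = propagate_event(
                state, event, targets, prop, half_life=config.half_life_years
            )
            if targets:
                trace.append(record)

    return (state, trace) if collect_trace else state
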