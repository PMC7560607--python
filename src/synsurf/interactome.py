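"""Extracellular interactome screen calling.

Implements the plate-ELISA hit caller for an AP-bait x Fc-prey ectodomain
screen: plate background is the mean of >=30 blank wells; a well's statistic
is its fold over background (FOB = OD650 / background); a well is positive
when FOB strictly exceeds the threshold (default 5) and its prey is not
promiscuous. Promiscuous ("sticky") preys — those whose signal exceeds the
threshold against every bait, or against the AP-only negative-control bait —
are rejected outright for that experiment. Positive wells from independent
experiments and both tag orientations are merged per unordered construct
pair, a pair being accepted when it accumulates at least ``min_detections``
events (default 2) regardless of orientation mix. Accepted pairs form an
interaction network whose modules are the connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import ScreenExperiment, CONTROL_BAIT, BLANK_LABEL

MIN_BLANKS = 30

__all__ = [
    "FobMatrix", "InteractionCall", "InteractionNetwork",
    "estimate_background", "compute_fob", "call_positives",
    "merge_experiments", "build_network", "annotate_novelty",
    "read_screen_tsv", "calls_to_frame", "run_screen",
]


def estimate_background(experiment: ScreenExperiment) -> float:
    """Plate background: arithmetic mean of the blank wells (>=30 required)."""
    blanks = np.asarray(experiment.blank_values, dtype=float)
    if blanks.size < MIN_BLANKS:
        raise ValueError(
            f"background estimation requires at least {MIN_BLANKS} blank wells "
            f"(got {blanks.size})")
    return float(blanks.mean())


@dataclass
class FobMatrix:
    """Fold-over-background matrix for one experiment."""

    experiment_id: str
    fob: pd.DataFrame            # prey rows x bait columns, control included
    background: float
    control_bait: str = CONTROL_BAIT


def compute_fob(experiment: ScreenExperiment, background: float) -> FobMatrix:
    """Elementwise OD650 / background."""
    if background <= 0:
        raise ValueError("background must be positive")
    return FobMatrix(experiment_id=experiment.experiment_id,
                     fob=experiment.od / background,
                     background=background,
                     control_bait=experiment.control_bait)


def call_positives(fob: FobMatrix, threshold: float = 5.0,
                   sticky_fraction: float = 1.0,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Positive-well calls for one experiment, with promiscuity rejection.

    A well is positive iff FOB > threshold (strictly) and its prey row is
    not flagged. A prey is flagged when it exceeds the threshold in at least
    ``sticky_fraction`` of all bait columns including the control (default
    1.0 — literally "present in every bait"), or when it exceeds the
    threshold against the AP-only control bait. Control-column wells never
    become pair calls.

    Returns ``(calls, flagged_preys)`` where ``calls`` is a boolean
    prey x bait DataFrame over the non-control baits.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not (0.0 < sticky_fraction <= 1.0):
        raise ValueError("sticky_fraction must lie in (0, 1]")

    above = fob.fob > threshold
    frac_above = above.mean(axis=1)  # over all baits incl. control
    flagged = frac_above >= sticky_fraction
    flagged |= above[fob.control_bait]
    flagged_preys = sorted(flagged.index[flagged])

    bait_cols = [c for c in fob.fob.columns if c != fob.control_bait]
    calls = above[bait_cols].copy()
    calls.loc[flagged, :] = False
    return calls, flagged_preys


@dataclass
class InteractionCall:
    """One unordered construct pair with its detection events.

    Events are unique (experiment_id, orientation) tuples; orientation is
    the string "AP-<bait>/Fc-<prey>". A heterophilic pair can accumulate up
    to 2 x n_experiments events, a homophilic (self) pair up to
    n_experiments.
    """

    pair: tuple[str, str]
    detections: set = field(default_factory=set)
    min_detections: int = 2

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def accepted(self) -> bool:
        return self.n_detections >= self.min_detections


def merge_experiments(call_sets: dict[str, pd.DataFrame],
                      min_detections: int = 2) -> list[InteractionCall]:
    """Merge per-experiment positive wells into unordered pair calls.

    ``call_sets`` maps experiment_id -> boolean prey x bait call matrix (as
    produced by :func:`call_positives`). Each positive well (bait X, prey Y)
    contributes one (experiment, orientation) event to pair {X, Y}; a pair
    is accepted when its event count reaches ``min_detections``, regardless
    of which orientations or experiments the events came from. Output is
    sorted lexicographically by pair.
    """
    universe: set[frozenset] = set()
    reference_constructs: set[str] | None = None
    events: dict[tuple[str, str], set] = {}

    for exp_id, calls in call_sets.items():
        constructs = set(calls.columns) | set(calls.index)
        if reference_constructs is None:
            reference_constructs = constructs
        elif constructs != reference_constructs:
            raise ValueError(
                f"experiment {exp_id!r} has an inconsistent construct set")
        rows, cols = np.nonzero(calls.to_numpy())
        for i, j in zip(rows, cols):
            prey = calls.index[i]
            bait = calls.columns[j]
            key = tuple(sorted((bait, prey)))
            events.setdefault(key, set()).add((exp_id, f"AP-{bait}/Fc-{prey}"))

    return [InteractionCall(pair=pair, detections=evts,
                            min_detections=min_detections)
            for pair, evts in sorted(events.items())]


@dataclass
class InteractionNetwork:
    """Accepted pairs as an undirected graph with connected-component modules."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def modules(self) -> list[list[str]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)
                 if self.graph.subgraph(c).number_of_edges() >= 1]
        return sorted(comps)


def build_network(calls: list[InteractionCall]) -> InteractionNetwork:
    """Graph of accepted pairs only; self-pairs become self-loop edges."""
    g = nx.Graph()
    for call in calls:
        if call.accepted:
            a, b = call.pair
            g.add_edge(a, b, n_detections=call.n_detections)
    return InteractionNetwork(graph=g)


def annotate_novelty(network: InteractionNetwork,
                     known_pairs) -> dict[tuple[str, str], bool]:
    """Flag each edge novel iff absent from the (unordered) known-pair list."""
    known = {frozenset(p) for p in known_pairs}
    return {edge: frozenset(edge) not in known for edge in network.edges}


# --- IO and the end-to-end caller -------------------------------------------

def read_screen_tsv(path) -> ScreenExperiment:
    """Read one experiment from long-format TSV.

    Columns: ``experiment_id, bait, prey, od650``; blank wells use
    bait = prey = "BLANK"; the control column uses bait = "AP-only".
    """
    df = pd.read_csv(path, sep="\t")
    required = {"experiment_id", "bait", "prey", "od650"}
    if not required.issubset(df.columns):
        raise ValueError(f"screen TSV must have columns {sorted(required)}")
    exp_ids = df["experiment_id"].unique()
    if len(exp_ids) != 1:
        raise ValueError("one screen TSV must hold exactly one experiment")
    blanks = df[(df["bait"] == BLANK_LABEL) & (df["prey"] == BLANK_LABEL)]
    wells = df.drop(blanks.index)
    od = wells.pivot(index="prey", columns="bait", values="od650")
    if od.isna().any().any():
        raise ValueError("screen TSV does not form a complete prey x bait matrix")
    preys = sorted(od.index)
    baits = sorted(c for c in od.columns if c != CONTROL_BAIT)
    od = od.loc[preys, baits + [CONTROL_BAIT]]
    return ScreenExperiment(experiment_id=str(exp_ids[0]), od=od,
                            blank_values=blanks["od650"].to_numpy())


def calls_to_frame(calls: list[InteractionCall],
                   novelty: dict[tuple[str, str], bool] | None = None,
                   ) -> pd.DataFrame:
    rows = []
    for call in calls:
        a, b = call.pair
        rows.append({
            "construct_a": a,
            "construct_b": b,
            "n_detections": call.n_detections,
            "orientations": ";".join(sorted({o for _, o in call.detections})),
            "experiments": ";".join(sorted({e for e, _ in call.detections})),
            "accepted": call.accepted,
            "novel": (novelty or {}).get((a, b), None) if call.accepted else None,
        })
    return pd.DataFrame(rows, columns=["construct_a", "construct_b",
                                       "n_detections", "orientations",
                                       "experiments", "accepted", "novel"])


def run_screen(experiments: list[ScreenExperiment],
               fob_threshold: float = 5.0,
               min_detections: int = 2,
               sticky_fraction: float = 1.0,
               known_pairs=(),
               ) -> tuple[list[InteractionCall], InteractionNetwork,
                          dict[tuple[str, str], bool]]:
    """Background -> FOB -> positive calls -> merge -> network -> novelty."""
    call_sets = {}
    for exp in experiments:
        bg = estimate_background(exp)
        fob = compute_fob(exp, bg)
        calls, _ = call_positives(fob, threshold=fob_threshold,
                                  sticky_fraction=sticky_fraction)
        call_sets[exp.experiment_id] = calls
    merged = merge_experiments(call_sets, min_detections=min_detections)
    network = build_network(merged)
    novelty = annotate_novelty(network, known_pairs)
    return merged, network, novelty
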