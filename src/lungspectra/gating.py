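"""Hierarchical gating: the lung immune-cell gate tree as a declarative,
testable classifier over unmixed marker abundances and scatter.

The tree mirrors the standard murine-lung manual gating strategy: debris
exclusion (FSC-A), singlets (FSC-H/FSC-A ratio), live cells (viability
dye negative), CD45+ leukocytes, then a myeloid branch (Ly6G+ neutrophils;
monocytes split into Ly6C+ inflammatory and CD11c+ resident; CD64+
macrophages split into CD11c+ alveolar and CD11b+ interstitial; CD64−CD24+
eosinophils and dendritic cells, the latter split into CD103+ cDC1 and
CD11b+ cDC2; CD64−CD24− CD11c+Ly6C+ pDCs) and a lymphoid branch (CD19+ B
cells; CD3+ T cells split into CD8+ cytotoxic, CD4+ helper and
CD4+CD25+CD127low regulatory T cells with CD44/CD62L memory sub-states;
CD3−CD19− NK/ILC gates on CD335 and CD127, with mature-NK and ILC2/ILC3
sub-gates).  17 terminal target populations in total.

Numeric gate thresholds are never hard-coded: each threshold reference is
derived from truth-labeled (or FMO-style) reference data, as the midpoint —
in inverse-hyperbolic-sine (asinh) transformed space — between the upper
quantile of the designated negative populations and the mode of the
designated positives.  Events descend the tree taking the first matching
child (children are ordered); the reported label is the deepest terminal
target population on the path, and events failing every child predicate at
a branch are labeled ``"<node>/unassigned"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .simulate import (
    DEAD_LABEL,
    PanelConfig,
    PopulationProfile,
    default_lung_profiles,
)
from .unmix import UnmixResult

__all__ = [
    "GateNode",
    "GateTree",
    "build_lung_gate_tree",
    "derive_thresholds",
    "apply_gates",
    "evaluate_recovery",
    "marker_frame",
    "GateTreeClassifier",
    "RecoveryReport",
]

#: Threshold-kind → (negative levels, positive levels) for auto-derivation.
_KIND_LEVELS = {
    "pos": ({"neg"}, {"pos", "hi"}),
    "lowpos": ({"neg", "low"}, {"pos", "hi"}),
    "neglow": ({"neg"}, {"low", "pos", "hi"}),
    "hi": ({"neg", "low", "pos"}, {"hi"}),
}


@dataclass(frozen=True)
class GateNode:
    """One gate: a conjunction of threshold terms plus optional labels.

    ``terms`` are (channel, direction, threshold_ref) with direction in
    {">", "<"}; an empty conjunction always matches (catch-all child).
    ``population`` marks a terminal target population; ``substate`` marks a
    documented sub-state (memory T subsets, mature NK, CD206/CX3CR1
    confirmation) that does not change the population label.
    """

    name: str
    parent: str | None
    terms: tuple[tuple[str, str, str], ...] = ()
    population: str | None = None
    substate: str | None = None


@dataclass
class GateTree:
    """Rooted gate hierarchy with named, resolvable thresholds."""

    nodes: dict[str, GateNode]
    threshold_specs: dict[str, dict]
    thresholds: dict[str, float] = field(default_factory=dict)
    version: str = "lung-v1"

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError("gate tree must have exactly one root")
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(f"node {node.name!r} has unknown parent {node.parent!r}")
        pops = [n.population for n in self.nodes.values() if n.population]
        if len(set(pops)) != len(pops):
            raise ValueError("terminal populations must be unique")
        # cycle check: every node must reach the root
        for node in self.nodes.values():
            seen = set()
            cur = node
            while cur.parent is not None:
                if cur.name in seen:
                    raise ValueError("gate tree contains a cycle")
                seen.add(cur.name)
                cur = self.nodes[cur.parent]

    @property
    def root(self) -> GateNode:
        return next(n for n in self.nodes.values() if n.parent is None)

    def children(self, name: str) -> list[GateNode]:
        return [n for n in self.nodes.values() if n.parent == name]

    @property
    def target_populations(self) -> tuple[str, ...]:
        return tuple(n.population for n in self.nodes.values() if n.population)

    def referenced_markers(self, exclude: Sequence[str] = ()) -> tuple[str, ...]:
        """Distinct non-scatter channels referenced by any predicate."""
        scatter = {"FSC-A", "SSC-A", "FSC-H", "FSC_ratio"}
        markers = {
            ch
            for node in self.nodes.values()
            for ch, _, _ in node.terms
            if ch not in scatter
        }
        return tuple(sorted(markers - set(exclude)))

    def path_to(self, population: str) -> list[str]:
        node = next(n for n in self.nodes.values() if n.population == population)
        path = [node.name]
        while node.parent is not None:
            node = self.nodes[node.parent]
            path.append(node.name)
        return list(reversed(path))


def _t(channel: str, direction: str, kind: str | None = None, ref: str | None = None):
    return (channel, direction, ref or f"{channel}:{kind}")


def build_lung_gate_tree() -> GateTree:
    """The full lung immune gating hierarchy (17 target populations)."""
    N = GateNode
    nodes = [
        N("All events", None),
        N("Non-debris", "All events", ( _t("FSC-A", ">", ref="FSC-A:debris"), )),
        N("Singlets", "Non-debris", ( _t("FSC_ratio", ">", ref="FSC_ratio:singlet"), )),
        N("Live", "Singlets", ( _t("Viability", "<", "pos"), )),
        N("CD45+", "Live", ( _t("CD45", ">", "pos"), )),
        # myeloid / lymphoid split; children are tried in order
        N("Neutrophils", "CD45+", ( _t("Ly6G", ">", "pos"), ), population="Neutrophil"),
        N(
            "Lymphoid",
            "CD45+",
            ( _t("CD11b", "<", "lowpos"), _t("CD11c", "<", "pos"), ),
        ),
        N("Intermediary 1", "CD45+"),  # catch-all: CD11b+ and/or CD11c+ myeloid
        # --- myeloid branch ---
        N(
            "Monocytes",
            "Intermediary 1",
            (
                ("SSC-A", "<", "SSC-A:int1-median"),
                _t("CD64", "<", "pos"),
                _t("CD24", "<", "pos"),
                _t("MHCII", "<", "pos"),
            ),
        ),
        N(
            "Inflammatory monocytes",
            "Monocytes",
            ( _t("Ly6C", ">", "pos"), ),
            population="Monocyte (inflammatory)",
        ),
        N(
            "Resident monocytes",
            "Monocytes",
            ( _t("CD11c", ">", "pos"), ),
            population="Monocyte (resident)",
        ),
        N("Intermediary 2", "Intermediary 1"),
        N("Macrophages", "Intermediary 2", ( _t("CD64", ">", "pos"), )),
        N(
            "Alveolar macrophages",
            "Macrophages",
            ( _t("CD11c", ">", "pos"), ),
            population="Alveolar macrophage",
        ),
        N(
            "AMO CD206+ (confirmatory)",
            "Alveolar macrophages",
            ( _t("CD206", ">", "pos"), ),
            substate="CD206+",
        ),
        N(
            "Interstitial macrophages",
            "Macrophages",
            ( _t("CD11c", "<", "pos"), _t("CD11b", ">", "pos"), ),
            population="Interstitial macrophage",
        ),
        N(
            "IMO CX3CR1+ (confirmatory)",
            "Interstitial macrophages",
            ( _t("CX3CR1", ">", "pos"), ),
            substate="CX3CR1+",
        ),
        N("CD24+ gate", "Intermediary 2", ( _t("CD64", "<", "pos"), _t("CD24", ">", "pos"), )),
        N(
            "Eosinophils",
            "CD24+ gate",
            ( _t("CD11b", ">", "pos"), _t("MHCII", "<", "pos"), ),
            population="Eosinophil",
        ),
        N("Dendritic cells", "CD24+ gate", ( _t("MHCII", ">", "pos"), )),
        N(
            "cDC1",
            "Dendritic cells",
            ( _t("CD103", ">", "pos"), _t("CD11b", "<", "pos"), ),
            population="cDC1",
        ),
        N(
            "cDC2",
            "Dendritic cells",
            ( _t("CD11b", ">", "pos"), _t("CD103", "<", "pos"), ),
            population="cDC2",
        ),
        N("CD24- gate", "Intermediary 2", ( _t("CD64", "<", "pos"), _t("CD24", "<", "pos"), )),
        N(
            "pDC",
            "CD24- gate",
            ( _t("CD11c", ">", "pos"), _t("Ly6C", ">", "pos"), ),
            population="pDC",
        ),
        # --- lymphoid branch ---
        N("B cells", "Lymphoid", ( _t("CD19", ">", "pos"), _t("CD3", "<", "pos"), ),
          population="B cell"),
        N("T cells", "Lymphoid", ( _t("CD3", ">", "pos"), _t("CD19", "<", "pos"), )),
        N(
            "Cytotoxic T",
            "T cells",
            ( _t("CD8", ">", "pos"), _t("CD4", "<", "pos"), ),
            population="Cytotoxic T",
        ),
        N("CD8 T effector", "Cytotoxic T",
          ( _t("CD44", ">", "pos"), _t("CD62L", "<", "pos"), ), substate="T_EFF"),
        N("CD8 T central memory", "Cytotoxic T",
          ( _t("CD44", ">", "pos"), _t("CD62L", ">", "pos"), ), substate="T_CM"),
        N("CD8 T naive", "Cytotoxic T",
          ( _t("CD44", "<", "pos"), _t("CD62L", ">", "pos"), ), substate="T_N"),
        N(
            "T helper",
            "T cells",
            ( _t("CD4", ">", "pos"), _t("CD8", "<", "pos"), ),
            population="T helper",
        ),
        N(
            "Treg",
            "T helper",
            ( _t("CD25", ">", "pos"), _t("CD127", "<", "lowpos"), ),
            population="Treg",
        ),
        N("CD4 T effector", "T helper",
          ( _t("CD44", ">", "pos"), _t("CD62L", "<", "pos"), ), substate="T_EFF"),
        N("CD4 T central memory", "T helper",
          ( _t("CD44", ">", "pos"), _t("CD62L", ">", "pos"), ), substate="T_CM"),
        N("CD4 T naive", "T helper",
          ( _t("CD44", "<", "pos"), _t("CD62L", ">", "pos"), ), substate="T_N"),
        N("DN", "Lymphoid", ( _t("CD3", "<", "pos"), _t("CD19", "<", "pos"), )),
        N("CD335+", "DN", ( _t("CD335", ">", "pos"), )),
        N("ILC1", "CD335+", ( _t("CD127", ">", "pos"), ), population="ILC1"),
        N("NK cells", "CD335+", ( _t("CD127", "<", "pos"), ), population="NK"),
        N(
            "Mature NK",
            "NK cells",
            (
                _t("CD11b", ">", "neglow"),
                _t("KLRG1", ">", "pos"),
                _t("CD122", ">", "pos"),
            ),
            substate="mature NK",
        ),
        N("CD335-CD127+", "DN", ( _t("CD335", "<", "pos"), _t("CD127", ">", "pos"), )),
        N("ILC2", "CD335-CD127+", ( _t("CD25", ">", "pos"), ), population="ILC2"),
        N(
            "ILC3",
            "CD335-CD127+",
            ( _t("CD25", "<", "pos"), _t("KLRG1", "<", "pos"), ),
            population="ILC3",
        ),
    ]
    node_map = {n.name: n for n in nodes}
    specs: dict[str, dict] = {}
    for node in nodes:
        for channel, _, ref in node.terms:
            if ref in specs:
                continue
            if ref == "FSC-A:debris":
                specs[ref] = {"channel": "FSC-A", "kind": "debris"}
            elif ref == "FSC_ratio:singlet":
                specs[ref] = {"channel": "FSC_ratio", "kind": "singlet"}
            elif ref == "SSC-A:int1-median":
                specs[ref] = {
                    "channel": "SSC-A",
                    "kind": "dynamic-median",
                    "scope": "Intermediary 1",
                }
            elif ref == "Viability:pos":
                specs[ref] = {"channel": "Viability", "kind": "viability"}
            else:
                channel_name, kind = ref.rsplit(":", 1)
                specs[ref] = {"channel": channel_name, "kind": kind}
    return GateTree(nodes=node_map, threshold_specs=specs)


# --------------------------------------------------------------------------
# Threshold derivation
# --------------------------------------------------------------------------


def _asinh(x: np.ndarray, cofactor: float) -> np.ndarray:
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def _mode(values: np.ndarray, bins: int = 128) -> float:
    values = np.asarray(values, dtype=float)
    if np.ptp(values) < 1e-9:  # degenerate (e.g. noise-free) reference
        return float(np.median(values))
    counts, edges = np.histogram(values, bins=bins)
    j = int(np.argmax(counts))
    return 0.5 * (edges[j] + edges[j + 1])


_LEVEL_RANK = {"neg": 0, "low": 1, "pos": 2, "hi": 3}
#: Symbolic position of each threshold kind on the level scale.
_KIND_CUT = {"pos": 1.5, "lowpos": 1.5, "neglow": 0.5, "hi": 2.5}


def _effective_ssc(profile: PopulationProfile) -> float:
    from .simulate import SSC_AF_SLOPE

    return profile.scatter[2] + SSC_AF_SLOPE * sum(profile.af_weights.values())


def _symbolic_reach(
    tree: GateTree, profiles: Sequence[PopulationProfile]
) -> dict[str, set[str]]:
    """Populations expected to reach each gate, by expression level.

    Mirrors the event descent symbolically: a population passes a marker
    term iff its expression level lies on the right side of the threshold
    kind, passes scatter/viability housekeeping gates trivially (alive
    fraction), and the dynamic SSC-low term by comparing its effective
    SSC-A mean against the median over the populations at that gate.
    First-match child semantics apply, as for events.
    """
    by_name = {p.name: p for p in profiles}

    def passes(profile: PopulationProfile, term, siblings: set[str]) -> bool:
        channel, direction, ref = term
        spec = tree.threshold_specs[ref]
        kind = spec["kind"]
        if kind in ("debris", "singlet"):
            return True
        if kind == "viability":
            return direction == "<"  # the live fraction passes
        if kind == "dynamic-median":
            med = float(np.median([_effective_ssc(by_name[n]) for n in sorted(siblings)]))
            mine = _effective_ssc(profile)
            return mine < med if direction == "<" else mine > med
        rank = _LEVEL_RANK[profile.level_of(channel)]
        cut = _KIND_CUT[kind]
        return rank > cut if direction == ">" else rank < cut

    reach: dict[str, set[str]] = {}
    tested: dict[str, set[str]] = {}

    def descend(node: GateNode, pops: set[str]) -> None:
        reach[node.name] = pops
        remaining = set(pops)
        for child in tree.children(node.name):
            tested[child.name] = set(remaining)
            taken = {
                name
                for name in remaining
                if all(passes(by_name[name], t, remaining) for t in child.terms)
            }
            descend(child, taken)
            remaining -= taken

    descend(tree.root, {p.name for p in profiles})
    return tested


def derive_thresholds(
    tree: GateTree,
    reference: pd.DataFrame,
    labels: Sequence[str],
    profiles: Sequence[PopulationProfile] | None = None,
    cofactor: float = 50.0,
    neg_quantile: float = 0.995,
    singlet_cutoff: float = 0.75,
) -> tuple[dict[str, float], list[str]]:
    """Resolve every gate threshold from truth-labeled reference data.

    Each threshold is placed the way a manual gate is: on the population
    context that actually reaches the gates using it.  The negative and
    positive strata are the populations — among those symbolically reaching
    any gate that references the threshold — whose expression level for the
    channel is on either side of the cut (e.g. the neg-vs-pos cut uses
    neg-level populations against pos/hi ones); the threshold is the
    midpoint, in asinh space, between the negatives' upper quantile and the
    positives' mode, mapped back to data scale.  Channels with no negative
    stratum anywhere (CD45 in an all-leukocyte sample) fall back to two
    asinh decades below the positive mode.  Returns (thresholds, problems);
    unresolved channels are listed in ``problems``.
    """
    profiles = list(profiles) if profiles is not None else default_lung_profiles()
    by_name = {p.name: p for p in profiles}
    labels = np.asarray(labels, dtype=object)
    tested = _symbolic_reach(tree, profiles)
    context: dict[str, set[str]] = {}
    for node in tree.nodes.values():
        for _, _, ref in node.terms:
            context.setdefault(ref, set()).update(tested.get(node.name, set()))
    thresholds: dict[str, float] = {}
    problems: list[str] = []
    for ref, spec in tree.threshold_specs.items():
        channel, kind = spec["channel"], spec["kind"]
        if kind == "dynamic-median":
            continue  # resolved per-sample at gate application
        if kind == "singlet":
            thresholds[ref] = singlet_cutoff
            continue
        if kind == "debris":
            thresholds[ref] = 0.25 * float(np.quantile(reference["FSC-A"], 0.01))
            continue
        if channel not in reference.columns:
            problems.append(f"{ref}: channel {channel!r} missing from reference")
            continue
        values = reference[channel].to_numpy(dtype=float)
        if kind == "viability":
            neg_mask = labels != DEAD_LABEL
            pos_mask = labels == DEAD_LABEL
        else:
            neg_levels, pos_levels = _KIND_LEVELS[kind]
            ctx = context.get(ref, set(by_name))
            neg_pops = {n for n in ctx if by_name[n].level_of(channel) in neg_levels}
            pos_pops = {n for n in ctx if by_name[n].level_of(channel) in pos_levels}
            if not pos_pops:  # context too narrow: fall back to the full panel
                pos_pops = {
                    n for n, p in by_name.items() if p.level_of(channel) in pos_levels
                }
            # no negatives in context -> back off from the positives below
            neg_mask = np.isin(labels, sorted(neg_pops))
            pos_mask = np.isin(labels, sorted(pos_pops))
        if pos_mask.sum() < 10:
            problems.append(f"{ref}: no positive reference events for {channel!r}")
            continue
        pos_t = _asinh(values[pos_mask], cofactor)
        pos_mode = _mode(pos_t)
        if neg_mask.sum() < 10:
            # no negative stratum in the reference: back off from the positives
            mid = pos_mode - 2.0
        else:
            neg_hi = float(np.quantile(_asinh(values[neg_mask], cofactor), neg_quantile))
            if neg_hi >= pos_mode:
                problems.append(
                    f"{ref}: negative and positive references overlap on {channel!r}"
                )
                continue
            mid = 0.5 * (neg_hi + pos_mode)
        thresholds[ref] = float(np.sinh(mid) * cofactor)
    return thresholds, problems


# --------------------------------------------------------------------------
# Gate application
# --------------------------------------------------------------------------


def marker_frame(
    unmixed: UnmixResult, scatter: pd.DataFrame, panel: PanelConfig
) -> pd.DataFrame:
    """Marker-named analysis frame: unmixed abundances + scatter channels."""
    data: dict[str, np.ndarray] = {}
    for name in unmixed.endmember_names:
        if name in panel.fluorochromes:
            data[panel.marker_of(name)] = unmixed.of(name)
        else:
            data[name] = unmixed.of(name)
    for col in ("FSC-A", "SSC-A", "FSC-H"):
        data[col] = scatter[col].to_numpy(dtype=float)
    frame = pd.DataFrame(data)
    frame["FSC_ratio"] = frame["FSC-H"] / frame["FSC-A"]
    return frame


@dataclass
class GatingResult:
    labels: np.ndarray
    substates: np.ndarray
    frequency_table: pd.DataFrame
    node_counts: dict[str, int]


def _check_resolved(tree: GateTree, thresholds: Mapping[str, float], X: pd.DataFrame):
    missing = []
    for ref, spec in tree.threshold_specs.items():
        if spec["kind"] == "dynamic-median":
            continue
        if ref not in thresholds:
            missing.append(ref)
    if missing:
        raise ValueError(f"unresolved gate thresholds: {sorted(missing)}")
    channels = {ch for node in tree.nodes.values() for ch, _, _ in node.terms}
    absent = sorted(ch for ch in channels if ch not in X.columns)
    if absent:
        raise ValueError(f"channels missing from data: {absent}")


def _apply_tree(
    tree: GateTree, X: pd.DataFrame, thresholds: Mapping[str, float]
) -> GatingResult:
    n = len(X)
    labels = np.full(n, None, dtype=object)
    substates = np.full(n, "", dtype=object)
    deepest = np.full(n, tree.root.name, dtype=object)
    counts: dict[str, int] = {}
    cols = {c: X[c].to_numpy(dtype=float) for c in X.columns}

    def node_thresholds(node: GateNode, idx: np.ndarray) -> dict[str, float]:
        local = dict(thresholds)
        for ref, spec in tree.threshold_specs.items():
            if spec["kind"] == "dynamic-median" and spec.get("scope") == node.name:
                values = cols[spec["channel"]][idx]
                local[ref] = float(np.median(values)) if values.size else 0.0
        return local

    def descend(node: GateNode, idx: np.ndarray) -> None:
        counts[node.name] = idx.size
        deepest[idx] = node.name
        if node.population is not None:
            labels[idx] = node.population
        if node.substate is not None:
            substates[idx] = node.substate
        kids = tree.children(node.name)
        if not kids:
            return
        local = node_thresholds(node, idx)
        remaining = idx
        for child in kids:
            if remaining.size == 0:
                mask = np.zeros(0, dtype=bool)
            else:
                mask = np.ones(remaining.size, dtype=bool)
                for channel, direction, ref in child.terms:
                    vals = cols[channel][remaining]
                    thr = local[ref]
                    mask &= (vals > thr) if direction == ">" else (vals < thr)
            descend(child, remaining[mask])
            remaining = remaining[~mask]
        counts[f"{node.name}/unassigned"] = remaining.size

    descend(tree.root, np.arange(n))
    unlabeled = labels == None  # noqa: E711  (object array comparison)
    labels[unlabeled] = np.char.add(
        deepest[unlabeled].astype(str), "/unassigned"
    ).astype(object)
    freq = _frequency_table(tree, counts)
    return GatingResult(labels.astype(object), substates, freq, counts)


def _frequency_table(tree: GateTree, counts: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    for name, node in tree.nodes.items():
        count = counts.get(name, 0)
        if node.parent is None:
            parent_count = count
        else:
            parent_count = counts.get(node.parent, 0)
        freq = 100.0 * count / parent_count if parent_count else 0.0
        rows.append(
            {
                "gate": name,
                "population": node.population or "",
                "parent": node.parent or "",
                "event_count": count,
                "frequency_of_parent_pct": freq,
            }
        )
    return pd.DataFrame(rows)


def apply_gates(
    unmixed: UnmixResult,
    scatter: pd.DataFrame,
    tree: GateTree,
    panel: PanelConfig,
    thresholds: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify unmixed events down the gate tree.

    Returns (labels, frequency-of-parent table).  Thresholds must be fully
    resolved (see :func:`derive_thresholds`) before any event is processed.
    """
    thresholds = dict(thresholds if thresholds is not None else tree.thresholds)
    X = marker_frame(unmixed, scatter, panel)
    _check_resolved(tree, thresholds, X)
    result = _apply_tree(tree, X, thresholds)
    return result.labels, result.frequency_table


@dataclass
class RecoveryReport:
    confusion: pd.DataFrame
    recall: pd.Series
    precision: pd.Series
    accuracy: float


def evaluate_recovery(
    truth: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str] | None = None,
) -> RecoveryReport:
    """Confusion matrix, per-population recall/precision, overall accuracy.

    Accuracy is computed over events whose truth label is one of ``classes``
    (default: all truth labels except ``"Dead"``, which the live gate is
    designed to remove).
    """
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted labels must have equal length")
    if classes is None:
        classes = sorted({t for t in truth if t != DEAD_LABEL})
    keep = np.isin(truth, list(classes))
    if not set(truth[keep]) & set(predicted[keep]):
        warnings.warn("truth and predicted label sets are disjoint")
    confusion = pd.crosstab(
        pd.Series(truth[keep], name="truth"),
        pd.Series(predicted[keep], name="predicted"),
    )
    correct = truth[keep] == predicted[keep]
    accuracy = float(correct.mean()) if keep.any() else 0.0
    recall = {}
    precision = {}
    for cls in classes:
        t_mask = truth[keep] == cls
        p_mask = predicted[keep] == cls
        recall[cls] = float((t_mask & correct).sum() / t_mask.sum()) if t_mask.any() else np.nan
        precision[cls] = (
            float((p_mask & correct).sum() / p_mask.sum()) if p_mask.any() else np.nan
        )
    return RecoveryReport(
        confusion=confusion,
        recall=pd.Series(recall, name="recall"),
        precision=pd.Series(precision, name="precision"),
        accuracy=accuracy,
    )


class GateTreeClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style classifier wrapping the gate tree.

    ``fit`` derives every gate threshold from a truth-labeled reference
    marker frame; ``predict`` descends the tree.  ``X`` is a marker-named
    DataFrame as produced by :func:`marker_frame`.

    Parameters
    ----------
    tree : GateTree, optional (default: the lung tree)
    cofactor : float
        asinh cofactor for the threshold-derivation transform.
    neg_quantile : float
        Upper quantile of the negative stratum used in derivation.
    singlet_cutoff : float
        FSC-H/FSC-A ratio cutoff for the singlet gate.
    profiles : sequence of PopulationProfile, optional
        Expression levels used to designate negative/positive strata.
    """

    def __init__(
        self,
        tree: GateTree | None = None,
        cofactor: float = 50.0,
        neg_quantile: float = 0.995,
        singlet_cutoff: float = 0.75,
        profiles: Sequence[PopulationProfile] | None = None,
    ):
        self.tree = tree
        self.cofactor = cofactor
        self.neg_quantile = neg_quantile
        self.singlet_cutoff = singlet_cutoff
        self.profiles = profiles

    def fit(self, X: pd.DataFrame, y: Sequence[str]):
        self.tree_ = self.tree if self.tree is not None else build_lung_gate_tree()
        thresholds, problems = derive_thresholds(
            self.tree_,
            X,
            y,
            profiles=self.profiles,
            cofactor=self.cofactor,
            neg_quantile=self.neg_quantile,
            singlet_cutoff=self.singlet_cutoff,
        )
        if problems:
            raise ValueError(f"could not resolve thresholds: {problems}")
        self.thresholds_ = thresholds
        self.classes_ = np.asarray(sorted(self.tree_.target_populations), dtype=object)
        return self

    def _gate(self, X: pd.DataFrame) -> GatingResult:
        if not hasattr(self, "thresholds_"):
            raise ValueError("classifier is not fitted")
        _check_resolved(self.tree_, self.thresholds_, X)
        return _apply_tree(self.tree_, X, self.thresholds_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self._gate(X).labels

    def gate(self, X: pd.DataFrame) -> GatingResult:
        """Full gating output: labels, sub-states, frequency table, counts."""
        return self._gate(X)

    def score(self, X: pd.DataFrame, y: Sequence[str]) -> float:
        return evaluate_recovery(y, self.predict(X)).accuracy
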