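"""Incremental confidence-driven merging of per-view 3D labelings.

The running :class:`FusionState` holds one label and one confidence per cloud
point.  Each incoming view is reconciled with the state through normalized
overlap tables: for a state group ``lx``, the row ``Qx[lx]`` distributes its
points over the incoming labels (including −1, "no information"), and ``Qy``
is the symmetric table for incoming groups.  Three cases follow:

* **unmatched** — an incoming group whose γ mass on −1 reaches
  ``tau_unmatched`` describes geometry the state has not seen; all its points
  enter as a fresh group, confidences inherited verbatim.
* **matched** — a pair with mutually high overlap (γ ≥ ``tau_match`` in both
  tables) is the same physical leaf seen twice; the groups are unified under
  the state's label and confidences are summed point by point (mutual
  validation increases reliability; scores are unnormalized masses and may
  exceed 1).
* **conflict** — partially overlapping or nested pairs.  The side with the
  higher group-mean confidence keeps the contested points; their confidences
  become |s_x − s_y| (agreement spent resolving the dispute), while points
  outside the overlap keep their own label and score.

Incoming points that remain unlabeled in the state after these cases (newly
visible parts of a group that did conflict or match elsewhere) are attached to
the group's dominant state correspondent, or to a fresh label when the group
corresponds to nothing — so every labeled incoming point ends up represented.

Folding this merge over the views in capture order (adjacent turntable
angles) yields the final instance segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .lifting import FusionConfig, ViewLabeling

__all__ = [
    "OverlapTablePair",
    "FusionState",
    "PairClassification",
    "overlap_tables",
    "classify_pairs",
    "group_mean",
    "merge_pair",
    "incremental_fuse",
]


@dataclass
class OverlapTablePair:
    """Normalized correspondence tables between two labelings of one cloud.

    ``Qx[lx][ly] = γ`` is the fraction of lx's points labeled ly in the other
    labeling (−1 included); rows sum to 1.  ``pairs[(lx, ly)]`` holds the
    shared point indices (the correspondence mapping M).
    """

    Qx: dict[int, dict[int, float]]
    Qy: dict[int, dict[int, float]]
    pairs: dict[tuple[int, int], np.ndarray]


@dataclass
class FusionState:
    """Running merged labeling over the original cloud."""

    labels: np.ndarray
    conf: np.ndarray
    next_label: int = 0
    merge_count: int = 0

    @classmethod
    def empty(cls, n: int) -> "FusionState":
        return cls(labels=np.full(n, -1, dtype=np.int64), conf=np.zeros(n), next_label=0)

    def fresh_label(self) -> int:
        lab = self.next_label
        self.next_label += 1
        return lab

    def copy(self) -> "FusionState":
        return FusionState(self.labels.copy(), self.conf.copy(), self.next_label, self.merge_count)


@dataclass
class PairClassification:
    unmatched_a: list[int]
    unmatched_b: list[int]
    matched: list[tuple[int, int]]
    conflicts: list[tuple[int, int]]


def _labels_of(obj) -> np.ndarray:
    return obj.labels if hasattr(obj, "labels") else np.asarray(obj, dtype=np.int64)


def overlap_tables(a, b) -> OverlapTablePair:
    """Correspondence mapping and row-normalized overlap tables between two labelings."""
    la, lb = _labels_of(a), _labels_of(b)
    if la.shape != lb.shape:
        raise ValueError("labelings must cover the same cloud")
    pairs: dict[tuple[int, int], np.ndarray] = {}
    # group indices by (la, lb) pair in one pass
    order = np.lexsort((lb, la))
    sla, slb = la[order], lb[order]
    boundaries = np.nonzero((np.diff(sla) != 0) | (np.diff(slb) != 0))[0] + 1
    for chunk in np.split(order, boundaries):
        key = (int(la[chunk[0]]), int(lb[chunk[0]]))
        pairs[key] = np.sort(chunk)

    def rows(first: int) -> dict[int, dict[int, float]]:
        counts: dict[int, dict[int, int]] = {}
        for (kx, ky), idx in pairs.items():
            key, other = (kx, ky) if first == 0 else (ky, kx)
            if key == -1:
                continue
            counts.setdefault(key, {})[other] = len(idx)
        out: dict[int, dict[int, float]] = {}
        for key, row in counts.items():
            total = sum(row.values())
            out[key] = {other: c / total for other, c in row.items()}
        return out

    return OverlapTablePair(Qx=rows(0), Qy=rows(1), pairs=pairs)


def classify_pairs(q: OverlapTablePair, cfg: FusionConfig) -> PairClassification:
    """Split groups into unmatched / matched / conflict cases.

    A group is unmatched when the majority (γ ≥ ``tau_unmatched``) of its
    points carry no label on the other side.  A pair is matched when both
    overlap ratios reach ``tau_match``; matched pairs are made one-to-one
    greedily by combined γ.  Every remaining overlapping real-real pair is a
    conflict.
    """
    unmatched_a = [lx for lx, row in q.Qx.items() if row.get(-1, 0.0) >= cfg.tau_unmatched]
    unmatched_b = [ly for ly, row in q.Qy.items() if row.get(-1, 0.0) >= cfg.tau_unmatched]

    candidates = []
    for lx, row in q.Qx.items():
        if lx in unmatched_a:
            continue
        for ly, gx in row.items():
            if ly == -1 or ly in unmatched_b:
                continue
            gy = q.Qy.get(ly, {}).get(lx, 0.0)
            if gx >= cfg.tau_match and gy >= cfg.tau_match:
                candidates.append((gx + gy, lx, ly))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched: list[tuple[int, int]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, lx, ly in candidates:
        if lx in used_a or ly in used_b:
            continue
        matched.append((lx, ly))
        used_a.add(lx)
        used_b.add(ly)

    conflicts = []
    matched_set = set(matched)
    for (lx, ly), idx in q.pairs.items():
        if lx == -1 or ly == -1 or (lx, ly) in matched_set:
            continue
        if lx in unmatched_a or ly in unmatched_b:
            continue
        conflicts.append((lx, ly))
    return PairClassification(unmatched_a, unmatched_b, matched, conflicts)


def group_mean(conf: Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean confidence of a group; errors on an empty group."""
    conf = np.asarray(conf, dtype=np.float64)
    if conf.size == 0:
        raise ValueError("group is empty")
    return float(conf.mean())


def merge_pair(state: FusionState, incoming: ViewLabeling, cfg: FusionConfig) -> FusionState:
    """Merge one incoming view labeling into the running state (in place)."""
    if state.labels.shape != incoming.labels.shape:
        raise ValueError("incoming labeling does not cover the state's cloud")
    inc_l, inc_s = incoming.labels, incoming.conf
    q = overlap_tables(state, incoming)
    cls = classify_pairs(q, cfg)
    resolved = np.zeros(len(state.labels), dtype=bool)
    mapping: dict[int, int] = {}  # incoming label -> state label

    # 1. unmatched incoming groups: add whole group as new
    for ly in cls.unmatched_b:
        member = np.nonzero(inc_l == ly)[0]
        lab = state.fresh_label()
        mapping[ly] = lab
        state.labels[member] = lab
        state.conf[member] = inc_s[member]
        resolved[member] = True

    # 2. matched pairs: unify under the state's label, sum confidences pointwise
    for lx, ly in cls.matched:
        mapping[ly] = lx
        in_x = state.labels == lx
        in_y = inc_l == ly
        union = np.nonzero((in_x | in_y) & ~resolved)[0]
        state.conf[union] = np.where(in_x[union], state.conf[union], 0.0) + np.where(
            in_y[union], inc_s[union], 0.0
        )
        state.labels[union] = lx
        resolved[union] = True

    # 3. conflicts, largest overlap first; a point is re-resolved at most once
    conflicts = sorted(
        cls.conflicts, key=lambda p: (-len(q.pairs[p]), p[0], p[1])
    )
    for lx, ly in conflicts:
        overlap = q.pairs[(lx, ly)]
        overlap = overlap[~resolved[overlap]]
        if len(overlap) == 0:
            continue
        sx_bar = group_mean(state.conf[state.labels == lx])
        in_y = inc_l == ly
        sy_bar = group_mean(inc_s[in_y])
        diff = np.abs(state.conf[overlap] - inc_s[overlap])
        if sx_bar >= sy_bar:
            # state keeps the contested points (ties favor accumulated evidence)
            state.conf[overlap] = diff
        else:
            if ly not in mapping:
                mapping[ly] = state.fresh_label()
            state.labels[overlap] = mapping[ly]
            state.conf[overlap] = diff
        resolved[overlap] = True

    # 4. residue: labeled incoming points still unknown to the state join
    #    their group's dominant state correspondent (or a fresh group)
    for ly, row in q.Qy.items():
        member = np.nonzero((inc_l == ly) & (state.labels == -1) & ~resolved)[0]
        if len(member) == 0:
            continue
        if ly not in mapping:
            real = {lx: g for lx, g in row.items() if lx != -1}
            if real:
                best = max(real, key=lambda lx: (real[lx], -lx))
                mapping[ly] = best
            else:
                mapping[ly] = state.fresh_label()
        state.labels[member] = mapping[ly]
        state.conf[member] = inc_s[member]
        resolved[member] = True

    state.merge_count += 1
    return state


def incremental_fuse(
    views: Iterable[ViewLabeling],
    cfg: FusionConfig | None = None,
    on_merge: Callable[[FusionState], None] | None = None,
) -> FusionState:
    """Fold :func:`merge_pair` over the views in capture order.

    ``on_merge`` is called with the running state after every merge (metric
    hooks, e.g. tracking fusion quality per iteration).
    """
    cfg = cfg or FusionConfig()
    state: FusionState | None = None
    for vl in views:
        if state is None:
            state = FusionState.empty(len(vl.labels))
        state = merge_pair(state, vl, cfg)
        if on_merge is not None:
            on_merge(state)
    if state is None:
        raise ValueError("at least one view labeling is required")
    return state
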