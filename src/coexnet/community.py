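"""Module detection by modularity / modularity-density maximization.

Two quality functions are supported on the weighted, thresholded
co-expression graph:

* **Q** — weighted Newman modularity,
  ``Q = sum_c [ W_c_in / W  -  (S_c / 2W)^2 ]``
  with ``W`` the total edge weight, ``W_c_in`` the weight inside community
  ``c`` and ``S_c`` the summed node strength of ``c``.

* **Qds** — modularity density, which multiplies each community's
  contribution by its internal weight density and adds a split penalty
  between community pairs.  Per community ``c``::

      (W_c_in / W) * d_c  -  ((2 W_c_in + W_c_out) / 2W * d_c)^2
          - sum_{c' != c} (W_cc' / 2W) * d_cc'

  with internal density ``d_c = 2 W_c_in / (n_c (n_c - 1))`` (defined as 0
  for singletons) and pair density ``d_cc' = W_cc' / (n_c n_c')``.  Qds
  penalizes both merging small well-defined communities into big ones and
  splitting dense communities, which counteracts the resolution limit of
  plain modularity.

Optimization is a deterministic greedy agglomeration (start from
singletons, repeatedly apply the connected-pair merge with the largest
positive gain) followed by a fine-tuning phase of single-node moves —
including splitting a node off into its own community — and further
merges, iterated to a local optimum.  All candidate evaluations happen in
a fixed order with ties broken by the smallest community-index pair, so
results are reproducible; the seed only drives optional randomized
restarts (shuffled node orders in the fine-tuning sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError

#: Label used for genes not placed in any module.
UNASSIGNED = 0

_NEW = -1  # sentinel target: split the node off into a fresh community


@dataclass
class Partition:
    """Gene -> module assignment; label ``0`` means unassigned."""

    assignment: dict

    def modules(self) -> dict[int, frozenset]:
        """Assigned modules as ``{label: frozenset(genes)}`` (label >= 1)."""
        out: dict[int, set] = {}
        for item, label in self.assignment.items():
            if label != UNASSIGNED:
                out.setdefault(label, set()).add(item)
        return {k: frozenset(v) for k, v in out.items()}

    def unassigned(self) -> frozenset:
        return frozenset(
            item for item, lab in self.assignment.items() if lab == UNASSIGNED
        )

    @property
    def n_modules(self) -> int:
        return len({lab for lab in self.assignment.values() if lab != UNASSIGNED})

    @property
    def n_unassigned(self) -> int:
        return sum(1 for lab in self.assignment.values() if lab == UNASSIGNED)

    def module_sizes(self) -> list[int]:
        """Sizes of assigned modules in decreasing order."""
        return sorted((len(m) for m in self.modules().values()), reverse=True)

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass
class ObjectiveScore:
    """Final objective plus both quality indices of a partition."""

    q: float
    qds: float
    objective_used: str

    @property
    def objective(self) -> float:
        return self.q if self.objective_used == "Q" else self.qds


def _check_objective(objective: str) -> str:
    if objective not in ("Q", "Qds"):
        raise ValueError(f"objective must be 'Q' or 'Qds', got {objective!r}")
    return objective


def _effective_labels(graph: nx.Graph, partition: Partition) -> dict:
    """Labels for scoring: unassigned nodes become unique singletons."""
    labels = {}
    missing = []
    counter = 0
    for node in graph.nodes:
        lab = partition.assignment.get(node)
        if lab is None:
            missing.append(node)
        elif lab == UNASSIGNED:
            counter -= 1
            labels[node] = counter
        else:
            labels[node] = lab
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing[:10]}")
    return labels


def _aggregates(graph: nx.Graph, labels: dict):
    """Per-community (size, internal weight, strength) and inter-weights."""
    size: dict = {}
    win: dict = {}
    strength: dict = {}
    inter: dict = {}
    for node in graph.nodes:
        c = labels[node]
        size[c] = size.get(c, 0) + 1
        win.setdefault(c, 0.0)
        strength.setdefault(c, 0.0)
    for u, v, w in graph.edges(data="weight", default=1.0):
        cu, cv = labels[u], labels[v]
        strength[cu] += w
        strength[cv] += w
        if cu == cv:
            win[cu] += w
        else:
            key = (cu, cv) if repr(cu) < repr(cv) else (cv, cu)
            inter[key] = inter.get(key, 0.0) + w
    return size, win, strength, inter


def modularity(graph: nx.Graph, partition: Partition) -> float:
    """Weighted Newman modularity Q of a partition.

    Unassigned nodes are scored as their own singleton communities.
    """
    total = graph.size(weight="weight")
    if total <= 0:
        raise ValueError("modularity undefined: graph has no (weighted) edges")
    labels = _effective_labels(graph, partition)
    size, win, strength, _ = _aggregates(graph, labels)
    return float(
        sum(win[c] / total - (strength[c] / (2 * total)) ** 2 for c in size)
    )


def modularity_density(graph: nx.Graph, partition: Partition) -> float:
    """Modularity density Qds of a partition (see module docstring).

    Singleton communities have internal density 0 by definition, so they
    contribute only through the split penalty with their neighbours.
    """
    total = graph.size(weight="weight")
    if total <= 0:
        raise ValueError("modularity density undefined: graph has no edges")
    labels = _effective_labels(graph, partition)
    size, win, strength, inter = _aggregates(graph, labels)
    qds = 0.0
    for c, n_c in size.items():
        d_c = 2 * win[c] / (n_c * (n_c - 1)) if n_c > 1 else 0.0
        qds += (win[c] / total) * d_c - (strength[c] * d_c / (2 * total)) ** 2
    for (c1, c2), w in inter.items():
        d_pair = w / (size[c1] * size[c2])
        qds -= (w / total) * d_pair  # both ordered directions combined
    return float(qds)


class _DenseOptimizer:
    """Array-based state for greedy merges and single-node moves.

    Communities are indexed by integer slots 0..n-1.  ``B`` holds the
    community-level weight matrix: ``B[c, c]`` is the internal weight of
    ``c`` and ``B[c, c']`` the weight between ``c`` and ``c'``.  ``size``
    and ``S`` hold community sizes and summed node strengths; emptied slots
    are deactivated and can be reused by split moves.
    """

    def __init__(self, adj: np.ndarray, objective: str, tol: float):
        n = adj.shape[0]
        self.n = n
        self.A = adj
        self.W = adj.sum() / 2.0
        self.s = adj.sum(axis=1)
        self.objective = objective
        self.tol = tol
        self.comm = np.arange(n)
        self.B = adj.astype(float).copy()
        self.size = np.ones(n)
        self.S = self.s.copy()
        self.active = np.ones(n, dtype=bool)

    # -- community quality terms (vectorized; works on scalars too) --------
    def _terms(self, win, strength, size):
        w2 = 2.0 * self.W
        if self.objective == "Q":
            return win / self.W - (strength / w2) ** 2
        pairs = size * (size - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(pairs > 0, 2.0 * win / np.maximum(pairs, 1e-300), 0.0)
        return (win / self.W) * dens - (strength * dens / w2) ** 2

    def value(self) -> float:
        idx = np.flatnonzero(self.active)
        sub = self.B[np.ix_(idx, idx)]
        din = sub.diagonal().copy()
        total = float(self._terms(din, self.S[idx], self.size[idx]).sum())
        if self.objective == "Qds":
            off = sub.copy()
            np.fill_diagonal(off, 0.0)
            nsz = self.size[idx]
            total -= float(
                (off**2 / np.outer(nsz, nsz)).sum() / (2.0 * self.W)
            )
        return total

    # -- merges -------------------------------------------------------------
    def best_merge(self):
        """Largest-gain merge of two connected communities, or None."""
        idx = np.flatnonzero(self.active)
        if idx.size < 2:
            return None
        sub = self.B[np.ix_(idx, idx)]
        din = sub.diagonal().copy()
        off = sub.copy()
        np.fill_diagonal(off, 0.0)
        nsz = self.size[idx]
        strg = self.S[idx]
        terms = self._terms(din, strg, nsz)
        win_m = din[:, None] + din[None, :] + off
        s_m = strg[:, None] + strg[None, :]
        n_m = nsz[:, None] + nsz[None, :]
        delta = self._terms(win_m, s_m, n_m) - terms[:, None] - terms[None, :]
        if self.objective == "Qds":
            w = self.W
            p2 = (off**2 / nsz[None, :]).sum(axis=1)
            cross = (off / nsz[None, :]) @ off.T
            removed = (
                p2[:, None] / nsz[:, None]
                + p2[None, :] / nsz[None, :]
                - off**2 / np.outer(nsz, nsz)
            ) / w
            added = (
                p2[:, None]
                + p2[None, :]
                + 2.0 * cross
                - off**2 / nsz[:, None]
                - off**2 / nsz[None, :]
            ) / (w * n_m)
            delta = delta + removed - added
        delta[off <= 0] = -np.inf  # only merge connected communities
        delta[np.tril_indices_from(delta)] = -np.inf
        flat = int(np.argmax(delta))  # row-major: ties -> smallest index pair
        a, b = np.unravel_index(flat, delta.shape)
        gain = delta[a, b]
        if not np.isfinite(gain) or gain <= self.tol:
            return None
        return gain, int(idx[a]), int(idx[b])

    def apply_merge(self, a: int, b: int) -> None:
        win_new = self.B[a, a] + self.B[b, b] + self.B[a, b]
        self.B[a, :] += self.B[b, :]
        self.B[:, a] += self.B[:, b]
        self.B[a, a] = win_new
        self.B[b, :] = 0.0
        self.B[:, b] = 0.0
        self.size[a] += self.size[b]
        self.size[b] = 0.0
        self.S[a] += self.S[b]
        self.S[b] = 0.0
        self.active[b] = False
        self.comm[self.comm == b] = a

    # -- single-node moves ---------------------------------------------------
    def _move_delta(self, v: int, a: int, b: int, kv: np.ndarray) -> float:
        """Objective change of moving node v from community a to b.

        ``b == _NEW`` splits v off into a fresh singleton community.
        ``kv`` is v's summed edge weight into each community slot.
        """
        w = self.W
        sv = self.s[v]
        n_a, win_a, s_a = self.size[a], self.B[a, a], self.S[a]
        if b == _NEW:
            n_b = 0.0
            win_b = 0.0
            s_b = 0.0
            o_ab = 0.0
            kv_b = 0.0
        else:
            n_b, win_b, s_b = self.size[b], self.B[b, b], self.S[b]
            o_ab = self.B[a, b]
            kv_b = kv[b]
        n_a2 = n_a - 1.0
        win_a2 = win_a - kv[a]
        s_a2 = s_a - sv
        n_b2 = n_b + 1.0
        win_b2 = win_b + kv_b
        s_b2 = s_b + sv
        delta = float(
            self._terms(win_a2, s_a2, max(n_a2, 1.0)) * (n_a2 > 0)
            + self._terms(win_b2, s_b2, n_b2)
            - self._terms(win_a, s_a, n_a)
            - (self._terms(win_b, s_b, n_b) if n_b > 0 else 0.0)
        )
        if self.objective == "Qds":
            mask = self.active.copy()
            mask[a] = False
            if b != _NEW:
                mask[b] = False
            o_a = self.B[a, mask]
            o_b = self.B[b, mask] if b != _NEW else np.zeros(int(mask.sum()))
            kc = kv[mask]
            nc = self.size[mask]
            old = (o_a**2 / (n_a * nc)).sum()
            if n_b > 0:
                old += (o_b**2 / (n_b * nc)).sum() + o_ab**2 / (n_a * n_b)
            new = ((o_b + kc) ** 2 / (n_b2 * nc)).sum()
            o_ab2 = o_ab + kv[a] - kv_b
            if n_a2 > 0:
                new += ((o_a - kc) ** 2 / (n_a2 * nc)).sum()
                new += o_ab2**2 / (n_a2 * n_b2)
            delta += (old - new) / w
        return delta

    def apply_move(self, v: int, a: int, b: int, kv: np.ndarray) -> None:
        if b == _NEW:
            free = np.flatnonzero(~self.active)
            b = int(free[0])
            self.active[b] = True
        cmask = self.active.copy()
        cmask[a] = False
        cmask[b] = False
        kc = kv[: self.n] * cmask
        o_ab = self.B[a, b]
        self.B[a, cmask] -= kc[cmask]
        self.B[cmask, a] -= kc[cmask]
        self.B[b, cmask] += kc[cmask]
        self.B[cmask, b] += kc[cmask]
        new_ab = o_ab + kv[a] - kv[b]
        self.B[a, b] = self.B[b, a] = new_ab
        self.B[a, a] -= kv[a]
        self.B[b, b] += kv[b]
        self.size[a] -= 1.0
        self.size[b] += 1.0
        self.S[a] -= self.s[v]
        self.S[b] += self.s[v]
        self.comm[v] = b
        if self.size[a] <= 0:
            self.active[a] = False
            self.B[a, :] = 0.0
            self.B[:, a] = 0.0

    def _best_move_for(self, v: int):
        """Best single move for node v, allowing negative gains (KL step)."""
        a = int(self.comm[v])
        kv = np.bincount(self.comm, weights=self.A[v], minlength=self.n)
        targets = [
            int(c) for c in np.flatnonzero(kv > 0) if self.active[c] and c != a
        ]
        if self.size[a] > 1:
            targets.append(_NEW)
        if not targets:
            return None
        best_gain, best_t = -np.inf, None
        for t in targets:
            gain = self._move_delta(v, a, t, kv)
            if gain > best_gain:
                best_gain, best_t = gain, t
        return best_gain, best_t, kv

    def _snapshot(self):
        return (
            self.B.copy(), self.size.copy(), self.S.copy(),
            self.active.copy(), self.comm.copy(),
        )

    def _restore(self, snap) -> None:
        self.B, self.size, self.S, self.active, self.comm = (
            snap[0].copy(), snap[1].copy(), snap[2].copy(),
            snap[3].copy(), snap[4].copy(),
        )

    def kl_pass(self, order: np.ndarray) -> bool:
        """Kernighan–Lin refinement: a chain of locked best single moves.

        Each step applies the best available move even when its gain is
        negative, locks the moved node, and tracks the cumulative gain; the
        chain is then rolled back to its best prefix.  This escapes local
        optima that single improving moves cannot leave.  Returns True if
        the objective improved by more than ``tol``.
        """
        nodes = [int(v) for v in order]
        locked = np.zeros(self.n, dtype=bool)
        snap = self._snapshot()
        cache: dict[int, tuple] = {}
        for v in nodes:
            hit = self._best_move_for(v)
            if hit is not None:
                cache[v] = (hit[0], hit[1])
        moves: list[tuple[int, int]] = []
        cum, best_cum, best_len = 0.0, 0.0, 0
        for _ in range(len(nodes)):
            fresh = None
            while True:
                pool = [v for v in nodes if not locked[v] and v in cache]
                if not pool:
                    break
                v = max(pool, key=lambda u: cache[u][0])
                hit = self._best_move_for(v)
                if hit is None:
                    del cache[v]
                    locked[v] = True
                    continue
                runner_up = max(
                    (cache[u][0] for u in pool if u != v), default=-np.inf
                )
                if hit[0] >= runner_up - 1e-15:
                    fresh = (v, hit)
                    break
                cache[v] = (hit[0], hit[1])
            if fresh is None:
                break
            v, (gain, target, kv) = fresh
            a = int(self.comm[v])
            self.apply_move(v, a, target, kv)
            locked[v] = True
            moves.append((v, target))
            cum += gain
            if cum > best_cum + self.tol:
                best_cum, best_len = cum, len(moves)
            b = int(self.comm[v])
            for u in nodes:
                if locked[u]:
                    continue
                if self.comm[u] in (a, b) or self.A[u, v] > 0:
                    hit = self._best_move_for(u)
                    if hit is None:
                        cache.pop(u, None)
                    else:
                        cache[u] = (hit[0], hit[1])
        self._restore(snap)
        if best_cum <= self.tol:
            return False
        for v, target in moves[:best_len]:
            kv = np.bincount(self.comm, weights=self.A[v], minlength=self.n)
            self.apply_move(v, int(self.comm[v]), target, kv)
        return True

    def sweep(self, order: np.ndarray) -> bool:
        """One pass of best single-node moves; returns True if any applied."""
        changed = False
        for v in order:
            a = int(self.comm[v])
            kv = np.bincount(self.comm, weights=self.A[v], minlength=self.n)
            targets = [
                int(c)
                for c in np.flatnonzero(kv > 0)
                if self.active[c] and c != a
            ]
            if self.size[a] > 1:
                targets.append(_NEW)
            best_gain, best_t = self.tol, None
            for t in targets:
                gain = self._move_delta(v, a, t, kv)
                if gain > best_gain:
                    best_gain, best_t = gain, t
            if best_t is not None:
                self.apply_move(v, a, best_t, kv)
                changed = True
        return changed

    def run(self, order: np.ndarray, max_rounds: int = 200) -> None:
        # each round strictly improves the (bounded) objective, so the
        # round cap is a safety net, not a tuning knob
        for _ in range(max_rounds):
            progress = False
            while True:
                hit = self.best_merge()
                if hit is None:
                    break
                self.apply_merge(hit[1], hit[2])
                progress = True
            for _ in range(max_rounds):
                if not self.sweep(order):
                    break
                progress = True
            if self.kl_pass(order):
                progress = True
            elif not progress:
                break


def _restricted_growth_strings(n: int):
    """All set partitions of range(n) as canonical label arrays."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield labels
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([labels])


def _labels_value(adj: np.ndarray, labels: np.ndarray, objective: str) -> float:
    """Objective of an explicit labelling of a dense adjacency matrix."""
    total = adj.sum() / 2.0
    strength = adj.sum(axis=1)
    n_comm = int(labels.max()) + 1
    member = np.zeros((adj.shape[0], n_comm))
    member[np.arange(adj.shape[0]), labels] = 1.0
    block = member.T @ adj @ member
    win = np.diag(block) / 2.0
    s_c = member.T @ strength
    if objective == "Q":
        return float((win / total - (s_c / (2 * total)) ** 2).sum())
    n_c = member.sum(axis=0)
    pairs = n_c * (n_c - 1)
    dens = np.where(pairs > 0, 2.0 * win / np.maximum(pairs, 1e-300), 0.0)
    value = ((win / total) * dens - (s_c * dens / (2 * total)) ** 2).sum()
    off = block - np.diag(np.diag(block))
    value -= (off**2 / np.outer(n_c, n_c)).sum() / (2.0 * total)
    return float(value)


#: Components up to this many nodes are clustered by exhaustive enumeration
#: (Bell(8) = 4140 partitions), which is both fast and exactly optimal; the
#: greedy heuristic takes over beyond it.
EXACT_SIZE_LIMIT = 8


def _exact_labels(adj: np.ndarray, objective: str) -> np.ndarray:
    best_val, best = -np.inf, None
    for labels in _restricted_growth_strings(adj.shape[0]):
        arr = np.asarray(labels)
        val = _labels_value(adj, arr, objective)
        if val > best_val + 1e-15:
            best_val, best = val, arr.copy()
    return best


def maximize(
    graph: nx.Graph,
    objective: str = "Qds",
    seed: int = 0,
    restarts: int = 1,
    tol: float = 1e-12,
) -> tuple[Partition, ObjectiveScore]:
    """Detect modules by greedily maximizing Q or Qds.

    Isolated nodes are excluded from optimization and returned as
    UNASSIGNED.  Module labels are contiguous (1..K) ordered by decreasing
    size.  With ``restarts > 1``, additional runs use seeded random node
    orders in the fine-tuning sweeps and the best final objective wins.
    """
    _check_objective(objective)
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if graph.number_of_edges() == 0:
        raise ValueError("cannot cluster a graph with no edges")
    nodes = sorted(graph.nodes, key=repr)
    connected = [v for v in nodes if graph.degree(v) > 0]
    adj = nx.to_numpy_array(graph, nodelist=connected, weight="weight")
    if len(connected) <= EXACT_SIZE_LIMIT:
        best_comm = _exact_labels(adj, objective)
    else:
        rng = np.random.default_rng(seed)
        best_val, best_comm = -np.inf, None
        for r in range(max(1, restarts)):
            order = (
                np.arange(len(connected))
                if r == 0
                else rng.permutation(len(connected))
            )
            opt = _DenseOptimizer(adj, objective, tol)
            opt.run(order)
            val = opt.value()
            if val > best_val:
                best_val, best_comm = val, opt.comm.copy()
    assignment = {node: UNASSIGNED for node in nodes}
    for i, node in enumerate(connected):
        assignment[node] = int(best_comm[i]) + 1
    partition = finalize_partition(Partition(assignment), graph)
    score = ObjectiveScore(
        q=modularity(graph, partition),
        qds=modularity_density(graph, partition),
        objective_used=objective,
    )
    return partition, score


def finalize_partition(
    partition: Partition, graph: nx.Graph, min_module_size: int = 1
) -> Partition:
    """Canonicalize a partition of a graph's nodes.

    Isolated nodes become UNASSIGNED, modules smaller than
    ``min_module_size`` are dissolved into UNASSIGNED, and surviving
    modules are relabelled 1..K by decreasing size (ties by smallest member
    id) so equivalent partitions are byte-identical on disk.
    """
    missing = [v for v in graph.nodes if v not in partition.assignment]
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing[:10]}")
    assignment = {}
    for node in graph.nodes:
        lab = partition.assignment[node]
        if lab != UNASSIGNED and graph.degree(node) == 0:
            lab = UNASSIGNED
        assignment[node] = lab
    groups: dict[int, list] = {}
    for node, lab in assignment.items():
        if lab != UNASSIGNED:
            groups.setdefault(lab, []).append(node)
    keep = {
        lab: members
        for lab, members in groups.items()
        if len(members) >= max(1, min_module_size)
    }
    ranked = sorted(
        keep.items(), key=lambda kv: (-len(kv[1]), repr(min(kv[1], key=repr)))
    )
    relabel = {old: new for new, (old, _) in enumerate(ranked, start=1)}
    out = {}
    for node, lab in assignment.items():
        out[node] = relabel.get(lab, UNASSIGNED)
    return Partition(out)
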