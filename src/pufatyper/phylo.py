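"""Distances, progressive alignment, neighbor-joining trees, bootstrap, monophyly.

A deliberately transparent desk-scale phylogenetics stack: 3-mer cosine guide
distances feed a neighbor-joining guide tree whose join order drives
profile-profile global alignment (BLOSUM62 column scores, linear gap penalty);
pairwise p-distances (optionally Poisson-corrected, -ln(1-p) capped at p=0.95)
feed Saitou-Nei neighbor joining with deterministic tie-breaking (smallest
index pair) and negative branch lengths clamped to zero; supports are the
classical Felsenstein column-bootstrap fractions of internal bipartitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .core_model import InputError

logger = logging.getLogger(__name__)

GAP = "-"
_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # profile rows add GAP as the 22nd state
_GAP_PENALTY = 4.0
POISSON_CAP = 0.95


# ---------------------------------------------------------------------------
# MSA and distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSA:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise InputError("MSA: ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("MSA: duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError("MSA: rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)].replace(GAP, "")

    def sample_columns(self, column_indices) -> "MSA":
        rows = tuple("".join(row[i] for i in column_indices) for row in self.rows)
        return MSA(self.ids, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray = field(compare=False)

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InputError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise InputError("distance matrix has negative entries")


def p_distance_matrix(msa: MSA, correction: str = "p") -> DistanceMatrix:
    """Pairwise fraction of mismatches over columns where both rows are
    ungapped; ``correction="poisson"`` applies -ln(1-p) with p capped at 0.95.

    Pairs with zero comparable columns get distance 1.0 with a warning.
    """
    if correction not in ("p", "poisson"):
        raise InputError(f"unknown distance correction {correction!r}")
    n = len(msa.ids)
    arr = np.array([list(r) for r in msa.rows])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != GAP) & (arr[j] != GAP)
            comparable = int(both.sum())
            if comparable == 0:
                logger.warning("no comparable columns between %s and %s; distance set to 1.0",
                               msa.ids[i], msa.ids[j])
                p = 1.0
            else:
                p = float((arr[i][both] != arr[j][both]).sum()) / comparable
            if correction == "poisson":
                p = -math.log(1.0 - min(p, POISSON_CAP))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(msa.ids, d)


# ---------------------------------------------------------------------------
# Unrooted tree
# ---------------------------------------------------------------------------

class Tree:
    """Unrooted tree with branch lengths and optional per-edge support."""

    def __init__(self):
        self._adj: dict[int, dict[int, float]] = {}
        self._labels: dict[int, str] = {}
        self._next = 0
        self.support: dict[frozenset, float] = {}  # frozenset({u, v}) -> support

    def add_node(self, label: str | None = None) -> int:
        node = self._next
        self._next += 1
        self._adj[node] = {}
        if label is not None:
            self._labels[node] = label
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        self._adj[u][v] = length
        self._adj[v][u] = length

    @property
    def tips(self) -> tuple[str, ...]:
        return tuple(sorted(self._labels.values()))

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in sorted(self._adj):
            for v, length in sorted(self._adj[u].items()):
                if u < v:
                    out.append((u, v, length))
        return out

    def _side_labels(self, u: int, v: int) -> frozenset:
        """Tip labels reachable from v without crossing the edge (u, v)."""
        seen = {u, v}
        stack = [v]
        labels = set()
        while stack:
            node = stack.pop()
            if node in self._labels:
                labels.add(self._labels[node])
            for nbr in self._adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(labels)

    def bipartitions(self) -> dict[frozenset, frozenset]:
        """Internal-edge bipartitions: canonical tip-set -> edge key.

        The canonical side is the one not containing the alphabetically first
        tip; only internal edges (both sides with >= 2 tips) are reported.
        """
        ref = min(self.tips)
        out: dict[frozenset, frozenset] = {}
        all_tips = set(self.tips)
        for u, v, _ in self.edges():
            side = self._side_labels(u, v)
            if len(side) < 2 or len(all_tips - side) < 2:
                continue
            canonical = side if ref not in side else frozenset(all_tips - side)
            out[canonical] = frozenset({u, v})
        return out

    def edge_sides(self) -> set[frozenset]:
        """Tip sets cut off by every edge (both orientations)."""
        sides: set[frozenset] = set()
        for u, v, _ in self.edges():
            side = self._side_labels(u, v)
            sides.add(side)
            sides.add(frozenset(set(self.tips) - side))
        return sides

    def path_length(self, label_a: str, label_b: str) -> float:
        start = next(n for n, lab in self._labels.items() if lab == label_a)
        goal = next(n for n, lab in self._labels.items() if lab == label_b)
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            if node == goal:
                return dist[node]
            for nbr, length in self._adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    stack.append(nbr)
        raise InputError("tree is disconnected")

    def newick(self, include_support: bool = False) -> str:
        """Serialize rooted at the highest-degree internal node; support values
        (when present and requested) become internal node labels."""
        if not self._adj:
            return ";"
        root = max(self._adj, key=lambda n: (len(self._adj[n]), n))

        def render(node: int, parent: int | None) -> str:
            children = [n for n in sorted(self._adj[node]) if n != parent]
            if not children:
                name = self._labels.get(node, "")
                length = self._adj[parent][node] if parent is not None else 0.0
                return f"{name}:{length:.6g}"
            inner = ",".join(render(c, node) for c in children)
            label = ""
            if include_support and parent is not None:
                sup = self.support.get(frozenset({parent, node}))
                if sup is not None:
                    label = f"{sup:.3g}"
            if parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{self._adj[parent][node]:.6g}"

        return render(root, None) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.warning("negative branch length %.4g in %s clamped to 0", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Join ties are broken by the smallest index pair (row-major scan of the Q
    matrix); negative branch lengths are clamped to zero with a warning.
    """
    n = len(dm.ids)
    if n < 2:
        raise InputError("neighbor joining needs at least 2 taxa")
    tree = Tree()
    nodes = [tree.add_node(label) for label in dm.ids]
    d = dm.values.astype(float).copy()

    if n == 2:
        tree.add_edge(nodes[0], nodes[1], _clamp(d[0, 1], "2-taxon tree"))
        return tree

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum in row-major order = smallest index pair
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = tree.add_node()
        tree.add_edge(parent, nodes[i], _clamp(li, "NJ join"))
        tree.add_edge(parent, nodes[j], _clamp(lj, "NJ join"))
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final 3-star exactly
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    center = tree.add_node()
    tree.add_edge(center, nodes[0], _clamp(0.5 * (d01 + d02 - d12), "final star"))
    tree.add_edge(center, nodes[1], _clamp(0.5 * (d01 + d12 - d02), "final star"))
    tree.add_edge(center, nodes[2], _clamp(0.5 * (d02 + d12 - d01), "final star"))
    return tree


def bootstrap_support(msa: MSA, n_reps: int = 1000, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      correction: str = "p") -> Tree:
    """NJ tree from the full alignment with classical bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of an
    internal bipartition is the fraction of replicate trees containing it.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = nj_tree(p_distance_matrix(msa, correction))
    bipartitions = tree.bipartitions()
    counts = {tip_set: 0 for tip_set in bipartitions}
    L = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_tree = nj_tree(p_distance_matrix(msa.sample_columns(cols), correction))
        rep_sets = set(rep_tree.bipartitions())
        for tip_set in counts:
            if tip_set in rep_sets:
                counts[tip_set] += 1
    tree.support = {bipartitions[tip_set]: counts[tip_set] / n_reps
                    for tip_set in bipartitions}
    return tree


def is_monophyletic(tree: Tree, tip_subset) -> bool:
    """True iff some edge of the unrooted tree bipartitions exactly
    ``tip_subset`` against the rest (trivially true for 0, 1 or all tips)."""
    subset = frozenset(tip_subset)
    tips = set(tree.tips)
    if not subset <= tips:
        raise InputError(f"tips not in tree: {sorted(subset - tips)}")
    if len(subset) in (0, 1, len(tips)):
        return True
    return subset in tree.edge_sides()


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _kmer_vector(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _cosine_distance(a: dict[str, int], b: dict[str, int]) -> float:
    dot = sum(v * b.get(key, 0) for key, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def _profile_score_matrix() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    size = len(_ALPHABET) + 1  # + gap state, which scores 0 against everything
    s = np.zeros((size, size))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            s[i, j] = b62[a, b]
    return s


_S_PROFILE = _profile_score_matrix()
_CHAR_INDEX = {ch: i for i, ch in enumerate(_ALPHABET + GAP)}


def _profile(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    prof = np.zeros((L, len(_CHAR_INDEX)))
    for row in rows:
        for col, ch in enumerate(row):
            prof[col, _CHAR_INDEX[ch]] += 1
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment, linear gap penalty, deterministic
    traceback preferring diagonal, then a column from the first profile."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    cell = pa @ _S_PROFILE @ pb.T  # (la, lb) column-pair scores
    g = _GAP_PENALTY
    score = np.zeros((la + 1, lb + 1))
    score[:, 0] = -g * np.arange(la + 1)
    score[0, :] = -g * np.arange(lb + 1)
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up (A col), 2 left (B col)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, la + 1):
        diag = score[i - 1, :-1] + cell[i - 1, :]
        up = score[i - 1, 1:] - g
        row = score[i]
        prev_left = row[0]
        for j in range(1, lb + 1):
            best = diag[j - 1]
            mv = 0
            if up[j - 1] > best:
                best, mv = up[j - 1], 1
            left = prev_left - g
            if left > best:
                best, mv = left, 2
            row[j] = prev_left = best
            move[i, j] = mv
    # traceback
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = la, lb
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            i -= 1
            j -= 1
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
        elif mv == 1:
            i -= 1
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
        else:
            j -= 1
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def progressive_align(sequences) -> MSA:
    """Progressive multiple alignment.

    ``sequences`` is a list of ``(id, sequence)`` pairs or objects with
    ``protein_id``/``sequence`` attributes.  The merge order comes from
    neighbor-joining agglomeration on 3-mer cosine distances; merge tie-breaks
    use sorted member ids, making the column set invariant to input order.
    """
    pairs = []
    for item in sequences:
        if hasattr(item, "protein_id"):
            pairs.append((item.protein_id, item.sequence))
        else:
            pairs.append((str(item[0]), str(item[1])))
    if len(pairs) < 2:
        raise InputError("progressive alignment needs at least 2 sequences")
    if len({sid for sid, _ in pairs}) != len(pairs):
        raise InputError("duplicate sequence ids")

    k = 3 if min(len(s) for _, s in pairs) >= 3 else 1
    vectors = {sid: _kmer_vector(seq, k) for sid, seq in pairs}

    # clusters: (sorted member ids, rows); distances via NJ-style reduction
    clusters: list[tuple[tuple[str, ...], list[str]]] = [
        ((sid,), [seq]) for sid, seq in sorted(pairs)
    ]
    m = len(clusters)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = _cosine_distance(
                vectors[clusters[i][0][0]], vectors[clusters[j][0][0]])

    while len(clusters) > 1:
        m = len(clusters)
        if m == 2:
            best_pair = (0, 1)
        else:
            r = d.sum(axis=1)
            best_pair = None
            best_key = None
            for i in range(m):
                for j in range(i + 1, m):
                    q = (m - 2) * d[i, j] - r[i] - r[j]
                    key = (q, tuple(sorted(clusters[i][0] + clusters[j][0])))
                    if best_key is None or key < best_key:
                        best_key = key
                        best_pair = (i, j)
        i, j = best_pair
        first, second = clusters[i], clusters[j]
        if second[0][0] < first[0][0]:  # canonical order: smaller min member id first
            first, second = second, first
        rows_a, rows_b = _align_profiles(first[1], second[1])
        merged = (tuple(sorted(first[0] + second[0])), rows_a + rows_b)
        merged_ids_order = first[0] + second[0]
        # rebuild distance matrix with NJ reduction
        keep = [x for x in range(len(clusters)) if x not in (i, j)]
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        new_d = np.zeros((len(keep) + 1, len(keep) + 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = np.maximum(dk[keep], 0.0)
        d = new_d
        clusters = [clusters[x] for x in keep]
        clusters.append((merged[0], merged[1]))
        # keep rows aligned with the sorted member tuple
        row_map = dict(zip(merged_ids_order, merged[1]))
        clusters[-1] = (merged[0], [row_map[sid] for sid in merged[0]])

    member_ids, rows = clusters[0]
    by_id = dict(zip(member_ids, rows))
    order = [sid for sid, _ in pairs]
    return MSA(tuple(order), tuple(by_id[sid] for sid in order))
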