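"""Kimura two-parameter distances, neighbor joining, column bootstrap,
outgroup rooting and Newick output.

Trees are stored as undirected graphs (node -> {neighbour: branch
length}) so that rerooting is a reorientation, not a rebuild. Bootstrap
support lives on bipartitions (splits of the leaf-name set), reported as
integer percent to match the usual figure convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AlignedLocus

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = frozenset("ACGT")


def k2p_distance(row_a: str, row_b: str) -> tuple[float, float, float, int]:
    """Kimura (1980) two-parameter distance between two aligned rows.

    Returns (d, P, Q, comparable_sites) where P and Q are the transition
    and transversion proportions over sites where both rows carry an
    unambiguous base (pairwise deletion). d is NaN on saturation
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0) and when no site is comparable.
    """
    comparable = transitions = transversions = 0
    for a, b in zip(row_a, row_b):
        if a in _VALID and b in _VALID:
            comparable += 1
            if a != b:
                if (a, b) in TRANSITIONS:
                    transitions += 1
                else:
                    transversions += 1
    if comparable == 0:
        return float("nan"), float("nan"), float("nan"), 0
    P = transitions / comparable
    Q = transversions / comparable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan"), P, Q, comparable
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d, P, Q, comparable


def _k2p_all_pairs(mat: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised all-pairs K2P over a (n, L) character matrix.

    Pairwise transition/transversion counts come from indicator-matrix
    products, so the whole matrix costs a handful of matmuls — this is
    what makes 1000-replicate bootstraps on ~100-taxon panels feasible.
    """
    n = mat.shape[0]
    ind = {b: (mat == b).astype(np.float64) for b in "ACGT"}
    valid = sum(ind.values())
    comparable = valid @ valid.T
    cross = {
        (a, b): ind[a] @ ind[b].T for a in "ACGT" for b in "ACGT" if a != b
    }
    ts = sum(cross[p] for p in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")))
    tv = sum(v for k, v in cross.items()
             if k not in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")))
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(comparable > 0, ts / comparable, np.nan)
        Q = np.where(comparable > 0, tv / comparable, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
            - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
            np.nan,
        )
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(Q, 0.0)
    return d, P, Q, comparable.astype(int)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    comparable_sites: np.ndarray
    n_undefined: int = 0

    @property
    def size(self) -> int:
        return len(self.ids)


def k2p_matrix(
    locus: AlignedLocus,
    members: list[str] | None = None,
    saturation_fallback: str = "max_scaled",
) -> DistanceMatrix:
    """All-pairs K2P matrix with saturation handling.

    ``saturation_fallback="max_scaled"`` substitutes undefined entries
    with 1.05 x the maximum defined distance (with a warning);
    ``"error"`` raises instead; ``"nan"`` leaves them undefined.
    """
    ids = members if members is not None else list(locus.accession_ids)
    mat = locus.subset(ids).matrix()
    d, P, Q, comp = _k2p_all_pairs(mat)
    undefined = [
        (i, j)
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if math.isnan(d[i, j])
    ]
    if undefined:
        if saturation_fallback == "error":
            raise ValueError(
                f"{locus.locus_id}: {len(undefined)} saturated/undefined "
                "K2P entries; mask the offending rows"
            )
        if saturation_fallback == "max_scaled":
            finite = d[np.isfinite(d)]
            if finite.size == 0:
                raise ValueError(
                    f"{locus.locus_id}: every pairwise distance is undefined"
                )
            fallback = float(finite.max()) * 1.05
            warnings.warn(
                f"{locus.locus_id}: {len(undefined)} saturated K2P entries "
                f"replaced with {fallback:.4f}"
            )
            for i, j in undefined:
                d[i, j] = d[j, i] = fallback
    return DistanceMatrix(ids, d, P, Q, comp, len(undefined))


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class Tree:
    """Phylogenetic tree as an undirected weighted graph.

    ``leaves`` maps node ids to leaf names; ``display_root`` is the node
    used to orient Newick output (the actual root only when ``rooted``).
    ``support`` maps bipartitions (canonical frozenset of leaf names) to
    integer percent.
    """

    adj: dict[int, dict[int, float]]
    leaves: dict[int, str]
    display_root: int
    rooted: bool = False
    support: dict[frozenset, int] = field(default_factory=dict)
    dropped_replicates: int = 0

    @property
    def leaf_names(self) -> set[str]:
        return set(self.leaves.values())

    def _side_leaves(self, parent: int, child: int) -> set[str]:
        """Leaf names on the ``child`` side of edge (parent, child)."""
        out: set[str] = set()
        stack = [(parent, child)]
        while stack:
            prev, node = stack.pop()
            if node in self.leaves:
                out.add(self.leaves[node])
            for nbr in self.adj[node]:
                if nbr != prev:
                    stack.append((node, nbr))
        return out

    def _canonical(self, side: set[str]) -> frozenset:
        anchor = min(self.leaf_names)
        if anchor in side:
            side = self.leaf_names - side
        return frozenset(side)

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits (both sides >= 2 leaves), canonicalised."""
        out = set()
        for u, v in self.edges():
            side = self._side_leaves(u, v)
            if 2 <= len(side) <= len(self.leaf_names) - 2:
                out.add(self._canonical(side))
        return out

    def total_length(self) -> float:
        return sum(l for _, nbrs in self.adj.items() for l in nbrs.values()) / 2.0

    def newick(self) -> str:
        def render(prev: int, node: int) -> str:
            if node in self.leaves:
                return self.leaves[node]
            parts = [
                render(node, nbr) + f":{self.adj[node][nbr]:.6f}"
                for nbr in sorted(self.adj[node])
                if nbr != prev
            ]
            label = ""
            if prev is not None:
                side = self._side_leaves(prev, node)
                key = self._canonical(side)
                if key in self.support:
                    label = str(self.support[key])
            return "(" + ",".join(parts) + ")" + label

        root = self.display_root
        if root in self.leaves:  # orient from its neighbour instead
            root = next(iter(self.adj[root]))
        return render(None, root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    Ties in the Q-criterion are broken by lowest (row, column) index for
    cross-platform determinism. Negative branch-length estimates are set
    to zero with the deficit moved to the sibling branch.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(matrix.d).any():
        raise ValueError("distance matrix contains undefined entries; mask first")

    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaves: dict[int, str] = {i: name for i, name in enumerate(matrix.ids)}
    next_id = n
    active: list[int] = list(range(n))
    D = matrix.d.astype(float).copy()

    def connect(a, b, length):
        length = max(length, 0.0)
        adj[a][b] = length
        adj[b][a] = length

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        # first flat index at the minimum == lowest (row, column) pair
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        a, b = active[i], active[j]
        dab = float(D[i, j])
        la = 0.5 * dab + (r[i] - r[j]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        u = next_id
        next_id += 1
        adj[u] = {}
        connect(u, a, la)
        connect(u, b, lb)
        dnew = 0.5 * (D[i] + D[j] - dab)
        keep = [t for t in range(m) if t not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        active = [active[t] for t in keep] + [u]

    if len(active) == 3:
        a, b, c = active
        u = next_id
        adj[u] = {}
        connect(u, a, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
        connect(u, b, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
        connect(u, c, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
        root = u
    else:  # exactly 2 left
        a, b = active
        connect(a, b, float(D[0, 1]))
        root = a

    return Tree(adj=adj, leaves=leaves, display_root=root, rooted=False)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    locus: AlignedLocus,
    members: list[str] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    saturation_fallback: str = "max_scaled",
) -> Tree:
    """NJ tree with column-bootstrap bipartition support.

    Columns are resampled with replacement per replicate; the support of
    an internal edge is the percentage of replicate trees containing the
    same bipartition. Replicates whose distance matrix cannot be computed
    at all are dropped and counted in ``dropped_replicates``. The whole
    procedure is deterministic for a fixed seed.
    """
    ids = members if members is not None else list(locus.accession_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        main = neighbor_joining(k2p_matrix(locus, ids, saturation_fallback))
    rng = np.random.default_rng(seed)
    mat = locus.subset(ids).matrix()
    L = mat.shape[1]
    counts: dict[frozenset, int] = {}
    dropped = 0
    valid_reps = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        d, P, Q, comp = _k2p_all_pairs(mat[:, cols])
        nan_off_diag = np.isnan(d)
        np.fill_diagonal(nan_off_diag, False)
        n_undef = int(nan_off_diag.sum() // 2)
        if n_undef:
            finite = d[np.isfinite(d)]
            off = finite[finite > 0]
            if saturation_fallback == "max_scaled" and off.size:
                d[nan_off_diag] = float(off.max()) * 1.05
            else:
                dropped += 1
                continue
        rep_dm = DistanceMatrix(list(ids), d, P, Q, comp, n_undef)
        try:
            rep_tree = neighbor_joining(rep_dm)
        except ValueError:
            dropped += 1
            continue
        valid_reps += 1
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    if valid_reps > 0:
        for bp in main.bipartitions():
            main.support[bp] = round(100.0 * counts.get(bp, 0) / valid_reps)
    main.dropped_replicates = dropped
    return main


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: Tree, outgroup_ids: list[str]) -> Tree:
    """Root the tree on the edge separating the outgroup from the rest.

    If the outgroups are not monophyletic, the root goes on the edge
    maximising the outgroup count (then minimising the ingroup count) on
    the outgroup side, with a warning.
    """
    og = set(outgroup_ids)
    missing = og - tree.leaf_names
    if missing:
        raise ValueError(f"outgroup id(s) not in tree: {sorted(missing)}")

    best = None
    best_score = None
    perfect = False
    for u, v in tree.edges():
        side = tree._side_leaves(u, v)
        for parent, child, og_side in ((u, v, side), (v, u, tree.leaf_names - side)):
            n_og = len(og & og_side)
            n_in = len(og_side - og)
            if n_og == 0:
                continue
            score = (n_og, -n_in)
            if best_score is None or score > best_score:
                best_score = score
                best = (parent, child, og_side)
            if og_side == og:
                perfect = True
    parent, child, og_side = best
    if not perfect:
        warnings.warn(
            "outgroup is not monophyletic; rooting on the edge that best "
            "separates it"
        )

    length = tree.adj[parent][child]
    root = max(max(tree.adj), max(tree.leaves)) + 1
    adj = {k: dict(v) for k, v in tree.adj.items()}
    del adj[parent][child]
    del adj[child][parent]
    adj[root] = {parent: length / 2.0, child: length / 2.0}
    adj[parent][root] = length / 2.0
    adj[child][root] = length / 2.0
    return Tree(
        adj=adj,
        leaves=dict(tree.leaves),
        display_root=root,
        rooted=True,
        support=dict(tree.support),
        dropped_replicates=tree.dropped_replicates,
    )
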