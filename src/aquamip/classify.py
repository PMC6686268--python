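"""Subfamily/subgroup assignment by distance-based placement.

Queries are threaded into the labelled reference alignment, pairwise
p-distances (mismatches over shared non-gap columns) are computed, a
neighbor-joining tree is built, and the query's subfamily is read off its
sister group.  Support comes from bootstrap resampling of alignment
columns.  PIP calls are refined by the N-terminal tail rule: PIP1 tails
are longer than PIP2 tails, with the cutoff calibrated on the panel.

Distances are plain p-distances rather than model-corrected distances:
at family-level divergence the topology is robust and no rate matrix
needs shipping; a gamma correction can be layered on the matrix by the
caller if desired.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .physchem import predict_tm_segments
from .residue_profile import ReferencePanel, thread_query
from .seqio import ProteinRecord, make_aligner


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with leaf ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


@dataclass
class Tree:
    """An unrooted tree as a Newick string, with skbio-backed traversal."""

    newick: str

    def to_skbio(self):
        from skbio import TreeNode

        # convert_underscores=False keeps leaf ids verbatim
        return TreeNode.read(io.StringIO(self.newick), convert_underscores=False)

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.to_skbio().tips()}


@dataclass(frozen=True)
class SubfamilyCall:
    subfamily: str
    subgroup: str
    nearest_refs: tuple[tuple[str, float], ...]
    support: float | None = None
    flags: tuple[str, ...] = ()


def _encode(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must share one length")
    arr = np.array([list(alignment[i]) for i in ids])
    return ids, arr


def build_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """p-distance with pairwise deletion of gap columns.

    For each pair, columns where either row is gapped are dropped;
    distance = mismatches / compared columns.  A pair sharing zero
    comparable columns is an error naming the pair.
    """
    ids, arr = _encode(alignment)
    non_gap = arr != "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = non_gap[i] & non_gap[j]
            ncols = int(both.sum())
            if ncols == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / ncols
    return DistanceMatrix(ids, d)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with a declared deterministic tie-break.

    The pair minimising Q is chosen; ties break to the lexicographically
    smallest index pair.  Negative branch lengths are clamped to zero.
    On additive matrices the generating topology and exact branch lengths
    are recovered.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # working copies; node "labels" are newick fragments
    dist = d.matrix.astype(float).copy()
    labels = list(d.ids)
    frags = [f"{name}" for name in labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(x, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        ai, aj = divmod(int(flat), m)
        # deterministic tie-break: smallest (i, j) with i < j
        best = q[ai, aj]
        ties = np.argwhere(np.isclose(q, best, rtol=0, atol=1e-12))
        pairs = sorted((min(i, j), max(i, j)) for i, j in ties)
        ai, aj = pairs[0]
        dij = sub[ai, aj]
        li = clamp(dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2)))
        lj = clamp(dij - li)
        gi, gj = active[ai], active[aj]
        new_frag = f"({frags[gi]}:{li:.10g},{frags[gj]}:{lj:.10g})"
        # distances from the new node to the remaining taxa
        new_row = np.zeros(dist.shape[0] + 1)
        for ak in range(m):
            if ak in (ai, aj):
                continue
            gk = active[ak]
            new_row[gk] = (dist[gi, gk] + dist[gj, gk] - dij) / 2.0
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :] = new_row
        dist[:, -1] = new_row
        frags.append(new_frag)
        new_idx = dist.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [new_idx]

    # final star join of the last three nodes
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = clamp((dab + dac - dbc) / 2.0)
    lb = clamp((dab + dbc - dac) / 2.0)
    lc = clamp((dac + dbc - dab) / 2.0)
    newick = f"({frags[a]}:{la:.10g},{frags[b]}:{lb:.10g},{frags[c]}:{lc:.10g});"
    return Tree(newick)


def _sister_subfamily(tree: Tree, query_id: str, labels: dict[str, str]) -> str:
    """Majority subfamily among the query's sister group in the NJ tree."""
    t = tree.to_skbio()
    tip = t.find(query_id)
    node = tip.parent
    sisters: list[str] = []
    while node is not None and not sisters:
        sisters = [x.name for x in node.tips() if x.name != query_id]
        node = node.parent
    counts: dict[str, int] = {}
    for name in sisters:
        fam = labels.get(name)
        if fam:
            counts[fam] = counts.get(fam, 0) + 1
    if not counts:
        return "unclassified"
    top = max(counts.values())
    winners = sorted(f for f, c in counts.items() if c == top)
    return winners[0]


def _pdist_to_refs(qrow: np.ndarray, ref_rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
    if cols is not None:
        qrow = qrow[cols]
        ref_rows = ref_rows[:, cols]
    q_non = qrow != "-"
    out = np.empty(len(ref_rows))
    for i, row in enumerate(ref_rows):
        both = q_non & (row != "-")
        ncols = int(both.sum())
        out[i] = np.nan if ncols == 0 else float((qrow[both] != row[both]).sum()) / ncols
    return out


def pip1_vs_pip2(
    query: ProteinRecord,
    tm_segments,
    panel: ReferencePanel,
    cutoff: float | None = None,
    _cache: dict = {},
) -> tuple[str, tuple[str, ...]]:
    """PIP1 vs PIP2 by N-terminal tail length before the first TM segment.

    The cutoff defaults to the midpoint between the panel's mean PIP1 and
    PIP2 tail lengths (computed with the same TM predictor).  Tail
    strictly above the cutoff is PIP1; a tail exactly at the cutoff is
    PIP2 by declared tie-break, flagged.  Returns (subgroup, flags).
    """
    key = id(panel)
    if cutoff is None and key not in _cache:
        tails: dict[str, list[int]] = {"PIP1": [], "PIP2": []}
        for m in panel.members:
            if m.subgroup in tails:
                segs = predict_tm_segments(m.sequence)
                if segs:
                    tails[m.subgroup].append(segs[0].start)
        if not tails["PIP1"] or not tails["PIP2"]:
            raise ValueError("panel lacks PIP1/PIP2 members for tail calibration")
        _cache[key] = (float(np.mean(tails["PIP1"])) + float(np.mean(tails["PIP2"]))) / 2.0
    if cutoff is None:
        cutoff = _cache[key]
    if not tm_segments:
        return "", ("no_tm_segments",)
    tail = tm_segments[0].start
    if tail > cutoff:
        return "PIP1", ()
    if tail == cutoff:
        return "PIP2", ("tail_at_cutoff",)
    return "PIP2", ()


def assign_subfamily(
    query: ProteinRecord,
    panel: ReferencePanel,
    bootstrap_n: int = 0,
    seed: int = 0,
    support_threshold: float = 0.7,
    min_score: float = 50.0,
    tm_segments=None,
    aligner=None,
) -> SubfamilyCall:
    """Place the query against the panel and call subfamily + subgroup.

    The subfamily is the label of the query's sister group in the NJ tree
    over the threaded alignment (majority over ``bootstrap_n`` column
    resamples when positive); the subgroup comes from the nearest
    reference, refined by the PIP1/PIP2 tail rule when TM segments are
    supplied.  A low-scoring thread yields ``unclassified``.
    """
    if aligner is None:
        aligner = make_aligner(free_end_gaps=True)
    qrow, best_id, score = thread_query(query, panel, aligner)
    if score < min_score:
        return SubfamilyCall("unclassified", "", (), None, ("no_alignment",))
    alignment = {m.id: m.aligned_seq for m in panel.members}
    alignment[query.id] = qrow
    labels = {m.id: m.subfamily for m in panel.members}

    ids, arr = _encode(alignment)
    qidx = ids.index(query.id)
    ref_idx = [i for i in range(len(ids)) if i != qidx]
    dists = _pdist_to_refs(arr[qidx], arr[ref_idx])
    order = np.argsort(dists, kind="stable")
    nearest = tuple(
        (ids[ref_idx[k]], round(float(dists[k]), 6)) for k in order[:5]
    )

    d = build_distance_matrix(alignment)
    call = _sister_subfamily(nj_tree(d), query.id, labels)

    support = None
    flags: list[str] = []
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        L = arr.shape[1]
        votes: dict[str, int] = {}
        for _ in range(bootstrap_n):
            cols = rng.integers(0, L, size=L)
            sub = {i: "".join(arr[k][cols]) for k, i in enumerate(ids)}
            try:
                fam = _sister_subfamily(nj_tree(build_distance_matrix(sub)), query.id, labels)
            except ValueError:
                continue
            votes[fam] = votes.get(fam, 0) + 1
        if votes:
            top = max(votes.values())
            call = sorted(f for f, c in votes.items() if c == top)[0]
            support = top / bootstrap_n
            if support < support_threshold:
                flags.append("low_support")

    nearest_member = panel.get(nearest[0][0])
    subgroup = nearest_member.subgroup
    if call == "PIP":
        if tm_segments is None:
            tm_segments = predict_tm_segments(query.sequence)
        refined, pip_flags = pip1_vs_pip2(query, tm_segments, panel)
        if refined:
            subgroup = refined
        flags.extend(pip_flags)
    elif not subgroup.startswith(call):
        # nearest reference disagrees with the tree call; keep tree call,
        # pick nearest reference within the called subfamily
        within = [
            (mid, dv) for mid, dv in nearest if panel.get(mid).subfamily == call
        ]
        subgroup = panel.get(within[0][0]).subgroup if within else ""
    return SubfamilyCall(call, subgroup, nearest, support, tuple(flags))


__all__ = [
    "DistanceMatrix",
    "SubfamilyCall",
    "Tree",
    "assign_subfamily",
    "build_distance_matrix",
    "nj_tree",
    "pip1_vs_pip2",
]
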