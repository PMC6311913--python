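"""Secondary-structure graphs and their 24 topological descriptors.

A hairpin's dot-bracket structure is converted to a simple undirected graph:
one node per nucleotide, backbone edges {i, i+1}, plus one edge per base
pair. The 24 descriptors summarise that graph at node, edge and whole-graph
level (A- prefixes are means over nodes/edges, V-/Var- are population
variances, N- are counts).

When no externally folded structure is supplied, :func:`fold_fallback`
predicts one by base-pair maximisation (Nussinov dynamic programming over
Watson-Crick and GU wobble pairs, minimum hairpin loop of 3 unpaired bases).
This is a combinatorial fallback, not a thermodynamic (minimum free energy)
fold; users wanting MFE structures supply their own folder's output.
"""

from __future__ import annotations

import logging

import igraph as ig
import numpy as np

from .io_formats import DotBracket, RnaRecord

logger = logging.getLogger(__name__)

#: Pairs allowed by the fallback folder: Watson-Crick plus GU wobble.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_LOOP = 3

#: Frozen 24-name layout of the network block.
NETWORK_FEATURE_NAMES: list[str] = [
    "net.A-degree",
    "net.V-degree",
    "net.A-closeness",
    "net.A-Nbetweenness",
    "net.Var-Vbetweenness",
    "net.A-Ebetweenness",
    "net.A-coreness",
    "net.V-coreness",
    "net.A-Burts",
    "net.A-hubscore",
    "net.A-cocitation",
    "net.A-bibliographic",
    "net.A-localtrans",
    "net.transitivity",
    "net.Densith",
    "net.Modularity",
    "net.diameter",
    "net.girth",
    "net.avgpathlen",
    "net.N-articulation",
    "net.N-motif3",
    "net.N-motif4",
    "net.A-eccentricity",
    "net.max-coreness",
]
assert len(NETWORK_FEATURE_NAMES) == 24


# ---------------------------------------------------------------------------
# Fallback folding (Nussinov base-pair maximisation)
# ---------------------------------------------------------------------------

def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def fold_fallback(seq: RnaRecord) -> DotBracket:
    """Maximum base-pair structure by Nussinov dynamic programming.

    Deterministic traceback: at each subproblem the unpaired-i branch is taken
    unless pairing strictly increases the count, and the smallest pairing
    partner k wins ties. The result always respects the minimum-loop
    constraint and is balanced by construction.
    """
    s = seq.sequence
    L = len(s)
    # N[i][j] = max pairs in s[i..j]
    N = np.zeros((L, L), dtype=np.int32)
    for span in range(MIN_LOOP + 1, L):
        for i in range(L - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = N[i + 1, k - 1] if k - 1 > i + 1 else 0
                    rest = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            N[i, j] = best
    structure = ["."] * L
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        if N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _can_pair(s[i], s[k]):
                inner = N[i + 1, k - 1] if k - 1 > i + 1 else 0
                rest = N[k + 1, j] if k + 1 <= j else 0
                if N[i, j] == 1 + inner + rest:
                    structure[i] = "("
                    structure[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return DotBracket("".join(structure))


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(seq: RnaRecord, db: DotBracket) -> ig.Graph:
    """Simple undirected nucleotide graph: backbone edges plus base pairs."""
    L = len(seq)
    if len(db) != L:
        raise ValueError(
            f"structure length {len(db)} != sequence length {L} for {seq.id!r}"
        )
    edges = {(i, i + 1) for i in range(L - 1)}
    edges |= set(db.pairs())  # merged with backbone if ever adjacent
    g = ig.Graph(n=L, edges=sorted(edges), directed=False)
    return g


# ---------------------------------------------------------------------------
# Topological descriptors
# ---------------------------------------------------------------------------

def _var(x) -> float:
    return float(np.var(np.asarray(x, dtype=float)))


def _mean(x) -> float:
    return float(np.mean(np.asarray(x, dtype=float)))


def _pair_mean(matrix: list[list[int]]) -> float:
    """Mean over ordered node pairs i != j (diagonal entries are zero)."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n < 2:
        return 0.0
    return float(m.sum() / (n * (n - 1)))


def _hub_scores(g: ig.Graph) -> np.ndarray:
    """Hub scores, scaled to max 1.

    For an undirected graph the hub score reduces to eigenvector centrality
    (the Perron vector of the adjacency matrix), which is unique on any
    connected graph; the A.A^T eigenproblem behind the directed definition
    is degenerate on bipartite graphs (e.g. unpaired sequences give path
    graphs). Computed with a dense symmetric eigensolver so repeated calls
    are bit-identical (iterative solvers with random starts are not).
    """
    A = np.asarray(g.get_adjacency().data, dtype=float)
    w, V = np.linalg.eigh(A)
    v = np.abs(V[:, int(np.argmax(w))])
    return v / v.max()


def _motif_count(g: ig.Graph, size: int) -> float:
    """Number of connected induced subgraphs on `size` nodes."""
    counts = np.asarray(g.motifs_randesu(size=size), dtype=float)
    return float(np.nansum(counts))


def network_block(g: ig.Graph) -> np.ndarray:
    """The 24 descriptors in the frozen :data:`NETWORK_FEATURE_NAMES` order."""
    if not g.is_connected():
        raise ValueError("structure graph must be connected")
    betweenness = g.betweenness()
    coreness = g.coreness()
    girth = g.girth()
    communities = g.community_fastgreedy().as_clustering()
    values = [
        _mean(g.degree()),
        _var(g.degree()),
        _mean(g.closeness()),
        _mean(betweenness),
        _var(betweenness),
        _mean(g.edge_betweenness()),
        _mean(coreness),
        _var(coreness),
        _mean(g.constraint()),
        _mean(_hub_scores(g)),
        _pair_mean(g.cocitation()),
        _pair_mean(g.bibcoupling()),
        _mean(g.transitivity_local_undirected(mode="zero")),
        float(g.transitivity_undirected(mode="zero")),
        float(g.density()),
        float(g.modularity(communities.membership)),
        float(g.diameter()),
        float(girth) if np.isfinite(girth) else 0.0,  # acyclic graph -> 0
        float(g.average_path_length()),
        float(len(g.articulation_points())),
        _motif_count(g, 3),
        _motif_count(g, 4),
        _mean(g.eccentricity()),
        float(max(coreness)),
    ]
    out = np.asarray(values, dtype=float)
    assert out.shape == (24,)
    return out


def structure_block(
    seq: RnaRecord, db: DotBracket | None = None
) -> np.ndarray:
    """Network block for a sequence; folds with the fallback if db is None."""
    if db is None:
        logger.debug("no structure supplied for %s; using fallback fold", seq.id)
        db = fold_fallback(seq)
    return network_block(build_graph(seq, db))
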