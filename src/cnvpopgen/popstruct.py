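"""Population structure from biallelic deletion markers.

Operates on the "12"/"22"-coded deletion genotypes produced by
:mod:`cnvpopgen.calling`:

* identity-by-state genetic distance D = 1 - (IBS2 + 0.5*IBS1)/N,
* method-of-moments relatedness (pi-hat) and greedy relative removal,
* classical (Torgerson) multidimensional scaling,
* neighbor-joining trees (Saitou-Nei) with Newick output,
* hierarchical clustering of mean-LRR profiles,
* maximum-likelihood admixture (EM on the standard mixture likelihood
  with cluster-specific deletion frequencies).

Because only two genotype codes exist, a pair of samples shares at least
one allele (the "2") at every marker, so D is bounded above by 0.5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .calling import GenotypeMatrix
from .errors import InputError

__all__ = [
    "DistanceMatrix", "AdmixtureFit", "Tree",
    "pihat", "pihat_matrix", "ibd_probs", "relatedness_filter", "ibs_distance",
    "mds", "nj_tree", "hier_cluster", "dendrogram_to_newick",
    "admixture_fit", "align_q_to_truth",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity in [0, 1] with a zero diagonal."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise InputError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal is not zero")
        if self.D.min() < -1e-12 or self.D.max() > 1 + 1e-12:
            raise InputError("distance entries must lie in [0, 1]")


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def is_leaf(self):
        return not self.children


@dataclass
class Tree:
    """Unrooted tree over sample ids, serializable to Newick.

    Internally anchored at an arbitrary internal node; branch lengths are
    non-negative (negative neighbor-joining estimates are clamped to 0 and
    recorded in ``clamped``).
    """

    root: _Node
    ids: list[str]
    clamped: list[tuple[str, str]] = field(default_factory=list)

    def leaf_names(self) -> list[str]:
        out = []

        def walk(node):
            if node.is_leaf():
                out.append(node.name)
            for ch, _ in node.children:
                walk(ch)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf():
                return str(node.name)
            inner = ",".join(f"{fmt(ch)}:{bl:.10g}" for ch, bl in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix (tests NJ additivity recovery)."""
        dists = {}

        def walk(node, acc):
            if node.is_leaf():
                dists[node.name] = acc
            for ch, bl in node.children:
                walk(ch, acc + bl)

        # distances via common traversal from every leaf: do full pairs by
        # rooting at each leaf's path from the anchor
        # simpler: compute node->leaf distance map per leaf via DFS from root
        # then combine through lowest common ancestor handling; easiest is to
        # run Dijkstra-like traversal on the undirected tree.
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def build(node):
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf():
                names[nid] = node.name
            for ch, bl in node.children:
                cid = id(ch)
                adj[nid].append((cid, bl))
                adj.setdefault(cid, []).append((nid, bl))
                build(ch)

        build(self.root)
        leaf_ids = {v: k for k, v in names.items()}
        n = len(self.ids)
        M = np.zeros((n, n))
        for i, a in enumerate(self.ids):
            # BFS from leaf a
            start = leaf_ids[a]
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, b in enumerate(self.ids):
                M[i, j] = dist[leaf_ids[b]]
        return pd.DataFrame(M, index=self.ids, columns=self.ids)


@dataclass
class AdmixtureFit:
    """Result of the EM admixture fit."""

    K: int
    Q: pd.DataFrame  # samples x K, rows on the simplex
    F: pd.DataFrame  # K x markers, cluster deletion frequencies
    loglik_trace: np.ndarray
    seed: int
    converged: bool

    def __post_init__(self):
        rows = self.Q.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise InputError("Q rows must sum to 1")
        f = self.F.to_numpy()
        if f.min() < -1e-12 or f.max() > 1 + 1e-12:
            raise InputError("F entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# relatedness


def _match_expectations(q: np.ndarray):
    """Per-locus code-match probabilities under IBD 0/1/2.

    ``q`` is the deletion-allele frequency. A sample shows code "12" when it
    carries >= 1 deletion allele (dominant carrier model; carrier frequency
    alpha = 1 - (1-q)^2). Conditioning on the number of alleles shared
    identical by descent:

    * IBD=0: genotypes independent, match = alpha^2 + (1-alpha)^2
    * IBD=1: one shared allele, match = (1-q)^3 + 1 - 2(1-q)^2 + (1-q)^3
    * IBD=2: genotypes identical, match = 1
    """
    one_q = 1.0 - q
    alpha = 1.0 - one_q**2
    m0 = alpha**2 + (1.0 - alpha) ** 2
    m1 = 1.0 - 2.0 * one_q**2 + 2.0 * one_q**3
    return m0, m1


def _prep_freqs(G: GenotypeMatrix):
    X = G.dosage.astype(float)
    alpha = X.mean(axis=0)
    poly = (alpha > 0) & (alpha < 1)
    if not poly.any():
        raise InputError("all markers are monomorphic; pi-hat is undefined")
    q = 1.0 - np.sqrt(1.0 - alpha[poly])
    return X[:, poly], q


def _solve_pihat(match: np.ndarray, m0: np.ndarray, m1: np.ndarray):
    """Moment estimate of the IBD-sharing coefficient for one or many pairs.

    ``match`` has shape (..., L). The match probability at a locus is
    m0 + theta*(1 - m0) where theta = P1/2 + P2 is the overall
    IBD-sharing coefficient (pi-hat): a weighted least-squares fit along
    the full-sharing direction gives theta directly, clamped to [0, 1].
    The two observable codes cannot statistically separate P1 from P2 for
    intermediate relatives (the IBD1/IBD2 moment directions are nearly
    collinear), so pi-hat is estimated directly and :func:`ibd_probs`
    reports the boundary-consistent decomposition.
    """
    w = 1.0 - m0
    theta = ((match - m0) @ w) / (w @ w)
    return np.clip(theta, 0.0, 1.0)


def ibd_probs(theta: float) -> tuple[float, float, float]:
    """Clamped, renormalized (P0, P1, P2) consistent with pi-hat = theta.

    theta <= 1/2 maps to (1-2theta, 2theta, 0); theta > 1/2 to
    (0, 2-2theta, 2theta-1). In both cases P1/2 + P2 = theta and the
    probabilities sum to 1 and lie in [0, 1].
    """
    theta = min(1.0, max(0.0, float(theta)))
    p2 = max(0.0, 2 * theta - 1.0)
    p1 = 2 * (theta - p2)
    return (1.0 - p1 - p2, p1, p2)


def pihat(g1: np.ndarray, g2: np.ndarray, freqs: np.ndarray) -> float:
    """Method-of-moments IBD-sharing estimate between two samples.

    ``g1``/``g2`` are deletion-presence dosage vectors (1 = "12", 0 = "22");
    ``freqs`` are per-marker deletion-allele frequencies. Per-locus
    code-match indicators are compared with their allele-frequency
    expectations under 0/1/2 alleles shared identical by descent, yielding
    the sharing coefficient pi-hat = P(IBD=1)/2 + P(IBD=2) (clamped to
    [0, 1]); :func:`ibd_probs` gives the matching state decomposition.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    q = np.asarray(freqs, float)
    poly = (q > 0) & (q < 1)
    if not poly.any():
        raise InputError("all markers are monomorphic; pi-hat is undefined")
    g1, g2, q = g1[poly], g2[poly], q[poly]
    m0, m1 = _match_expectations(q)
    match = (g1 == g2).astype(float)
    return float(_solve_pihat(match, m0, m1))


def pihat_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs pi-hat with allele frequencies estimated from the cohort."""
    X, q = _prep_freqs(G)
    n = X.shape[0]
    m0, m1 = _match_expectations(q)
    out = np.zeros((n, n))
    for i in range(n):
        match = (X[i + 1:] == X[i]).astype(float)  # (n-i-1, L)
        if match.size:
            out[i, i + 1:] = _solve_pihat(match, m0, m1)
    out = out + out.T
    return pd.DataFrame(out, index=G.samples, columns=G.samples)


def relatedness_filter(G: GenotypeMatrix, samplesheet: pd.DataFrame | None = None,
                       max_pihat: float = 0.4,
                       exclude: list[str] | None = None) -> list[str]:
    """Greedy removal of relatives until no pair exceeds ``max_pihat``.

    While any retained pair has pi-hat > ``max_pihat``, the member of the
    worst (highest pi-hat) pair with the larger mean pi-hat to all other
    retained samples is removed; ties break toward the later sample in the
    input order, making the procedure deterministic. ``exclude`` lists
    samples removed a priori (e.g. known from pedigree records).
    """
    P = pihat_matrix(G).to_numpy()
    ids = list(G.samples)
    active = [i for i, s in enumerate(ids) if not (exclude and s in exclude)]
    while True:
        sub = P[np.ix_(active, active)]
        np.fill_diagonal(sub, -np.inf)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] <= max_pihat:
            break
        a, b = active[worst[0]], active[worst[1]]
        others_a = [i for i in active if i != a and i != b]
        mean_a = P[a, others_a].mean() if others_a else 0.0
        mean_b = P[b, others_a].mean() if others_a else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # deterministic tie-break: later sample leaves
        active.remove(drop)
    return [ids[i] for i in active]


# ---------------------------------------------------------------------------
# distance / embedding


def ibs_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise genetic distance D = 1 - (IBS2 + 0.5*IBS1)/N.

    IBS2 counts loci where the pair shares both alleles (identical codes);
    IBS1 counts loci sharing exactly one ("12" vs "22" share the "2");
    N is the marker count. With codes restricted to {"12", "22"} the
    maximum attainable distance is 0.5.
    """
    if G.n_markers == 0:
        raise InputError("cannot compute IBS distance with zero markers")
    X = G.dosage.astype(float)
    n, N = X.shape
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)  # pairwise IBS1 count
    ibs2 = N - diff
    D = 1.0 - (ibs2 + 0.5 * diff) / N
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(G.samples), D)


def mds(D: DistanceMatrix, dims: int = 4) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers -D^2/2, takes the top ``dims`` eigenpairs with positive
    eigenvalues and scales eigenvectors by sqrt(eigenvalue). If fewer than
    ``dims`` positive eigenvalues exist, the available coordinates are
    returned with a warning. Each coordinate's sign is fixed so that its
    largest-magnitude loading is positive.
    """
    n = len(D.ids)
    if not 1 <= dims < n:
        raise InputError(f"dims must satisfy 1 <= dims < n={n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > max(1e-12, 1e-9 * abs(w[0]) if w.size else 0)
    avail = int(min(dims, pos.sum()))
    if avail < dims:
        import warnings

        warnings.warn(f"only {avail} positive eigenvalues; returning {avail} dimensions")
    coords = V[:, :avail] * np.sqrt(w[:avail])
    for k in range(avail):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(coords, index=D.ids, columns=[f"C{k + 1}" for k in range(avail)])


# ---------------------------------------------------------------------------
# trees


def nj_tree(D: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei) on a pairwise distance matrix.

    Uses the standard Q-criterion; ties break toward the smallest (i, j)
    index pair in the current join order. Negative branch-length estimates
    are clamped to 0 and recorded. The returned tree is unrooted
    (anchored at the final 3-way join).
    """
    n = len(D.ids)
    if n < 3:
        raise InputError("neighbor joining needs >= 3 taxa")
    d = D.D.astype(float).copy()
    nodes: list[_Node] = [_Node(name=s) for s in D.ids]
    labels = [s for s in D.ids]
    clamped: list[tuple[str, str]] = []

    def clamp(bl, a, b):
        if bl < 0:
            clamped.append((a, b))
            return 0.0
        return bl

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Qc = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Qc, np.inf)
        # minimum Q entry; ties break toward the smallest (i, j) pair
        bmin = Qc.min()
        cand = np.argwhere(Qc <= bmin + 1e-12)
        cand = cand[cand[:, 0] < cand[:, 1]]
        i, j = cand[np.lexsort((cand[:, 1], cand[:, 0]))[0]]
        i, j = int(i), int(j)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li = clamp(li, labels[i], labels[j])
        lj = clamp(lj, labels[j], labels[i])
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [f"internal_{len(clamped)}_{m}"]

    # final 3-way join: three-point formulas
    (a, b, c) = range(3)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la = clamp(la, labels[a], "center")
    lb = clamp(lb, labels[b], "center")
    lc = clamp(lc, labels[c], "center")
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Tree(root=root, ids=list(D.ids), clamped=clamped)


def hier_cluster(region_means: pd.DataFrame, linkage_method: str = "average") -> np.ndarray:
    """Agglomerative clustering of per-sample mean-LRR profiles.

    Euclidean distance, average linkage by default. Returns the scipy
    linkage matrix (merge list with heights).
    """
    X = region_means.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise InputError("region mean matrix contains non-finite values")
    return linkage(pdist(X), method=linkage_method)


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix to Newick with height-derived lengths."""
    tree = to_tree(Z)

    def fmt(node, parent_height):
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.10g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{bl:.10g}"

    inner = f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)})"
    return inner + ";"


# ---------------------------------------------------------------------------
# admixture


def _em_once(X: np.ndarray, K: int, c: int, rng: np.random.Generator,
             max_iter: int, tol: float):
    n, L = X.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, L))
    eps = 1e-12
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        P = Q @ F  # (n, L) mixture deletion frequency
        P = np.clip(P, eps, 1 - eps)
        ll = float(np.sum(X * np.log(P) + (c - X) * np.log1p(-P)))
        trace.append(ll)
        # responsibilities
        # A[i,l,k] = Q[i,k] F[k,l] / P[i,l];  B likewise for the absent allele
        A = Q[:, :, None] * F[None, :, :] / P[:, None, :]
        B = Q[:, :, None] * (1 - F)[None, :, :] / (1 - P)[:, None, :]
        wA = X[:, None, :] * A  # weighted by observed deletion draws
        wB = (c - X)[:, None, :] * B
        Q = (wA + wB).sum(axis=2) / (c * L)
        Q = Q / Q.sum(axis=1, keepdims=True)
        denom = (wA + wB).sum(axis=0)
        F = np.where(denom > 0, wA.sum(axis=0) / np.where(denom > 0, denom, 1.0), F)
        F = np.clip(F, eps, 1 - eps)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    # final log-likelihood after the last M-step
    P = np.clip(Q @ F, eps, 1 - eps)
    trace.append(float(np.sum(X * np.log(P) + (c - X) * np.log1p(-P))))
    return Q, F, np.array(trace), converged


def admixture_fit(G: GenotypeMatrix, K: int, seed: int = 0, max_iter: int = 500,
                  tol: float = 1e-6, n_restarts: int = 3, c: int = 1) -> AdmixtureFit:
    """Maximum-likelihood admixture via EM.

    Model: individual i draws ``c`` alleles per marker l (default 1: the
    single observed deletion-presence code), each from a mixture of K
    cluster deletion frequencies F weighted by the individual's ancestry
    proportions Q. EM maximizes
    sum_il [x log(QF) + (c-x) log(1-QF)]; the best of ``n_restarts`` runs
    by final log-likelihood is returned. The log-likelihood trace is
    non-decreasing within each run (EM guarantee).
    """
    if K < 1:
        raise InputError("K must be >= 1")
    if K > len(G.samples):
        raise InputError(f"K={K} exceeds sample count {len(G.samples)}")
    X = G.dosage.astype(float) * c  # presence scaled to c draws
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, r]))
        Q, F, trace, conv = _em_once(X, K, c, rng, max_iter, tol)
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, F, trace, conv)
    Q, F, trace, conv = best
    return AdmixtureFit(
        K=K,
        Q=pd.DataFrame(Q, index=G.samples, columns=[f"K{k + 1}" for k in range(K)]),
        F=pd.DataFrame(F, index=[f"K{k + 1}" for k in range(K)], columns=G.markers),
        loglik_trace=trace,
        seed=seed,
        converged=conv,
    )


def align_q_to_truth(Q: pd.DataFrame, truth_Q: pd.DataFrame) -> pd.DataFrame:
    """Permute the columns of Q to best match a reference ancestry matrix.

    Cluster labels are arbitrary; this searches all column permutations for
    the one minimizing mean absolute error against ``truth_Q``.
    """
    K = Q.shape[1]
    q = Q.to_numpy()
    t = truth_Q.to_numpy()
    best_perm, best_err = None, np.inf
    for perm in itertools.permutations(range(K)):
        err = np.abs(q[:, perm] - t).mean()
        if err < best_err:
            best_err, best_perm = err, perm
    out = Q.iloc[:, list(best_perm)]
    out.columns = truth_Q.columns
    return out
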