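"""Fixed-topology likelihood engine.

Felsenstein pruning over partitioned alignments, with discrete-gamma rate
heterogeneity (equal-weight categories, category means), per-node scaling
against underflow, and round-robin branch-length optimization on a fixed
topology.

Trees with a bifurcating root are internally derooted (the two root edges
are merged) so that every optimized edge is identifiable under a reversible
model; optimized lengths are written back by splitting the merged edge
evenly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .models import SubstitutionModel

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0


class MissingTaxonError(KeyError):
    """A tree leaf has no row in the alignment."""


class InvalidTreeError(ValueError):
    pass


class _TreeIndex:
    """Array view of a dendropy tree for fast traversal.

    Node 0..n-1; each non-root node carries the edge to its parent.
    ``edge_sources[i]`` lists the dendropy edges this indexed edge stands
    for (two edges when a bifurcating root was merged away).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        seed = tree.seed_node
        kids = seed.child_nodes()
        merged = None
        if len(kids) == 2:
            # virtual deroot: hang one child off the other with summed length
            internal = [k for k in kids if not k.is_leaf()]
            carrier = internal[0] if internal else kids[0]
            other = kids[1] if carrier is kids[0] else kids[0]
            merged = (carrier, other)
        self.children: list[list[int]] = []
        self.lengths: list[float] = []
        self.labels: list[str | None] = []
        self.edge_sources: list[list] = []
        self.parent: list[int] = []

        def add(dnode, parent_idx, length, sources):
            idx = len(self.children)
            self.children.append([])
            self.parent.append(parent_idx)
            self.lengths.append(length)
            self.labels.append(dnode.taxon.label if dnode.taxon else None)
            self.edge_sources.append(sources)
            if parent_idx >= 0:
                self.children[parent_idx].append(idx)
            return idx

        def grow(dnode, idx, skip=()):
            for ch in dnode.child_nodes():
                if ch in skip:
                    continue
                ln = ch.edge.length if ch.edge.length is not None else 0.0
                if ln < 0:
                    raise InvalidTreeError("negative branch length")
                cidx = add(ch, idx, ln, [ch.edge])
                grow(ch, cidx)

        if merged:
            carrier, other = merged
            root_idx = add(carrier, -1, 0.0, [])
            grow(carrier, root_idx)
            la = carrier.edge.length or 0.0
            lb = other.edge.length or 0.0
            oidx = add(other, root_idx, la + lb, [carrier.edge, other.edge])
            grow(other, oidx)
        else:
            root_idx = add(seed, -1, 0.0, [])
            grow(seed, root_idx)
        self.root = root_idx
        self.n_nodes = len(self.children)
        self.postorder = self._postorder()
        self.preorder = list(reversed(self.postorder))

    def _postorder(self):
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_indices(self):
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def write_back(self):
        """Copy current lengths onto the underlying dendropy edges."""
        for i in range(self.n_nodes):
            sources = self.edge_sources[i]
            if not sources:
                continue
            share = self.lengths[i] / len(sources)
            for e in sources:
                e.length = share


def _pmats(model: SubstitutionModel, t: float) -> np.ndarray:
    """Stack of P(t * r_c) over gamma categories, shape (k, n, n)."""
    lam, right, left = model._eigendecomposition()
    rates = model.category_rates
    if t == 0.0:  # exact: conflicting states across t=0 must yield 0
        return np.broadcast_to(np.eye(model.n_states),
                               (len(rates), model.n_states, model.n_states))
    e = np.exp(np.outer(rates, lam) * t)              # (k, n)
    p = np.einsum("im,km,mj->kij", right, e, left)
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=2, keepdims=True)


def _leaf_partials(model: SubstitutionModel, aln: Alignment,
                   index: _TreeIndex, lo: int, hi: int) -> dict[int, np.ndarray]:
    """Per-taxon (n_sites, n_states) partial rows for alignment columns lo:hi.

    Covers every labeled node: after virtual derooting of a two-leaf tree
    the root itself carries an observation.
    """
    row_of = {t: i for i, t in enumerate(aln.taxa)}
    out = {}
    for i in range(index.n_nodes):
        label = index.labels[i]
        if label is None:
            continue
        if label not in row_of:
            if index.is_leaf(i):
                raise MissingTaxonError(
                    f"tree taxon {label!r} missing from alignment")
            continue
        chars = aln.matrix[row_of[label], lo:hi]
        uniq, inv = np.unique(chars, return_inverse=True)
        table = np.stack([model.state_index(ch) for ch in uniq])
        out[i] = table[inv]
    return out


@dataclass
class _PartitionContext:
    """One partition's model and leaf data bound to a tree index."""

    name: str
    model: SubstitutionModel
    lo: int
    hi: int
    leaf: dict[int, np.ndarray]

    @classmethod
    def build(cls, name, model, lo, hi, aln, index):
        return cls(name, model, lo, hi, _leaf_partials(model, aln, index, lo, hi))

    @property
    def k(self):
        return len(self.model.category_rates)


def _resolve_contexts(aln: Alignment, index: _TreeIndex, models) -> list[_PartitionContext]:
    if isinstance(models, SubstitutionModel):
        return [_PartitionContext.build("all", models, 0, aln.n_sites, aln, index)]
    if not aln.partitions:
        raise ValueError("alignment has no partitions but a model map was given")
    covered = 0
    ctxs = []
    for name, (lo, hi) in aln.partitions.items():
        if name not in models:
            raise KeyError(f"no model for partition {name!r}")
        ctxs.append(_PartitionContext.build(name, models[name], lo, hi, aln, index))
        covered += hi - lo
    if covered != aln.n_sites:
        raise ValueError("partitions do not cover every site")
    return ctxs


def _down_pass(index: _TreeIndex, ctx: _PartitionContext, lengths):
    """Post-order partials D[node]: (k, sites, states), with log-scalers."""
    k = ctx.k
    D: list = [None] * index.n_nodes
    LS: list = [None] * index.n_nodes
    n_sites = ctx.hi - ctx.lo
    for i in index.postorder:
        if index.is_leaf(i):
            D[i] = np.broadcast_to(ctx.leaf[i][None], (k, n_sites, ctx.model.n_states))
            LS[i] = np.zeros((k, n_sites))
        else:
            acc = None
            ls = np.zeros((k, n_sites))
            for c in index.children[i]:
                p = _pmats(ctx.model, lengths[c])
                m = np.matmul(D[c], p.transpose(0, 2, 1))
                acc = m if acc is None else acc * m
                ls += LS[c]
            if i in ctx.leaf:  # derooted two-leaf case: observation at root
                acc = acc * ctx.leaf[i][None]
            mx = acc.max(axis=2)
            safe = np.where(mx > 0, mx, 1.0)
            acc = acc / safe[:, :, None]
            with np.errstate(divide="ignore"):
                ls = ls + np.log(np.where(mx > 0, mx, 0.0))
            D[i], LS[i] = acc, ls
    return D, LS


def _root_sitewise(index, ctx, D, LS):
    pi = ctx.model.frequencies
    like = np.einsum("ksj,j->ks", D[index.root], pi)
    with np.errstate(divide="ignore"):
        logl = np.log(np.where(like > 0, like, 0.0)) + LS[index.root]
    k = ctx.k
    return logsumexp(logl - np.log(k), axis=0)


def site_log_likelihoods(aln: Alignment, tree: dendropy.Tree, models) -> np.ndarray:
    """Per-site log-likelihood (nats) of ``aln`` on ``tree``.

    ``models`` is either one :class:`SubstitutionModel` for the whole matrix
    or a mapping partition-name -> model covering every site.  Gaps and
    ambiguity codes contribute a partial vector of ones over the compatible
    states.  A site that is impossible on the tree (conflicting fixed states
    across a zero-length path) yields ``-inf`` with a warning.
    """
    index = _TreeIndex(tree)
    out = np.empty(aln.n_sites)
    for ctx in _resolve_contexts(aln, index, models):
        D, LS = _down_pass(index, ctx, index.lengths)
        out[ctx.lo:ctx.hi] = _root_sitewise(index, ctx, D, LS)
    if np.any(np.isneginf(out)):
        warnings.warn("some sites have zero likelihood (log-likelihood -inf)")
    return out


def total_log_likelihood(aln: Alignment, tree: dendropy.Tree, models) -> float:
    return float(site_log_likelihoods(aln, tree, models).sum())


@dataclass
class SiteScoreTable:
    """Per-site log-likelihoods under each candidate topology."""

    scores: dict[str, np.ndarray]
    site_partition: np.ndarray  # per-site partition name

    def __post_init__(self):
        lengths = {len(v) for v in self.scores.values()}
        lengths.add(len(self.site_partition))
        if len(lengths) != 1:
            raise ValueError("score vectors have mismatched lengths")

    @property
    def labels(self):
        return list(self.scores)

    @property
    def n_sites(self):
        return len(self.site_partition)

    def total(self, label: str) -> float:
        return float(self.scores[label].sum())

    def to_frame(self):
        import pandas as pd
        data = {"site": np.arange(1, self.n_sites + 1),
                "partition": self.site_partition}
        for label, v in self.scores.items():
            data[f"LL_{label}"] = v
        return pd.DataFrame(data)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path):
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        labels = [c[3:] for c in df.columns if c.startswith("LL_")]
        return cls({lb: df[f"LL_{lb}"].to_numpy() for lb in labels},
                   df["partition"].fillna("").to_numpy(dtype=object))


def score_topologies(aln: Alignment, trees: dict[str, dendropy.Tree],
                     models) -> SiteScoreTable:
    """Sitewise log-likelihoods of the same matrix under several topologies."""
    scores = {label: site_log_likelihoods(aln, tree, models)
              for label, tree in trees.items()}
    return SiteScoreTable(scores, aln.site_partition_index())


# ---------------------------------------------------------------------------
# branch-length optimization


def _up_pass(index, ctx, lengths, D, LS):
    """Pre-order complement partials A[v] for every non-root node v.

    ``A[v][k, s, i]`` is the likelihood of everything outside v's subtree,
    indexed by the state i at v's parent, equilibrium prior included.
    """
    k = ctx.k
    n_sites = ctx.hi - ctx.lo
    n = ctx.model.n_states
    A: list = [None] * index.n_nodes
    LSA: list = [None] * index.n_nodes
    pi = ctx.model.frequencies
    C = {index.root: np.broadcast_to(pi[None, None, :], (k, n_sites, n))}
    LSC = {index.root: np.zeros((k, n_sites))}
    for p in index.preorder:
        if index.is_leaf(p):
            continue
        kids = index.children[p]
        M, LM = {}, {}
        for c in kids:
            pm = _pmats(ctx.model, lengths[c])
            M[c] = np.matmul(D[c], pm.transpose(0, 2, 1))
            LM[c] = LS[c]
        base = C[p]
        if p in ctx.leaf:  # observation carried by an internal (merged root) node
            base = base * ctx.leaf[p][None]
        for v in kids:
            acc = base.copy()
            ls = LSC[p].copy()
            for c in kids:
                if c is v:
                    continue
                acc = acc * M[c]
                ls = ls + LM[c]
            mx = acc.max(axis=2)
            safe = np.where(mx > 0, mx, 1.0)
            acc = acc / safe[:, :, None]
            with np.errstate(divide="ignore"):
                ls = ls + np.log(np.where(mx > 0, mx, 0.0))
            A[v], LSA[v] = acc, ls
            if not index.is_leaf(v):
                pm = _pmats(ctx.model, lengths[v])
                C[v] = np.matmul(acc, pm)
                LSC[v] = ls
    return A, LSA


def _edge_loglik(ctx, A, LSA, D, LS, v, t):
    pm = _pmats(ctx.model, t)
    val = (np.matmul(A[v], pm) * D[v]).sum(axis=2)
    with np.errstate(divide="ignore"):
        logl = np.log(np.where(val > 0, val, 0.0)) + LSA[v] + LS[v]
    m = logl.max(axis=0)
    good = np.isfinite(m)
    out = np.full(logl.shape[1], -np.inf)
    out[good] = m[good] + np.log(
        np.exp(logl[:, good] - m[good][None, :]).mean(axis=0))
    return float(out.sum())


@dataclass
class BranchLengthResult:
    tree: dendropy.Tree
    log_likelihood: float
    converged: bool
    n_passes: int
    history: list = field(default_factory=list)


def optimize_branch_lengths(
    aln: Alignment,
    topology: dendropy.Tree,
    models,
    tol: float = 1e-6,
    max_passes: int = 50,
    xatol: float = 1e-5,
) -> BranchLengthResult:
    """Maximize the likelihood over branch lengths on a fixed topology.

    Round-robin bounded scalar optimization (one edge at a time on
    ``[1e-8, 10]``) with complement partials refreshed once per pass; stops
    when a full pass improves the total log-likelihood by less than ``tol``.
    The result never scores below the input tree.
    """
    tree = topology.clone(depth=1)
    index = _TreeIndex(tree)
    for i in range(index.n_nodes):
        if i != index.root:
            index.lengths[i] = max(index.lengths[i], MIN_BRANCH_LENGTH)
    ctxs = _resolve_contexts(aln, index, models)

    def total_ll(lengths):
        s = 0.0
        for ctx in ctxs:
            D, LS = _down_pass(index, ctx, lengths)
            s += _root_sitewise(index, ctx, D, LS).sum()
        return float(s)

    best = total_ll(index.lengths)
    history = [best]
    converged = False
    n_passes = 0
    for _ in range(max_passes):
        n_passes += 1
        prev_lengths = list(index.lengths)
        per_ctx = []
        for ctx in ctxs:
            D, LS = _down_pass(index, ctx, index.lengths)
            A, LSA = _up_pass(index, ctx, index.lengths, D, LS)
            per_ctx.append((ctx, D, LS, A, LSA))

        for v in range(index.n_nodes):
            if v == index.root:
                continue

            def neg(t, v=v):
                return -sum(_edge_loglik(ctx, A, LSA, D, LS, v, t)
                            for ctx, D, LS, A, LSA in per_ctx)

            current = neg(index.lengths[v])
            res = minimize_scalar(neg, bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                                  method="bounded", options={"xatol": xatol})
            if res.fun <= current:
                index.lengths[v] = float(res.x)
        now = total_ll(index.lengths)
        if now < best:            # stale-partial overshoot: keep previous
            index.lengths = prev_lengths
            converged = True
            break
        improved = now - best
        best = now
        history.append(best)
        if improved < tol:
            converged = True
            break
    index.write_back()
    return BranchLengthResult(tree, best, converged, n_passes, history)


def estimate_gamma_shape(aln: Alignment, tree: dendropy.Tree,
                         model: SubstitutionModel,
                         bounds=(0.05, 50.0)) -> float:
    """1-D bounded search for the discrete-gamma shape maximizing total LL."""
    from dataclasses import replace

    def neg(log_a):
        m = replace(model, alpha=float(np.exp(log_a)), _eig=None)
        return -total_log_likelihood(aln, tree, m)

    res = minimize_scalar(neg, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))
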