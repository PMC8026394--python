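"""Admixture graphs: expected f-statistics, parameter fitting, diagnostics.

An admixture graph is a rooted DAG whose solid edges carry non-negative
drift lengths in f2 units (squared frequency difference) and whose dotted
(admixture) edges carry mixing proportions and no drift.  Expected
f-statistics are linear in the drift lengths given the admixture
proportions: with ``w_leaf(e)`` the probability that a lineage sampled in
a leaf traverses drift edge ``e`` on its way to the root,

    E[f2(i, j)]   = sum_e L_e (w_i - w_j)^2
    E[f3(c;a,b)]  = sum_e L_e (w_c - w_a)(w_c - w_b)
    E[f4(a,b;c,d)]= sum_e L_e (w_a - w_b)(w_c - w_d)

Fitting uses the outgroup-f3 basis f3(O; i, j) over all non-outgroup leaf
pairs, a block-jackknife covariance, and a nested optimisation: a
deterministic grid + golden-section search over each admixture proportion
wrapped around a non-negative generalised least squares solve for the
edge lengths.  Residual Z scores are reported for every f2/f3/f4
combination of leaves, each against its own jackknife standard error.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import fstats
from .formats_io import FormatError


class GraphError(ValueError):
    pass


@dataclasses.dataclass
class DriftEdge:
    child: str
    parent: str
    length: float | None = None  # None = free parameter


@dataclasses.dataclass
class Admixture:
    node: str
    parent1: str
    parent2: str
    alpha: float | None = None  # proportion from parent1; None = free


class AdmixtureGraph:
    """Rooted DAG with drift edges (f2 units) and admixture nodes."""

    def __init__(self, drift_edges: list[DriftEdge],
                 admixtures: list[Admixture] | None = None):
        self.drift_edges = list(drift_edges)
        self.admixtures = {a.node: a for a in (admixtures or [])}
        self._check()

    # -- structure ---------------------------------------------------------
    def _check(self) -> None:
        nodes = set()
        parents: dict[str, list[str]] = {}
        for e in self.drift_edges:
            nodes.update((e.child, e.parent))
            parents.setdefault(e.child, []).append(e.parent)
            if e.length is not None and not (0 <= e.length < 1):
                raise GraphError(f"drift length on {e.child} must be in [0, 1)")
        for a in self.admixtures.values():
            nodes.update((a.node, a.parent1, a.parent2))
            parents.setdefault(a.node, []).extend((a.parent1, a.parent2))
            if a.alpha is not None and not (0 <= a.alpha <= 1):
                raise GraphError(f"admixture proportion on {a.node} not in [0,1]")
        for n in self.admixtures:
            if any(e.child == n for e in self.drift_edges):
                raise GraphError(f"node {n} has both drift and admixture parents")
        roots = [n for n in nodes if n not in parents]
        if len(roots) != 1:
            raise GraphError(f"graph must have exactly one root, found {roots}")
        self.root = roots[0]
        self.nodes = nodes
        self._parents = parents
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        # children before parents (upward order); iteration is over sorted
        # names so the order — and any RNG draw sequence that follows it —
        # is identical across processes
        order, seen, temp = [], set(), set()

        def visit(n):
            if n in seen:
                return
            if n in temp:
                raise GraphError("graph contains a cycle")
            temp.add(n)
            for p in self._parents.get(n, []):
                visit(p)
            temp.discard(n)
            seen.add(n)
            order.append(n)

        for n in sorted(self.nodes):
            visit(n)
        # order currently parents-first; reverse for children-first traversal
        return order[::-1]

    @property
    def leaves(self) -> list[str]:
        children = {e.parent for e in self.drift_edges}
        children |= {a.parent1 for a in self.admixtures.values()}
        children |= {a.parent2 for a in self.admixtures.values()}
        return sorted(self.nodes - children)

    def free_alphas(self) -> list[str]:
        return sorted(a.node for a in self.admixtures.values() if a.alpha is None)

    def with_params(self, lengths: dict | None = None,
                    alphas: dict | None = None) -> "AdmixtureGraph":
        edges = [DriftEdge(e.child, e.parent,
                           (lengths or {}).get((e.child, e.parent), e.length))
                 for e in self.drift_edges]
        adm = [Admixture(a.node, a.parent1, a.parent2,
                         (alphas or {}).get(a.node, a.alpha))
               for a in self.admixtures.values()]
        return AdmixtureGraph(edges, adm)

    # -- lineage weights ---------------------------------------------------
    def lineage_weights(self, leaf: str,
                        alphas: dict[str, float] | None = None) -> dict:
        """Probability a lineage from ``leaf`` traverses each drift edge."""
        if leaf not in self.nodes:
            raise GraphError(f"unknown leaf {leaf!r}")
        alphas = alphas or {}
        mass = {n: 0.0 for n in self.nodes}
        mass[leaf] = 1.0
        weights = {(e.child, e.parent): 0.0 for e in self.drift_edges}
        drift_parent = {e.child: e.parent for e in self.drift_edges}
        for n in self._order:  # children before parents
            m = mass[n]
            if m == 0.0 or n == self.root:
                continue
            if n in self.admixtures:
                a = self.admixtures[n]
                al = alphas.get(n, a.alpha)
                if al is None:
                    raise GraphError(f"alpha for {n} unspecified")
                mass[a.parent1] += al * m
                mass[a.parent2] += (1 - al) * m
            else:
                p = drift_parent[n]
                weights[(n, p)] += m
                mass[p] += m
        return weights


def read_graph(path) -> AdmixtureGraph:
    """Edge-list TSV: columns child, parent, type in {drift, admix}, value.

    ``value`` is a number or ``free``; admixture rows come in pairs, the
    first parent carrying the proportion.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"child", "parent", "type", "value"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: graph file needs columns {sorted(need)}")
    drift, admix_rows = [], {}
    for r in df.itertuples(index=False):
        val = None if str(r.value).strip().lower() == "free" else float(r.value)
        if r.type == "drift":
            drift.append(DriftEdge(r.child, r.parent, val))
        elif r.type == "admix":
            admix_rows.setdefault(r.child, []).append((r.parent, val))
        else:
            raise FormatError(f"{path}: bad edge type {r.type!r}")
    adm = []
    for node, rows in admix_rows.items():
        if len(rows) != 2:
            raise FormatError(f"{path}: admixture node {node} needs 2 parents")
        (p1, a1), (p2, _) = rows
        adm.append(Admixture(node, p1, p2, a1))
    return AdmixtureGraph(drift, adm)


def write_graph(graph: AdmixtureGraph, path) -> None:
    rows = []
    for e in graph.drift_edges:
        rows.append((e.child, e.parent, "drift",
                     "free" if e.length is None else repr(float(e.length))))
    for a in graph.admixtures.values():
        al = "free" if a.alpha is None else repr(float(a.alpha))
        rows.append((a.node, a.parent1, "admix", al))
        rows.append((a.node, a.parent2, "admix", ""))
    pd.DataFrame(rows, columns=["child", "parent", "type", "value"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expected statistics
# ---------------------------------------------------------------------------

def _edge_vector(graph, leaves, alphas):
    """Weight matrix W[leaf, edge] over drift edges, in fixed edge order."""
    edges = [(e.child, e.parent) for e in graph.drift_edges]
    W = np.zeros((len(leaves), len(edges)))
    for i, leaf in enumerate(leaves):
        w = graph.lineage_weights(leaf, alphas)
        W[i] = [w[e] for e in edges]
    return W, edges


def expected_f2(graph: AdmixtureGraph, i: str, j: str) -> float:
    wi = graph.lineage_weights(i)
    wj = graph.lineage_weights(j)
    return sum((e.length or 0.0) * (wi[(e.child, e.parent)] - wj[(e.child, e.parent)]) ** 2
               for e in graph.drift_edges)


def expected_f3(graph: AdmixtureGraph, c: str, a: str, b: str) -> float:
    wc, wa, wb = (graph.lineage_weights(x) for x in (c, a, b))
    return sum((e.length or 0.0)
               * (wc[k] - wa[k]) * (wc[k] - wb[k])
               for e in graph.drift_edges
               for k in [(e.child, e.parent)])


def expected_f4(graph: AdmixtureGraph, a: str, b: str, c: str, d: str) -> float:
    wa, wb, wc, wd = (graph.lineage_weights(x) for x in (a, b, c, d))
    return sum((e.length or 0.0)
               * (wa[k] - wb[k]) * (wc[k] - wd[k])
               for e in graph.drift_edges
               for k in [(e.child, e.parent)])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GraphFit:
    graph: AdmixtureGraph          # with fitted parameters filled in
    lengths: dict
    alphas: dict
    objective: float
    residuals: pd.DataFrame        # statistic, pops, observed, fitted, se, z
    worst_abs_z: float
    n_snps_used: int
    identifiable: bool


def _basis_pairs(leaves, outgroup):
    inner = [l for l in leaves if l != outgroup]
    return [(a, b) for i, a in enumerate(inner) for b in inner[i:]]


def _observed_basis(freqs, outgroup, pairs, block_mb):
    """Outgroup-f3 basis values, per-block sums and jackknife covariance."""
    blocks = fstats.assign_blocks(freqs.chrom, freqs.pos_bp, block_mb)
    g = blocks.max() + 1
    contribs = np.array([fstats.f3(freqs, outgroup, a, b, corrected=True)
                         for a, b in pairs])
    ok = np.isfinite(contribs).all(axis=0)
    contribs, blocks = contribs[:, ok], blocks[ok]
    codes, _ = pd.factorize(blocks, sort=True)
    g = codes.max() + 1
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")
    n = contribs.shape[1]
    m = np.bincount(codes, minlength=g).astype(float)
    sums = np.zeros((len(pairs), g))
    for s in range(len(pairs)):
        sums[s] = np.bincount(codes, weights=contribs[s], minlength=g)
    y = sums.sum(axis=1) / n
    theta_j = (y[:, None] * n - sums) / (n - m)[None, :]  # leave-one-block-out means
    h = n / m
    # weighted jackknife covariance: (1/g) sum_j outer(tau_j - est_J)/(h_j - 1)
    tau = h[None, :] * y[:, None] - (h - 1.0)[None, :] * theta_j
    est_j = g * y - ((1.0 - m / n)[None, :] * theta_j).sum(axis=1)
    dev = tau - est_j[:, None]
    cov = (dev / (h - 1.0)[None, :]) @ dev.T / g
    cov = (cov + cov.T) / 2.0
    cov += np.eye(len(pairs)) * (1e-6 * max(np.trace(cov) / len(pairs), 1e-12))
    return y, cov, int(n)


def _design_matrix(graph, outgroup, pairs, alphas):
    leaves = graph.leaves
    W, edges = _edge_vector(graph, leaves, alphas)
    idx = {l: i for i, l in enumerate(leaves)}
    X = np.zeros((len(pairs), len(edges)))
    wo = W[idx[outgroup]]
    for r, (a, b) in enumerate(pairs):
        X[r] = (wo - W[idx[a]]) * (wo - W[idx[b]])
    return X, edges


def _gls_nnls(X, y, cov, fixed_mask=None, fixed_vals=None):
    """Non-negative GLS solve; columns with fixed values are held."""
    if fixed_mask is not None and fixed_mask.any():
        y = y - X[:, fixed_mask] @ fixed_vals[fixed_mask]
        X_free = X[:, ~fixed_mask]
    else:
        fixed_mask = np.zeros(X.shape[1], dtype=bool)
        X_free = X
    L = np.linalg.cholesky(np.linalg.inv(cov))
    A, b = L.T @ X_free, L.T @ y
    sol_free, _ = nnls(A, b)
    sol = np.empty(X.shape[1])
    sol[~fixed_mask] = sol_free
    if fixed_mask.any():
        sol[fixed_mask] = fixed_vals[fixed_mask]
    resid = y - X_free @ sol_free
    obj = float(resid @ np.linalg.solve(cov, resid))
    return sol, obj


def _fixed_arrays(graph):
    mask = np.array([e.length is not None for e in graph.drift_edges])
    vals = np.array([0.0 if e.length is None else e.length
                     for e in graph.drift_edges])
    return mask, vals


def _design_rank_ok(graph, X, fixed_mask):
    """Rank check on free columns, merging the provably collinear
    root-child edge columns (the outgroup-f3 basis only sees their sum)."""
    root_children = {e.child for e in graph.drift_edges if e.parent == graph.root}
    cols, root_col = [], None
    for j, e in enumerate(graph.drift_edges):
        if fixed_mask[j]:
            continue
        if e.child in root_children:
            root_col = X[:, j] if root_col is None else root_col + X[:, j]
        else:
            cols.append(X[:, j])
    if root_col is not None:
        cols.append(root_col)
    if not cols:
        return True
    M = np.column_stack(cols)
    return np.linalg.matrix_rank(M, tol=1e-10) >= min(M.shape)


def fit_graph_basis(graph: AdmixtureGraph, outgroup: str, basis_values,
                    basis_cov=None, alpha_step: float = 0.02):
    """Fit free parameters to a supplied outgroup-f3 basis vector.

    ``basis_values`` follows the pair order of all (i <= j) non-outgroup
    leaf pairs in sorted leaf order.  Returns (lengths, alphas, objective).
    Identity covariance is used when none is given (ordinary NNLS).
    """
    pairs = _basis_pairs(graph.leaves, outgroup)
    y = np.asarray(basis_values, float)
    if len(y) != len(pairs):
        raise GraphError(f"basis has {len(y)} entries, expected {len(pairs)}")
    cov = np.eye(len(pairs)) if basis_cov is None else np.asarray(basis_cov, float)
    free = graph.free_alphas()
    fixed = {a.node: a.alpha for a in graph.admixtures.values()
             if a.alpha is not None}

    fixed_mask, fixed_vals = _fixed_arrays(graph)

    def solve(alpha_vals):
        X, edges = _design_matrix(graph, outgroup, pairs, {**fixed, **alpha_vals})
        sol, obj = _gls_nnls(X, y, cov, fixed_mask, fixed_vals)
        return sol, obj, edges

    alphas = {a: 0.5 for a in free}
    if free:
        grid = np.arange(0.0, 1.0 + 1e-9, alpha_step)
        for _ in range(2 if len(free) > 1 else 1):
            for node in free:
                objs = [solve({**alphas, node: float(v)})[1] for v in grid]
                best = grid[int(np.argmin(objs))]
                lo, hi = max(0.0, best - alpha_step), min(1.0, best + alpha_step)
                alphas[node] = _golden(
                    lambda v: solve({**alphas, node: v})[1], lo, hi)
    sol, obj, edges = solve(alphas)
    return dict(zip(edges, sol)), {**fixed, **alphas}, obj


def basis_pair_order(graph: AdmixtureGraph, outgroup: str):
    """Pair order used by :func:`fit_graph_basis`."""
    return _basis_pairs(graph.leaves, outgroup)


def fit_graph(graph: AdmixtureGraph, freqs: fstats.FreqTable, outgroup: str,
              block_mb: float = 5.0, alpha_step: float = 0.02,
              residual_block_mb: float | None = None) -> GraphFit:
    """Fit free drift lengths and admixture proportions to outgroup-f3 data.

    Deterministic: coarse grid over each free admixture proportion with
    golden-section refinement, a non-negative GLS solve for edge lengths
    inside, and residual Z scores over all leaf f2/f3/f4 combinations.
    """
    leaves = graph.leaves
    if outgroup not in leaves:
        raise GraphError(f"outgroup {outgroup!r} is not a leaf")
    pairs = _basis_pairs(leaves, outgroup)
    y, cov, n_snps = _observed_basis(freqs, outgroup, pairs, block_mb)
    free = graph.free_alphas()
    fixed = {a.node: a.alpha for a in graph.admixtures.values()
             if a.alpha is not None}

    fixed_mask, fixed_vals = _fixed_arrays(graph)

    def solve(alpha_vals: dict):
        X, edges = _design_matrix(graph, outgroup, pairs, {**fixed, **alpha_vals})
        sol, obj = _gls_nnls(X, y, cov, fixed_mask, fixed_vals)
        return sol, obj, X, edges

    alphas = {a: 0.5 for a in free}
    if free:
        grid = np.arange(0.0, 1.0 + 1e-9, alpha_step)
        for _ in range(2 if len(free) > 1 else 1):  # coordinate passes
            for node in free:
                objs = []
                for val in grid:
                    alphas[node] = float(val)
                    objs.append(solve(alphas)[1])
                best = grid[int(np.argmin(objs))]
                lo = max(0.0, best - alpha_step)
                hi = min(1.0, best + alpha_step)
                alphas[node] = _golden(lambda v: solve({**alphas, node: v})[1], lo, hi)

    sol, obj, X, edges = solve(alphas)
    identifiable = _design_rank_ok(graph, X, fixed_mask)

    lengths = dict(zip(edges, sol))
    fitted = graph.with_params(lengths=lengths, alphas={**fixed, **alphas})
    residuals = _residual_table(fitted, freqs, block_mb=residual_block_mb or block_mb)
    worst = float(residuals["z"].abs().max()) if len(residuals) else 0.0
    return GraphFit(graph=fitted, lengths=lengths, alphas=dict(alphas),
                    objective=obj, residuals=residuals, worst_abs_z=worst,
                    n_snps_used=n_snps, identifiable=bool(identifiable))


def _golden(fun, lo, hi, tol=1e-4):
    gr = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = fun(d)
    return float((a + b) / 2)


def _residual_table(fitted: AdmixtureGraph, freqs, block_mb=5.0) -> pd.DataFrame:
    """Observed-vs-fitted Z for every leaf f2 pair, f3 triple and f4 quadruple."""
    leaves = [l for l in fitted.leaves if l in freqs.pops]
    rows = []

    def add(kind, pops, contrib, exp):
        res = fstats.block_jackknife(contrib, np.ones_like(contrib),
                                     freqs.chrom, freqs.pos_bp, block_mb,
                                     kind=kind, pops=pops)
        resid = res.estimate - exp
        if res.se > 0:
            z = resid / res.se
        else:
            z = 0.0 if abs(resid) < 1e-9 else np.inf
        rows.append({"statistic": kind, "pops": ",".join(pops),
                     "observed": res.estimate, "fitted": exp,
                     "se": res.se, "z": z})

    for a, b in itertools.combinations(leaves, 2):
        add("f2", (a, b), fstats.f2(freqs, a, b), expected_f2(fitted, a, b))
    for c in leaves:
        for a, b in itertools.combinations([l for l in leaves if l != c], 2):
            add("f3", (c, a, b), fstats.f3(freqs, c, a, b),
                expected_f3(fitted, c, a, b))
    for a, b, c, d in itertools.combinations(leaves, 4):
        for quad in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
            num, _ = fstats.f4_and_d(freqs, *quad)
            add("f4", quad, num, expected_f4(fitted, *quad))
    return pd.DataFrame(rows)


def compare_topologies(graphs: list[AdmixtureGraph], freqs, outgroup,
                       **kwargs) -> list[tuple[int, GraphFit]]:
    """Fit each topology and rank by (worst |Z|, objective); ties kept."""
    if len(graphs) < 1:
        raise GraphError("need at least one topology")
    leaf_sets = {tuple(g.leaves) for g in graphs}
    if len(leaf_sets) > 1:
        raise GraphError("topologies must share the same leaf set")
    fits = [fit_graph(g, freqs, outgroup, **kwargs) for g in graphs]
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].worst_abs_z, fits[i].objective))
    return [(i, fits[i]) for i in order]
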