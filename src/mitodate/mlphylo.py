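"""GTR+Γ+I maximum-likelihood phylogenetics.

The likelihood engine implements Felsenstein's pruning algorithm over
compressed site patterns with per-pattern log scaling, under a general
time-reversible model with discrete-gamma among-site rate variation and a
proportion of invariant sites.  Branch lengths are optimized one edge at a
time (Brent) using edge-local partial-likelihood vectors; model parameters
by bounded quasi-Newton.  Nonparametric bootstrap (column resampling)
yields percentile confidence intervals for named branches and a two-sided
test of rate equality between two branches.

Branch lengths are in expected substitutions per site: the rate matrix is
scaled so the expected substitution rate at stationarity is 1, the
discrete-gamma category rates have mean 1, and with invariant sites the
variable categories are rescaled by 1/(1 - p_inv) so the average over all
sites stays 1 (the PhyML/phangorn convention).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import gammainc, gammaincinv

from .seqio import Alignment

__all__ = [
    "SubstitutionModel",
    "MlFit",
    "BootstrapResult",
    "RateTestResult",
    "discrete_gamma_rates",
    "log_likelihood",
    "TreeLikelihood",
    "nj_tree",
    "p_distance_matrix",
    "jc_distance_matrix",
    "fit_ml",
    "bootstrap_branch_lengths",
    "rate_equality_test",
    "branch_keys",
]

_STATES = "ACGT"
_STATE_INDEX = {c: i for i, c in enumerate(_STATES)}
#: order of exchangeability parameters
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Equal-probability discrete-gamma rate multipliers (category means).

    Categories are the ``n`` equal-probability slices of a Gamma(alpha,
    alpha) distribution (mean 1); each category's rate is the mean of its
    slice, so the returned rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    probs = np.arange(1, n_categories) / n_categories
    # category boundaries: quantiles of Gamma(shape=alpha, scale=1/alpha)
    bounds = gammaincinv(alpha, probs) / alpha
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # mean within each slice via the Gamma(alpha+1) CDF identity
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = n_categories * (upper - lower)
    return rates


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+Γ+I nucleotide model (states ordered A, C, G, T).

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT with GT
    fixed to 1 by convention; ``alpha`` is the gamma shape, ``p_inv`` the
    proportion of invariant sites.
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6:
            raise ValueError("need 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if any(x <= 0 for x in self.exchangeabilities):
            raise ValueError("exchangeabilities must be positive")
        freqs = np.asarray(self.base_frequencies, float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @classmethod
    def jc(cls, alpha: float = 1.0, p_inv: float = 0.0, n_categories: int = 1
           ) -> "SubstitutionModel":
        """Jukes-Cantor special case (equal frequencies/exchangeabilities)."""
        return cls(alpha=alpha, p_inv=p_inv, n_categories=n_categories)

    def rate_matrix(self) -> np.ndarray:
        """Scaled GTR rate matrix Q (rows sum to 0, mean rate 1)."""
        pi = np.asarray(self.base_frequencies, float)
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(pairs, self.exchangeabilities):
            s[i, j] = s[j, i] = x
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        return q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spectral decomposition Q = left @ diag(lam) @ right."""
        pi = np.asarray(self.base_frequencies, float)
        sq = np.sqrt(pi)
        sym = self.rate_matrix() * sq[:, None] / sq[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        left = u / sq[:, None]
        right = u.T * sq[None, :]
        return lam, left, right

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def site_rates(self) -> np.ndarray:
        """Rates of the variable-site gamma categories.

        With invariant sites present the variable categories are rescaled
        by 1/(1 - p_inv) so the expected substitution rate over *all*
        sites is 1 and branch lengths read as expected substitutions per
        site (the PhyML/phangorn convention).
        """
        return self.category_rates() / (1.0 - self.p_inv)

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t * r_c) for each length and variable-site rate category.

        Returns an array of shape ``(len(lengths), n_categories, 4, 4)``.
        """
        lam, left, right = self.eigensystem()
        rates = self.site_rates()
        t = np.asarray(lengths, float)
        expo = np.exp(np.einsum("e,c,k->eck", t, rates, lam))
        p = np.einsum("ik,eck,kj->ecij", left, expo, right)
        return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# pattern compression


def _encode_alignment(alignment: Alignment, tip_order: Sequence[str]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Compress columns into unique patterns.

    Returns (codes, weights): ``codes`` is (n_tips, n_patterns) with values
    0-3 for A,C,G,T and 4 for anything else (gap, N, ambiguity = missing).
    """
    mat = np.empty((len(tip_order), alignment.n_columns), dtype=np.uint8)
    for k, tid in enumerate(tip_order):
        seq = alignment[tid].residues
        mat[k] = [_STATE_INDEX.get(c, 4) for c in seq]
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _tip_partials(codes: np.ndarray) -> np.ndarray:
    """(n_tips, n_patterns, 4) indicator partials; missing = all ones."""
    n_tips, n_pat = codes.shape
    out = np.zeros((n_tips, n_pat, 4))
    for s in range(4):
        out[:, :, s] = (codes == s) | (codes == 4)
    return out


# ---------------------------------------------------------------------------
# likelihood engine


class TreeLikelihood:
    """Pruning-algorithm likelihood for a fixed tree topology.

    The dendropy tree is indexed once at construction; branch lengths live
    in ``self.lengths`` (indexed by child node) and are written back to the
    tree by :meth:`sync_tree`.
    """

    def __init__(self, alignment: Alignment, tree: dendropy.Tree,
                 model: SubstitutionModel,
                 patterns: tuple[np.ndarray, np.ndarray] | None = None):
        self.alignment = alignment
        self.tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = [t for t in leaves if t not in alignment]
        if missing:
            raise ValueError(f"tree tip(s) without sequence: {missing}")
        self.tip_order = leaves
        if patterns is None:
            patterns = _encode_alignment(alignment, leaves)
        self.codes, self.weights = patterns
        self.n_sites = float(self.weights.sum())
        self.tipvec = _tip_partials(self.codes)
        self._index_tree()
        self.set_model(model)

    # -- tree indexing ----------------------------------------------------
    def _index_tree(self) -> None:
        nodes = list(self.tree.postorder_node_iter())
        self.node_index = {id(nd): i for i, nd in enumerate(nodes)}
        self.nodes = nodes
        n = len(nodes)
        self.root = n - 1
        self.parent = np.full(n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.tip_row = np.full(n, -1, dtype=int)
        self.lengths = np.zeros(n)
        row_of = {label: i for i, label in enumerate(self.tip_order)}
        for i, nd in enumerate(nodes):
            for ch in nd.child_nodes():
                j = self.node_index[id(ch)]
                self.parent[j] = i
                self.children[i].append(j)
                self.lengths[j] = max(ch.edge.length or 0.0, MIN_BRANCH_LENGTH)
            if nd.is_leaf():
                self.tip_row[i] = row_of[nd.taxon.label]
        self.postorder = [i for i in range(n)]  # nodes list is postorder
        self.edges = [i for i in range(n) if i != self.root]
        depth = np.zeros(n, dtype=int)
        for i in reversed(range(n)):
            for c in self.children[i]:
                depth[c] = depth[i] + 1
        height = depth.max() - depth
        self._rescale = (height % 4 == 3) | (np.arange(n) == self.root)

    def sync_tree(self) -> dendropy.Tree:
        """Write current branch lengths back onto the dendropy tree."""
        for i, nd in enumerate(self.nodes):
            if i != self.root:
                nd.edge.length = float(self.lengths[i])
        return self.tree

    # -- model ------------------------------------------------------------
    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        lam, left, right = model.eigensystem()
        self._lam, self._left, self._right = lam, left, right
        self._rates = model.site_rates()
        self._pi = np.asarray(model.base_frequencies, float)
        # invariant-site component: constant in branch lengths, and its
        # tip-indicator product does not depend on the model at all
        if not hasattr(self, "_inv_prod"):
            prod = np.ones((self.codes.shape[1], 4))
            for row in range(len(self.tip_order)):
                prod *= self.tipvec[row]
            self._inv_prod = prod
        self._l_inv = self._inv_prod @ self._pi

    def _pmats(self, lengths: np.ndarray) -> np.ndarray:
        expo = np.exp(np.einsum("e,c,k->eck", lengths, self._rates, self._lam))
        p = np.einsum("ik,eck,kj->ecij", self._left, expo, self._right)
        return np.clip(p, 0.0, None)

    # -- pruning ----------------------------------------------------------
    def _down_pass(self, lengths: np.ndarray
                   ) -> tuple[list[np.ndarray | None], np.ndarray, np.ndarray]:
        """Conditional likelihoods of each subtree at its root node.

        Returns (D, scalers, P): ``D[i]`` is (ncat, npat, 4) for internal
        node *i* (tips are read from ``self.tipvec``), ``scalers[i]`` the
        per-pattern log scaling factor accumulated below node *i*.
        """
        ncat = len(self._rates)
        npat = self.codes.shape[1]
        pmats = self._pmats(lengths)
        D: list[np.ndarray | None] = [None] * len(self.nodes)
        scal = np.zeros((len(self.nodes), npat))
        for i in self.postorder:
            if self.tip_row[i] >= 0:
                continue
            acc = np.ones((ncat, npat, 4))
            s = np.zeros(npat)
            for c in self.children[i]:
                if self.tip_row[c] >= 0:
                    dc = np.broadcast_to(self.tipvec[self.tip_row[c]],
                                         (ncat, npat, 4))
                else:
                    dc = D[c]
                    s += scal[c]
                acc = acc * (dc @ pmats[c].transpose(0, 2, 1))
            # rescaling every few levels is enough to prevent underflow and
            # saves two passes over the partials at most nodes
            if self._rescale[i]:
                mx = acc.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                acc /= mx[None, :, None]
                s = s + np.log(mx)
            D[i] = acc
            scal[i] = s
        return D, scal, pmats

    def _site_loglik(self, per_cat: np.ndarray, scal: np.ndarray) -> np.ndarray:
        """Combine per-category likelihoods with the invariant component."""
        p_inv = self.model.p_inv
        mean_cat = per_cat.mean(axis=0)
        with np.errstate(divide="ignore"):
            log_var = np.log(np.clip(mean_cat, 1e-300, None)) + scal
            if p_inv > 0:
                log_var = np.logaddexp(
                    np.log1p(-p_inv) + log_var,
                    np.where(self._l_inv > 0,
                             np.log(p_inv) + np.log(np.clip(self._l_inv, 1e-300, None)),
                             -np.inf),
                )
        return log_var

    def log_likelihood(self, lengths: np.ndarray | None = None) -> float:
        if lengths is None:
            lengths = self.lengths
        D, scal, _ = self._down_pass(lengths)
        per_cat = D[self.root] @ self._pi
        site_ll = self._site_loglik(per_cat, scal[self.root])
        return float(self.weights @ site_ll)

    # -- edge-local branch optimization -----------------------------------
    def _edge_vectors(self, v: int, D: list, scal: np.ndarray,
                      pmats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(G, g_scal, Dv, d_scal): factors of the likelihood local to edge v."""
        ncat = len(self._rates)
        npat = self.codes.shape[1]
        path = []
        u = v
        while u != self.root:
            path.append(u)
            u = self.parent[u]
        path.reverse()  # root-side first, ends with v
        R = np.broadcast_to(self._pi[None, None, :], (ncat, npat, 4)).copy()
        r_scal = np.zeros(npat)
        for node in path:
            u = self.parent[node]
            for c in self.children[u]:
                if c == node:
                    continue
                if self.tip_row[c] >= 0:
                    dc = np.broadcast_to(self.tipvec[self.tip_row[c]],
                                         (ncat, npat, 4))
                else:
                    dc = D[c]
                    r_scal = r_scal + scal[c]
                R = R * (dc @ pmats[c].transpose(0, 2, 1))
            if node != v:
                R = R @ pmats[node]
            mx = R.max(axis=(0, 2))
            mx = np.where(mx > 0, mx, 1.0)
            R = R / mx[None, :, None]
            r_scal = r_scal + np.log(mx)
        if self.tip_row[v] >= 0:
            dv = np.broadcast_to(self.tipvec[self.tip_row[v]], (ncat, npat, 4))
            d_scal = np.zeros(npat)
        else:
            dv, d_scal = D[v], scal[v]
        return R, r_scal, dv, d_scal

    def _edge_loglik(self, t: float, G: np.ndarray, g_scal: np.ndarray,
                     dv: np.ndarray, d_scal: np.ndarray) -> float:
        p = np.clip(np.einsum(
            "ik,ck,kj->cij", self._left,
            np.exp(np.outer(self._rates, self._lam) * t), self._right,
        ), 0.0, None)
        per_cat = ((G @ p) * dv).sum(axis=-1)
        site_ll = self._site_loglik(per_cat, g_scal + d_scal)
        return float(self.weights @ site_ll)

    def optimize_branch_lengths(self, sweeps: int = 3, tol: float = 1e-6
                                ) -> float:
        """Coordinate ascent over edges; returns the final log-likelihood."""
        ll = self.log_likelihood()
        for _ in range(sweeps):
            D, scal, pmats = self._down_pass(self.lengths)
            for v in self.edges:
                G, gs, dv, ds = self._edge_vectors(v, D, scal, pmats)
                res = optimize.minimize_scalar(
                    lambda t: -self._edge_loglik(t, G, gs, dv, ds),
                    bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                    method="bounded",
                    options={"xatol": 1e-9},
                )
                self.lengths[v] = float(res.x)
                # refresh the arrays the remaining edges will read
                D, scal, pmats = self._down_pass(self.lengths)
            new_ll = self.log_likelihood()
            if new_ll - ll < tol * max(1.0, abs(new_ll)):
                ll = new_ll
                break
            ll = new_ll
        return ll

    # -- model optimization ------------------------------------------------
    def optimize_model(self, optimize_alpha: bool = True,
                       optimize_p_inv: bool = True,
                       maxiter: int = 100) -> float:
        """Optimize model parameters jointly with a global tree-length scale.

        The scale parameter absorbs the strong coupling between rate
        heterogeneity (alpha, p_inv) and the overall amount of inferred
        change, which otherwise makes the alternation with per-branch
        optimization converge very slowly.
        """
        m = self.model
        base_lengths = self.lengths.copy()
        x0 = np.concatenate([
            np.log(m.exchangeabilities[:5]),
            np.log(np.asarray(m.base_frequencies[:3])
                   / m.base_frequencies[3]),
            [np.log(m.alpha)],
            [m.p_inv],
            [0.0],  # log global branch-length scale
        ])
        bounds = ([(-7, 7)] * 5 + [(-7, 7)] * 3
                  + [(np.log(0.02), np.log(100.0)) if optimize_alpha
                     else (np.log(m.alpha),) * 2]
                  + [(0.0, 0.99) if optimize_p_inv else (m.p_inv,) * 2]
                  + [(-3.0, 3.0)])

        def unpack(x: np.ndarray) -> SubstitutionModel:
            ex = tuple(np.exp(x[:5])) + (1.0,)
            raw = np.exp(np.concatenate([x[5:8], [0.0]]))
            freqs = tuple(raw / raw.sum())
            return replace(m, exchangeabilities=ex, base_frequencies=freqs,
                           alpha=float(np.exp(x[8])), p_inv=float(x[9]))

        def negll(x: np.ndarray) -> float:
            try:
                self.set_model(unpack(x))
            except ValueError:
                return 1e12
            lengths = np.clip(base_lengths * np.exp(x[10]),
                              MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH)
            return -self.log_likelihood(lengths)

        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-10})
        self.set_model(unpack(res.x))
        self.lengths = np.clip(base_lengths * np.exp(res.x[10]),
                               MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH)
        return -float(res.fun)


def log_likelihood(alignment: Alignment, tree: dendropy.Tree,
                   model: SubstitutionModel) -> float:
    """GTR+Γ+I log-likelihood of an alignment on a tree with branch lengths."""
    return TreeLikelihood(alignment, tree, model).log_likelihood()


# ---------------------------------------------------------------------------
# distance matrices and neighbor joining


def p_distance_matrix(alignment: Alignment) -> tuple[list[str], np.ndarray]:
    from .divergence import p_distance

    ids = alignment.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(alignment, ids[i], ids[j]).p_distance
    return ids, d


def jc_distance_matrix(alignment: Alignment) -> tuple[list[str], np.ndarray]:
    """Jukes-Cantor-corrected distances (for NJ starting trees).

    Uncorrected distances underestimate long branches; the JC correction
    d = -3/4 ln(1 - 4p/3) is enough for a starting topology.
    """
    ids, p = p_distance_matrix(alignment)
    p = np.clip(p, 0.0, 0.749)
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return ids, d


def nj_tree(distance_matrix: np.ndarray | Sequence[Sequence[float]],
            labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths clamped to 0."""
    d = np.asarray(distance_matrix, float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix / label shape mismatch")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for lab, row in zip(labels, d):
        buf.write(lab + "," + ",".join(f"{x:.12g}" for x in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# ML fitting


@dataclass
class MlFit:
    tree: dendropy.Tree
    model: SubstitutionModel
    log_likelihood: float
    converged: bool = True
    n_patterns: int = 0


def _nni_neighbors(tree: dendropy.Tree) -> list[dendropy.Tree]:
    """All trees one NNI move away (on internal edges)."""
    out = []
    base = tree.as_string(schema="newick")
    internal = []
    for i, nd in enumerate(tree.postorder_node_iter()):
        if nd.is_leaf() or nd.parent_node is None:
            continue
        internal.append(i)
    for edge_i in internal:
        for swap in (0, 1):
            t = dendropy.Tree.get(data=base, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
            t.is_rooted = tree.is_rooted
            nodes = list(t.postorder_node_iter())
            v = nodes[edge_i]
            u = v.parent_node
            v_children = v.child_nodes()
            u_others = [c for c in u.child_nodes() if c is not v]
            if len(v_children) < 2 or not u_others:
                continue
            a = v_children[swap % len(v_children)]
            b = u_others[0]
            v.remove_child(a)
            u.remove_child(b)
            v.add_child(b)
            u.add_child(a)
            out.append(t)
    return out


def fit_ml(alignment: Alignment, start_tree: dendropy.Tree | None = None,
           search: str = "fixed_topology",
           model: SubstitutionModel | None = None,
           optimize_model: bool = True, tol: float = 1e-6,
           max_rounds: int = 12) -> MlFit:
    """Maximum-likelihood tree estimation under GTR+Γ+I.

    Alternates per-branch Brent optimization with bounded quasi-Newton
    updates of the model parameters.  With ``search="nni"`` the topology is
    additionally improved by nearest-neighbor interchanges until no move
    raises the log-likelihood.
    """
    if search not in ("fixed_topology", "nni"):
        raise ValueError("search must be 'fixed_topology' or 'nni'")
    if start_tree is None:
        ids, d = jc_distance_matrix(alignment)
        start_tree = nj_tree(d, ids)
    if model is None:
        counts = np.zeros(4)
        for rec in alignment.records:
            for c, i in _STATE_INDEX.items():
                counts[i] += rec.residues.count(c)
        freqs = tuple((counts + 1.0) / (counts.sum() + 4.0))
        model = SubstitutionModel(base_frequencies=freqs, alpha=0.5,
                                  p_inv=0.2)

    def optimize_on(tree: dendropy.Tree, mdl: SubstitutionModel,
                    do_model: bool) -> tuple[TreeLikelihood, float, bool]:
        engine = TreeLikelihood(alignment, tree, mdl)
        ll = engine.log_likelihood()
        converged = False
        for _ in range(max_rounds):
            engine.optimize_branch_lengths(sweeps=1, tol=tol)
            new_ll = (engine.optimize_model() if do_model and optimize_model
                      else engine.log_likelihood())
            if new_ll - ll < tol * max(1.0, abs(new_ll)):
                converged = True
                ll = new_ll
                break
            ll = new_ll
        return engine, ll, converged

    engine, ll, converged = optimize_on(start_tree, model, True)
    if search == "nni":
        improved = True
        while improved:
            improved = False
            best = (ll, None)
            for cand in _nni_neighbors(engine.sync_tree()):
                cand_engine = TreeLikelihood(alignment, cand, engine.model)
                cand_ll = cand_engine.optimize_branch_lengths(sweeps=2, tol=tol)
                if cand_ll > best[0] + 1e-6:
                    best = (cand_ll, cand_engine)
            if best[1] is not None:
                engine, ll = best[1], best[0]
                if optimize_model:
                    ll = engine.optimize_model()
                    ll = engine.optimize_branch_lengths(sweeps=1, tol=tol)
                improved = True
    if not converged:
        warnings.warn("ML optimization did not reach the requested tolerance; "
                      "returning best fit found", RuntimeWarning)
    tree = engine.sync_tree()
    return MlFit(tree=tree, model=engine.model, log_likelihood=ll,
                 converged=converged, n_patterns=engine.codes.shape[1])


# ---------------------------------------------------------------------------
# bootstrap


def branch_keys(tree: dendropy.Tree) -> dict[int, tuple[str, ...]]:
    """Name each edge by the tip bipartition it induces.

    Terminal edges are keyed by their single tip label; internal edges by
    the sorted tuple of tip labels on the side of the edge that does not
    contain the lexicographically smallest tip label.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = labels[0]
    all_set = set(labels)
    keys = {}
    for i, nd in enumerate(tree.postorder_node_iter()):
        if nd.parent_node is None:
            continue
        if nd.is_leaf():
            keys[i] = (nd.taxon.label,)
            continue
        below = {lf.taxon.label for lf in nd.leaf_iter()}
        side = below if anchor not in below else all_set - below
        keys[i] = tuple(sorted(side))
    return keys


@dataclass
class BootstrapResult:
    """Per-replicate branch lengths from column resampling."""

    n_replicates: int
    seed: int | None
    branch_lengths: dict[tuple[str, ...], np.ndarray]
    n_failed: int = 0
    reoptimized_model: bool = False

    def ci(self, key: tuple[str, ...], level: float = 0.95
           ) -> tuple[float, float]:
        x = self.branch_lengths[key]
        lo, hi = np.percentile(x, [100 * (1 - level) / 2,
                                   100 * (1 + level) / 2])
        return float(lo), float(hi)

    def cis(self, level: float = 0.95) -> dict[tuple[str, ...], tuple[float, float]]:
        return {k: self.ci(k, level) for k in self.branch_lengths}


def bootstrap_branch_lengths(alignment: Alignment, tree: dendropy.Tree,
                             model: SubstitutionModel, n: int = 1000,
                             seed: int | None = None,
                             optimize_model: bool = False,
                             sweeps: int = 2) -> BootstrapResult:
    """Nonparametric bootstrap of branch lengths on a fixed topology.

    Columns of the original alignment are resampled with replacement; for
    each pseudoreplicate the branch lengths (and optionally the model) are
    re-optimized starting from the maximum-likelihood values.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    engine = TreeLikelihood(alignment, tree, model)
    keys = branch_keys(tree)
    ml_lengths = engine.lengths.copy()
    base_weights = engine.weights.copy()
    probs = base_weights / base_weights.sum()
    n_cols = int(round(base_weights.sum()))
    rng = np.random.default_rng(seed)
    store = {keys[e]: np.empty(n) for e in engine.edges}
    n_failed = 0
    for rep in range(n):
        engine.weights = rng.multinomial(n_cols, probs).astype(float)
        engine.lengths = ml_lengths.copy()
        try:
            if optimize_model:
                engine.optimize_model()
            engine.optimize_branch_lengths(sweeps=sweeps)
            for e in engine.edges:
                store[keys[e]][rep] = engine.lengths[e]
        except Exception:
            n_failed += 1
            for e in engine.edges:
                store[keys[e]][rep] = np.nan
    engine.weights = base_weights
    engine.lengths = ml_lengths
    if optimize_model:
        engine.set_model(model)
    store = {k: v[~np.isnan(v)] for k, v in store.items()}
    return BootstrapResult(n_replicates=n, seed=seed, branch_lengths=store,
                           n_failed=n_failed, reoptimized_model=optimize_model)


@dataclass
class RateTestResult:
    """Bootstrap test of equal length for two branches.

    The two-sided tail fraction of the per-replicate length difference
    serves as the p-value; the per-branch percentile CIs reproduce the
    CI-overlap presentation.
    """

    branch_a: tuple[str, ...]
    branch_b: tuple[str, ...]
    differences: np.ndarray
    tail_fraction: float
    level: float
    reject: bool
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def rate_equality_test(result: BootstrapResult, branch_a: tuple[str, ...],
                       branch_b: tuple[str, ...], level: float = 0.05
                       ) -> RateTestResult:
    """Two-sided bootstrap test that two branch lengths are equal."""
    for key in (branch_a, branch_b):
        if key not in result.branch_lengths:
            raise KeyError(f"branch {key} not in bootstrap result")
    a = result.branch_lengths[branch_a]
    b = result.branch_lengths[branch_b]
    d = a - b
    frac_le = float(np.mean(d <= 0))
    frac_ge = float(np.mean(d >= 0))
    tail = min(1.0, 2.0 * min(frac_le, frac_ge))
    return RateTestResult(
        branch_a=branch_a, branch_b=branch_b, differences=d,
        tail_fraction=tail, level=level, reject=tail < level,
        ci_a=result.ci(branch_a), ci_b=result.ci(branch_b),
    )
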