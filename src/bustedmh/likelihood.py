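"""Phylogenetic likelihood under the branch-site omega / site alpha mixtures.

The branch-site omega draws are iid per (branch, site), so the site
likelihood factorizes into per-branch mixture transition matrices
``M_b = sum_k p_k expm(alpha * Q(omega_k) * t_b * 3 / C)`` and a single
Felsenstein pruning pass per site-level alpha category; the site likelihood
is then the f-weighted mixture over alpha categories. ``C`` is the
mixture-averaged codon flux, so branch lengths are expected substitutions
per nucleotide site.

Matrix exponentials exploit reversibility: with stationary distribution pi,
``S = diag(sqrt pi) Q diag(1/sqrt pi)`` is symmetric, so a single
eigendecomposition per omega category serves every (branch, alpha)
combination. Underflow is controlled by per-node rescaling with the factors
accumulated in log space. Gaps and IUPAC ambiguity codes enter as partial
(indicator) likelihood vectors over the compatible sense codons; an all-gap
column has likelihood one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genetic_code import GeneticCode, get_code
from .rates import (
    AlphaGrid,
    MHRates,
    NucleotideBias,
    OmegaGrid,
    PositionalFrequencies,
    build_rate_matrix,
    stationary_distribution,
)

__all__ = [
    "PhyloTree",
    "CodonAlignment",
    "ModelParameters",
    "SiteLikelihoodTable",
    "LikelihoodEngine",
    "mixture_transition_matrix",
    "transition_matrix",
]


class AlignmentError(ValueError):
    pass


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted view of an (effectively unrooted) phylogeny with branch lengths.

    Bifurcating roots are collapsed on ingestion (the two root edges are not
    separately identifiable under a reversible model), so an N-leaf binary
    tree exposes 2N-3 free branches. Node ids are assigned so that leaves
    come first in parse order; ``postorder`` visits children before parents.
    """

    def __init__(self, parent: np.ndarray, children: list[list[int]],
                 branch_lengths: np.ndarray, leaf_names: list[str],
                 node_names: list[str]):
        self.parent = parent
        self.children = children
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.leaf_names = leaf_names
        self.node_names = node_names
        self.n_nodes = len(parent)
        self.n_leaves = len(leaf_names)
        self.leaf_ids = {name: i for i, name in enumerate(leaf_names)}
        if len(self.leaf_ids) != self.n_leaves:
            raise TreeError("leaf labels must be unique")
        roots = [i for i in range(self.n_nodes) if parent[i] < 0]
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = roots[0]
        if np.any(self.branch_lengths[np.arange(self.n_nodes) != self.root] < 0):
            raise TreeError("branch lengths must be nonnegative")
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(children[node])
        self.postorder = order[::-1]

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree,
                      default_branch_length: float = 0.1) -> "PhyloTree":
        tree = tree.clone(depth=1)
        seed = tree.seed_node
        if len(seed.child_nodes()) == 2:
            a, b = seed.child_nodes()
            keep, fold = (a, b) if a.child_nodes() else (b, a)
            if keep.child_nodes():
                la = keep.edge.length or 0.0
                lb = fold.edge.length or 0.0
                seed.remove_child(keep)
                for child in keep.child_nodes():
                    keep.remove_child(child)
                    seed.add_child(child)
                fold.edge.length = la + lb
        nodes = list(tree.preorder_node_iter())
        leaves = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        ordering = leaves + internals
        ids = {id(n): i for i, n in enumerate(ordering)}
        n = len(ordering)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        names: list[str] = []
        for node in ordering:
            i = ids[id(node)]
            if node.parent_node is not None:
                parent[i] = ids[id(node.parent_node)]
                children[parent[i]].append(i)
                if node.edge.length is None:
                    lengths[i] = default_branch_length
                else:
                    lengths[i] = node.edge.length
            if node.is_leaf():
                names.append(node.taxon.label if node.taxon else f"leaf{i}")
            elif node.label:
                names.append(node.label)
            else:
                names.append(f"node{i}")
        leaf_names = names[:len(leaves)]
        return cls(parent, children, lengths, leaf_names, names)

    @classmethod
    def from_newick(cls, newick: str,
                    default_branch_length: float = 0.1) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"invalid newick: {exc}") from exc
        return cls.from_dendropy(tree, default_branch_length)

    # -- queries ----------------------------------------------------------
    @property
    def n_branches(self) -> int:
        """Free branches in the unrooted sense (non-root nodes)."""
        return self.n_nodes - 1

    @property
    def branch_ids(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if i != self.root])

    def branch_name(self, node: int) -> str:
        return self.node_names[node]

    def to_newick(self, branch_lengths: np.ndarray | None = None) -> str:
        bl = self.branch_lengths if branch_lengths is None else branch_lengths

        def render(node: int) -> str:
            if not self.children[node]:
                label = self.leaf_names[node]
            else:
                label = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return label
            return f"{label}:{bl[node]:.10g}"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class CodonAlignment:
    """Pattern-compressed in-frame codon alignment.

    Each site column is stored once with a multiplicity. Per sequence and
    site the state is either a sense-codon index or a partial-state indicator
    over compatible sense codons (ambiguity codes and gaps). Columns with an
    unambiguous in-frame stop codon are rejected unless ``mask_stops`` is
    set, in which case the offending codon becomes fully missing.
    """

    def __init__(self, sequences: dict[str, str],
                 code: GeneticCode | None = None,
                 mask_stops: bool = False):
        self.code = code or get_code()
        if not sequences:
            raise AlignmentError("alignment is empty")
        names = list(sequences)
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate sequence identifiers")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError("sequences must be aligned (equal lengths)")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} is not divisible by 3")

        self.names = names
        self.n_sites = length // 3
        n_seq = len(names)

        idx = self.code.codon_index
        ambig_masks: list[np.ndarray] = []
        ambig_keys: dict[str, int] = {}
        states = np.zeros((n_seq, self.n_sites), dtype=np.int32)
        for si, name in enumerate(names):
            seq = sequences[name].upper().replace("U", "T")
            for s in range(self.n_sites):
                codon = seq[3 * s: 3 * s + 3]
                state = idx.get(codon)
                if state is not None:
                    states[si, s] = state
                    continue
                if self.code.is_stop(codon):
                    if not mask_stops:
                        raise AlignmentError(
                            f"in-frame stop codon {codon} in sequence "
                            f"{name!r} at codon {s + 1}")
                    codon = "NNN"
                if codon not in ambig_keys:
                    mask = self.code.compatible_sense_indices(codon)
                    if not mask.any():
                        raise AlignmentError(
                            f"codon {codon!r} in sequence {name!r} at codon "
                            f"{s + 1} is compatible with no sense codon")
                    ambig_keys[codon] = len(ambig_masks)
                    ambig_masks.append(mask)
                states[si, s] = -1 - ambig_keys[codon]
        self.states = states
        self.ambiguity_masks = ambig_masks

        # pattern compression on columns
        cols, pattern_index, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = cols.T  # (n_seq, n_patterns)
        self.pattern_index = pattern_index.ravel()
        self.pattern_counts = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    def codon_counts(self) -> np.ndarray:
        """Counts of unambiguous sense codons (input to CF3x4)."""
        counts = np.zeros(self.code.n_sense)
        flat = self.states.ravel()
        unamb = flat[flat >= 0]
        np.add.at(counts, unamb, 1.0)
        if counts.sum() == 0:
            raise AlignmentError("no unambiguous codons in alignment")
        return counts

    def leaf_partial(self, seq_index: int) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-pattern exact states (or -1) and partial matrix if needed."""
        col = self.patterns[seq_index]
        exact = np.where(col >= 0, col, -1).astype(np.int64)
        if (col < 0).any():
            partial = np.zeros((self.n_patterns, self.code.n_sense))
            partial[col >= 0, col[col >= 0]] = 1.0
            for p in np.nonzero(col < 0)[0]:
                partial[p] = self.ambiguity_masks[-1 - col[p]]
            return exact, partial
        return exact, None

    def sequence_string(self, name: str) -> str:
        si = self.names.index(name)
        out = []
        for s in range(self.n_sites):
            st = self.states[si, s]
            out.append(self.code.sense_codons[st] if st >= 0 else "NNN")
        return "".join(out)


# ---------------------------------------------------------------------------
# Parameters and engine
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Full parameter set for one model in the hierarchy."""

    theta: NucleotideBias
    pi: PositionalFrequencies
    omega_grid: OmegaGrid
    alpha_grid: AlphaGrid
    mh: MHRates
    branch_lengths: np.ndarray  # indexed by node id; root entry ignored
    psi_nonsynonymous_only: bool = False


@dataclass
class SiteLikelihoodTable:
    """Per-site likelihood bookkeeping from one pruning pass."""

    log_site: np.ndarray                 # (n_sites,) log P(D_s)
    log_site_by_alpha: np.ndarray        # (L, n_sites) log P(D_s | alpha_l)
    lnl: float
    pattern_index: np.ndarray = field(repr=False, default=None)

    @property
    def site_likelihoods(self) -> np.ndarray:
        return np.exp(self.log_site)


def transition_matrix(decomp, s: float) -> np.ndarray:
    """exp(Q s) from a cached symmetric eigendecomposition."""
    A, lam, Binv = decomp
    return (A * np.exp(lam * s)) @ Binv


class LikelihoodEngine:
    """Pruning machinery bound to one alignment and tree."""

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree,
                 code: GeneticCode | None = None):
        self.code = code or alignment.code
        self.alignment = alignment
        self.tree = tree
        missing = [n for n in tree.leaf_names if n not in alignment.names]
        extra = [n for n in alignment.names if n not in tree.leaf_ids]
        if missing or extra:
            raise TreeError(
                f"leaf/alignment mismatch; tree-only={missing}, "
                f"alignment-only={extra}")
        # leaf partials keyed by tree leaf id, in pattern space
        self._leaf_exact = {}
        self._leaf_partial = {}
        for leaf_id, name in enumerate(tree.leaf_names):
            exact, partial = alignment.leaf_partial(alignment.names.index(name))
            self._leaf_exact[leaf_id] = exact
            self._leaf_partial[leaf_id] = partial
        self._cache_qparts: dict = {}
        self._cache_decomp: dict = {}
        self._cache_pstack: dict = {}

    # -- generator bookkeeping -------------------------------------------
    # Finite-difference optimization perturbs one parameter at a time, so
    # the generator pieces are cached at three levels: the omega-independent
    # syn/nonsyn hit-class components, the per-omega eigendecomposition, and
    # the per-omega transition-matrix stacks over (alpha, branch) slots.

    def _q_parts(self, theta: NucleotideBias, pi: PositionalFrequencies,
                 psi_nonsyn_only: bool):
        from .rates import _pair_factors  # shared factor table

        key = (theta.as_vector().tobytes(), pi.pi.tobytes(), psi_nonsyn_only)
        hit = self._cache_qparts.get(key)
        if hit is not None:
            return key, hit
        code = self.code
        fac = _pair_factors(theta, pi, code)
        d = code.n_diff_matrix
        ns = code.nonsyn_matrix
        np.fill_diagonal(fac, 0.0)
        parts = {}
        for dd, tag in ((1, "1"), (2, "2"), (3, "3")):
            parts["S" + tag] = np.where((d == dd) & ~ns, fac, 0.0)
            parts["N" + tag] = np.where((d == dd) & ns, fac, 0.0)
        if psi_nonsyn_only:
            parts["S3"] = np.zeros_like(fac)
        parts["statd"] = stationary_distribution(pi, code)
        if len(self._cache_qparts) > 8:
            self._cache_qparts.clear()
        self._cache_qparts[key] = parts
        return key, parts

    def _decomposition(self, qkey, parts, omega: float, delta: float,
                       psi: float):
        key = (qkey, omega, delta, psi)
        hit = self._cache_decomp.get(key)
        if hit is not None:
            return key, hit
        off = (parts["S1"] + delta * parts["S2"] + psi * parts["S3"]
               + omega * (parts["N1"] + delta * parts["N2"]
                          + psi * parts["N3"]))
        statd = parts["statd"]
        rows = off.sum(axis=1)
        scale = float(statd @ rows)
        q = off.copy()
        np.fill_diagonal(q, -rows)
        sqrt = np.sqrt(statd)
        sym = (sqrt[:, None] * q) / sqrt[None, :]
        lam, U = np.linalg.eigh((sym + sym.T) / 2.0)
        A = U / sqrt[:, None]
        Binv = (U * sqrt[:, None]).T
        entry = (A, lam, Binv, scale)
        if len(self._cache_decomp) > 128:
            self._cache_decomp.clear()
        self._cache_decomp[key] = entry
        return key, entry

    def _decompositions(self, params: ModelParameters):
        qkey, parts = self._q_parts(params.theta, params.pi,
                                    params.psi_nonsynonymous_only)
        decomps = []
        keys = []
        scales = []
        for om in params.omega_grid.omegas:
            dkey, (A, lam, Binv, scale) = self._decomposition(
                qkey, parts, float(om), params.mh.delta, params.mh.psi)
            decomps.append((A, lam, Binv))
            keys.append(dkey)
            scales.append(scale)
        C = float(np.dot(params.omega_grid.weights, scales))
        if C <= 0:
            raise ValueError("generator has zero flux; cannot scale branch lengths")
        return parts["statd"], decomps, keys, C

    def _transition_stack(self, dkey, decomp, s_values: np.ndarray
                          ) -> np.ndarray:
        key = (dkey, s_values.tobytes())
        hit = self._cache_pstack.get(key)
        if hit is not None:
            return hit
        A, lam, Binv = decomp
        E = np.exp(np.multiply.outer(s_values, lam))
        P = np.matmul(A[None, :, :] * E[:, None, :], Binv)
        if len(self._cache_pstack) > 24:
            self._cache_pstack.clear()
        self._cache_pstack[key] = P
        return P

    # -- main entry -------------------------------------------------------
    def log_likelihood(self, params: ModelParameters,
                       collapse_branch: int | None = None) -> SiteLikelihoodTable:
        """Site and total log-likelihood via pruning.

        ``collapse_branch`` replaces the omega mixture on that branch (node
        id) with a point mass on the last (selective) category — the
        conditional likelihood needed by the empirical Bayes diagnostics.
        """
        aln, tree = self.alignment, self.tree
        if np.any(params.branch_lengths[tree.branch_ids] < 0):
            raise ValueError("branch lengths must be nonnegative")
        statd, decomps, dkeys, C = self._decompositions(params)
        weights = params.omega_grid.weights
        n_pat = aln.n_patterns
        n_state = self.code.n_sense
        L = params.alpha_grid.L
        bids = tree.branch_ids
        s_all = (3.0 / C) * np.multiply.outer(params.alpha_grid.alphas,
                                              params.branch_lengths[bids])
        s_flat = np.ascontiguousarray(s_all.ravel())
        M_all = None
        for w, dkey, dec in zip(weights, dkeys, decomps):
            if w <= 0:
                continue
            P = self._transition_stack(dkey, dec, s_flat)
            M_all = w * P if M_all is None else M_all + w * P
        M_all = M_all.reshape(L, len(bids), n_state, n_state)
        if collapse_branch is not None:
            col = int(np.nonzero(bids == collapse_branch)[0][0])
            A, lam, Binv = decomps[-1]
            for li in range(L):
                E = np.exp(lam * s_all[li, col])
                M_all[li, col] = (A * E[None, :]) @ Binv
        branch_slot = {int(b): i for i, b in enumerate(bids)}
        # batched pruning over all alpha categories at once
        log_scale = np.zeros((L, n_pat))
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            kids = tree.children[node]
            if not kids:
                continue
            part = None
            for child in kids:
                Mc = M_all[:, branch_slot[child]]          # (L, n, n)
                McT = Mc.transpose(0, 2, 1)
                if not tree.children[child]:
                    exact = self._leaf_exact[child]
                    pm = self._leaf_partial[child]
                    msg = McT[:, np.clip(exact, 0, None), :]
                    if pm is not None:
                        amb = np.matmul(pm[None, :, :], McT)
                        msg = np.where((exact >= 0)[None, :, None], msg, amb)
                else:
                    msg = np.matmul(partials.pop(child), McT)
                part = msg if part is None else part * msg
            peak = part.max(axis=2)
            peak = np.where(peak > 0, peak, 1.0)
            part /= peak[:, :, None]
            log_scale += np.log(peak)
            partials[node] = part
        site = partials[tree.root] @ statd                  # (L, n_pat)
        bad = ~np.isfinite(site) | (site <= 0)
        if bad.any():
            pat_bad = np.nonzero(bad.any(axis=0))[0]
            offender = int(np.nonzero(np.isin(aln.pattern_index, pat_bad))[0][0])
            raise FloatingPointError(
                f"non-finite site likelihood at codon site {offender + 1}")
        log_pat_alpha = np.log(site) + log_scale
        fw = np.log(np.clip(params.alpha_grid.weights, 1e-300, None))
        stacked = log_pat_alpha + fw[:, None]
        mx = stacked.max(axis=0)
        log_pat = mx + np.log(np.exp(stacked - mx).sum(axis=0))
        lnl = float(aln.pattern_counts @ log_pat)
        pidx = aln.pattern_index
        return SiteLikelihoodTable(
            log_site=log_pat[pidx],
            log_site_by_alpha=log_pat_alpha[:, pidx],
            lnl=lnl,
            pattern_index=pidx,
        )


def mixture_transition_matrix(theta: NucleotideBias, pi: PositionalFrequencies,
                              omega_grid: OmegaGrid, alpha: float, t: float,
                              mh: MHRates = MHRates(),
                              code: GeneticCode | None = None,
                              flux_scale: float | None = None) -> np.ndarray:
    """Row-stochastic per-branch mixture matrix sum_k p_k expm(alpha Q_k t 3/C)."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    code = code or get_code()
    from scipy.linalg import expm

    mats = []
    scales = []
    for om in omega_grid.omegas:
        rm = build_rate_matrix(theta, pi, om, mh, code)
        mats.append(rm.q)
        scales.append(rm.scale)
    C = flux_scale if flux_scale is not None else float(
        np.dot(omega_grid.weights, scales))
    M = np.zeros_like(mats[0])
    for w, q in zip(omega_grid.weights, mats):
        M += w * expm(q * (3.0 * alpha * t / C))
    return M
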