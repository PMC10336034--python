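"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the model definition with
plain loops and :func:`scipy.linalg.expm` — no code is shared with the
pruning engine, its eigendecomposition shortcut, or its caches.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

NUC = "ACGT"
PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


def slow_rate_matrix(sense_codons, aa_of, theta: dict, pi: np.ndarray,
                     omega: float, delta: float, psi: float) -> np.ndarray:
    """Direct double-loop construction of the codon generator."""
    n = len(sense_codons)
    q = np.zeros((n, n))
    for i, ci in enumerate(sense_codons):
        for j, cj in enumerate(sense_codons):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            mult = {1: 1.0, 2: delta, 3: psi}[len(diff)]
            rate = mult
            for p in diff:
                rate *= theta["".join(sorted(ci[p] + cj[p]))]
                rate *= pi[p, NUC.index(cj[p])]
            if aa_of[ci] != aa_of[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def slow_stationary(sense_codons, pi: np.ndarray) -> np.ndarray:
    w = np.array([pi[0, NUC.index(c[0])] * pi[1, NUC.index(c[1])]
                  * pi[2, NUC.index(c[2])] for c in sense_codons])
    return w / w.sum()


def _prune_fixed(tree, leaf_states_site, P_by_branch, statd):
    """Standard pruning for ONE site with a fixed matrix per branch."""
    def conditional(node):
        if not tree.children[node]:
            vec = np.zeros(len(statd))
            vec[leaf_states_site[node]] = 1.0
            return vec
        out = np.ones(len(statd))
        for child in tree.children[node]:
            down = conditional(child)
            out = out * (P_by_branch[child] @ down)
        return out
    return float(conditional(tree.root) @ statd)


def brute_force_loglik(alignment, tree, sense_codons, aa_of, theta, pi,
                       omega_grid, alpha_grid, delta, psi) -> float:
    """Exhaustive mixture enumeration: sum over every per-branch omega
    assignment and per-site alpha category, pruning each combination with a
    single (non-mixture) transition matrix per branch."""
    omegas, ow = omega_grid
    alphas, aw = alpha_grid
    qs = [slow_rate_matrix(sense_codons, aa_of, theta, pi, om, delta, psi)
          for om in omegas]
    statd = slow_stationary(sense_codons, pi)
    flux = [float(statd @ -np.diag(q)) for q in qs]
    C = float(np.dot(ow, flux))
    branches = [b for b in range(tree.n_nodes) if b != tree.root]
    P = {}
    for b in branches:
        for k in range(len(omegas)):
            for li, al in enumerate(alphas):
                s = 3.0 * al * tree.branch_lengths[b] / C
                P[(b, k, li)] = expm(qs[k] * s)
    leaf_states = {tree.leaf_ids[name]: alignment.states[si]
                   for si, name in enumerate(alignment.names)}
    total = 0.0
    for site in range(alignment.n_sites):
        states_site = {leaf: leaf_states[leaf][site] for leaf in leaf_states}
        site_lik = 0.0
        for li in range(len(alphas)):
            acc = 0.0
            for combo in itertools.product(range(len(omegas)),
                                           repeat=len(branches)):
                weight = float(np.prod([ow[k] for k in combo]))
                mats = {b: P[(b, k, li)] for b, k in zip(branches, combo)}
                acc += weight * _prune_fixed(tree, states_site, mats, statd)
            site_lik += aw[li] * acc
        total += np.log(site_lik)
    return total
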