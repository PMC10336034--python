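"""Maximum-likelihood fitting for the BUSTED model hierarchy.

The user-facing surface follows the statsmodels convention: a
:class:`BustedModel` is built from a codon alignment and a tree, and
``fit()`` returns a :class:`BustedResults` carrying the MLEs, the maximized
log-likelihood, the parameter count, AICc, and a ``summary()`` table.

Optimization notes
------------------
All constrained quantities are mapped to a box so a single L-BFGS-B pass
applies: the omega grid uses cumulative shrinkage factors
(omega_{K-1} = s_{K-1}, omega_{K-2} = s_{K-1} s_{K-2}, ... with s in [0, 1])
and omega_K = 1 + e^u for the alternative model (omega_K pinned to 1 under
the null); mixture weights use stick-breaking; the alpha grid is
parameterized by L-1 ordered raw-rate increments plus L-1 weights with the
overall scale solved from the unit-mean constraint; delta and psi live on
[0, inf) so the nested single-hit model is an interior boundary point of the
search space, never excluded.

The fitting schedule is staged: (1) a nucleotide-level GTR fit supplies
initial branch lengths and exchangeabilities (positional frequencies come
from CF3x4 and are held fixed, as in the reference procedure); (2) the
mixture hyperparameters are optimized with branch lengths and theta held at
their current values (with optional jittered restarts); (3) a joint
quasi-Newton polish over all free parameters. Richer models seeded from a
nested fit start at the nested optimum, which guarantees the monotone
nesting of maximized log-likelihoods.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .genetic_code import NUCLEOTIDE_PAIRS, GeneticCode
from .likelihood import (
    CodonAlignment,
    LikelihoodEngine,
    ModelParameters,
    PhyloTree,
    SiteLikelihoodTable,
)
from .rates import (
    AlphaGrid,
    MHRates,
    ModelConfig,
    NucleotideBias,
    OmegaGrid,
    PositionalFrequencies,
    cf3x4,
)

__all__ = ["BustedModel", "BustedResults", "count_parameters", "fit_model"]

_BL_MAX = 25.0
_THETA_BOUNDS = (1e-4, 100.0)
_MH_BOUNDS = (0.0, 100.0)
_OMEGA3_UMAX = 10.0  # omega3 <= 1 + e^10 ~ 2.2e4


def count_parameters(config: ModelConfig, n_branches: int) -> int:
    """Estimated-parameter count for a model configuration.

    Component tally: B branch lengths + 5 GTR exchangeabilities + 9
    positional frequencies + (2K - 1) omega-grid hyperparameters
    + 2(L - 1) alpha-grid hyperparameters when SRV is on + 1 (delta) or 2
    (delta, psi) multihit rates.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    k = n_branches + 5 + 9 + (2 * config.K - 1)
    if config.srv:
        k += 2 * (config.L - 1)
    if config.mh_mode == "double":
        k += 1
    elif config.mh_mode == "double+triple":
        k += 2
    return k


# ---------------------------------------------------------------------------
# box transform between free vectors and ModelParameters
# ---------------------------------------------------------------------------

class _Transform:
    """Pack/unpack a ModelParameters into a bounded free vector."""

    def __init__(self, config: ModelConfig, tree: PhyloTree,
                 pi: PositionalFrequencies,
                 constrain_omega_last: bool = False,
                 psi_nonsynonymous_only: bool = False):
        self.config = config
        self.tree = tree
        self.pi = pi
        self.constrain = constrain_omega_last
        self.psi_nonsyn = psi_nonsynonymous_only
        K, L = config.K, config.L
        self.branch_ids = tree.branch_ids
        blocks = []
        lo, hi = [], []

        def add(name, size, lo_v, hi_v):
            blocks.append((name, size))
            lo.extend([lo_v] * size)
            hi.extend([hi_v] * size)

        add("theta", 5, *_THETA_BOUNDS)
        add("bl", len(self.branch_ids), 0.0, _BL_MAX)
        add("omega_s", K - 1, 0.0, 1.0)
        if not self.constrain:
            add("omega_u", 1, -25.0, _OMEGA3_UMAX)
        add("omega_w", K - 1, 0.0, 1.0)
        if config.srv:
            add("alpha_d", L - 1, 0.0, 1e4)
            add("alpha_w", L - 1, 0.0, 1.0)
        if config.mh_mode in ("double", "double+triple"):
            add("delta", 1, *_MH_BOUNDS)
        if config.mh_mode == "double+triple":
            add("psi", 1, *_MH_BOUNDS)
        self.slices = {}
        off = 0
        for name, size in blocks:
            self.slices[name] = slice(off, off + size)
            off += size
        self.n_free = off
        self.bounds = list(zip(lo, hi))
        self.mixture_indices = np.concatenate([
            np.arange(self.slices[n].start, self.slices[n].stop)
            for n in ("omega_s", "omega_u", "omega_w", "alpha_d", "alpha_w",
                      "delta", "psi") if n in self.slices
        ]).astype(int)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _stick_break(b: np.ndarray) -> np.ndarray:
        w = np.empty(len(b) + 1)
        rem = 1.0
        for i, bi in enumerate(b):
            w[i] = rem * bi
            rem *= (1.0 - bi)
        w[-1] = rem
        return np.clip(w, 0.0, 1.0)

    @staticmethod
    def _stick_unbreak(w: np.ndarray) -> np.ndarray:
        b = np.empty(len(w) - 1)
        rem = 1.0
        for i in range(len(w) - 1):
            b[i] = w[i] / rem if rem > 1e-12 else 0.0
            rem -= w[i]
        return np.clip(b, 0.0, 1.0)

    # -- vector -> params -------------------------------------------------
    def unpack(self, x: np.ndarray) -> ModelParameters:
        cfg = self.config
        g = lambda n: x[self.slices[n]]
        theta = NucleotideBias(dict(zip(
            NUCLEOTIDE_PAIRS,
            [v if p != "AG" else 1.0 for p, v in zip(
                NUCLEOTIDE_PAIRS, self._theta_full(g("theta")))])))
        bl = np.zeros(self.tree.n_nodes)
        bl[self.branch_ids] = g("bl")
        s = g("omega_s")
        om = np.empty(cfg.K)
        om[-1] = 1.0 if self.constrain else 1.0 + np.exp(g("omega_u")[0])
        # cumulative products of s in [0,1] give the ordered sub-neutral bins
        om[:-1] = np.cumprod(s[::-1])[::-1]
        ow = self._stick_break(g("omega_w"))
        omega_grid = OmegaGrid(om, ow)
        if cfg.srv:
            raw = np.concatenate([[1.0], 1.0 + np.cumsum(g("alpha_d"))])
            aw = self._stick_break(g("alpha_w"))
            alpha_grid = AlphaGrid.from_raw(raw, aw)
        else:
            alpha_grid = AlphaGrid.constant(cfg.L if cfg.srv else 1)
        delta = g("delta")[0] if "delta" in self.slices else 0.0
        psi = g("psi")[0] if "psi" in self.slices else 0.0
        return ModelParameters(
            theta=theta, pi=self.pi, omega_grid=omega_grid,
            alpha_grid=alpha_grid, mh=MHRates(delta, psi),
            branch_lengths=bl, psi_nonsynonymous_only=self.psi_nonsyn)

    @staticmethod
    def _theta_full(free5: np.ndarray) -> np.ndarray:
        out = []
        it = iter(free5)
        for p in NUCLEOTIDE_PAIRS:
            out.append(1.0 if p == "AG" else next(it))
        return np.array(out)

    # -- params -> vector -------------------------------------------------
    def pack(self, params: ModelParameters) -> np.ndarray:
        cfg = self.config
        x = np.zeros(self.n_free)
        x[self.slices["theta"]] = [params.theta.theta[p]
                                   for p in NUCLEOTIDE_PAIRS if p != "AG"]
        x[self.slices["bl"]] = params.branch_lengths[self.branch_ids]
        om = np.asarray(params.omega_grid.omegas, dtype=float)[:cfg.K]
        if len(om) < cfg.K:
            om = np.pad(om, (0, cfg.K - len(om)), constant_values=om[-1])
        om_sub = np.clip(om[:-1], 0.0, 1.0)
        s = np.empty(cfg.K - 1)
        for i in range(cfg.K - 2, -1, -1):
            upper = om_sub[i + 1] if i + 1 < cfg.K - 1 else 1.0
            s[i] = om_sub[i] / upper if upper > 1e-12 else 1.0
        x[self.slices["omega_s"]] = np.clip(s, 0.0, 1.0)
        if not self.constrain:
            x[self.slices["omega_u"]] = np.log(max(om[-1] - 1.0, 1e-8))
        w = np.asarray(params.omega_grid.weights, dtype=float)[:cfg.K]
        w = w / w.sum()
        x[self.slices["omega_w"]] = self._stick_unbreak(w)
        if cfg.srv:
            al = np.asarray(params.alpha_grid.alphas, dtype=float)
            aw = np.asarray(params.alpha_grid.weights, dtype=float)
            if len(al) != cfg.L:
                al = np.linspace(0.5, 2.0, cfg.L)
                aw = np.full(cfg.L, 1.0 / cfg.L)
            base = al[0] if al[0] > 1e-9 else 1e-9
            raw = al / base
            x[self.slices["alpha_d"]] = np.clip(np.diff(raw), 0.0, 1e4)
            x[self.slices["alpha_w"]] = self._stick_unbreak(aw / aw.sum())
        if "delta" in self.slices:
            x[self.slices["delta"]] = params.mh.delta
        if "psi" in self.slices:
            x[self.slices["psi"]] = params.mh.psi
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class BustedResults:
    """MLEs and fit diagnostics for one model of the hierarchy."""

    model: "BustedModel" = field(repr=False)
    config: ModelConfig
    params: ModelParameters = field(repr=False)
    llf: float
    k_params: int
    nobs: int
    constrained: bool
    converged: bool
    n_iter: int
    n_fev: int
    fit_seconds: float
    site_table: SiteLikelihoodTable = field(repr=False, default=None)

    @property
    def name(self) -> str:
        return self.config.name + (" (null)" if self.constrained else "")

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def tree_length(self) -> float:
        return float(self.params.branch_lengths[self.model.tree.branch_ids].sum())

    @property
    def omega3(self) -> float:
        return float(self.params.omega_grid.omegas[-1])

    @property
    def p3(self) -> float:
        return float(self.params.omega_grid.weights[-1])

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{self.name} fit",
            "=" * 58,
            f"log-likelihood {self.llf:14.4f}   parameters {self.k_params:4d}",
            f"AICc           {self.aicc:14.4f}   n (chars)  {self.nobs:4d}",
            f"tree length    {self.tree_length:14.4f}   converged  {self.converged}",
            "omega grid : " + "  ".join(
                f"{o:.4g}@{w:.1%}" for o, w in
                zip(p.omega_grid.omegas, p.omega_grid.weights)),
        ]
        if self.config.srv:
            lines.append("alpha grid : " + "  ".join(
                f"{a:.4g}@{w:.1%}" for a, w in
                zip(p.alpha_grid.alphas, p.alpha_grid.weights))
                + f"   CV(alpha)={p.alpha_grid.cv:.3f}")
        if self.config.mh_mode != "none":
            lines.append(f"delta (2H) : {p.mh.delta:.4g}"
                         + (f"   psi (3H) : {p.mh.psi:.4g}"
                            if self.config.mh_mode == "double+triple" else ""))
        lines.append("theta      : " + "  ".join(
            f"{k}={v:.3g}" for k, v in sorted(p.theta.theta.items())))
        return "\n".join(lines)

    def check_overfitting(self) -> list[str]:
        """Flag near-duplicate grid rates or vanishing weights."""
        msgs = []
        for label, vals, w in (
                ("omega", self.params.omega_grid.omegas,
                 self.params.omega_grid.weights),
                ("alpha", self.params.alpha_grid.alphas,
                 self.params.alpha_grid.weights)):
            v = np.asarray(vals)
            for i in range(len(v) - 1):
                denom = max(abs(v[i + 1]), 1e-12)
                if abs(v[i + 1] - v[i]) / denom < 1e-3:
                    msgs.append(f"{label} grid rates {i + 1} and {i + 2} "
                                "are nearly identical")
            if np.any(np.asarray(w) < 1e-4):
                msgs.append(f"{label} grid has a near-zero weight")
        return msgs


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class BustedModel:
    """Episodic-selection model bound to one alignment and tree.

    Parameters
    ----------
    alignment, tree :
        Codon data and phylogeny; leaf labels must match.
    config :
        Which hierarchy member to fit (default the full +S+MH model).
    """

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree,
                 config: ModelConfig = ModelConfig.smh(),
                 code: GeneticCode | None = None,
                 psi_nonsynonymous_only: bool = False):
        self.alignment = alignment
        self.tree = tree
        self.config = config
        self.code = code or alignment.code
        self.psi_nonsynonymous_only = psi_nonsynonymous_only
        self.engine = LikelihoodEngine(alignment, tree, self.code)
        self._pi: PositionalFrequencies | None = None
        self._nuc_stage: tuple[NucleotideBias, np.ndarray] | None = None

    @classmethod
    def from_files(cls, alignment_path, tree_path, config=ModelConfig.smh(),
                   mask_stops: bool = False, **kwargs) -> "BustedModel":
        from .io import read_codon_alignment, read_tree
        aln = read_codon_alignment(alignment_path, mask_stops=mask_stops)
        tree = read_tree(tree_path, alignment=aln)
        return cls(aln, tree, config=config, **kwargs)

    # -- stage 0: fixed quantities ---------------------------------------
    @property
    def pi(self) -> PositionalFrequencies:
        if self._pi is None:
            self._pi = cf3x4(self.alignment.codon_counts(), self.code)
        return self._pi

    @property
    def nobs(self) -> int:
        """AICc sample size: characters = sequences x codon sites."""
        return self.alignment.n_sequences * self.alignment.n_sites

    # -- stage 1: nucleotide GTR for starting values ----------------------
    def nucleotide_stage(self) -> tuple[NucleotideBias, np.ndarray]:
        """GTR fit at the nucleotide level for theta and branch-length inits."""
        if self._nuc_stage is not None:
            return self._nuc_stage
        aln, tree = self.alignment, self.tree
        # nucleotide matrix in tree-leaf order, -1 for ambiguous
        n_leaf = tree.n_leaves
        cols = np.full((n_leaf, aln.n_sites * 3), -1, dtype=np.int8)
        for leaf_id, name in enumerate(tree.leaf_names):
            si = aln.names.index(name)
            for s in range(aln.n_sites):
                st = aln.states[si, s]
                if st >= 0:
                    cols[leaf_id, 3 * s: 3 * s + 3] = \
                        self.code.codon_nucleotides[st]
        pats, inv, cnt = np.unique(cols.T, axis=0, return_inverse=True,
                                   return_counts=True)
        pats = pats.T
        counts = cnt.astype(float)
        freq = np.bincount(cols[cols >= 0].ravel(), minlength=4).astype(float)
        freq = (freq + 1.0) / (freq + 1.0).sum()
        bids = tree.branch_ids
        n_free = 5 + len(bids)

        def nll(x):
            th = _Transform._theta_full(x[:5])
            bl = x[5:]
            R = np.zeros((4, 4))
            k = 0
            for i in range(4):
                for j in range(i + 1, 4):
                    R[i, j] = R[j, i] = th[k]
                    k += 1
            Q = R * freq[None, :]
            np.fill_diagonal(Q, 0.0)
            scale = float(freq @ Q.sum(axis=1))
            Q = Q / scale
            np.fill_diagonal(Q, -Q.sum(axis=1))
            sq = np.sqrt(freq)
            sym = sq[:, None] * Q / sq[None, :]
            lam, U = np.linalg.eigh((sym + sym.T) / 2)
            A = U / sq[:, None]
            Binv = (U * sq[:, None]).T
            mats = {}
            for bi, node in enumerate(bids):
                mats[node] = (A * np.exp(lam * bl[bi])) @ Binv
            partials = {}
            logsc = np.zeros(pats.shape[1])
            for node in tree.postorder:
                kids = tree.children[node]
                if not kids:
                    continue
                part = np.ones((pats.shape[1], 4))
                for child in kids:
                    M = mats[child]
                    if not tree.children[child]:
                        obs = pats[child]
                        msg = np.where((obs >= 0)[:, None],
                                       M[:, np.clip(obs, 0, None)].T, 1.0)
                    else:
                        msg = partials.pop(child) @ M.T
                    part *= msg
                peak = np.where(part.max(1) > 0, part.max(1), 1.0)
                part /= peak[:, None]
                logsc += np.log(peak)
                partials[node] = part
            site = partials[tree.root] @ freq
            return -float(counts @ (np.log(np.clip(site, 1e-300, None)) + logsc))

        x0 = np.concatenate([np.ones(5) * 0.5,
                             np.clip(tree.branch_lengths[bids], 1e-4, 5.0)])
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(1e-4, 100.0)] * 5 + [(1e-8, _BL_MAX)] * len(bids),
                       options={"maxiter": 300, "ftol": 1e-9})
        theta = NucleotideBias(dict(zip(
            NUCLEOTIDE_PAIRS, _Transform._theta_full(res.x[:5]))))
        bl = np.zeros(tree.n_nodes)
        bl[bids] = res.x[5:]
        self._nuc_stage = (theta, bl)
        return self._nuc_stage

    # -- initial parameter sets ------------------------------------------
    def default_start(self, constrain_omega_last: bool) -> ModelParameters:
        theta, bl = self.nucleotide_stage()
        K, L = self.config.K, self.config.L
        if K == 1:
            om = OmegaGrid([1.0 if constrain_omega_last else 1.5], [1.0])
        else:
            sub = np.linspace(0.2, 0.7, K - 1)
            last = 1.0 if constrain_omega_last else 2.0
            w = np.full(K, 1.0 / K)
            om = OmegaGrid(np.concatenate([sub, [last]]), w)
        if self.config.srv:
            alpha = AlphaGrid.from_raw(np.linspace(0.6, 2.0, L),
                                       np.full(L, 1.0 / L))
        else:
            alpha = AlphaGrid.constant(1)
        if self.config.mh_mode == "none":
            mh = MHRates(0.0, 0.0)
        elif self.config.mh_mode == "double":
            mh = MHRates(0.05, 0.0)
        else:
            mh = MHRates(0.05, 0.05)
        return ModelParameters(theta=theta, pi=self.pi, omega_grid=om,
                               alpha_grid=alpha, mh=mh, branch_lengths=bl,
                               psi_nonsynonymous_only=self.psi_nonsynonymous_only)

    def _adapt_seed(self, seed_params: ModelParameters,
                    constrain_omega_last: bool) -> ModelParameters:
        """Project a (possibly nested) parameter set onto this config."""
        base = self.default_start(constrain_omega_last)
        om = np.array(seed_params.omega_grid.omegas, dtype=float)
        ow = np.array(seed_params.omega_grid.weights, dtype=float)
        if len(om) == self.config.K:
            if constrain_omega_last:
                om = om.copy()
                om[-1] = 1.0
            omega = OmegaGrid(np.minimum.accumulate(om[::-1])[::-1]
                              if np.any(np.diff(om) < 0) else om, ow)
        else:
            omega = base.omega_grid
        if not self.config.srv:
            alpha = base.alpha_grid
        elif seed_params.alpha_grid.L == self.config.L:
            alpha = seed_params.alpha_grid
        else:
            # seed had no (or a different) SRV grid: start at the degenerate
            # equal-rates point so the seeded likelihood is reproduced exactly
            alpha = AlphaGrid(np.ones(self.config.L),
                              np.full(self.config.L, 1.0 / self.config.L))
        if self.config.mh_mode == "none":
            mh = MHRates(0.0, 0.0)
        elif self.config.mh_mode == "double":
            mh = MHRates(seed_params.mh.delta, 0.0)
        else:
            mh = MHRates(seed_params.mh.delta, seed_params.mh.psi)
        return ModelParameters(
            theta=seed_params.theta, pi=self.pi, omega_grid=omega,
            alpha_grid=alpha, mh=mh,
            branch_lengths=seed_params.branch_lengths.copy(),
            psi_nonsynonymous_only=self.psi_nonsynonymous_only)

    # -- fitting ----------------------------------------------------------
    def fit(self, start_params: ModelParameters | BustedResults | None = None,
            constrain_omega3: bool = False,
            starts: int = 3, seed: int = 0,
            maxiter: int = 400, mixture_maxiter: int = 120,
            phase_a: bool = True, effort: float = 1.0,
            warn_overfit: bool = True) -> BustedResults:
        """Maximize the likelihood; deterministic given (starts, seed).

        ``start_params`` may be a nested model's results (or parameter set);
        the optimizer then starts from that optimum, which guarantees
        lnL(richer) >= lnL(nested) up to optimizer tolerance.
        ``constrain_omega3`` pins the selective omega category to 1 (the EDS
        null hypothesis). ``effort`` scales the per-phase evaluation budgets
        (1.0 = publication quality; replicate harnesses use less).
        """
        t0 = time.perf_counter()
        if isinstance(start_params, BustedResults):
            start_params = start_params.params
        tr = _Transform(self.config, self.tree, self.pi,
                        constrain_omega_last=constrain_omega3,
                        psi_nonsynonymous_only=self.psi_nonsynonymous_only)
        if start_params is None:
            init = self.default_start(constrain_omega3)
        else:
            init = self._adapt_seed(start_params, constrain_omega3)
        x0 = tr.pack(init)
        n_fev = [0]

        def nll(x):
            n_fev[0] += 1
            try:
                return -self.engine.log_likelihood(tr.unpack(x)).lnl
            except FloatingPointError:
                return 1e12

        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in tr.bounds])
        hi = np.array([b[1] for b in tr.bounds])
        mix = tr.mixture_indices
        mix_bounds = [tr.bounds[i] for i in mix]
        best_x, best_f = x0.copy(), nll(x0)
        n_iter = 0

        def mixture_pass(x_base, x_mix_start, opts):
            def nll_mix(xm):
                y = x_base.copy()
                y[mix] = xm
                return nll(y)
            return minimize(nll_mix, x_mix_start, method="L-BFGS-B",
                            bounds=mix_bounds, options=opts)

        # A: mixture hyperparameters only, with jittered restarts
        if phase_a and len(mix) > 0 and mixture_maxiter > 0:
            starts_list = [x0[mix]]
            if not constrain_omega3 and starts > 1 and self.config.K > 1:
                # strong-selection start: a small branch-site fraction with a
                # large omega_3 lives in a narrow basin the gradient cannot
                # reach once the weight has collapsed to zero
                eds = x0.copy()
                eds[tr.slices["omega_u"]] = np.log(49.0)
                w_sticks = np.full(self.config.K - 1, 0.5)
                w_sticks[-1] = 0.9  # leaves ~5% beyond the last stick
                eds[tr.slices["omega_w"]] = w_sticks
                starts_list.append(eds[mix])
            for _ in range(max(starts - len(starts_list), 0)):
                jit = x0[mix] + rng.normal(scale=0.25, size=len(mix)) * \
                    np.maximum(np.abs(x0[mix]), 0.3)
                starts_list.append(np.clip(jit, lo[mix], hi[mix]))
            for sx in starts_list:
                res_a = mixture_pass(x0, sx, {"maxiter": mixture_maxiter,
                                              "maxfun": int(450 * effort),
                                              "ftol": 1e-6})
                n_iter += res_a.nit
                if res_a.fun < best_f:
                    best_f = res_a.fun
                    best_x = x0.copy()
                    best_x[mix] = res_a.x

        # A2 (cold starts only): 1-D tree-length rescale — the nucleotide
        # stage underestimates codon-model branch lengths under selection,
        # and a single scalar recovers most of the difference cheaply
        if start_params is None and "bl" in tr.slices:
            from scipy.optimize import minimize_scalar
            bl_sl = tr.slices["bl"]
            base = best_x.copy()

            def scaled(u):
                y = base.copy()
                y[bl_sl] = np.clip(base[bl_sl] * np.exp(u), 1e-8, _BL_MAX)
                return nll(y)

            rs = minimize_scalar(scaled, bounds=(-1.5, 1.5), method="bounded",
                                 options={"xatol": 1e-3})
            if rs.fun < best_f:
                best_f = rs.fun
                best_x = base.copy()
                best_x[bl_sl] = np.clip(base[bl_sl] * np.exp(rs.x),
                                        1e-8, _BL_MAX)

        # B: joint pass over all free parameters
        res = minimize(nll, best_x, method="L-BFGS-B", bounds=tr.bounds,
                       options={"maxiter": maxiter,
                                "maxfun": int(1000 * effort), "ftol": 3e-7})
        n_iter += res.nit
        if res.fun <= best_f:
            best_x, best_f = res.x, res.fun
        converged = bool(res.success) or res.status == 1

        # C/D: tight mixture refinement, then a short joint polish
        if len(mix) > 0 and mixture_maxiter > 0:
            res_c = mixture_pass(best_x, best_x[mix],
                                 {"maxiter": 80, "maxfun": int(450 * effort),
                                  "ftol": 1e-9})
            n_iter += res_c.nit
            if res_c.fun < best_f:
                best_f = res_c.fun
                best_x = best_x.copy()
                best_x[mix] = res_c.x
        res_d = minimize(nll, best_x, method="L-BFGS-B", bounds=tr.bounds,
                         options={"maxiter": 40,
                                  "maxfun": int(350 * effort), "ftol": 1e-8})
        n_iter += res_d.nit
        if res_d.fun <= best_f:
            best_x, best_f = res_d.x, res_d.fun
        params = tr.unpack(best_x)
        table = self.engine.log_likelihood(params)
        k = count_parameters(self.config, self.tree.n_branches)
        if constrain_omega3:
            k -= 1  # omega_K pinned to 1 is no longer estimated
        out = BustedResults(
            model=self, config=self.config, params=params,
            llf=table.lnl, k_params=k,
            nobs=self.nobs, constrained=constrain_omega3,
            converged=converged, n_iter=int(n_iter), n_fev=n_fev[0],
            fit_seconds=time.perf_counter() - t0, site_table=table)
        if not converged:
            warnings.warn(f"{out.name}: optimizer stopped without convergence "
                          f"(status {res.status}); result flagged",
                          RuntimeWarning, stacklevel=2)
        if warn_overfit:
            for msg in out.check_overfitting():
                warnings.warn(f"{out.name}: possible overfitting — {msg}",
                              RuntimeWarning, stacklevel=2)
        return out


def fit_model(alignment: CodonAlignment, tree: PhyloTree, config: ModelConfig,
              seed_fit: BustedResults | None = None,
              constrain_omega3: bool = False, fix_psi_zero: bool = False,
              starts: int = 3, seed: int = 0, **kwargs) -> BustedResults:
    """Functional wrapper around :meth:`BustedModel.fit`."""
    if fix_psi_zero and config.mh_mode == "double+triple":
        config = replace(config, mh_mode="double")
    model = BustedModel(alignment, tree, config=config)
    if seed_fit is not None:
        model._nuc_stage = (seed_fit.params.theta,
                            seed_fit.params.branch_lengths.copy())
    return model.fit(start_params=seed_fit, constrain_omega3=constrain_omega3,
                     starts=starts, seed=seed, **kwargs)
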