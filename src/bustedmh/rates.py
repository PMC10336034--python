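"""The +S+MH codon rate-matrix family and its analytic summaries.

The instantaneous generator acts on sense codons. A change at ``d`` nucleotide
positions (d = 1, 2, 3) between codons ``i`` and ``j`` has rate

    q_ij = m_d * (omega if nonsynonymous else 1)
           * prod_n theta(i_n, j_n) * pi^n_{j_n}

with multipliers m_1 = 1, m_2 = delta (the double-hit rate) and m_3 = psi
(the triple-hit rate). ``theta`` are the five identifiable GTR
exchangeabilities (theta_AG = 1 is the reference), and ``pi^n`` are
position-specific target-nucleotide frequencies estimated by the CF3x4
procedure. The site-level synonymous rate alpha and the branch-site omega
mixture are applied by the likelihood layer; setting delta = psi = 0 recovers
the classic single-hit codon model entry-for-entry.

The chain is reversible with stationary distribution proportional to the
positional product restricted to sense codons. Branch lengths are measured in
expected substitutions per *nucleotide* site: the generator is rescaled by
3 / C with C the mixture-averaged codon flux (see :func:`mixture_scale`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .genetic_code import NUCLEOTIDE_PAIRS, GeneticCode, get_code

__all__ = [
    "NucleotideBias",
    "PositionalFrequencies",
    "OmegaGrid",
    "AlphaGrid",
    "MHRates",
    "ModelConfig",
    "RateMatrix",
    "Decomposition",
    "build_rate_matrix",
    "stationary_distribution",
    "mixture_scale",
    "branch_length_decomposition",
    "cf3x4",
    "f3x4",
]


@dataclass(frozen=True)
class NucleotideBias:
    """Symmetric GTR exchangeabilities over unordered nucleotide pairs.

    ``theta[AG] = 1`` is the reference, giving five free parameters.
    """

    theta: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(NUCLEOTIDE_PAIRS) - set(self.theta)
        if missing:
            raise ValueError(f"missing exchangeabilities: {sorted(missing)}")
        if any(v < 0 for v in self.theta.values()):
            raise ValueError("exchangeabilities must be nonnegative")

    @classmethod
    def equal(cls) -> "NucleotideBias":
        return cls({p: 1.0 for p in NUCLEOTIDE_PAIRS})

    @classmethod
    def hky(cls, kappa: float) -> "NucleotideBias":
        """HKY embedding into GTR: transitions (AG, CT) at 1, transversions 1/kappa."""
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        return cls({p: (1.0 if p in ("AG", "CT") else 1.0 / kappa)
                    for p in NUCLEOTIDE_PAIRS})

    def as_vector(self) -> np.ndarray:
        return np.array([self.theta[p] for p in NUCLEOTIDE_PAIRS])


@dataclass(frozen=True)
class PositionalFrequencies:
    """Position-specific nucleotide frequencies (3 positions x ACGT)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (3, 4):
            raise ValueError("pi must be a 3x4 array")
        if np.any(pi <= 0):
            raise ValueError("positional frequencies must be positive")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each positional row must sum to 1")
        object.__setattr__(self, "pi", pi)

    @classmethod
    def equal(cls) -> "PositionalFrequencies":
        return cls(np.full((3, 4), 0.25))


@dataclass(frozen=True)
class OmegaGrid:
    """Ordered general discrete distribution for the branch-site dN/dS ratio."""

    omegas: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        om = np.asarray(self.omegas, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if om.ndim != 1 or om.shape != w.shape:
            raise ValueError("omegas and weights must be matching 1-d arrays")
        if np.any(om < 0):
            raise ValueError("omega values must be nonnegative")
        if np.any(np.diff(om) < -1e-9):
            raise ValueError("omega values must be nondecreasing")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must form a probability vector")
        object.__setattr__(self, "omegas", om)
        object.__setattr__(self, "weights", np.clip(w, 0.0, None) / w.sum())

    @property
    def K(self) -> int:
        return len(self.omegas)

    @property
    def n_free(self) -> int:
        return 2 * self.K - 1

    @property
    def mean(self) -> float:
        return float(self.omegas @ self.weights)


@dataclass(frozen=True)
class AlphaGrid:
    """Unit-mean general discrete distribution for the site synonymous rate."""

    alphas: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        al = np.asarray(self.alphas, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if al.ndim != 1 or al.shape != w.shape:
            raise ValueError("alphas and weights must be matching 1-d arrays")
        if np.any(al < 0):
            raise ValueError("alpha values must be nonnegative")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must form a probability vector")
        mean = float(al @ w)
        if abs(mean - 1.0) > 1e-8:
            raise ValueError(f"alpha grid mean must be 1 (got {mean:.6g}); "
                             "use AlphaGrid.from_raw to normalize")
        object.__setattr__(self, "alphas", al)
        object.__setattr__(self, "weights", np.clip(w, 0.0, None) / w.sum())

    @classmethod
    def from_raw(cls, raw_rates, weights) -> "AlphaGrid":
        """Normalize raw nonnegative rates to satisfy the mean-one constraint."""
        raw = np.asarray(raw_rates, dtype=float)
        w = np.asarray(weights, dtype=float)
        mean = raw @ w
        if mean <= 0:
            raise ValueError("raw alpha rates must have positive mean")
        return cls(raw / mean, w)

    @classmethod
    def constant(cls, L: int = 1) -> "AlphaGrid":
        return cls(np.ones(L), np.full(L, 1.0 / L))

    @property
    def L(self) -> int:
        return len(self.alphas)

    @property
    def n_free(self) -> int:
        return 2 * (self.L - 1)

    @property
    def cv(self) -> float:
        """Coefficient of variation of the site synonymous rate."""
        var = float(self.weights @ (self.alphas - 1.0) ** 2)
        return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class MHRates:
    """Global relative rates of multinucleotide substitutions."""

    delta: float = 0.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        if self.delta < 0 or self.psi < 0:
            raise ValueError("multihit rates must be nonnegative")

    @classmethod
    def none(cls) -> "MHRates":
        return cls(0.0, 0.0)


_MH_MODES = ("none", "double", "double+triple")


@dataclass(frozen=True)
class ModelConfig:
    """Which members of the model hierarchy are switched on.

    The four canonical models are BUSTED (srv=False, mh=none), BUSTED+S
    (True, none), BUSTED+MH (False, double+triple) and BUSTED+S+MH
    (True, double+triple); the intermediate BUSTED+S+2H is (True, double).
    """

    srv: bool = False
    mh_mode: str = "none"
    K: int = 3
    L: int = 3

    def __post_init__(self) -> None:
        if self.mh_mode not in _MH_MODES:
            raise ValueError(f"mh_mode must be one of {_MH_MODES}")
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")

    @classmethod
    def busted(cls, K: int = 3) -> "ModelConfig":
        return cls(srv=False, mh_mode="none", K=K, L=1)

    @classmethod
    def s(cls, K: int = 3, L: int = 3) -> "ModelConfig":
        return cls(srv=True, mh_mode="none", K=K, L=L)

    @classmethod
    def mh(cls, K: int = 3) -> "ModelConfig":
        return cls(srv=False, mh_mode="double+triple", K=K, L=1)

    @classmethod
    def smh(cls, K: int = 3, L: int = 3) -> "ModelConfig":
        return cls(srv=True, mh_mode="double+triple", K=K, L=L)

    @classmethod
    def s2h(cls, K: int = 3, L: int = 3) -> "ModelConfig":
        return cls(srv=True, mh_mode="double", K=K, L=L)

    @classmethod
    def from_name(cls, name: str, K: int = 3, L: int = 3) -> "ModelConfig":
        key = name.upper().replace("BUSTED", "").strip()
        mapping = {
            "": cls.busted(K),
            "+S": cls.s(K, L),
            "+MH": cls.mh(K),
            "+S+MH": cls.smh(K, L),
            "+S+2H": cls.s2h(K, L),
        }
        try:
            return mapping[key]
        except KeyError as exc:
            raise ValueError(f"unknown model name {name!r}") from exc

    @property
    def name(self) -> str:
        tag = ""
        if self.srv:
            tag += "+S"
        if self.mh_mode == "double+triple":
            tag += "+MH"
        elif self.mh_mode == "double":
            tag += "+2H"
        return "BUSTED" + tag


@dataclass
class RateMatrix:
    """A 61x61 instantaneous generator over the sense-codon ordering.

    ``scale`` is the expected number of codon substitutions per unit time at
    stationarity for this matrix (the flux sum_{i!=j} pi_i q_ij).
    """

    q: np.ndarray
    scale: float
    stationary: np.ndarray = field(repr=False, default=None)


def stationary_distribution(pi: PositionalFrequencies,
                            code: GeneticCode | None = None) -> np.ndarray:
    """Normalized positional-product distribution over sense codons."""
    code = code or get_code()
    codes = code.codon_nucleotides  # (n, 3)
    prod = (pi.pi[0, codes[:, 0]] * pi.pi[1, codes[:, 1]] * pi.pi[2, codes[:, 2]])
    return prod / prod.sum()


def _pair_factors(theta: NucleotideBias, pi: PositionalFrequencies,
                  code: GeneticCode) -> np.ndarray:
    """prod over changed positions of theta(i_n, j_n) * pi^n_{j_n}, per (i, j)."""
    th = theta.as_vector()
    tp = code.theta_position_index  # (n, n, 3), -1 where unchanged
    codes = code.codon_nucleotides
    fac = np.ones((code.n_sense, code.n_sense))
    for p in range(3):
        idx = tp[:, :, p]
        changed = idx >= 0
        theta_fac = np.where(changed, th[np.clip(idx, 0, None)], 1.0)
        pi_fac = np.where(changed, pi.pi[p, codes[:, p]][None, :], 1.0)
        fac *= theta_fac * pi_fac
    return fac


def build_rate_matrix(theta: NucleotideBias,
                      pi: PositionalFrequencies,
                      omega: float,
                      mh: MHRates = MHRates(),
                      code: GeneticCode | None = None,
                      psi_nonsynonymous_only: bool = False) -> RateMatrix:
    """Construct the generator for a single omega category (alpha = 1).

    ``psi_nonsynonymous_only`` restricts the triple-hit rate to nonsynonymous
    changes (synonymous triples then have rate zero); the default applies psi
    to both, following the rate-table parameterization.
    """
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    code = code or get_code()
    d = code.n_diff_matrix
    mult = np.zeros_like(d, dtype=float)
    mult[d == 1] = 1.0
    mult[d == 2] = mh.delta
    mult[d == 3] = mh.psi
    if psi_nonsynonymous_only:
        mult[(d == 3) & ~code.nonsyn_matrix] = 0.0
    q = mult * _pair_factors(theta, pi, code)
    q[code.nonsyn_matrix] *= omega
    np.fill_diagonal(q, 0.0)
    statd = stationary_distribution(pi, code)
    scale = float(statd @ q.sum(axis=1))
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(q=q, scale=scale, stationary=statd)


def mixture_scale(theta: NucleotideBias, pi: PositionalFrequencies,
                  omega_grid: OmegaGrid, mh: MHRates = MHRates(),
                  code: GeneticCode | None = None,
                  psi_nonsynonymous_only: bool = False) -> float:
    """Mixture-averaged codon flux C = sum_k p_k B(omega_k).

    Dividing the generator by C / 3 makes branch lengths read as expected
    substitutions per nucleotide site (the unit-mean alpha mixture
    contributes a factor of one).
    """
    return float(sum(
        w * build_rate_matrix(theta, pi, om, mh, code, psi_nonsynonymous_only).scale
        for om, w in zip(omega_grid.omegas, omega_grid.weights)
    ))


@dataclass(frozen=True)
class Decomposition:
    """Expected-substitution flux split by hit class, averaged over omega."""

    B: float
    B2H: float
    B3H: float
    frac2H: float
    frac3H: float


def branch_length_decomposition(theta: NucleotideBias,
                                pi: PositionalFrequencies,
                                omega_grid: OmegaGrid,
                                mh: MHRates,
                                code: GeneticCode | None = None,
                                psi_nonsynonymous_only: bool = False
                                ) -> Decomposition:
    """Split the expected substitution flux into 1H/2H/3H components.

    B = sum_{i != j} q_ij pi_j with pi the stationary codon distribution;
    B2H and B3H restrict the sum to pairs differing at exactly two or three
    positions. All three are averaged over the omega mixture (the unit-mean
    alpha mixture contributes a factor of one), and frac2H = B2H / B,
    frac3H = B3H / B. Reversibility makes the target-weighted sum equal to
    the conventional source-weighted flux.
    """
    code = code or get_code()
    d = code.n_diff_matrix
    off = ~np.eye(code.n_sense, dtype=bool)
    B = B2 = B3 = 0.0
    for om, w in zip(omega_grid.omegas, omega_grid.weights):
        rm = build_rate_matrix(theta, pi, om, mh, code, psi_nonsynonymous_only)
        flux = np.where(off, rm.q, 0.0) * rm.stationary[None, :]
        B += w * flux.sum()
        B2 += w * flux[d == 2].sum()
        B3 += w * flux[d == 3].sum()
    if B <= 0:
        raise ValueError("degenerate generator: zero total flux")
    return Decomposition(B=B, B2H=B2, B3H=B3, frac2H=B2 / B, frac3H=B3 / B)


# ---------------------------------------------------------------------------
# Equilibrium frequency estimators
# ---------------------------------------------------------------------------

def f3x4(observed_codon_counts: np.ndarray,
         code: GeneticCode | None = None) -> PositionalFrequencies:
    """Plain F3x4: column-normalized positional marginal nucleotide tallies."""
    code = code or get_code()
    counts = np.asarray(observed_codon_counts, dtype=float)
    if counts.shape != (code.n_sense,):
        raise ValueError(f"expected a length-{code.n_sense} count vector")
    if counts.sum() <= 0:
        raise ValueError("total codon count must be positive")
    codes = code.codon_nucleotides
    pi = np.zeros((3, 4))
    for p in range(3):
        for b in range(4):
            pi[p, b] = counts[codes[:, p] == b].sum()
    pi = (pi + 1e-9) / (pi + 1e-9).sum(axis=1, keepdims=True)
    return PositionalFrequencies(pi)


def cf3x4(observed_codon_counts: np.ndarray,
          code: GeneticCode | None = None,
          tol: float = 1e-8) -> PositionalFrequencies:
    """Corrected F3x4: ML positional frequencies with stop-codon exclusion.

    Maximizes the multinomial log-likelihood of the observed sense-codon
    counts under the model where codon frequencies are proportional to the
    positional product restricted to sense codons. Nine free parameters
    (three per position, via logits); initialized at the plain F3x4 tallies.
    """
    code = code or get_code()
    counts = np.asarray(observed_codon_counts, dtype=float)
    if counts.shape != (code.n_sense,):
        raise ValueError(f"expected a length-{code.n_sense} count vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total codon count must be positive")
    codes = code.codon_nucleotides
    start = f3x4(counts, code).pi

    def unpack(x: np.ndarray) -> np.ndarray:
        logits = np.concatenate([x.reshape(3, 3), np.zeros((3, 1))], axis=1)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def nll(x: np.ndarray) -> float:
        pi = unpack(x)
        logp = (np.log(pi[0, codes[:, 0]]) + np.log(pi[1, codes[:, 1]])
                + np.log(pi[2, codes[:, 2]]))
        logz = np.log(np.exp(logp).sum())
        return -float(counts @ (logp - logz)) / total

    x0 = np.log(start[:, :3] / start[:, 3:4]).ravel()
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"ftol": tol, "gtol": 1e-10, "maxiter": 500})
    return PositionalFrequencies(unpack(res.x))
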