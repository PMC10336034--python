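"""Hypothesis tests for episodic diversifying selection and multihit rates.

The EDS test compares a model against the same model with the selective
omega category pinned to 1. Because the null places hyperparameters on the
boundary of the parameter space, critical values come from a 50:50 mixture
of chi2_0 and chi2_2: p = 0.5 * Pr(chi2_2 >= LRT), so p is capped at 0.5
and equals 0.5 exactly whenever the LRT statistic is nonpositive.

Model uncertainty is handled by Akaike-weight averaging: with
w_m proportional to exp((AICc_best - AICc_m) / 2), the model-averaged
p-value is p_MA = sum_m w_m p_m, a convex combination of the per-model
p-values. Screens over many alignments can be corrected with
Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .likelihood import CodonAlignment, PhyloTree
from .model import BustedModel, BustedResults
from .rates import ModelConfig

__all__ = [
    "EdsTest",
    "eds_pvalue",
    "mh_rate_tests",
    "model_averaged_p",
    "bh_fdr",
    "fit_eds_pair",
    "ModelTest",
    "ModelTestReport",
    "RefitRequired",
]

#: Detection-pattern bit order used in reports.
PATTERN_ORDER = ("+S+MH", "BUSTED", "+S", "+MH", "Averaged", "Best")

_LRT_SLACK = 0.01  # optimizer noise allowance before a refit is demanded


class RefitRequired(RuntimeError):
    """Nested log-likelihood ordering violated beyond optimizer tolerance."""


@dataclass(frozen=True)
class EdsTest:
    lrt: float
    p: float


def eds_pvalue(lnl_alt: float, lnl_null: float) -> EdsTest:
    """EDS likelihood ratio test with the 50:50 chi2_0 / chi2_2 mixture null.

    A marginally negative statistic (above -0.01, optimizer noise) is
    clamped to zero and reported as p = 0.5; a more negative value is also
    clamped but flagged with a warning — callers that can refit should do so.
    """
    lrt = 2.0 * (lnl_alt - lnl_null)
    if lrt < -_LRT_SLACK:
        warnings.warn(
            f"alternative log-likelihood below null by {-lrt / 2:.4g}; "
            "the alternative fit should be refit from the null optimum",
            RuntimeWarning, stacklevel=2)
    stat = max(lrt, 0.0)
    p = 0.5 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=2))
    return EdsTest(lrt=lrt, p=min(p, 0.5))


@dataclass(frozen=True)
class MHRateTests:
    lrt_delta: float
    p_delta: float
    lrt_psi: float
    p_psi: float
    lrt_joint: float
    p_joint: float


def mh_rate_tests(fit_S: BustedResults, fit_S2H: BustedResults,
                  fit_SMH: BustedResults) -> MHRateTests:
    """Decompose multihit support: delta (+S vs +S+2H), psi (+S+2H vs +S+MH).

    Single-rate tests use a conservative chi2_1 reference; the joint
    delta = psi = 0 test uses the conservative chi2_2.
    """
    pairs = [(fit_S, fit_S2H), (fit_S2H, fit_SMH)]
    for lo_fit, hi_fit in pairs:
        if hi_fit.llf < lo_fit.llf - _LRT_SLACK:
            raise RefitRequired(
                f"{hi_fit.name} log-likelihood below nested {lo_fit.name}; "
                "refit the richer model seeded from the nested optimum")

    def one(lo_fit, hi_fit, df):
        lrt = max(2.0 * (hi_fit.llf - lo_fit.llf), 0.0)
        return lrt, float(chi2.sf(lrt, df=df)) if lrt > 0 else 1.0

    ld, pd_ = one(fit_S, fit_S2H, 1)
    lp, pp = one(fit_S2H, fit_SMH, 1)
    lj, pj = one(fit_S, fit_SMH, 2)
    return MHRateTests(lrt_delta=ld, p_delta=pd_, lrt_psi=lp, p_psi=pp,
                       lrt_joint=lj, p_joint=pj)


@dataclass(frozen=True)
class ModelAverage:
    weights: np.ndarray
    p_ma: float


def akaike_weights(aicc_values) -> np.ndarray:
    """w_m proportional to exp((AICc_best - AICc_m) / 2), summing to 1."""
    a = np.asarray(aicc_values, dtype=float)
    raw = np.exp((a.min() - a) / 2.0)
    return raw / raw.sum()


def model_averaged_p(fits: list[BustedResults], pvalues) -> ModelAverage:
    """Akaike-weighted average of per-model EDS p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(fits) != len(p):
        raise ValueError("fits and pvalues must have matching lengths")
    if len(fits) < 2:
        raise ValueError("model averaging needs at least two models")
    w = akaike_weights([f.aicc for f in fits])
    return ModelAverage(weights=w, p_ma=float(w @ p))


@dataclass(frozen=True)
class FdrResult:
    qvalues: np.ndarray
    significant: np.ndarray


def bh_fdr(pvalues, q_threshold: float = 0.2) -> FdrResult:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return FdrResult(qvalues=np.array([]), significant=np.array([], bool))
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return FdrResult(qvalues=q, significant=q <= q_threshold)


def fit_eds_pair(bm: BustedModel, seed_res: BustedResults | None = None,
                 starts: int = 2, seed: int = 0, maxiter: int = 300,
                 mixture_maxiter: int = 100, effort: float = 1.0
                 ) -> tuple[BustedResults, BustedResults]:
    """Fit the EDS alternative and its omega3 = 1 null for one model.

    The null is seeded from the alternative's optimum; if, on near-null
    data, the constrained fit ends up above the alternative (the boundary
    case), the alternative is refit seeded from the null so the pair always
    satisfies lnL(alt) >= lnL(null) up to optimizer tolerance.
    """
    alt = bm.fit(start_params=seed_res, constrain_omega3=False,
                 starts=starts, seed=seed, maxiter=maxiter,
                 mixture_maxiter=mixture_maxiter, effort=effort,
                 warn_overfit=False)
    null = bm.fit(start_params=alt, constrain_omega3=True,
                  starts=1, seed=seed, maxiter=min(maxiter, 35),
                  mixture_maxiter=mixture_maxiter // 2,
                  phase_a=False, effort=0.7 * effort, warn_overfit=False)
    if alt.llf < null.llf:
        alt2 = bm.fit(start_params=null, constrain_omega3=False,
                      starts=1, seed=seed + 1, maxiter=maxiter,
                      mixture_maxiter=mixture_maxiter // 2,
                      phase_a=False, effort=0.7 * effort, warn_overfit=False)
        if alt2.llf > alt.llf:
            alt = alt2
    return alt, null


# ---------------------------------------------------------------------------
# Model-test runner
# ---------------------------------------------------------------------------

@dataclass
class ModelTestReport:
    """Joint report over the model hierarchy for one alignment."""

    fits: dict[str, BustedResults] = field(repr=False)
    nulls: dict[str, BustedResults] = field(repr=False)
    tests: dict[str, EdsTest]
    weights: dict[str, float]
    p_averaged: float
    best_model: str
    alpha: float = 0.05
    schema_version: str = "1.0"

    @property
    def detection_pattern(self) -> str:
        """Bit per criterion, ordered (+S+MH, BUSTED, +S, +MH, Averaged, Best)."""
        bits = []
        for key in PATTERN_ORDER:
            if key == "Averaged":
                bits.append("1" if self.p_averaged <= self.alpha else "0")
            elif key == "Best":
                bits.append("1" if self.tests[self.best_model].p <= self.alpha
                            else "0")
            elif key in self.tests:
                bits.append("1" if self.tests[key].p <= self.alpha else "0")
            else:
                bits.append("x")  # model not part of this run
        return "".join(bits)

    def to_dict(self) -> dict:
        models = {}
        for name, fit in self.fits.items():
            models[name] = {
                "lnL": fit.llf,
                "lnL_null": self.nulls[name].llf,
                "k": fit.k_params,
                "AICc": fit.aicc,
                "LRT": self.tests[name].lrt,
                "p": self.tests[name].p,
                "weight": self.weights[name],
                "omega3": fit.omega3,
                "p3": fit.p3,
                "delta": fit.params.mh.delta,
                "psi": fit.params.mh.psi,
                "tree_length": fit.tree_length,
                "converged": fit.converged,
            }
        return {
            "schema_version": self.schema_version,
            "models": models,
            "p_averaged": self.p_averaged,
            "best_model": self.best_model,
            "detection_pattern": self.detection_pattern,
            "alpha": self.alpha,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        head = (f"{'model':>8} {'lnL':>12} {'k':>4} {'AICc':>12} "
                f"{'LRT':>9} {'p':>8} {'weight':>8}")
        rows = [head, "-" * len(head)]
        for name, fit in self.fits.items():
            t = self.tests[name]
            rows.append(f"{name:>8} {fit.llf:12.3f} {fit.k_params:4d} "
                        f"{fit.aicc:12.3f} {t.lrt:9.3f} {t.p:8.4f} "
                        f"{self.weights[name]:8.4f}")
        rows.append(f"model-averaged p = {self.p_averaged:.4f}   "
                    f"best model = {self.best_model}   "
                    f"pattern = {self.detection_pattern}")
        return "\n".join(rows)


class ModelTest:
    """Fit the model hierarchy with nested seeding and average the evidence.

    ``models`` defaults to the four canonical members; the intermediate
    +S+2H model can be appended for the delta/psi decomposition tests.
    """

    DEFAULT_MODELS = ("BUSTED", "+S", "+MH", "+S+MH")

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree,
                 models: tuple[str, ...] = DEFAULT_MODELS,
                 K: int = 3, L: int = 3, alpha: float = 0.05):
        self.alignment = alignment
        self.tree = tree
        self.models = models
        self.K, self.L = K, L
        self.alpha = alpha

    @staticmethod
    def _fit_pair(bm: BustedModel, seed_res, starts, seed, maxiter,
                  mixture_maxiter, effort):
        return fit_eds_pair(bm, seed_res=seed_res, starts=starts, seed=seed,
                            maxiter=maxiter, mixture_maxiter=mixture_maxiter,
                            effort=effort)

    def run(self, starts: int = 2, seed: int = 0, maxiter: int = 300,
            mixture_maxiter: int = 100, effort: float = 1.0
            ) -> ModelTestReport:
        fits: dict[str, BustedResults] = {}
        nulls: dict[str, BustedResults] = {}
        seeds_for = {
            "BUSTED": None, "+S": "BUSTED", "+MH": "BUSTED",
            "+S+2H": "+S", "+S+MH": None,  # +S+MH picks the better of +S/+MH
        }
        for name in self.models:
            cfg = ModelConfig.from_name(name, K=self.K, L=self.L)
            bm = BustedModel(self.alignment, self.tree, config=cfg)
            seed_key = seeds_for.get(name)
            seed_res = fits.get(seed_key) if seed_key else None
            if name == "+S+MH":
                candidates = [fits[n] for n in ("+S", "+MH") if n in fits]
                if candidates:
                    seed_res = max(candidates, key=lambda r: r.llf)
            if seed_res is not None:
                bm._nuc_stage = (seed_res.params.theta,
                                 seed_res.params.branch_lengths.copy())
            alt, null = self._fit_pair(bm, seed_res, starts, seed, maxiter,
                                       mixture_maxiter, effort)
            fits[name] = alt
            nulls[name] = null
        tests = {n: eds_pvalue(fits[n].llf, nulls[n].llf) for n in fits}
        canonical = [n for n in self.DEFAULT_MODELS if n in fits]
        if len(canonical) >= 2:
            avg = model_averaged_p([fits[n] for n in canonical],
                                   [tests[n].p for n in canonical])
        else:
            avg = ModelAverage(weights=np.array([1.0]),
                               p_ma=tests[canonical[0]].p)
        weights = dict(zip(canonical, avg.weights))
        for n in fits:
            weights.setdefault(n, float("nan"))
        best = min(canonical, key=lambda n: fits[n].aicc)
        return ModelTestReport(fits=fits, nulls=nulls, tests=tests,
                               weights=weights, p_averaged=avg.p_ma,
                               best_model=best, alpha=self.alpha)
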