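"""Post hoc localization of selection signal.

Three complementary views of *where* in the alignment (and tree) the
statistical signal for episodic diversifying selection lives:

* per-site evidence ratios between two fitted models,
* per-(branch, site) empirical Bayes factors for the selective omega class,
* the per-site decomposition of the EDS likelihood-ratio statistic.

All three are exploratory: empirical Bayes estimates at single branch-site
pairs are noisy and are meant for spotting hot-spots (for example, a single
multinucleotide substitution on a short branch carrying a whole-gene
positive result), not for formal site-level testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import BustedResults

__all__ = [
    "BranchSiteSupport",
    "SiteProfile",
    "branch_site_ebf",
    "site_evidence_ratios",
    "lrt_site_profile",
    "plot_branch_values",
]


@dataclass
class BranchSiteSupport:
    """Empirical Bayes support for omega_3 > 1 per (branch, site)."""

    branch_names: list[str]
    posterior: np.ndarray | None   # (n_branches, n_sites)
    ebf: np.ndarray | None         # (n_branches, n_sites)
    prior: float
    no_selective_class: bool = False

    def pairs_above(self, cutoff: float = 100.0) -> int:
        if self.no_selective_class:
            return 0
        return int((self.ebf > cutoff).sum())

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "prior": self.prior,
            "no_selective_class": self.no_selective_class,
            "ebf": {} if self.no_selective_class else {
                name: [float(v) for v in row]
                for name, row in zip(self.branch_names, self.ebf)
            },
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def branch_site_ebf(fit: BustedResults) -> BranchSiteSupport:
    """Empirical Bayes factors for the selective class at each branch-site.

    For branch b and site s, the posterior P(omega_3^{bs} > 1 | D_s) is
    P(D_s | omega collapsed to class 3 on b) * p_3 / P(D_s); the EBF is the
    posterior-to-prior odds ratio. Only the focal branch's omega mixture is
    collapsed — every other branch keeps the full mixture — and, with SRV
    active, both numerator and denominator marginalize over the fitted
    alpha categories. A fit with p_3 = 0 has no selective class and yields
    an explicit marker instead of factors.
    """
    engine = fit.model.engine
    tree = fit.model.tree
    prior = fit.p3
    names = [tree.branch_name(b) for b in tree.branch_ids]
    if prior <= 0.0:
        return BranchSiteSupport(branch_names=names, posterior=None, ebf=None,
                                 prior=prior, no_selective_class=True)
    base = fit.site_table
    if base is None:
        base = engine.log_likelihood(fit.params)
    n_sites = base.log_site.shape[0]
    post = np.empty((len(names), n_sites))
    for row, b in enumerate(tree.branch_ids):
        collapsed = engine.log_likelihood(fit.params, collapse_branch=int(b))
        post[row] = np.exp(collapsed.log_site + np.log(prior) - base.log_site)
    post = np.clip(post, 0.0, 1.0)
    prior_odds = prior / (1.0 - prior) if prior < 1.0 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        post_odds = post / (1.0 - post)
        ebf = np.where(np.isfinite(post_odds), post_odds / prior_odds, np.inf)
    return BranchSiteSupport(branch_names=names, posterior=post, ebf=ebf,
                             prior=prior)


def site_evidence_ratios(fit_a: BustedResults, fit_b: BustedResults
                         ) -> np.ndarray:
    """Per-site likelihood ratios ER_s = P(D_s | a) / P(D_s | b).

    The log-ERs sum to the total log-likelihood difference, so they
    decompose model preference site by site.
    """
    la, lb = fit_a.site_table.log_site, fit_b.site_table.log_site
    if la.shape != lb.shape:
        raise ValueError("fits cover different numbers of sites")
    return np.exp(la - lb)


@dataclass
class SiteProfile:
    """Per-site contributions to the EDS likelihood-ratio statistic."""

    contributions: np.ndarray   # per site, 2 * (log P_alt - log P_null)
    total_lrt: float
    n_sites_for_share: int
    share: float
    n_pairs_ebf_above: int | None = None
    ebf_cutoff: float = 100.0
    order: np.ndarray = field(repr=False, default=None)

    def to_table(self) -> str:
        lines = ["site\tdelta_lnL_x2\tcumulative_share"]
        cum = 0.0
        for s in self.order:
            cum += max(self.contributions[s], 0.0)
            share = f"{cum / self.total_lrt:.4f}" if self.total_lrt > 0 else "NA"
            lines.append(f"{s + 1}\t{self.contributions[s]:.6f}\t{share}")
        return "\n".join(lines)


def lrt_site_profile(alt_fit: BustedResults, null_fit: BustedResults,
                     lrt_share: float = 0.80, ebf_cut: float = 100.0,
                     ebf: BranchSiteSupport | None = None,
                     compute_ebf: bool = False) -> SiteProfile:
    """Decompose the EDS LRT into per-site contributions.

    ``n_sites_for_share`` is the smallest number of top-contributing sites
    whose positive contributions reach the requested share (default 80%) of
    the total statistic; zero when the total statistic is nonpositive.
    When an EBF matrix is supplied (or requested), the count of
    (branch, site) pairs exceeding ``ebf_cut`` is included.
    """
    contrib = 2.0 * (alt_fit.site_table.log_site - null_fit.site_table.log_site)
    total = float(contrib.sum())
    order = np.argsort(-contrib, kind="stable")
    if total <= 0:
        n_top = 0
    else:
        target = lrt_share * total
        cum = 0.0
        n_top = 0
        for s in order:
            if contrib[s] <= 0 or cum >= target - 1e-9 * abs(total):
                break
            cum += contrib[s]
            n_top += 1
        n_top = max(n_top, 1) if cum > 0 else 0
    if ebf is None and compute_ebf:
        ebf = branch_site_ebf(alt_fit)
    n_pairs = ebf.pairs_above(ebf_cut) if ebf is not None else None
    return SiteProfile(contributions=contrib, total_lrt=total,
                       n_sites_for_share=n_top, share=lrt_share,
                       n_pairs_ebf_above=n_pairs, ebf_cutoff=ebf_cut,
                       order=order)


def plot_branch_values(tree, values: dict[str, float], path=None, ax=None,
                       label: str = "EBF ratio", log_scale: bool = True):
    """Rectangular cladogram with branches colored by a per-branch value.

    ``values`` maps branch names (as in :meth:`PhyloTree.branch_name`) to
    the quantity to display — typically the ratio of empirical Bayes
    factors at a focal site between two models. Values are plotted raw
    (optionally on a log color scale); no clipping is applied.
    """
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * tree.n_leaves + 1))
    # leaf y-positions in postorder; internal nodes midway between children
    ys = {}
    next_y = [0.0]

    def assign(node):
        kids = tree.children[node]
        if not kids:
            ys[node] = next_y[0]
            next_y[0] += 1.0
        else:
            for c in kids:
                assign(c)
            ys[node] = float(np.mean([ys[c] for c in kids]))

    assign(tree.root)
    depth = {tree.root: 0.0}
    for node in tree.postorder[::-1]:
        for c in tree.children[node]:
            depth[c] = depth[node] + max(tree.branch_lengths[c], 1e-9)

    vals = np.array([values.get(tree.branch_name(b), np.nan)
                     for b in tree.branch_ids])
    finite = vals[np.isfinite(vals)]
    if finite.size and log_scale and np.all(finite > 0):
        norm = colors.LogNorm(vmin=finite.min(), vmax=max(finite.max(),
                                                          finite.min() * 1.01))
    else:
        lo = finite.min() if finite.size else 0.0
        hi = finite.max() if finite.size else 1.0
        norm = colors.Normalize(vmin=lo, vmax=max(hi, lo + 1e-9))
    cmap = cm.coolwarm
    for b in tree.branch_ids:
        parent = tree.parent[b]
        v = values.get(tree.branch_name(b))
        color = cmap(norm(v)) if v is not None and np.isfinite(v) else "0.6"
        ax.plot([depth[parent], depth[b]], [ys[b], ys[b]], color=color, lw=2)
        ax.plot([depth[parent], depth[parent]], [ys[parent], ys[b]],
                color="0.6", lw=1)
        if not tree.children[b]:
            ax.text(depth[b] + 0.01, ys[b], tree.leaf_names[b], va="center")
    ax.set_yticks([])
    ax.set_xlabel("substitutions/nucleotide")
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    ax.figure.colorbar(sm, ax=ax, label=label)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax
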