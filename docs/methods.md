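# Methods

## Model family

The substitution process is a reversible continuous-time Markov chain on
the sense codons of the universal genetic code (61 states; stop codons are
excluded from the chain, and columns containing unambiguous in-frame stops
are rejected at ingestion unless explicitly masked). Instantaneous rates
between codons differing at *d* ∈ {1, 2, 3} nucleotide positions carry a
hit-class multiplier (1, δ, ψ), the product of GTR exchangeabilities
θ(i_n, j_n) and position-specific target frequencies π^n over the changed
positions, the branch–site dN/dS factor ω_bs on nonsynonymous exchanges,
and the site-level synonymous rate α_s. ψ multiplies both synonymous and
nonsynonymous triple changes; a `psi_nonsynonymous_only` switch (default
off) restricts it to nonsynonymous triples for users who prefer the
stricter reading. Setting δ = ψ = 0 reproduces the classic single-hit
codon model entry for entry.

The chain is reversible with stationary distribution proportional to the
positional product restricted to sense codons; π is estimated once per
alignment by the CF3×4 procedure (a 9-parameter maximum-likelihood fit of
positional frequencies under stop-codon exclusion, initialized at the
plain F3×4 tallies, L-BFGS-B on logits with objective tolerance 1e-8) and
held fixed during likelihood optimization. All other parameters — branch
lengths, θ, the ω and α grids, δ and ψ — are estimated by direct
likelihood maximization.

### Random effects

* ω_bs: K-bin general discrete distribution (default K = 3), drawn iid per
  (branch, site), with ordering 0 ≤ ω₁ ≤ … ≤ ω_{K−1} ≤ 1 ≤ ω_K. The iid
  draws factorize the site likelihood into per-branch mixture transition
  matrices.
* α_s: L-bin general discrete distribution (default L = 3), drawn once per
  site, constrained to mean one for identifiability against branch
  lengths. No branch-to-branch α variation is modeled.

The hierarchy BUSTED ⊂ {+S, +MH} ⊂ +S+MH (and the intermediate +S+2H with
ψ := 0) gives parameter counts B + 13 + 2K, B + 11 + 2(K+L), B + 15 + 2K,
B + 13 + 2(K+L), where B is the number of free branch lengths in the
unrooted sense (2N − 3 for N leaves; bifurcating roots are collapsed on
ingestion because the two root edges are not separately identifiable under
reversibility).

## Units and the flux decomposition

Branch lengths are expected substitutions per **nucleotide** site: the
generator is divided by C/3 where C = Σ_k p_k B(ω_k) is the
mixture-averaged expected codon substitution rate at stationarity (the
unit-mean α mixture contributes a factor of one). The interpretable
summary of the MH rates is the decomposition B, B2H, B3H — total flux and
the parts through pairs differing at exactly two or three positions —
averaged over the ω mixture; frac2H = B2H/B and frac3H = B3H/B.

Two conventions exist for these sums: weighting each rate q_ij by the
target frequency π_j (the form used here for B) or by the source
frequency π_i (the expected event rate, used for the time-scaling constant
C and realized by the simulator's event log). Although detailed balance
holds pairwise, the two *sums* coincide only for symmetric restrictions
such as equal positional frequencies — which is the regime of every
simulation experiment in this package; with skewed frequencies the two
decompositions differ slightly and the package deliberately keeps both
roles separate (B for reporting, C for time scaling).

## Likelihood computation

Felsenstein pruning on pattern-compressed columns, one pass per α
category, with per-branch mixture matrices M_b = Σ_k p_k exp(α Q(ω_k) t_b
3/C). Matrix exponentials use the symmetric eigendecomposition available
under reversibility (similarity by √π), so one decomposition per ω
category serves every branch and α category; reconstructed matrices are
row-stochastic to ~1e-12 and the engine validates site likelihoods are
finite and positive, naming the offending codon site otherwise. Gaps and
IUPAC ambiguity codes become indicator ("partial") likelihood vectors over
compatible sense codons; an all-gap column has likelihood exactly one.
Underflow is controlled by per-node rescaling accumulated in log space.
Because optimization uses one-parameter-at-a-time finite differences, the
engine caches the ω-independent rate-matrix components, the per-ω
eigendecompositions, and the per-ω transition-matrix stacks, keyed by the
exact parameter values.

## Fitting schedule

1. A nucleotide-level GTR fit (4-state pruning, empirical base
   frequencies) supplies starting branch lengths and θ.
2. Phase A optimizes the mixture hyperparameters (ω grid, α grid, δ, ψ)
   with branch lengths and θ fixed, from multiple starts: the seed point,
   a deterministic strong-selection start (ω₃ = 50 at ~5% weight — the
   small-weight/large-ω₃ basin is not reachable by gradient once the
   selective weight has collapsed to zero), and random jitters.
3. One bounded L-BFGS-B pass over all free parameters (for cold starts,
   preceded by a 1-D tree-length rescale, which captures most of the gap
   between nucleotide-level and codon-level branch lengths).
4. A tight mixture-only refinement and a short joint polish.

Constrained quantities are box-transformed: ordered sub-neutral ω bins via
cumulative shrinkage factors in [0, 1], ω_K = 1 + e^u (pinned to 1 in the
null), stick-breaking weights, α grids as L−1 ordered raw-rate increments
with the scale solved from the mean-one constraint, and δ, ψ ≥ 0 so the
single-hit model is always inside the search region. Models seeded from a
nested fit start at the nested optimum (a seed without SRV enters a richer
model at the degenerate equal-rates α point), which makes the monotone
nesting of maximized log-likelihoods structural rather than hoped-for. The
EDS null is seeded from the alternative; if on near-null data the
constrained fit ends above the alternative, the alternative is refit from
the null's optimum (`fit_eds_pair`).

An `effort` knob scales the per-phase function-evaluation budgets. The
default (1.0) is the publication profile; the replicate harnesses and the
acceptance script use 0.5–0.55, which on 4-taxon × 800-codon data leaves
maximized log-likelihoods within a few hundredths of the tight optimum —
ample for tests whose statistics sit far from the decision threshold, and
safe for size control because the precision-critical null fits start at
the alternative's optimum. Fits that stop on budget are flagged, never
silently returned; near-duplicate grid rates or near-zero weights trigger
an overfitting warning (thresholds 1e-3 relative and 1e-4).

AICc uses the characters convention n = sequences × codon sites. Absolute
AICc values therefore depend on this choice; model ranking and Akaike
weights, which only use ΔAICc across models on the same data, do not.

## Hypothesis tests and averaging

The EDS test statistic 2ΔlnL is referred to the 50:50 χ²₀/χ²₂ boundary
mixture: p = 0.5 · Pr(χ²₂ ≥ max(LRT, 0)), capped at 0.5, with p = 0.5
reported exactly for nonpositive statistics (marginally negative
statistics above −0.01 are optimizer noise and are clamped; worse
violations warn and should trigger a refit). The δ and ψ rate tests use a
conservative χ²₁ without boundary correction (+S vs +S+2H and +S+2H vs
+S+MH), the joint δ = ψ = 0 test a conservative χ²₂. Model-averaged
p-values use Akaike weights over the four canonical models; screens can be
corrected by Benjamini–Hochberg q-values.

## Diagnostics

Per-site evidence ratios ER_s = P(D_s | model a)/P(D_s | model b) decompose
a model preference over sites (their logs sum to the total lnL
difference). Branch–site empirical Bayes factors collapse the focal
branch's ω distribution onto the selective class — other branches keep the
full mixture, and with SRV active both numerator and denominator
marginalize over the fitted α categories — giving posterior-to-prior odds
for ω₃ at each (branch, site); a fit with p₃ = 0 yields an explicit
"no selective class" marker. The LRT site profile reports each site's
contribution to the EDS statistic, the number of top sites carrying 80% of
it, and the count of (branch, site) pairs with EBF > 100. All three are
exploratory screens, not site-level tests.

## Simulator

Exact event-time (Gillespie) simulation per site down the tree under any
model of the hierarchy, using the same scaled generator as inference, so
branch lengths mean the same thing end to end; every substitution is
logged with its hit class, which makes the analytic flux fractions
directly observable as event-class proportions. Per site an α category is
drawn once; per (branch, site) an ω category is drawn iid (an optional
fixed per-site category assignment supports site-level scenarios). The
default 4-taxon harness: 800 codons, equal positional frequencies, HKY
κ = 2 exchangeabilities, five branches of 0.2 substitutions/nucleotide,
null ω mixture (0.1@50%, 0.5@25%, 1.0@25%) and power mixture (0.1@50%,
0.5@40%, ω₃@10%). The generating α grid is (0.5, 1, 2)/mean at equal
weights (CV ≈ 0.55), a moderate level of synonymous rate variation chosen
to sit inside the range seen in empirical alignments; the tree's branch
lengths are uniform because the published 4-taxon design states only
approximate lengths, with the two "varied" branches exposed as a scan
parameter.

What the simulator does *not* emulate: real alignments' base-composition
skew per gene, alignment error, recombination, codon-boundary-spanning
multinucleotide events (also unmodeled in the inference, a conservative
omission that misses a subset of MH events), or selection that varies
systematically across branches. Passing tests therefore demonstrate
internal statistical correctness of the tests under the model family —
size, power, bias and identifiability — not robustness to every process in
real data.

## Experiment scales

The replicate experiments (false-positive rates with δ up to 1.0, power at
ω₃ = 16, and δ recovery) use 20 seeded replicates of 4 taxa × 800 codons —
the package's desk-scale profile; rates are asserted with the matching
binomial slack (e.g., nominal 100% is tested as ≥ 18–19/20, size control
as ≤ 0.05 + 2 binomial standard errors). Full-scale replications of
published benchmark and genome-screen analyses require the original
alignments and are out of scope; the harness accepts any fitted model's
parameters as a generator, so empirically-parameterized simulation works
when such data are supplied.

## Known limitations

* Whole-gene EDS power at 4 taxa is intrinsically low for signals
  concentrated in a single site; the selective mixture class can lack any
  positive-likelihood basin in that regime. Site localization of multihit
  support is done through +S+MH vs +S evidence ratios instead.
* Optimization is multi-start local search; pathological likelihood
  surfaces can still trap it. Increase `starts` and `effort` for final
  analyses.
* The ω₃ upper bound is 1 + e¹⁰ ≈ 2.2 × 10⁴; genuinely unbounded MLEs
  (e.g., a nonsynonymous change on a zero-length branch) land on the
  bound.
* Only the universal genetic code is exercised end to end, though the code
  table is pluggable (NCBI table ids).
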