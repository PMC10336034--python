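# bustedmh

Whole-gene tests for **episodic diversifying selection** (EDS) in
protein-coding sequence alignments that account for two confounding
evolutionary processes at once: **site-to-site synonymous rate variation**
(SRV, "+S") and **instantaneous multinucleotide substitutions** ("+MH",
double- and triple-nucleotide changes within a codon). It is written for
molecular evolutionary biologists running dN/dS-based selection screens who
need false-positive control when real substitution processes violate the
classic single-hit, constant-dS assumptions.

## The model

Codon evolution follows a reversible continuous-time Markov chain on the 61
sense codons. For codons *i*, *j* differing at *d* nucleotide positions,

    q_ij = m_d · ω_bs^{[nonsyn]} · α_s · ∏_n θ(i_n, j_n) · π^n_{j_n}

with *m*₁ = 1, *m*₂ = δ (double-hit rate), *m*₃ = ψ (triple-hit rate);
θ the five identifiable GTR nucleotide exchangeabilities (θ_AG = 1); π the
position-specific target-nucleotide frequencies estimated by CF3×4; ω_bs a
branch–site random effect drawn iid from a K(=3)-bin general discrete
distribution with 0 ≤ ω₁ ≤ ω₂ ≤ 1 ≤ ω₃; and α_s a site-level synonymous
rate from an L(=3)-bin unit-mean general discrete distribution.

Four nested models form the hierarchy — BUSTED (no SRV, no MH), +S, +MH,
and +S+MH — plus the intermediate +S+2H (δ free, ψ = 0) for decomposing
double- vs triple-hit support. The EDS test compares each model against
itself with ω₃ := 1, using the 50:50 χ²₀/χ²₂ boundary mixture, so
p ≤ 0.5 always and p = 0.5 exactly when the statistic is nonpositive.
Model uncertainty is absorbed by Akaike-weight averaging:
p_MA = Σ_m w_m p_m with w_m ∝ exp((AICc_best − AICc_m)/2).

The interpretable summary of the MH rates is the flux decomposition
B2H/B and B3H/B — the expected fractions of substitutions that are double
or triple hits — with B = Σ_{i≠j} q_ij π_j averaged over the ω mixture.

## Worked example

Simulate a null alignment whose generator includes double hits
(δ = 1, no positive selection), then ask both +S and +S+MH whether there
was selection:

```python
from bustedmh import BustedModel, ModelConfig, eds_pvalue, fit_eds_pair
from bustedmh.simulate import null_spec, simulate_alignment

sim = simulate_alignment(null_spec(delta=1.0, seed=2))
for name in ("+S", "+S+MH"):
    model = BustedModel(sim.alignment, sim.spec.tree,
                        config=ModelConfig.from_name(name))
    alt, null = fit_eds_pair(model, starts=1, seed=2, effort=0.5)
    t = eds_pvalue(alt.llf, null.llf)
    print(f"{name:>6}: LRT = {t.lrt:7.3f}  p = {t.p:.4f}  "
          f"omega3 = {alt.omega3:6.2f}  delta_hat = {alt.params.mh.delta:.3f}")
```

Output:

```
    +S: LRT =  14.794  p = 0.0003  omega3 =   1.62  delta_hat = 0.000
 +S+MH: LRT =   0.008  p = 0.4980  omega3 =   1.00  delta_hat = 1.211
```

The +S model, blind to multinucleotide substitutions, absorbs them into an
inflated ω₃ and falsely declares selection (p = 0.0003). The +S+MH model
attributes the same patterns to its double-hit rate (δ̂ ≈ 1.2, close to
the generating value 1.0) and correctly reports no selection (p = 0.5, a
zero LRT). The same machinery is available from the shell via the
`bustedmh` command (`fit`, `modeltest`, `simulate`, `null-grid`,
`power-grid`, `diagnose`).

For a fitted model, `bustedmh.diagnostics` localizes the evidence:
per-site evidence ratios between two fits, per-(branch, site) empirical
Bayes factors for the ω₃ class, and the per-site decomposition of the LRT
statistic — useful for spotting single codons whose multinucleotide
substitutions drive a whole-gene result.

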