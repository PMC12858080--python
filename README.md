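# tadwalk

Target-search kinetics of DNA-binding proteins on chromatin-like contact
networks.

## The problem

Transcription factors and repair proteins must find specific target sites
inside densely packed chromatin.  The classical *facilitated diffusion*
picture — rounds of 1D sliding along DNA interleaved with 3D bulk
excursions — ignores a third move that chromatin folding makes abundant:
**intersegmental hops** between loci that are far apart along the genome but
adjacent in space.  Inside topologically associating domains (TADs), where
the contact probability decays slowly with genomic separation
(`P_c(s) = c s^-γ` with `γ < 1`), such hops dominate.

`tadwalk` models a chromatin domain of `L + 1` coarse-grained (1 kb) beads as
a network in *contact space*: backbone bonds `C[i, i+1] = 1` plus Bernoulli
intersegmental bonds drawn from `P_c(s)` (uniform `p_u`, or power-law
`c s^-γ`).  A protein starts at the domain midpoint and, each step of
duration `τ`, either unbinds with probability `p_off` (paying a bulk
excursion `τ_f = 100 τ` before rebinding uniformly), or moves to a uniformly
chosen bonded neighbour (cost `τ` for a slide, `t_jump` for a hop).  The
search ends at the absorbing boundary beads `0` and `L`.  Writing `T_i` for
the mean first-passage time from bead `i`, the backward equations form an
exact linear system

```
T_i = τ + (1 - p_off)/N_i Σ_j C_ij T_j + p_off T_f        (interior i)
T_f = τ_f + (1/(L+1)) Σ_j T_j ,   T_0 = T_L = 0
```

solved for quenched (fixed) networks and — via the exact bond-ensemble
expectation `E[C_ij/N_i]` — for annealed (redrawn each step) networks.  A
numba Monte-Carlo walker simulates the same process on static or dynamically
reshuffled networks.  Headline phenomenology the package reproduces:

* the mean search time is **non-monotone in compaction** (`p_u` or `γ`):
  an optimal degree of folding minimises the search time, with the optimum
  at `γ < 1` for TAD-like parameters;
* bulk unbinding helps only on sparse networks — the facilitated-diffusion
  optimum in `p_off` disappears once intersegmental bonds are common;
* search times on TAD-parameter networks (`c = 0.0214`, `γ = 0.71`) scale
  **near-ballistically**, `⟨T⟩ ~ L^ν` with `ν ≈ 0.9`, against `ν = 2` for
  pure 1D sliding.

Beyond the parametric networks, the package generates polymer conformations
(freely rotating chains; LJ and soft-LJ bead-spring chains via a
reduced-scale Langevin integrator), converts them to contact networks by a
distance cutoff, and analyses Hi-C data: per-TAD contact-probability curves,
log-log power-law fits of `(c, γ)`, Bernoulli networks drawn directly from
contact maps, and search-time/length scaling fits.  A synthetic Hi-C
generator with known ground truth makes the whole pipeline testable offline.

## Worked example

```python
from tadwalk import (ContactModel, WalkerParams, solve_annealed, mean_quenched,
                     ensemble_search_time, SyntheticMapSpec, generate_map,
                     intra_tad_contact_curve, fit_power_law, fit_scaling_exponent)

params = WalkerParams()          # tau=1, tau_f=100 tau, p_off=0, start L//2
L = 500

for p_u in (0.0, 1e-3, 1.0):
    T = solve_annealed(ContactModel.uniform(p_u), L, params).T_mid
    print(f"p_u={p_u:<6g}  <T>={T:>10.1f} tau   T/T_d={T/62_500:.4f}")

model = ContactModel.powerlaw(c=0.0214, gamma=0.71)   # average TAD parameters
est = mean_quenched(model, L, params, n_configs=50, rng_seed=1)
print(f"TAD-like static ensemble: {est.mean:.0f} +/- {est.sem:.0f} tau")

sim = ensemble_search_time(model, L, params, n_configs=10, n_walks=1000, rng_seed=2)
print(f"Monte-Carlo walker:       {sim.mean:.0f} +/- {sim.sem:.0f} tau")

spec = SyntheticMapSpec(n_bins=320, tads=((10_000, 310_000),), sigma_log=0.2)
hic, tads = generate_map(spec, rng_seed=3)
s, pc = intra_tad_contact_curve(hic, tads[0])
fit = fit_power_law(s, pc)
print(f"synthetic TAD fit: c={fit.c:.4f}, gamma={fit.gamma:.3f}, R^2={fit.r_squared:.3f}")

Ls = [100, 200, 400, 800, 1600]
Ts = [solve_annealed(model, n, params).T_mid for n in Ls]
print(f"scaling exponent nu = {fit_scaling_exponent(Ls, Ts).nu:.3f}")
```

prints

```
p_u=0       <T>=   62500.0 tau   T/T_d=1.0000
p_u=0.001   <T>=    1328.9 tau   T/T_d=0.0213
p_u=1       <T>=  124501.0 tau   T/T_d=1.9920
TAD-like static ensemble: 2460 +/- 154 tau
Monte-Carlo walker:       2594 +/- 28 tau
synthetic TAD fit: c=0.0218, gamma=0.710, R^2=0.999
scaling exponent nu = 0.903
```

Reading: a bare chain takes the diffusive reference time `T_d = L²τ/4`; a
thousandth of a contact probability already cuts the search ~50-fold; a
fully connected interior over-diverts the walker and doubles `T_d`.
TAD-parameter networks are searched in ~2.5 kτ (static ensemble and direct
simulation agree), a fitted synthetic map returns its ground-truth
exponent, and search times grow almost linearly (ν ≈ 0.9) with domain
length.

## Command line

`tadwalk` exposes the same operations as subcommands — `net`, `sim`,
`solve`, `scan`, `frc`, `poly2net`, `tad-fit`, `tad-search`, `scaling`,
`synth-hic` — all taking `--seed` and writing their seed/parameters into
output headers.  For example:

```sh
tadwalk scan --var gamma --grid 0.1,0.5,0.71,1.0,1.5,2.2 \
        --kind powerlaw --c 0.0214 --L 500 --out gamma_scan.tsv
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the log-log scaling exponents of mean search time
versus domain length: on power-law networks with the average TAD parameters
(`c = 0.0214`, `γ = 0.71`, annealed solver, `L = 100 … 1600`) and on
backbone-only chains (the exactly diffusive control), writing both to the
given JSON file.
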