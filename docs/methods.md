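# Methods

## Contact-space model

A chromatin domain is a chain of `L + 1` beads (1 kb each), beads `0` and
`L` absorbing targets.  Connectivity is a symmetric binary matrix `C`:
backbone bonds are deterministic (`C[i, i±1] = 1`); every pair with
`|i - j| ≥ 2` carries an independent Bernoulli bond with probability

* uniform: `P_c(s) = p_u`,
* power-law: `P_c(s) = min(1, c s^-γ)`.

The cap at 1 is required for validity when `c s^-γ > 1` at small `s`.
Boundary beads are insulated by default: intersegmental bonds are drawn only
among interior beads `1..L-1`.  `boundary_factor ∈ (0, 1]` relaxes this by
scaling the probability of boundary-touching pairs (0 = full insulation,
1 = none).  The same convention is applied when networks are derived from
polymer conformations or Hi-C maps (`insulate_boundaries=True`); without it
the walker can hop straight onto the target from anywhere, which destroys
the non-monotone dependence of search time on compaction (verified for
freely-rotating-chain networks, where the interior optimum in the bond angle
only appears with insulation).

Counting: with `n = L + 1` beads there are `C(n,2) - (n-1)` pairs at
`|i - j| ≥ 2` (`N_b_max`); of these, `C(n-2,2) - (n-3)` are interior-only
and eligible under full insulation (123,753 for `L = 500`).  A commonly
quoted approximation `C(L,2) - L` differs by 1 and is not used.

Randomness: every sampling call takes an integer seed and creates
`numpy.random.default_rng(seed)` (PCG64); one uniform variate is drawn per
ordered bead pair in row-major order (`rng.random((n, n))`, strict upper
triangle used), so matrices are bit-reproducible given (model, L, seed).

## Walker dynamics

Per step from interior bead `i`:

1. with probability `p_off`: unbind — pay the residence `τ` plus the bulk
   excursion `τ_f`, then rebind uniformly over all `L + 1` beads (landing on
   a target counts as success).  The unbinding decision precedes the
   neighbour choice, and the bulk time is deterministic (`τ_f` is a mean;
   only the mean enters the first-passage system).
2. otherwise: move to a uniform random bonded neighbour; a backbone move
   costs `τ`, an intersegmental hop `t_jump` (default `τ`).

Defaults state the modelled regime: `τ = 1` (time unit), `τ_f = 100 τ`,
`p_off = 0` (proteins spend nearly all time bound in dense chromatin),
start at `floor(L/2)`.  Dynamic networks redraw all intersegmental bonds,
memorylessly, every `t_config_switch` walker steps (1 = fully dynamic,
None/inf = static).  The dynamic kernel draws bond rows lazily — only rows
the walker visits within a switch window — enforcing symmetry against rows
already drawn in the window; this is distributionally identical to redrawing
the full symmetric matrix and keeps the per-step cost `O(L)`.

## First-passage theory

With states = beads plus a bulk state `f`, the mean absorption times solve
`A T = B` where interior rows carry `-(1 - p_off) C_ij / N_i` and `-p_off`
towards `f`, the `f` row rebinds uniformly (`-1/(L+1)`) with `B_f = τ_f`,
and `B_i` is the expected residence per step
(`(1-p_off)(2τ + (N_i - 2) t_jump)/N_i + p_off τ`, reducing to `τ` when
`t_jump = τ`).  Solves are dense LAPACK; the residual `‖A T - B‖` is checked
against a 1e-10 relative tolerance (scaled), and the system is well posed
for any `p_off ∈ [0, 1]` because rebinding reaches the absorbing beads.

**Annealed solver.**  For a fully dynamic network the transition probability
is the exact bond-ensemble expectation.  Conditioning on the used bond and
writing `K` for the Poisson-binomial count of the remaining bonds at bead
`i`:

```
E[C_ij/N_i] = p_ij E[1/(3 + K')]          (intersegmental pair)
E[1/(2 + K)]                               (backbone move)
E[1/(a + K)] = ∫₀¹ u^(a-1) Π_k (1 - p_k (1 - u)) du
```

The integrand is a polynomial of degree ≤ `L`, integrated exactly by
Gauss–Legendre quadrature with `(L+5)//2 + 1` nodes.  Because `p` depends
only on separation, the per-bead products reduce to cumulative sums over
separations and the full transition matrix assembles from two matrix
products (`O(L² · n_q)` flops; ~2 s at `L = 1600`).  The implementation is
verified against exhaustive enumeration over all bond configurations at
small `L` (agreement ≤ 5e-12) and against fully dynamic Monte-Carlo walks.
A mean-field alternative (`P_ij / E[N_i]`) was considered and rejected: the
exact conditioning costs the same here and removes an uncontrolled
approximation.

Printed asymptotics of the annealed uniform model are provided:
the low-connectivity expansion
`T/T_d ≈ 1 - (L³ - 5L² - 20L + 48) p_u / 48` (valid for `p_u ≪ 1/L²`; a
warning fires when `p_u L² > 0.1`) and the high-connectivity closed form
`T = [2 + (L-3) p_u + (2 + (L-4) p_u)²]/(2 p_u)`.  The latter is an
*asymptote*: at `p_u = 1` the exact fully connected system gives
`T = (L-1) + (L-2)²/2` (hand-checkable at `L = 4`: `T = 5`), while the
closed form gives `(L-1)/2 + (L-2)²/2`, a relative gap of ≈ `1/L` that the
test suite measures rather than hides.

## Polymer models

* **FRC**: unit bonds, fixed angle `θ` between successive bond *vectors*
  (so `θ → 0` is a rod and large `θ` collapses the coil), azimuth uniform on
  `[0, 2π)` — "within a cone" is read as the uniform-azimuth convention.
  First bond along +z.  `⟨R²⟩/(n b²) → (1 + cos θ)/(1 - cos θ)`.
* **LJ / soft-LJ bead-spring chains**: harmonic springs `k/2 (r - σ)²`
  between neighbours plus pair energies as piecewise printed: LJ
  `4ε[(σ/r)¹² - (σ/r)⁶]` cut at `2.5σ`; soft-LJ replaces the core below
  `r_m = 1.12` by `V0 [1 - (r/r_m)^η1]^η2 - ε` (`V0 = 1e7`, `η2 = 3.16`),
  a finite overlap penalty `V0 - ε` whose softness is set by `η1`.
* **Langevin integrator**: velocity Verlet with friction `γ = 1`, mass 1,
  `dt = 0.01`, Gaussian noise of variance `2γk_BT/dt` per half step.
  Intended for reduced scale (`L ≲ 300`); it demonstrates the coil–globule
  contrast and the softness-controlled packing, not full phase diagrams.
  A force magnitude above 1e12 (hard-core overlap) aborts with an error.

Conformations convert to networks by an inclusive distance cutoff
(`r_ij ≤ r_c`).  The cutoff is not dictated by the model; the default
`r_c = 1.5 σ` (between bead contact at `1 σ` and the attraction range
`2.5 σ`) is a package choice, exposed as a required-visible flag on the CLI
(`poly2net --rc`), and all qualitative results quoted here were obtained at
that value.

## Hi-C analysis

Maps are dense matrices over 1-kb bins (dense-TSV and COO-triplet readers;
binary multi-resolution containers are out of scope).  `probability_scale`
divides by the chromosome-wide maximum off-diagonal entry (per-chromosome,
not per-TAD).  Method-1 fits `log P_c(s)` vs `log s` by ordinary least
squares over `s ∈ [10, L_kb - 100]`; the range is empty for TADs of
`L_kb ≤ 110`, which are rejected with an explicit error (callers may pass a
custom range).  Zero or negative curve values are dropped from the fit, not
imputed.  Method-2 draws Bernoulli networks from the scaled `P_ij`
(backbone forced, terminal bins insulated).  With matched parameters the
two routes agree on the ensemble-mean search time within the
configuration-sampling error (tested at 10%).

## Synthetic maps

The generator states a ground-truth world: intra-TAD pairs follow
`c s^-γ` with defaults `(0.0214, 0.71)` (the experimentally reported
genome-wide averages), background pairs `(0.0214, 1.08)` (the chromosome-
scale exponent with the same prefactor, an arbitrary but realistic
choice), multiplicative lognormal noise with `σ_log = 0.2` on the
probabilities (matching the scatter of real intra-TAD curves; a
read-sampling noise model is not implemented), symmetrised, capped at 1,
diagonal set to 1.  Maps are emitted flagged as probabilities; their maximum
off-diagonal entry is below 1 by construction, so `probability_scale` is
applied only when emulating the raw-map normalisation step — rescaling a
synthetic map would silently change its ground-truth `c`.

What a green round-trip test establishes: the curve-extraction and fitting
code is unbiased under the stated noise model.  What it does not: robustness
to real Hi-C artefacts (coverage bias, unmappable bins, distance-dependent
filtering), which the generator deliberately omits.  The genome-wide values
(`⟨c⟩ = 0.0214`, `⟨γ⟩ = 0.71`, 8,355 TADs) require the external GM12878
maps and TAD annotations and are not recomputed here.

## Numerical and scale choices

* Dense linear solves up to `L = 1600` (the largest length used anywhere);
  a sparse path is unnecessary at these sizes.
* Monte-Carlo ensembles in tests are scaled to keep the suite fast
  (e.g. 4,000 instead of 10,000 draws for bond-count statistics, with the
  acceptance bands tied to the actual standard errors; 10,000 walks are
  kept where the check specifies them).  Statistical assertions use 3-SE
  bands and fixed seeds.
* The Langevin demonstrations run at `L = 50–60`, 6,000 steps — far below
  publication scale; they assert orderings (R_g and bond-count across the
  collapse, softness-controlled strength of the search-time rise), not
  absolute values.
* `N_b_max` uses the exact eligible-pair count `C(n,2) - (n-1)`.
* Times are always reported in units of `τ`; scaled tables include
  `T/T_d` with `T_d = L²τ/4`.

## Known limitations

* The contact-space representation ignores higher-order loop correlations;
  bonds are pairwise independent given `P_c(s)`.
* Bulk excursions are a single effective state with a deterministic
  duration; no spatial 3D diffusion.
* Single walker; no protein–protein interactions or sequence-dependent
  binding.
* The annealed solver models the fully dynamic limit; intermediate
  switching rates are accessible only through the Monte-Carlo walker.
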