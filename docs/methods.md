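# Methods

## The community model

`mnyield` simulates a community of `S` fish species as abundance densities
`N_i(w)` (numbers per gram body mass, per unit system area) on a shared
logarithmic mass grid, together with a background resource spectrum `N_R(w)`
representing unmodelled food (plankton, benthos). The state evolves by the
McKendrick–von Foerster transport equation

```
∂N_i/∂t + ∂(g_i N_i)/∂w = −μ_i N_i ,
```

with growth `g_i(w)` and mortality `μ_i(w)` emerging from size-based
encounter rather than being prescribed per species.

**Encounter and feeding.** A predator of mass `w` prefers prey of mass
`w/β`, with lognormal preference
`φ(w, w_p) = exp(−ln²(w/(β w_p)) / 2σ²)`. Encountered biomass flux is
`E_i(w) = γ_i w^q ∫ φ_i(w, w_p) [Σ_j θ_ij N_j(w_p) + N_R(w_p)] w_p dw_p`,
where `θ_ij ∈ [0,1]` is the interaction (availability) matrix, all ones by
default. The realised feeding level saturates Holling-II style:
`f_i = E_i / (E_i + h_i w^n)` with maximum intake `h w^n`.

**Energy budget.** Assimilated intake minus standard metabolism,
`e = max(0, α f h w^n − k_s w^p)`, is split by a maturity allocation
`ψ(w) = min(1, [1+(w/w_mat)^{-10}]^{-1} (w/w_∞)^{1−n})` (forced to 1 at
`w ≥ w_∞` so growth stops exactly at the asymptotic mass): somatic growth
`g = e (1−ψ)`, reproduction `e ψ`.

**Recruitment.** Egg production `R_di = ε_r ∫ e ψ N dw / (2 w_min)`
(the factor 2 for a 1:1 sex ratio) is capped by a Beverton–Holt ceiling:
`R = R_max R_di / (R_max + R_di)`. The ratio `ρ = R_di/R_max` at the
unfished equilibrium — the *recruitment level* `ρ/(1+ρ)` — controls how hard
a stock can be fished before recruitment fails, and is a first-class
calibration target of the generators (below).

**Mortality.** Predation
`μ_p,j(w_p) = Σ_i θ_ij ∫ φ_i (1−f_i) γ_i w^q N_i dw`, plus a constant
allometric background `μ_b = μ_b0 w_∞^{n−1}`, plus fishing
`F_i(w) = Σ_g S_{g,i}(w) Q_{g,i} E_g` with sigmoid trawl selectivity
`S(w) = [1+exp(−slope·(ln w − ln w50))]^{-1}`.

**Resource.** Semi-chemostat dynamics
`dN_R/dt = r_0 w^{n−1}(κ w^{−λ} − N_R) − μ_grazing N_R`, with carrying
capacity truncated above `w_res,max`.

### Default parameters

| parameter | default | units | role |
|---|---|---|---|
| `n`, `p` | 0.75 | – | intake and metabolism exponents |
| `q` | 0.8 | – | search-volume exponent |
| `λ` | 2 + q − n = 2.05 | – | resource spectrum slope |
| `β`, `σ` | 100, 1.3 | – | preferred predator–prey mass ratio, diet breadth |
| `h` | 30 | g^(1−n)/yr | maximum intake coefficient |
| `α` | 0.6 | – | assimilation efficiency |
| `k_s` | f_c α h (f_c = 0.2) | g^(1−p)/yr | metabolism fixed by a critical feeding level 0.2 |
| `γ` | closed form | – | chosen so f = 0.6 on an unperturbed resource spectrum |
| `μ_b0` | 0.6 | 1/yr·g^(1−n) | background mortality coefficient |
| `w_min` | 10⁻³ | g | egg mass |
| `w_mat` | 0.25 `w_∞` | g | maturation mass |
| `κ`, `r_0`, `w_res,max` | 10¹¹, 4/yr, 100 g | – | resource magnitude, regeneration, cutoff |
| grid | 100 log bins, +3 decades of resource | – | discretisation |
| `dt` | 0.1 | yr | time step |

These are conventional trait-based community values. Two were chosen
deliberately for community viability: the resource extends to 100 g at full
strength (so piscivore juveniles do not starve in a community whose fish
spectrum alone cannot feed them), and `R_max = 10 κ w_∞^{−1.5}` places the
fish community near the continuation of the resource spectrum, which makes
predation a leading mortality source — without that, species decouple and
every nutrient question becomes trivially neutral.

## Numerics

**Time stepping** uses operator splitting: an implicit upwind sweep for the
growth transport with the recruitment boundary flux
(`g_0 N_0 = R` enters the first bin as `R/dw_0`), followed by exact
exponential decay `N ← N e^{−μ dt}` for total mortality, and a semi-implicit
update for the resource. The scheme is unconditionally stable, first-order
in `dt`, conserves non-negativity, and reproduces constant-mortality decay
exactly — with growth off, ten simulated years match `e^{−μt}` to machine
precision, which anchors the decay oracle test. The stepping kernel is
compiled with numba (a pure-numpy implementation is kept as a fallback and
cross-checked in the tests).

**Equilibration.** A run is converged when every species' biomass changes
by less than `tol` (default 10⁻⁵) per year, averaged over a trailing 10-year
window, within `t_max` (default 600 yr). Species whose biomass is below
10⁻⁶ of community biomass are exempt: a stock decaying towards zero never
stabilises in relative terms while contributing nothing to any output.
Two caveats discovered during development and worth knowing:

- *Slow transients and oscillations.* Cold starts need several hundred
  years; near collapse boundaries the dynamics show critical slowing and,
  at some effort levels, small persistent predator–prey cycles that never
  meet `tol`. Such runs return the `t_max` state with a logged warning; the
  induced error in the curves is at the 0.1–1% level.
- *Alternative stable states.* With Beverton–Holt recruitment and strong
  predation the unfished community can hold alternative equilibria; very
  different initial spectra may converge to states with different species
  compositions. All pipeline stages therefore warm-start from a common
  equilibrium and treat "equilibrium" as the attractor of that basin.

**Reference points.** Single-species `F_MSY` holds all other species at a
background mortality vector and maximises the focal species' equilibrium
yield: an adaptive ascending scan (geometric steps from 0.02/yr, stopping
once the yield has clearly passed its peak) brackets the maximum, and
golden-section search refines it to 0.5% by default. The one-at-a-time
procedure is iterated across species with damped updates
(`F ← 0.5 F_new + 0.5 F_old`) until no estimate moves by more than 1%
(at most 10 rounds); undamped iteration falls into a small limit cycle on
interacting communities. The fixed point depends weakly on the search path,
so `F_MSY` values carry a few-percent irreducible uncertainty — comparisons
built on them (the effort axis, the classifications) inherit that.

**Curves and maxima.** The effort sweep fishes every species at
`F_MSY,i × E` for `E = 0, 0.05, …, 4`, warm-starting each equilibrium from
the previous one, and truncates after the first `E` at which community
biomass falls below 10% of unfished or more than half the stocks are
collapsed (a stock is collapsed below 10% of its unfished biomass). Each
maximum is located on the grid and refined by a 3-point quadratic clamped to
the neighbouring interval; grid-only argmaxes would quantise the
`F_mMNY/F_mMSY` ratios to the 5%-step resolution. A nutrient is *neutral*
when its ratio is within 5% of 1, otherwise over-/underfished by sign. Both
the effort-multiplier and the exploitation-rate (total catch / total
biomass) values of each optimum are reported; ratios are taken on the
effort-multiplier axis, the controlled variable.

## The constrained optimiser

`optimise_nutrient` maximises one nutrient's equilibrium yield over the
per-species fully-selected mortality vector, bounded to [0.01, 2]/yr.
Because "discard any policy that collapses a stock" breaks quasi-Newton
line searches, infeasibility enters as a smooth penalty
(yield/yield_baseline − 100 Σ max(0, 0.1 − B_i/B0_i)); the candidate from
each start is then re-verified against the *hard* constraint by a fresh
equilibrium run, and only verified candidates are returned. Gradients are
central finite differences (step 10⁻³/yr). Starts: the baseline policy plus
5 seeded Latin-hypercube points (starting from the baseline also guarantees
the returned optimum never undercuts a feasible baseline). Deltas against
the baseline are reported for nutrient yield, total catch, fishable biomass
and per-species F; the generic baseline is every species at its `F_MSY`.
With that baseline the optimiser often finds little headroom — an honest
property of communities already fished at their single-species optima —
while seeds that concentrate a nutrient on few stocks show gains of ~10%
traded against fishable biomass.

## The evenness–vulnerability framework

For a catch composition `w` (catch or nutrient catch per taxon), evenness is
Pielou's `J = −Σ p ln p / ln S⁺` over the `S⁺` taxa with positive weight;
a single-taxon composition is defined as `J = 0` (maximally uneven), and
zero-weight taxa do not count towards richness — `J` describes the realised
catch. Vulnerability is the weighted mean `V = Σ w v / Σ w` in one of two
currencies: simulated `F_MSY` (model mode, higher = *less* vulnerable) or
the intrinsic 1–100 index (catch-table mode, higher = *more* vulnerable);
classifications flip sign accordingly. A nutrient is *resilient* (expected
underfished) when its catch-weighted mean `F_MSY` exceeds the total-catch
value at mMSY, *vulnerable* when below.

Catch-table mode aggregates records per region; genus- and family-rank
records inherit the unweighted mean concentration of their group's species,
and unresolvable records are dropped with a logged count. Per-region means
across the six catch-table nutrients (vitamin D is excluded there, as
species-level estimates are largely unavailable in global catch data) are
reported with twice the sample SEM (n = 6). The per-nutrient deviation
`ΔV = V_n − V_tot` (a difference, symmetric about 0) feeds the global
summary: the fraction of regions where each nutrient's catch is less/more
vulnerable than total catch, with ties counted separately.

## Synthetic data: what it does and does not emulate

`make_generic_community` builds the *generic interacting community*:
asymptotic masses log-spaced over 10 g–100 kg, `w_mat = 0.25 w_∞`, one
dedicated trawl per species (`w50 = 0.05 w_∞`, slope 3, Q = 1), nutrient
concentrations lognormal around medians on each nutrient's customary
per-100 g scale (log-SD 0.6), optionally with a negative loading of log
concentration on log `w_∞` ("size-correlated" mode — smaller fish richer,
the empirical pattern for forage species). Reproduction efficiencies are
calibrated at build time (two equilibrium passes) so every species sits at
recruitment level 0.9 unfished.

`make_nutrient_loading_fixture` is the directional test bed: four forage /
mesopredator species (100–2000 g) plus a large piscivore (9 kg) whose
juveniles and adults prey on the forage; a flattened `R_max ∝ w_∞^{-1}`
keeps catch shares comparable; recruitment levels (0.95, 0.5, 0.5, 0.35,
0.35) make the smallest forage species highly resilient and the piscivores
genuinely collapsible; and the resource regenerates fast (`r_0 = 50`/yr) so
interactions act through predation rather than shared-resource competition.
Fishing down the community collapses the piscivore, releases the forage
species from predation, and pushes its catch maximum beyond the
community-wide optimum — the mechanism behind nutrient underfishing by
resilient forage stocks. Loading one nutrient 2500-fold onto the resilient
forage species yields `F_mMNY/F_mMSY ≈ 1.1` and classification *resilient*;
loading it onto the piscivore yields ≈ 0.15 and *vulnerable*. The design is
deliberate: in a plain log-spaced size chain, predation release flows to
mid-trophic species rather than to the smallest one, and the directional
link between `F_MSY` rank and curve peak does not emerge — it requires the
short predator-on-forage topology built here.

`make_catch_table` emulates reconstructed regional catch statistics: a
global species pool with genus/family lineage, lognormal catch shares of
tunable skew, a tunable fraction of records demoted to genus/family rank
(losing their species profile), and vulnerability scores tied to asymptotic
length through a Gaussian copula. It reproduces the *statistical structure*
the framework consumes — skewed shares, incomplete taxonomy, size-linked
vulnerability — not any real region's composition, gear structure, discard
treatment or multi-year averaging.

Passing tests on these generators show that the pipeline's logic, oracles
and directional mechanisms are correct under controlled conditions; they do
not validate the simulator against any observed fishery, which would require
calibration to real catch and biomass series (out of scope).

## Problem sizes and tolerances used in the shipped runs

The test suite and `scripts/acceptance.py` run at desk scale: 80 size bins
for 15- and 5-species communities, 60 for 3-species fixtures; sweep grid
0–4 in steps of 0.05; equilibrium tolerance 10⁻⁴/yr with `t_max` 300 yr for
the large fixtures (the directional fixture uses the default
10⁻⁵/600 yr, as its signal rides on curve shape near the optimum); `F_MSY`
iteration capped at 1–3 damped rounds in the heavy fixtures. The
equal-concentration identity, decay oracle, hand-arithmetic checks and
determinism checks are exact and independent of these sizes; oracle
agreements (golden-section vs dense grid, optimiser vs 10⁴ random policies)
hold at 1–2% at these sizes.

## Known limitations

- Strategic, not tactical: no calibration to observed time series, no
  spatial structure, seasonality, temperature effects or technical
  interactions between métiers.
- Reference points inherit a few-percent path dependence from the iterated
  `F_MSY` fixed point, and near-collapse equilibria a 0.1–1% residual drift.
- The per-species effort axis requires a one-to-one species–gear mapping;
  multi-species gears can be simulated but not swept per species.
- Nutrient concentrations are inputs; no attempt is made to predict them
  from traits.
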