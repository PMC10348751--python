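# Methods

## Model

`medspace` simulates communities of microbial species that interact
exclusively through diffusible chemical mediators on a one-dimensional
habitat. Species `i` has density `S_i(z, t)` (cells/ml) and mediator
`j` concentration is `C_j(z, t)` (fmol/ml). The coupled dynamics are

    dS_i/dt = D_cell ∂²S_i/∂z²
              + (1 − Σ_j S_j / k_Y) [ r0_i + Σ_j ρ_ij g_ij(C_j) ] S_i
    dC_j/dt = D_med ∂²C_j/∂z² + Σ_i (β_ji − α_ji) S_i

with no-flux boundaries at z = 0 and z = Z for both fields. Mediators
act additively on growth. A facilitative influence (ρ_ij > 0)
saturates, `g = C/(C + k_sat)`, so a benefit is bounded by ρ_ij; an
inhibitory influence (ρ_ij < 0) is linear, `g = C/k_sat`, so toxicity
keeps growing with concentration. The logistic crowding factor uses
the local total density against the per-point cap `k_Y` and multiplies
the whole bracket, including negative rates, exactly as written.

A community blueprint (`InteractionNetwork`) is random: production
links with probability `qp` per (mediator, species) pair, influence
links with probability `qc`; a species consumes a mediator exactly
when the mediator influences it, whatever the sign. Rates are uniform
on [0.5v, 1.5v] around their set values (β0 = 0.1, α0 = 0.15 fmol per
cell per hour), influence magnitudes uniform on (0, rint0 = 0.2] 1/hr,
signs facilitative with probability `fac_ratio`, and basal rates r0
uniform on [0.1, 0.2] 1/hr.

## Numerics

Updates are asynchronous on three clocks: growth/uptake every
`dtau = 0.01 hr`, mediator diffusion every `dt = 0.1 dz²/D_med`, cell
dispersal every `dc = 0.1 dz²/D_cell`, executed in time order with the
fixed tie-break growth → mediator diffusion → cell dispersal (the
orderings differ at O(step)). Event clocks restart at each `advance()`
call (each growth round).

* Growth is multiplicative, `S ← S·exp(rate·dtau)`, which preserves
  nonnegativity exactly; at `dtau = 0.01 hr` it is indistinguishable
  from forward Euler for the rates the model produces.
* Mediator uptake is applied as written, `ΔC = (β − α)·S·dtau`, with C
  clamped at zero afterwards (the printed consumption term does not
  vanish with the stock, so clamping is required). An optional
  `saturating_consumption` mode multiplies consumption by
  `C/(C + k_sat)` for strictly stock-limited uptake; it is off by
  default.
* Diffusion is the standard explicit second-difference stencil with
  reflecting boundaries on a cell-centred grid (`dz = 0.005 cm`,
  stability factor 0.1 ≤ 0.5). All diffusion events that fall between
  two growth updates compose into the linear operator A^k; the
  integrator caches these dense powers and applies them as one matrix
  product per growth step. This is the same linear map as k successive
  stencil applications (floating-point rounding order differs at the
  1e-14 level) and is what keeps a default-parameter enrichment
  instance at ~1.5 s. An optional backward-Euler operator
  (`implicit_diffusion`) is available; the explicit scheme is the
  reference and the default.
* Densities below 1e-30 cells/ml are flushed to zero (nine orders of
  magnitude below the extinction threshold; keeps the arithmetic out
  of subnormals).
* Non-finite fields abort integration with the time and grid index.

The well-mixed counterpart drops both diffusion operators and runs the
identical growth/uptake kernel on single-point fields. The
infinite-dispersal mode re-uniformises the species fields at t = 0 and
after every growth update; because uniform fields are fixed points of
diffusion, both diffusion operators are skipped exactly, and the mode
reproduces the well-mixed limit bit-for-bit up to BLAS summation
order. Uniform initialisation of the spatial integrator agrees with
the well-mixed trajectory to ~1e-11 relative over 20 hr (tested).

## Enrichment protocol

Species are inoculated in adjacent, non-overlapping blocks of
~n_z/n_species grid points, each species' spatial average set to
TID/n_species (total spatial-average density TID = 1e4 cells/ml);
mediators start at zero. A round integrates until the spatially
averaged total density reaches DilTh = 1e7 cells/ml (checked after
each growth update), then everything is divided everywhere by the
realized factor end-density/TID — i.e. DilTh/TID = 1000 up to the
sub-percent overshoot of the final growth step — which preserves the
spatial distribution. Mediators are diluted by the same factor by
default ("retain" and "reset" are available; the choice is not
dictated by the model). A species whose spatially averaged density
falls below ExtTh = 0.1 cells/ml after dilution is zeroed everywhere.

Generations accrue as log2 of each round's realized fold-growth
(≈ 9.966 per full round) and the run stops once 100 generations have
accumulated — 11 rounds under the defaults. A round that fails to
reach DilTh within `round_t_max = 2000 hr` ends with generations from
its realized growth; a capped round with essentially no growth
(< 0.05 generations) ends the run, since such a community is inert.

**Coexistence scoring.** A species is *present* if its final spatial
average exceeds ExtTh, and *stable* if its relative frequency at the
end is at least 90% of its frequency 20 generations earlier. The
reference point is the recorded round boundary nearest to
(end − 20 generations), which is two dilution rounds (19.93
generations) before the end under the defaults. Richness is the
number of stable species; a presence-only variant is available.
Shannon diversity `H = −Σ p ln p` is computed over the final
spatially averaged abundances.

## Ensembles and statistics

Instance k of any condition draws its network from
`SeedSequence([master_seed, k])`, with one child stream per random
component (production links, production rates, influence links,
magnitudes, signs, consumption rates, r0). Consequences: spatial and
well-mixed runs of an instance share the identical network, and two
conditions differing in a single generation parameter share every
other draw (common random numbers). The original study used
independent 500-instance ensembles per condition; this package
defaults to paired, smaller ensembles, which sharpen directional
comparisons at a fraction of the cost. Mean richness per condition is
reported with a percentile-bootstrap 95% CI over instances
(100 resamples, scipy).

Problem sizes used by the shipped tests and the acceptance script,
chosen to keep a full run in the tens of minutes on one CPU: fac:inh
ensembles n = 40 per condition (tests) and n = 24 (acceptance script),
auxiliary sweeps (dispersal, mediator diffusion, crowding cap) n = 32,
infinite-dispersal pairs n = 20 (tests) / 10 (script), position
shuffles 8 networks × 8 arrangements. Directional claims are asserted
on paired ensemble means.

## What the generator does and does not emulate

The synthetic communities follow the standard study conditions: 10
species, 5 mediators, qp = qc = 0.5, D_med = 1.8e-2 cm²/hr (500 µm²/s,
a generic small molecule in water), D_cell = 5e-9 cm²/hr (essentially
immotile cells; no dispersal event fires within a round), Z = 0.5 cm,
k_Y = 1e9 cells/ml (crowding nearly irrelevant at DilTh = 1e7). They
do not emulate: heterogeneous per-species dispersal or per-mediator
diffusion, degree-constrained or empirically calibrated topologies,
correlated production/consumption rates, demographic noise, or more
than one spatial dimension. Passing trend tests therefore says the
mechanisms (self-organisation under facilitation, interaction
localisation) operate in this model class, not that their magnitudes
transfer to any real community.

## Known limitations and open choices

* The printed consumption term can only be reconciled with
  nonnegative concentrations by clamping; the saturating mode is the
  physically cleaner alternative and changes quantitative outcomes
  slightly.
* Whether production/consumption pause when a species' net growth
  rate is negative is unspecified; they stay on.
* With n of order tens, paired one-sided trend comparisons are
  directional checks, not effect-size estimates; the
  spatial-vs-well-mixed richness gap at 90:10 is a fraction of a
  species at these sizes.
* Block widths are equal only when n_species divides n_z; otherwise
  the first remainder blocks are one point wider, which introduces a
  deterministic sub-percent asymmetry in per-species crowding.
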