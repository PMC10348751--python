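# medspace

Mediator-explicit simulation of microbial coexistence in a
one-dimensional spatial habitat.

`medspace` is for ecologists and systems biologists who want to ask
how spatial structure changes the outcome of metabolite-mediated
microbial interactions. Species interact only through diffusible
mediators they produce and consume; each mediator raises or lowers the
growth rates of the species it influences. Communities are enriched
through serial growth–dilution rounds, and the package scores how many
species stably coexist — in space, in a well-mixed flask with the same
interaction network, and in an infinite-dispersal control that
recovers the well-mixed limit.

## Model

On a 1D grid with no-flux boundaries,

    dS_i/dt = D_Cell ∂²S_i/∂z² + (1 − Σ_j S_j/k_Y)
              [ r⁰_i + Σ_j ρ_ij ( C_j/k_sat δ⁻_ij
                                  + C_j/(C_j+k_sat) δ⁺_ij ) ] S_i
    dC_j/dt = D_Med ∂²C_j/∂z² + Σ_i (β_ji − α_ji) S_i

where δ± pick the saturating response for facilitative influences
(ρ_ij > 0) and the linear one for inhibitory influences (ρ_ij < 0),
and a species consumes every mediator that influences it. Interaction
networks are random: link probabilities `qp` (production) and `qc`
(influence/consumption), uniform rates around set values, influence
signs facilitative with probability `fac_ratio`. Enrichment grows the
community from a total density of 10⁴ cells/ml to 10⁷ cells/ml,
dilutes everything 1000-fold preserving the spatial distribution, and
repeats for 100 generations; richness counts species whose relative
frequency declined less than 10% over the final 20 generations. See
`docs/methods.md` for the numerics and all defaults.

## Worked example

```python
import medspace as ms

cfg = ms.SimulationConfig()                # standard study conditions
net = ms.generate_network(fac_ratio=0.9, seed=(7, 13))

spatial = ms.run_enrichment(net, cfg, mode="spatial")
mixed   = ms.run_enrichment(net, cfg, mode="well_mixed")
print("spatial:    richness", spatial.richness,
      "shannon %.2f" % spatial.shannon,
      "generations %.1f" % spatial.generations)
print("well-mixed: richness", mixed.richness,
      "shannon %.2f" % mixed.shannon)
```

prints

    spatial:    richness 4 shannon 1.36 generations 109.7
    well-mixed: richness 1 shannon 0.03

Instance 13 of master seed 7 is a mostly-facilitative community
(fac:inh = 90:10): four of ten species stably coexist when grown in
space, but only one dominates the same enrichment in a well-mixed
environment — the spatial arrangement lets species sit next to their
facilitators, amplifying positive interactions. 109.7 generations is
11 dilution rounds of log2(1000) ≈ 9.97 generations each.

Ensembles with bootstrap confidence intervals:

```python
from medspace.experiments import sweep
table = sweep({"fac_ratio": [0.1, 0.5, 0.9]}, n_instances=24,
              master_seed=7, modes=("spatial", "well_mixed"))
print(table.aggregates[["fac_ratio", "mode", "mean_richness",
                        "ci_lower", "ci_upper"]])
```

The same experiments are available from the shell: `medspace simulate`,
`medspace sweep`, `medspace shuffle` and `medspace network
generate/inspect` (see `medspace --help`).

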