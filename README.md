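# spedre

Scalable rate-parameter estimation for ODE models of biochemical signalling
networks in **data-rich** settings — where every molecular species is observed
at every timepoint. Given a mass-action reaction network and dense time-series
concentration data, `spedre` estimates the unknown rate constants by

1. fitting spline curves through the observed time courses and interpolating
   the time derivatives dx̂ᵢ/dt;
2. forming one collocation error term per experiment *e*, species *i* and
   timepoint *tⱼ*,
   ε₍ₑ,ᵢ,ⱼ₎ = ( fᵢ(x̂(tⱼ), k̄) − dx̂ᵢ/dt(tⱼ) )²,
   where fᵢ is the ODE right-hand side evaluated at the *observed*
   concentrations — so each term involves only the few parameters appearing in
   species *i*'s ODE;
3. minimizing the decomposable product-of-functions objective
   POF(k̄) = ∏₍ₑ,ᵢ,ⱼ₎ ε₍ₑ,ᵢ,ⱼ₎ approximately, by discretizing each parameter
   into equidistant bins, pre-computing a Boltzmann-weighted joint probability
   table p ∝ exp(−β·ε) per error term, and running max-product loopy belief
   propagation on the resulting bipartite factor graph (the *base* stage,
   yielding a MAP bin per parameter);
4. refining the MAP bin midpoints with bounded trust-region nonlinear least
   squares (Levenberg–Marquardt-style) on the primal simulate-and-match
   weighted SSE (the *full* pipeline).

The pre-computation cost is ∑_factors (bins)^degree: polynomial in the number
of species, timepoints and bins, exponential only in the network degree (the
maximum number of rate parameters per ODE), which is small for typical
signalling topologies. Quality is scored by weighted SSE, species maximum
relative error (MRE, % of the observed dynamic range) and parameter percentage
error (PPE = 100·|k̂−k|/k, aggregated by the median).

The package ships the synthetic benchmark families used to evaluate the
method: ring networks of unimolecular conversions, random low-degree networks
(two-thirds bimolecular), and an Akt-activation topology with redox regulation
of PTEN (placeholder unit-scale rate constants), plus a seeded noisy-dataset
generator.

## Worked example

Recover the ten rate constants of a ring network from one noise-free
experiment (11 timepoints over 4 s; 10 bins per parameter on [0.05, 1.05];
true rates at bin midpoints):

```python
import spedre as sp

scenario, scheme = sp.make_ring_scenario(10, seed=0)
dataset = sp.generate_dataset(scenario)

base = sp.spedre_base(scenario.network, dataset, scheme)
print("MAP bin midpoints:", base.midpoints)
print("truth:            ", scenario.nominal_params)

full = sp.spedre_full(scenario.network, dataset, scheme)
ppe, median = sp.parameter_percentage_error(full.refined_params,
                                            scenario.nominal_params)
print(f"median PPE after refinement: {median:.2e} %")
```

prints

```
MAP bin midpoints: [0.7 0.3 0.1 0.1 0.8 0.9 0.6 0.8 0.6 0.9]
truth:             [0.7 0.3 0.1 0.1 0.8 0.9 0.6 0.8 0.6 0.9]
median PPE after refinement: 0.00e+00 %
```

i.e. belief propagation identifies the exact data-generating bin for every
parameter (here after 5 iterations and 9 000 pre-computed table cells), and
local refinement then reproduces the true rate constants to machine precision.

The same pipeline is available from the shell:

```sh
spedre generate --scenario ring --n-species 10 --seed 0 --outdir ring10
spedre estimate --model ring10/model.txt --data ring10/data_exp0.csv \
                --truth ring10/manifest.json --outdir ring10/out
```

which writes the MAP beliefs, the refined parameters, a convergence log and a
score report (`scores.json`) to the output directory. `spedre benchmark`
sweeps ring sizes × grids × seeds × methods into a TSV table, and
`spedre simulate` / `spedre score` integrate a model and score a candidate
parameter vector.

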