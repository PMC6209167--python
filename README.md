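# abxlattice

Stochastic lattice model of competition between antibiotic-producing
bacteria (P), non-producing cheaters (N), sensitive cells (S) and
resistant cells (R), together with its well-mixed ODE counterpart.

Two species share an L×L torus. Species 1 carries an evolvable
antibiotic production rate `a` (`a = 0` is the cheater N) and pays a
growth cost `a·c`; species 2 is either sensitive — its birth rate is
reduced by the local antibiotic concentration `A_loc = Σaᵢ/(9b)` over
the 9-site Moore neighbourhood — or resistant, paying a fixed cost
`c_R`. Each time step `δt`, every site is visited once in random order:
an occupied site reproduces into a random neighbour with probability
`max(0, rᵢ)·δt` (offspring mutate with probability `u`) and dies with
probability `v·δt`. Spatial structure sustains cyclic-dominance
coexistence (P beats S, S beats N, N beats P) that is impossible in the
well-mixed limit.

## Library

```python
import abxlattice as ax

params = ax.ModelParams(L=256, allowed_a=(0.0, 150.0), c=0.001, seed=7)
result = ax.run(params, ax.standard_composition(150.0), t_end=2000.0)
print(ax.classify_outcome(result.lattice).label)   # e.g. "coexist_PNS"
result.series.to_csv("series.csv")
```

Modules:

- `abxlattice.core` — parameters, cell states, pointwise rate formulas.
- `abxlattice.meanfield` — well-mixed ODEs (bacteriostatic and colicin
  variants), closed-form equilibria, the unstable (P0, S0) point and the
  production-rate window where it exists.
- `abxlattice.lattice` — the stochastic spatial engine (numba kernel),
  snapshot I/O, time series.
- `abxlattice.experiments` — outcome classification, replicate
  ensembles, the a–c phase diagram, staged protocols, multi-strain
  production-rate evolution, resistance sweeps.
- `abxlattice.config` / `abxlattice.cli` — TOML configs and the CLI.

## Command line

```sh
abxlattice run --a 150 --length 256 --t-end 2000 --seed 1 --outdir out/
abxlattice replicates --a 30 --c 0.001 --n 20 --t-end 2000
abxlattice phase-diagram --n 10 --length 256
abxlattice evolve --t-end 10000 --burn-in 1000
abxlattice resist-sweep --r-values 2.0,2.1,2.2,2.3,2.4,2.5
abxlattice ode window --c 0.001
abxlattice ode integrate --a 110 --init 0.05,0.05,0.05
abxlattice snapshot out/final.snap --png out/final.png
```

Every simulation command writes CSV outputs, a plain-text lattice
snapshot and a `metadata.json` (parameters, seeds, version, wall time)
sufficient for bit-exact replay; `--config file.toml` loads a validated
TOML configuration that round-trips through `save_config`.

## Reproducibility

All stochastic state flows through seeded xorshift64* streams; identical
(seed, parameters, composition) give bit-identical trajectories,
independent of numpy/numba versions. Replicate ensembles derive child
seeds deterministically from a base seed.
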