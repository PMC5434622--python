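# mscfate

Simulation and analysis toolkit for mechanical-memory dynamics in
mesenchymal stem cell (MSC) fate decisions.

MSCs differentiate according to the stiffness of the substrate they are
cultured on — soft substrates favour neurogenic and adipogenic fates,
stiff substrates myogenic and osteogenic ones — and they *remember*
earlier substrates: cells primed long enough on a stiff substrate keep
differentiating into osteoblasts after being moved to a soft one. This
package implements a six-variable ordinary-differential-equation model of
that behaviour and the analyses that go with it:

- **Gene regulatory network** (`mscfate.model`): substrate stiffness drives
  an effective substrate adhesion area (SAA) through saturating Hill
  gates; SAA drives YAP/TAZ; YAP/TAZ and SAA in turn gate four lineage
  marker genes (TUBB3 → neurogenic, PPARG → adipogenic, MYOD1 → myogenic,
  RUNX2 → osteogenic); each gene feeds back onto the adhesion area. The
  feedback loops are what store the memory. Includes an analytic Jacobian,
  feedback-blocked variants, and a cooperative (AND-gate) variant with a
  degeneracy check explaining why the non-cooperative (OR-gate) form is
  used.
- **Hysteresis and memory regions** (`mscfate.equilibria`): quasi-static
  stiffness sweeps (Newton-first continuation with integration fallback),
  multi-start equilibrium counting, and detection of the stiffness
  intervals where the increasing and decreasing sweeps disagree — the
  mechanical-memory regions, refined by bisection.
- **Mechanical dosing** (`mscfate.dosing`): the two-seeding protocol
  (first stiffness, priming duration, second stiffness) with lineage fate
  classification and fate maps over condition grids.
- **Parameter robustness** (`mscfate.robustness`): log-normal perturbation
  analysis of all 41 kinetic constants against the hysteresis branch
  structure.
- **Quasi-potential landscape** (`mscfate.landscape`): weak-noise Gaussian
  mixture built from per-attractor Lyapunov covariances and multi-start
  basin occupancies, projected onto the (SAA, YAP/TAZ) plane as
  U = −ln P.
- **Stochastic extension** (`mscfate.stochastic`): Euler–Maruyama
  simulation with multiplicative (state-proportional) noise and detection
  of noise-induced fate switching.

Stiffness is given in kPa at every public interface and converted
internally (1 kPa = 1000 internal units); time is in the model's
dimensionless relative units (unit degradation rates set the clock).

## Worked example

Find the memory regions and probe the dosing protocol:

```python
from mscfate import (DosingSchedule, classify_fate, default_stiffness_grid,
                     detect_memory_regions, run_two_seeding, sweep)

grid = default_stiffness_grid(0.1, 60.0, 400)
up = sweep(grid, "increasing")            # naive cells, stiffness ramped up
down = sweep(grid[::-1], "decreasing")    # committed cells, ramped down

for region in detect_memory_regions(up, down):
    print(f"{region.gene:6s} [{region.lo_kpa:6.3f}, {region.hi_kpa:6.3f}] kPa"
          f"  ON on the {region.on_direction} sweep")

schedule = DosingSchedule(first_S_kpa=30.0, first_duration=50.0,
                          second_S_kpa=0.4)
call = classify_fate(run_two_seeding(schedule))
print(f"30 kPa priming for 50 time units, re-seeded at 0.4 kPa "
      f"-> {call.lineage}")
```

Output:

```text
TUBB3  [ 0.358,  0.598] kPa  ON on the increasing sweep
PPARG  [ 0.617,  1.303] kPa  ON on the increasing sweep
MYOD1  [ 9.779, 13.099] kPa  ON on the increasing sweep
RUNX2  [ 0.100, 16.134] kPa  ON on the decreasing sweep
30 kPa priming for 50 time units, re-seeded at 0.4 kPa -> osteogenic
```

Each lineage gene has its own memory window; RUNX2's is by far the widest,
which is why osteogenic commitment survives re-seeding onto soft
substrates. The `examples/` directory walks through every capability
(hysteresis, attractor counting and landscapes, dosing maps, feedback
blocking, stochastic switching, robustness).

## Command line

```bash
mscfate sweep --s-min 0.1 --s-max 60 --n 500 --out out/
mscfate dose --first-s 30 --first-t 50 --second-s 0.4 --out out/
mscfate dose --first-s 30 --first-t 0 --second-s 0.4 \
        --grid "0,0.5,5,15,50x0.4,0.9,12" --out out/
mscfate landscape --s 0.4 --s 0.8 --s 12 --s 20 --seed 0 --out out/
mscfate sde --first-s 12 --first-t 20 --second-s 12 --replicates 8 --out out/
mscfate robustness --n-stiffness 200 --n-perturb 200 --seed 0 --out out/
```

All commands accept `--config <yaml>` (defaults filled in, unknown keys
rejected) and write the fully resolved configuration as a JSON sidecar
next to their outputs. Exit codes: 0 success, 2 validation error,
3 numerical failure.

## Testing

```bash
python -m pytest -q
```

`tests/test_acceptance.py` checks quantitative targets; the remaining
files unit-test each module, including property-based tests (analytic
Jacobian vs finite differences, non-negativity, the YAP/TAZ closed form,
seeded reproducibility of all stochastic outputs).

## Layout

```
src/mscfate/        library (params, model, solve, equilibria, dosing,
                    robustness, landscape, stochastic, config, reproduce, cli)
examples/           narrative walkthroughs of each capability
scripts/            acceptance metric computation
docs/methods.md     model equations, numerical methods, limitations
tests/              unit, property and acceptance tests
```
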