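# noseflow

Desk-scale tooling for a deceptively simple question in upper-airway CFD:
when you compare two airway geometries (say, before and after surgery),
*what do you hold constant?* The flow rate (CFR), the ambient-to-throat
pressure drop (CPG), or the mechanical power driving the flow (CPI)?
For a single geometry the three choices are equivalent; across a
comparison they are not, and the apparent benefit of an operation —
flow-rate gain, pressure-drop relief, nasal-resistance reduction —
depends systematically on the choice, with CFR and CPG as the extreme
cases and CPI in between.

`noseflow` implements the three forcing controllers and two flow backends
that expose this effect without a cluster:

- **`noseflow.forcing`** — global quantities, sign conventions, the
  lagged constant-power controller `p_th = -P0 / Q_prev`, percent-change
  and time-averaging utilities.
- **`noseflow.lumped`** — a quasi-steady lumped airway network (two nasal
  branches in parallel, pharynx in series, each with a linear+quadratic
  pressure–flow law `aQ + bQ²`). Steady states under each forcing are
  bracketed root-finds on monotone maps, checkable against closed forms.
- **`noseflow.duct`** — a 2D unsteady incompressible Navier–Stokes solver
  (staggered grid, explicit advection, pressure projection via cached
  sparse factorization) on a channel with a smooth one-wall constriction;
  all three forcings are realized as boundary conditions.
- **`noseflow.compare`** — the six-run pre/post comparison protocol,
  reference-triple calibration, consistency checks, and the
  global-quantities report (including a report-only mode that performs the
  table arithmetic on externally supplied values).
- **`noseflow.synth`** — seeded generation of matched pre/post model
  pairs with controllable operation severity.
- **`noseflow.cli`** — `simulate`, `compare`, `make-fixtures`, `sweep`.

## CLI

Single run (lumped backend shown; `backend: duct` takes a `geometry` and
`solver` section instead of `model`):

```yaml
# run.yaml
backend: lumped
model:  # calibrated so dp(2.67e-4 m3/s) = 24.45 Pa
  left:   {a: 48838.95, b: 4.5729e8}
  right:  {a: 73258.43, b: 1.0289e9}
  common: {a:  7325.84, b: 4.1156e7}
forcing:
  mode: CFR
  target: {value: 2.67e-4, units: m3/s}
```

```sh
noseflow simulate --config run.yaml --out out/
noseflow compare  --config compare.yaml --out report/
noseflow sweep    --config sweep.yaml --out sweep/
noseflow make-fixtures --config recipe.yaml --out fixtures/
```

`compare` accepts either two models (runs the full six-simulation
protocol) or a `globals:` section with pre/post `(Q, dp)` pairs
(report-only arithmetic). Every output directory gets a `manifest.json`
with the config hash, package version and seed.

## Conventions

Inspiration is positive flow; the throat pressure is stored signed
(negative during inspiration, ambient at 0 Pa) while pressure drops and
resistances are reported as positive magnitudes. Power is
`P = Q · Δp = −Q · p_th`. Duct quantities are per unit spanwise depth.
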