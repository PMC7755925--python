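# Methods

## Model and assumptions

The simulator integrates an overdamped self-propelled-particle system in
which the only interaction is *statistical*: each agent senses the
headings `Θ_n` and speeds `V_n` of the agents within radius `R` and
moves along (or against) the gradient of the differential entropy of
parametric models of those samples.  Headings are modeled as wrapped
Cauchy with concentration `γ`, speeds as half-normal with scale `σ`;
both entropies then have closed forms, and `γ` and `σ²` are tied to
sample statistics of the neighborhood:

* `γ = −ln S¹_loc`, where `S¹_loc` is the local polar order computed
  **including** the focal agent.  Including the focal heading is what
  makes the angular entropy depend on `θ_n` at all; with it, the entropy
  is stationary exactly at the mean neighbor heading `θ̄` (minimum,
  parallel) and `θ̄ + π` (maximum, anti-parallel), which is the
  correspondence with Vicsek-type alignment: `β_θ < 0` descends the
  entropy and aligns, `β_θ > 0` ascends it and anti-aligns.
* `σ²` is the neighborhood mean of squared speeds (half-normal maximum
  likelihood scale), focal included.  The speed gradient is
  `∂S/∂v_n = v_n/(N_A σ²)`.

Orientation and speed dynamics are assumed decoupled; noise is Gaussian
and white; the box is fully periodic; all agents share one parameter
set.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `beta_theta` | angular sensitivity | 0 | <0 aligns, >0 anti-aligns |
| `beta_v` | radial sensitivity | 0 | <0 homogenizes speeds |
| `R` | interaction radius (box units) | 3 | inclusive threshold, ties included |
| `noise_std_theta` | per-step angular noise std | 0.01 | increment std, not a diffusion coefficient |
| `noise_std_v` | per-step speed noise std | 0 | |
| `epsilon` | friction proportionality | 0 | force `−ε(ρ_n − ρ̄)v_n` |
| `rho_bar` | global mean density | `N/L²` | filled at validation |
| `g_mode` | angular-noise modulation | `unit` | `inverse_speed` → `1/max(v, v_min)` |
| `dt` | integration step | 0.1 | "time steps" are integrator steps |
| `v_min` | speed floor for `g` | 0.01 | |
| `s1_clip` | polar-order clip | 1e-6 | bounds the log-potential divergence |

Noise figures quoted in scenario descriptions are interpreted as the
standard deviation of the per-step noise increment, so the equivalent
diffusion coefficient is `D = noise_std²/(2 dt)`.  This convention is a
package choice (captions in the source literature quote a dimensionless
std next to step counts); both the std and `dt` are config-exposed so
the alternative reading can be configured.

The scenario presets put `N = 1000` agents in an `L = 32` box (mean
density ≈ 1, so a radius-3 neighborhood holds ~28 agents — a
medium-range information-spread regime); the bacteria preset uses
`L = 16` so an 11-point density grid stays tractable on one CPU.  Box
size and density are free choices: the underlying study conditions do
not pin them down.

## Integration scheme

Euler–Maruyama with synchronous updates: all gradients, densities and
noise modulations are evaluated on the pre-step state, positions advance
with the pre-step heading and speed.  Per step, one `(N, 2)` block of
standard normals is drawn (agent-major, angular before speed noise), so
a (config, seed) pair reproduces bit-identical trajectories.  Speeds are
reflected at zero (`v ← |v|`), preserving the half-normal support
without biasing small speeds; headings are wrapped to `[0, 2π)`.

Degenerate inputs: an isolated agent has zero entropy gradients (its own
heading gives `S¹_loc = 1`, clipped); all-zero speeds are protected by a
`σ² ≥ 1e−12` floor; `ρ_n` counts the focal agent, so it is never zero.

### Stiffness of the logarithmic potential

Both entropies are logarithmic potentials and diverge as the
neighborhood becomes perfectly ordered (`S¹_loc → 1`) or perfectly still
(`σ² → 0`).  The `s1_clip` regularization bounds the angular gradient,
but within the bound the discrete update still overshoots once the
heading mismatch falls below `sqrt(2 |β_θ| dt / N_A)`: ordered states
therefore fluctuate at that discretization scale instead of converging
to a point, and a two-agent pair contracts monotonically only down to
`sqrt(2 |β_θ| dt)`.  Analogously, strong negative `β_v` drives the
neighborhood mean-square speed toward a scale set by `|β_v| dt / N_A`
where the per-step contraction factor crosses −1.  These scales are
properties of the explicit scheme at fixed `dt`; they shrink with `dt`.

## Observables

* Polar / nematic order `S¹, S²`: moduli of the first and second moments
  of `e^{iθ}`; bounded in [0, 1]; rotation invariant.
* Vorticity: agent velocities are averaged on a square grid (bin size a
  parameter, ≥ 3 bins per axis), `ω = ∂v_y/∂x − ∂v_x/∂y` by periodic
  central differences.  Empty bins are filled by iterative periodic
  nearest-neighbor averaging and masked; the fill avoids spurious curl
  at cluster edges, the mask keeps filled bins out of summary means.
  The "mean absolute vorticity" divides mean `|ω|` over occupied bins by
  the population mean speed — the "spatially normalized" convention was
  not pinned down by the source literature, so the normalization is a
  documented package choice and an unnormalized variant is exposed.
* Orientation histogram: circular binning (36 bins default), 3-bin
  circular smoothing, peaks are circular local maxima with prominence at
  least 10% of the maximum; fewer than two peaks flags unimodality.
* Rayleigh check: MLE scale `σ̂ = sqrt(mean(v²)/2)` plus a one-sample
  Kolmogorov–Smirnov test against `Rayleigh(σ̂)`.

## Fit machinery

For observables `j` (speed, vorticity) on a density grid,
`χ²_j = Σ_i ((Ô − O)/σ̂)²` with `Ô, σ̂` the ensemble prediction mean and
standard deviation; the reduced statistic divides by
`dof = observables × points` with no parameter-count correction.
Observation tables are plain CSV (`density, observable, value`) matched
to predictions by density with an absolute tolerance.  Since the
experimental dataset the scenario imitates is not redistributable, a
synthetic stand-in generator draws observations from the model's own
predictive distribution; fits against it calibrate the pipeline
(reduced χ² ≈ 1) but carry no empirical content.

## What the synthetic scenarios do and do not show

The presets emulate idealized study conditions: homogeneous parameters,
uniform random initial positions, uniform initial speeds on [0, scale],
isotropic initial headings (or a fixed common heading).  They contain no
steric exclusion, hydrodynamics, birth/death, or measurement noise, so
passing tests demonstrate internal consistency of the model and its
analysis chain — not agreement with any real migration data.  The
χ² stage accepts arbitrary user-supplied observation tables for that
purpose.

## Design choices made where the design was open

* Focal agent included in `S¹_loc` and `σ²` but excluded from the
  neighbor-mean sums `v̄`; this is the only combination under which the
  entropy extrema sit at `θ̄` and `θ̄ + π` while the gradients stay
  non-trivial.
* `ρ_n` counts the focal agent (a cell contributes to its own
  crowding); switchable at the call site.
* `g(v)` modulates only the angular noise, exactly as the dynamics is
  written.  The motivation given in the source literature for
  `g = 1/v` — a Rayleigh stationary speed distribution — concerns the
  speed equation; applied to the angular noise it does not reshape the
  speed marginal, and the simulated speed distributions at strong
  negative `β_v` are heavy-tailed rather than Rayleigh (see
  limitations).
* Pattern flags in regime maps use the threshold `3/sqrt(N)` (three
  times the finite-size noise floor of the order parameters) since
  "nonzero order" is never exact in a finite system.
* Ensemble seeds derive from `SeedSequence([master, counter])`, making
  ensembles reproducible and extensible without reusing streams.

## Known limitations

* First-order explicit integration only; no higher-order SDE scheme.
  The stationary fluctuation scales quoted above are `dt`-dependent.
* The global nematic order attainable in the anti-aligning regime is
  small at the shipped study conditions.  The locally balanced
  (maximum-entropy) heading configurations form a manifold degenerate
  with respect to the common axis, so the dynamics exerts no restoring
  force that selects a global axis; prepared global nematic states decay
  within ~10³ steps, and ensemble-mean `S²` stays below ~0.1 for all
  angular sensitivities and densities we scanned.  Consequently the
  orientation distribution in that regime is not reliably bimodal at the
  population level.
* Speed distributions under strong speed homogenization (`β_v ≪ 0`)
  exhibit intermittent bursts (a known artifact family of logarithmic
  potentials under explicit integration) and are not Rayleigh; mean
  speed is not monotone in density in the swarming preset.
* Entropies are parametric (wrapped Cauchy / half-normal only);
  non-parametric estimators are out of scope, as are 3D domains,
  non-periodic boundaries, heterogeneous per-agent parameters, and
  colored or Lévy noise.
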