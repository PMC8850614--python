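# Methods

## Model

`flocksir` simulates N self-propelled agents in a periodic square arena
of side L, coupled to a susceptible–infectious–recovered (SIR) contagion
living on the agents' proximity graph.

**Spatial dynamics.** Each agent i moves overdamped at constant
self-propulsion speed v0 along its heading n̂_i = (cos θ_i, sin θ_i),
displaced additionally by soft-core pair repulsion:

    dr_i/dt = v0 n̂_i + F_i,
    F_i     = Σ_{j∈S_i} ((r_int − |r_ji|)/r_int) · r_ji/|r_ji|,

with r_ji = r_i − r_j taken under the minimum-image convention and
S_i = { j ≠ i : |r_ji| ≤ r_int } the contact set (inclusive bound; the
same set defines alignment partners, repulsion partners, potential
infection routes, and cluster membership). Headings relax toward the
local mean heading on a timescale τ under angular white noise of
intensity σ:

    dθ_i/dt = (1/τ) ⟨ mod*(θ_j − θ_i) ⟩_{j∈S_i} + σ ξ_i,

where mod*(x) = mod(x+π, 2π) − π wraps angle differences into [−π, π)
and ⟨ξ_i(t)ξ_i(t')⟩ = δ(t−t'). An agent with no contacts keeps its
heading up to noise. The focal agent is excluded from S_i: including it
would only rescale the average (its own term is zero) while changing
the divisor, and exclusion is the convention under which "mean over
neighbors" is well defined; an empty average is defined as zero.

Two dimensionless groups locate the collective state: the Peclet number
Pe = v0/(r_int σ²) (persistence of individual motion against angular
diffusion) and the coupling strength g = 1/(τ σ²) (alignment against
noise). The package works at fixed v0 = 0.2, r_int = 1 and fixed packing
fraction N π r_int²/(4L²) = 0.3 by default, scanning (Pe, g) through σ
and τ.

**Contagion.** Each agent carries a label in {S, I, R}. Per epidemic
step of length Δt, a susceptible agent with k infected contacts is
infected with probability min(1, k β_b Δt) — independent pairwise
channels summed, the linearization of the continuous-time rate k β_b,
valid for k β_b Δt ≪ 1 (the step size is chosen to keep per-contact
probabilities ≤ 0.1; a "strained" counter records any violation of
that bound by multi-contact sums). Each infected agent recovers with
probability γΔt; R is absorbing. All transitions in a step are
evaluated against the pre-step labels and applied simultaneously, so
an agent infected in a step neither transmits nor recovers within it.
The epidemic parameters are usually given as the infection-lifetime
transmissibility Θ = β_b/γ and the mean infectious duration
T_inf = 1/γ.

## Numerical integration

* **Scheme.** Explicit Euler–Maruyama with synchronous updates: forces,
  alignment averages, and the contact graph are all evaluated on the
  pre-step state. The noise increment is σ√Δt·ξ with ξ ~ N(0,1) i.i.d.
* **Time step.** Default dt = min(0.1, τ/10, 0.02 r_int/v0): the first
  bound resolves the alignment relaxation (stiff at large g), the last
  keeps the deterministic displacement well below the interaction
  range. A configuration guard additionally requires
  (v0 + F_max) dt < r_int/2. The default was settled after checking
  during development that halving it leaves the stationary (Φ, Λ)
  behavior of the reference states unchanged within replicate scatter.
* **Epidemic subclock.** The contagion shares the spatial clock when
  the rates allow (γ dt ≤ 0.1 and β_b dt ≤ 0.1). When they do not
  (e.g. Θ = 2 at T_inf = 10⁻², where β_b = 200), the SIR transitions
  advance in n_sub equal substeps per spatial frame on that frame's
  contact graph, with n_sub chosen to restore the probability bounds.
  Positions move only v0·dt = 0.02 r_int per frame, so the graph is
  effectively constant across substeps; in the short-T_inf regime this
  is precisely the quasi-static-network limit. During development,
  same-clock runs (dt = dt_epi everywhere) were checked to agree with
  subclocked runs within replicate scatter; the test suite verifies
  exactly that the subclocked integrator is the faithful composition
  of the per-substep transition kernels.
* **Coincident agents.** The repulsion direction is undefined at zero
  separation; such a pair receives independent random unit kicks. This
  is a measure-zero fallback, never observed at the default packing.
* **Neighbor search.** Exact cell-list search (cells ≥ r_int wide,
  half-stencil sweep, periodic shifts precomputed per stencil
  direction), set-identical to the all-pairs scan; the cell count is
  capped at O(N) in dilute boxes. Connected components use union-find.
* **RNG streams.** Every run derives four named generators from one
  `SeedSequence` — spatial noise, infection draws, recovery draws,
  seeding — so a stored stationary state can be replayed under fresh
  epidemic randomness, and the spatial trajectory for a fixed spatial
  seed is bit-identical whatever the epidemic parameters. All derived
  seeds are recorded in the outputs.

## Observables and state classification

Polarization Φ = |Σ n̂_i|/N measures orientational order; clustering
Λ is the fraction of agents in the largest connected component of the
contact graph. A stationary run is classified from time-averaged
(Φ̄, Λ̄):

* D (disordered) if Φ̄ < Φ_c;
* OH (ordered homogeneous) if Φ̄ ≥ Φ_c and Λ̄ < Λ_c;
* otherwise OB (bands) or OC (clusters), split by the sign of the
  largest cluster's elongation relative to the mean heading: the
  gyration tensor of the cluster's minimum-image coordinates (unwrapped
  about the circular-mean center, well defined for arena-spanning
  structures) gives principal axes; a long axis within 45° of the mean
  heading is cluster-like (OC), perpendicular is band-like (OB).

Defaults Φ_c = 0.5, Λ_c = 0.2 sit in the wide gaps between regimes;
both are configuration-exposed because the underlying phase boundaries
are crossovers, not sharp lines.

Contact statistics treat a contact event as a maximal run of
consecutive frames in which a pair stays an edge; the mean event length
(× dt) is the contact duration, and event onsets per agent per time the
contact rate. These feed the mean-field baseline (below). Density
fields are histograms on an n×n grid smoothed with a periodic Gaussian
kernel (default width two bins); smoothing conserves mass to 1e−9.

## Burn-in protocol

Runs start from uniformly random positions and headings. The spatial
dynamics is integrated until the means of Φ and Λ over two consecutive
windows of W = 200 time units differ by less than ε = 0.05 each, with a
hard cap T_max = 5000 and a floor T_min = 1500. The floor is load-
bearing: slowly ordering states (e.g. Pe = 512, g = 16, where τ = 160)
pass the two-window test long before global order develops (Φ ≈ 0.04
at t = 400 on its way to ≈ 0.97), and the strongly coupled state
(32, 1024) crosses through a transient large-cluster phase that decays
by t ≈ 1500. A capped, unconverged run returns its state with a flag
rather than raising.

## Replicate protocol

For each parameter point: burn in `n_stationary_states` independent
spatial states, then run `n_outbreaks_per_state` outbreaks per state
with fresh epidemic streams, seeding 1% of agents uniformly at random
(localized seeding at the arena center is available for case studies).
The reported quantity is the mean and standard deviation of the final
recovered fraction ρ_R(∞) over the ensemble. Outbreaks hitting the
absorption time cap (default 50·T_inf + 5000 time units) are flagged
unfinished and excluded from means, with a count. The full-scale
protocol is 5 × 10 = 50 runs per point; the desk-scale checks in this
repository use 5 × 4 (final-size levels) and 3 × 4 (onset sweeps) at
N = 2500, keeping the packing fraction at 0.3 (L ≈ 80.9) — packing,
not agent count, controls the local contact structure. Problem sizes
were chosen so the whole acceptance computation completes on one CPU
in tens of minutes.

## Mean-field baseline

For the disordered state the package provides a homogeneous-mixing
baseline: an effective reproduction number
R0 = (β_b · mean contact duration) × (mean contact rate / γ) — the
linearized per-contact transmission probability times the contacts per
infectious period — inserted into the Kermack–McKendrick final-size
relation r∞ = 1 − s0 exp(−R0 r∞), solved by bracketed root-finding
(Brent, tolerance 1e−10; the largest root in [i0, 1] is taken, with an
explicit bracket restart at the supercritical double root). This is a
baseline, not a derivation from the microscopic dynamics: it is
documented as valid when β_b × contact duration ≪ 1 and mixing is
fast, and a warning fires outside that regime.

## What the desk-scale runs do and do not show

The N = 2500 simulations reproduce, at their scale: the disordered,
ordered-homogeneous, and ordered-clustered phenomenology of four of
the five reference (Pe, g) points; the near-0.8 final size of the
disordered state and the strongly reduced (≈ 0.3–0.4) final size of
the ordered homogeneous state at very high transmissibility; the
clustered state's large outbreaks at very short infectious duration;
and the advantage of the clustered state over homogeneous states at
intermediate transmissibility.

One known finite-size limitation: the band state at (Pe, g) = (32, 2).
At N = 2500 this parameter point orders in polarization but the dense
band does not condense — the largest-cluster fraction stays far below
the clustering threshold — so the desk-scale phenomenology checks at
that point fail by construction, and the band-state outbreak onset
behaves like that of a weakly polar ordered state rather than a banded
one. Development runs at larger N showed band-like structures forming
during ordering at these parameters, and neither halving the time step
nor switching the alignment-average convention changes the desk-scale
outcome, pointing to a system-size (and possibly simulation-horizon)
effect rather than an integration artifact. The relevant checks run at
N = 2500 anyway and report honestly.

## Degenerate inputs and edge cases

Zero noise (σ = 0) is allowed as the deterministic limit (Pe, g report
infinity); an isolated noise-free agent moves exactly ballistically.
`r_int ≥ L/2` is refused (minimum-image ambiguity). β_b = 0 yields a
final size exactly equal to the seed fraction. Pair distances exactly
at r_int count as contact. NaN positions abort the integrator with a
diagnostic rather than propagating.
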