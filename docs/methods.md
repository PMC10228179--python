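# Methods

## Physical model

A focused IR laser heats an aqueous colloid suspension inside a glass
capillary; the resulting temperature gradient drives thermophoretic
migration of the particles, read out as a fluorescence time course. The
package models the axisymmetric (r, z) half-plane around the beam axis:
a cylinder of radius 0.2 mm (the capillary bore) and axial half-length
0.2 mm with the laser focus at the origin.

**Heat source.** The deposited power density is a Gaussian transverse
profile times Beer–Lambert attenuation along the beam,

q(r,z) = A · exp(−r²/2σ²) · exp(−A_c (z + L)),

with σ = 2.5 µm (beam diameter 10 µm read as the 1/e² intensity diameter,
the usual laser convention; configurable), A_c = 0.50 cm⁻¹ and a lumped
capillary reflection R_c = 0.05. The prefactor A is fixed by requiring the
*discrete* volume integral on the active grid to equal the absorbed power
Q₀(1−R_c)(1−e^(−2 A_c L)) ≈ 0.94 mW at Q₀ = 0.05 W — normalising against
the grid quadrature rather than the analytic integral makes the energy
bookkeeping exact on any admissible grid.

**Heat transport.** Steady and transient conduction in water
(k = 0.60 W m⁻¹ K⁻¹, ρ = 998 kg m⁻³, c_p = 4182 J kg⁻¹ K⁻¹) with the
ambient temperature (default 293.15 K; only rises matter and the ambient is
configurable) clamped on the capillary wall and the axial domain ends. The
glass wall itself is not meshed; its optical effect is already lumped into
R_c and A_c, and its thermal resistance is absorbed into the Dirichlet
boundary. Convection is deliberately omitted: the thin-capillary MST
geometry was designed to suppress it. Discretisation is a node-centred
finite-volume scheme on a tensor grid (graded radial spacing, ≈0.6 µm at
the axis resolving the beam waist, coarsening to 15 µm at the wall; ≤10 µm
axially; ~1700 cells), with implicit Euler in time (Δt = 10 ms through the
establishment transient, 50 ms afterwards). The solve is direct (sparse
LU), with factorisations cached per step size. With the default
parameters the steady focal rise is ≈2.5 K and 99% of it is established
≈0.13 s after switch-on — comfortably inside the sub-second establishment
the instrument relies on. Peak rise and establishment time move by <2%
under 2× mesh refinement.

**Particle transport.** Concentration follows ∂c/∂t = −∇·J with
J = −D∇c − c D_T ∇T and D_T = D·S_T, starting from a uniform 1 mol m⁻³ and
with no-flux walls. The default D = 2.25 × 10⁻¹² m² s⁻¹ is the 200 nm
polystyrene value used for all library builds. Because heat establishes in
~0.1 s while mass transport evolves over the whole 20 s laser-on phase, the
coupling is one-way: the temperature field is interpolated per time step
and frozen there; the transport matrix is rebuilt only while the field is
still changing.

Face fluxes use Scharfetter–Gummel exponential fitting. The drift velocity
derives from the potential S_T·T, so the face Péclet number reduces to
−S_T·ΔT_face independently of D, and the discretisation reproduces the
Boltzmann stationary state c ∝ exp(−S_T (T − T_ref)) *exactly* at the
nodes, for any Péclet number, with no spurious oscillations or negative
concentrations. This is why the long-time solver field matches the
closed-form exponential to solver precision across S_T ∈ [−2, 2] K⁻¹, and
mass drifts by <10⁻¹⁴ relative over the cycle (the conservation form plus
direct solves). Implicit steps of 50 ms (first second) and 250 ms
(remainder) leave the end-of-cycle Conc(t) within ~3 × 10⁻⁶ relative of a
5× finer integration.

**Observable.** Conc(t) is the probe-region mean concentration normalised
to 1 at laser-on (the model's amplitude parameter absorbs any other
normalisation). Three probe reductions are provided: the 3-D disk
(diameter 130 µm × thickness 20 µm), the 2-D focal-plane circle (the
default fitting observable, diameter 130 µm), and a 1-D focal line
integral (65 µm). Disk and circle agree within a few percent of the
depletion depth because the axial temperature variation across the disk is
minor; the line integral weights the focus more strongly and shows the
characteristic fast-then-slow nonlinear decay most clearly.

## Curve library and interpolation

`build_conc_library` runs the solver once per S_T grid point (default
51 points over [−2.5, 2.5] K⁻¹, covering the measured colloid range with
headroom) on a shared time base. Libraries persist as a full-precision CSV
plus a JSON sidecar holding a SHA-256 provenance hash of the solver
settings; a cached library is reused only on an exact provenance match,
otherwise rebuilt with a warning. Off-grid curves are interpolated
linearly pointwise in S_T: the probe-averaged depletion is nearly linear
in S_T at these gradient strengths (measured interpolation error ~10⁻⁷ in
Conc, far below 0.5% of depletion depth at the default 0.1 K⁻¹ spacing),
and linear interpolation preserves the pointwise ordering between
bracketing curves.

## Two-stage fit

Stage 1 fits I = B + C e^{kt} to the free-fluorophore trace over the
laser-on window (time re-zeroed at switch-on) by Levenberg–Marquardt with
endpoint-heuristic initialisation (B from the tail mean, C from head−tail,
k from a log-ratio of two interior points). k is the *signed* exponent
coefficient — a decaying trace has k < 0 (the reference decay constant
used throughout examples is −0.22 s⁻¹). A constant trace returns C = 0
with a `decay-unidentifiable` flag instead of a spurious rate.

Stage 2 fixes k (averaged over fluorophore replicates — it is never refit
per particle trace) and evaluates, for every library S_T, the model
I = d0 + e0·e^{kt}·Conc(t; S_T), linear in (d0, e0) and solved in closed
form from the 2×2 normal equations. The S_T estimate is the SSE-profile
minimum refined by a parabola through the minimum and its neighbours and a
bounded scalar minimisation over interpolated curves within the bracketing
interval (xatol 10⁻⁷ K⁻¹). Noiseless round trips recover off-grid truths
to ~10⁻⁷ K⁻¹. Two failure modes are flagged rather than silently
reported: a minimum on the dictionary boundary (`range-limited`; no
extrapolation) and a thermophoretic signal below the noise floor
(`weakly-identified`, when |e0|·max|e^{kt}(Conc−1)| at the best fit is
under 3× the residual RMS plus an absolute floor). The latter captures the
regime where the fluorophore's own decay dominates the particle migration
and the extracted S_T scatters widely — there the mean is still reported,
carrying the flag.

Replicates aggregate as arithmetic mean ± sample SD (n−1 denominator, n
reported; SD is NaN for a single replicate).

## Synthetic traces

The generator emulates the canonical trace morphology: 5 s flat baseline,
20 s on-phase following the stage-1/stage-2 forward models exactly, and a
post-laser plateau (back-diffusion recovery is simulated by the PDE but
deliberately not modelled in the trace generator, since the fit uses only
the on-phase). Noise is additive Gaussian with SD given as a fraction of
the decay amplitude — adequate for the high count rates of the instrument;
shot-noise weighting is future work. Defaults: background 200, amplitude
800 counts, 301 samples over 30 s, noise off unless requested. Every
trace is bit-reproducible from its integer seed; replicate sets use
consecutive seeds.

What passing round trips on these traces demonstrate: the deconvolution
is an exact inverse of the forward model and its numerical pipeline is
unbiased at realistic signal scales. What they do not demonstrate: that
real instrument traces obey the lumped single-exponential fluorophore
model, that the probe region matches the instrument's actual optical
volume, or that D of the measured sample equals the library's D — those
remain assumptions of the method itself.

## Quality control

Aggregates transiting the detection volume produce sudden jumps
("bumpiness"). `qc_bumpiness` detrends with a rolling median (window 11)
and z-scores the residuals against a robust noise scale — the larger of
the residual MAD and the MAD of first differences (scaled by √2). The
two-scale floor matters: a smooth noiseless decay otherwise has a
vanishing scale and its laser-on corner would z-score as a spike. Samples
with |z| > 5 (default) count as spikes; any spike flags the trace. On
noisy synthetic traces the detector recovers injected 10σ jumps exactly
with no false positives over 50 seeds.

## Electrokinetics

Debye length λ = √(ε₀ε_r k_B T / 2 N_A e² I) with I in mol m⁻³ (so 1 mM of
a 1:1 salt ⇒ λ ≈ 9.6 nm at 298 K); buffer "ionic concentration" is taken
as the user-supplied ionic strength — no speciation model for borate/MES
equilibria is attempted. Charge from zeta uses the Debye–Hückel sphere
relation Q = 4πε₀ε_r R (1+κR) ζ, warning above |ζ| = 50 mV where the
linearisation degrades; σ is reported in e/µm². The double-layer scaling
S_T ∝ σ²λ is exposed only as a ratio between two conditions — the theory
fixes no absolute prefactor, so no absolute S_T is ever derived from it.

## Numerical choices and limitations

- Direct sparse LU throughout; the grids are small enough (~1.7k cells)
  that iterative solvers would add tolerance knobs without speed.
- Degenerate inputs refuse loudly: grids not resolving the beam waist,
  probe regions exceeding the domain, extrapolation outside the library,
  zero ionic strength, traces with fewer than 20 on-phase samples.
- Temperature-dependent water properties, convection, particle–particle
  interactions, concentration-dependent D or S_T, and thermoelectric
  (Seebeck) ion effects are out of scope; the last is the known physical
  mechanism behind sign changes between buffers and is discussed only
  qualitatively.
- The fit assumes the particle decay rate equals the fluorophore's; if the
  dye's environment differs on the particle surface this biases S_T, and
  no diagnostic in the package can detect it.
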