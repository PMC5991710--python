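# Methods

## Model

`sizespectra` simulates the dynamics of a marine community size spectrum —
the distribution of abundance n against individual body mass m on log–log
axes — with a size-structured matrix model. The model is a discretization of
the McKendrick–von Foerster equation on a geometric body-mass grid
m_{i+1} = δ·m_i with k classes: class 1 holds the background resources,
classes 2..k the consumers, with class 2 pinned to a marine fish egg mass of
1 mg. One Euler step updates the abundance vector by four independent,
individually mass-conserving increments:

    n(t+Δt) = n(t) + Δn^P + Δn^R + Δn^Q + Δn^U

* **Predation** (Δn^P). A predator of mass m_i searches γ·m_i^p m³/yr and
  eats prey weighted by an unnormalized lognormal kernel
  φ_{i,j} = exp(−(ln(β_i m_j/m_i))²/2σ²) around the preferred predator–prey
  mass ratio β_i = υ·m_i^τ (a type-I functional response). Assimilated
  biomass (fraction e) advances G_i = e·Σ_j m_j P_{i,j}/(m_{i+1}−m_i)
  individuals one class up ("growth diffusion": only part of a class moves
  per step); egesta (1−e) are recycled as class-1 resources; individuals
  growing out of class k die and their carrion returns as resources.
* **Reproduction** (Δn^R). Classes 3..k spawn at rate c·m^r; the female
  share α becomes eggs in class 2, the male share is recycled to class 1,
  and B_i = c·m_i^r·n_i/(m_i−m_{i−1}) parents drop one class from the mass
  spent.
* **Metabolism** (Δn^Q). Consumers pay v·m^q, recycled as resources, with
  the analogous down-transfer L_i. Resource metabolism recycles within
  class 1 and is omitted.
* **Mortality** (Δn^U). Non-predation mortality is density dependent:
  per-capita rate n_i·(μ₀/k_s)·m_i^{−(d−f)}, built from the allometric
  natural mortality μ₀·m^{−d} and a size-based carrying capacity k_s·m^{−f};
  fishing adds h_i. Carrion and catches are recycled to class 1.

Because every loss term reappears as class-1 resources (scaled by 1/m_1),
each increment satisfies mᵀ·Δn = 0 exactly; total biomass is conserved to
floating-point accumulation (observed drift over 40 years: ~1e−13 relative).

So that the smallest consumers see a full prey-size range, the kernel column
for class 1 aggregates an *imaginary* resource range of s+1 classes
(masses m_1·δ^{x−1}, x = −s..0, i.e. a resource spectrum of slope −1 below
the grid). Imaginary classes never carry abundance.

## Default parameters

| symbol | meaning | default | units |
|---|---|---|---|
| γ, p | searching rate factor/exponent | 600, 0.75 | m³ yr⁻¹ g⁻ᵖ, – |
| υ, τ, σ | preferred PPMR factor/exponent, kernel width | 100, 0, 1.3 | – |
| v, q | metabolic rate factor/exponent | 2.4, 0.75 | yr⁻¹ g^{1−q}, – |
| μ₀, d | non-predation mortality factor/exponent | 0.6, 0.25 | yr⁻¹ g⁻ᵈ, – |
| k_s, f | carrying-capacity factor/exponent | 0.0015, 1.15 | –, – |
| c, r | reproduction rate factor/exponent | 10, 0.75 | yr⁻¹ g^{1−r}, – |
| α, e | sex ratio, assimilation efficiency | 0.5, 0.6 | – |
| q₀ | catchability | 0.1 | – |
| Δt | Euler time step | 0.001 | yr |
| m₂, δ, k, s | egg mass, class ratio, class counts | 0.001 g, 1.5, 50, 37 |
| a₀ | initial biomass per class | 0.01 | g m⁻³ |

Derived constants: z₀ = μ₀/k_s = 400, z = d−f = −0.9. The default grid runs
from m₁ = 6.67×10⁻⁴ g to m₅₀ = 2.83×10⁵ g with the imaginary range reaching
down to 1.36×10⁻¹⁰ g; s = 37 is the unique step count whose ratio-1.5 ladder
reproduces both printed imaginary endpoints. m_{k+1} = m_k·δ continues the
geometric grid, which is also what makes the carrion-recycling entry conserve
mass exactly. The initial condition n_i = a₀/m_i gives every class the same
biomass (total 0.5 g m⁻³) and an exact −1 spectrum.

## Integration and numerical choices

The integrator is explicit forward Euler, exactly the scheme the update rule
defines; there is no adaptive stepping. Instead, each step checks that no
per-capita *transfer* probability exceeds one — the fraction of a class
growing up (G_i·Δt ≤ n_i), dropping down (B_i·Δt ≤ n_i, L_i·Δt ≤ n_i), or
dying (rate·Δt ≤ 1) — and raises a step-size error naming the violating
class. Aggregate predation pressure on the resource class legitimately
exceeds 1/Δt at the default settings (recycling inflows compensate within
the same step), so prey removal is not probability-checked; any genuine
removal overshoot surfaces as a negative abundance, which aborts the run
rather than being clamped — clamping would silently break the conservation
identity that anchors the test suite.

Stiff parameterizations need a smaller step, in line with keeping transfer
probabilities below one: c = 100 raises the egg-class down-transfer rate to
~1.5×10³ yr⁻¹ (we use Δt = 10⁻⁴ yr), and the c = 0.1 transient requires
Δt = 2×10⁻⁴ yr. Steady states are Δt-invariant (halving Δt changes the
reference steady spectrum by < 10⁻¹², and the c = 0.1 state by < 10⁻¹²).

Steady state is taken as the 40-year horizon, which the reference case
reaches with ample margin; `is_steady` additionally checks the per-year
relative change between the last two records (default tolerance 10⁻⁶ yr⁻¹).
The steady state is independent of the initial spectrum shape at fixed total
biomass. The cut-off case (c = 100) is integrated for 20 years, by which
point it satisfies the steadiness check at 10⁻⁴ yr⁻¹.

Constant-resource mode pins n₁ back to its initial value after each step —
the simplest reading of holding resource biomass constant. It deliberately
breaks mass balance; with μ₀ = 0 it sustains traveling waves where the
mass-balanced model settles into static waves.

## Analysis conventions

* **Spectrum fit:** ordinary least squares of log₁₀ n on log₁₀ m over all k
  classes by default (the published fit appears global); the class range is
  a parameter so the resource or egg class can be excluded.
* **Waves:** local extrema of the fit residuals with magnitude ≥ 0.05
  decades (the threshold that separates the flat reference case from the
  wave regimes); wavelengths are reported as peak–peak and trough–trough
  spacings in decades of body mass. In the low-c regime the egg class is
  itself a deep residual trough; that departure is a reproduction-boundary
  effect (the egg input collapses), not part of the predation cascade, so
  cascade-wavelength comparisons against the 2·log₁₀β bound should use the
  interior extrema.
* **Normalization:** abundance divided by the log₁₀ class width (a natural-
  log switch exists); this shifts the intercept, never the slope.
* **Yield:** Σ h_i n_i m_i in g m⁻³ yr⁻¹ per record; scenario comparisons
  use the final (steady) record, plus a trapezoid-integrated total.
* **Fishing scenarios:** unbalanced — constant h = q₀F₀ on classes heavier
  than 10⁴ g; balanced — h = q₀F₀·m^{−0.25} (proportional to natural
  productivity) above 10 g. Thresholds use strict inequality; no default
  grid mass equals either threshold, so the choice is inconsequential.

## What the simulations do and do not show

All experiments here are self-generated: the model is deterministic and
closed (no external data), so "synthetic data" means the simulated
trajectories themselves under the reference parameter table and its
published perturbations. Reproducing the linear spectrum (slope ≈ −1),
wave and cut-off regimes, and fishing contrasts shows internal consistency
of the discretization and its conservation structure — not calibration to
any real ecosystem. Known limitations: a type-I functional response (no
satiation); resources are a single recycled pool with no intrinsic growth;
no species identity, space, stochasticity, or seasonality; explicit Euler
requires the user to respect the transfer-probability bound.

One comparison does not reproduce the qualitative claim attached to it:
with steady-state biomass yield Σ h_i n_i m_i, balanced harvesting out-yields
threshold ("unbalanced") harvesting at F₀ = 30 and 50 yr⁻¹ but not at 5 and
10 yr⁻¹, where the density-dependent mortality buffers the lightly fished
stock and the unbalanced pattern's higher per-class rate wins. The
corresponding assertions are kept and fail honestly rather than being
weakened; the remaining fishing contrasts (progressively deeper cut-offs,
balanced spectra staying linear within 0.3 decades) reproduce as stated.
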