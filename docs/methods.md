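# Model and methods

## The signalling module

Early lung branching is driven by a small signalling circuit between the
epithelial bud and its surrounding mesenchyme.  FGF10 (`f`), secreted by
the distal mesenchyme, induces SHH (`s`) in the epithelium; SHH binds its
membrane receptor Patched-1 (`p`, "Ptc"), and — because SHH acts as a
multimer — one ligand effectively engages two receptors.  The SHH–Ptc
complex (`c`) feeds back twice: it represses FGF10 expression and induces
further Ptc expression.  Assuming the complex equilibrates fast
(quasi-steady state), `c = Γ s p²` with Γ an effective binding constant,
and the network closes into three reaction–diffusion equations for
dimensionless concentrations on the 2D bud cross-section:

```
∂f/∂t = ∇·(D_f ∇f) + 1_mes · ν_f / (1 + c²)        − δ_f f
∂s/∂t = ∇·(D_s ∇s) + 1_epi · ν_s f²/(K_s² + f²)    − δ_s s − δ_c c
∂p/∂t = ∇·(D_p ∇p) + 1_mes · (ρ0 + ρ1 c)           − δ_p p − 2 δ_c c
```

Production is compartment-gated (`1_mes`, `1_epi` indicators): FGF10 and
Ptc are produced in the mesenchyme, SHH in the epithelium.  The δ_c·c
terms are the net binding fluxes at quasi-equilibrium (one SHH and two Ptc
consumed per complex turned over).  In the cavities (lumen, interstitial
space) the ligands diffuse fast (`D_cav`) and only decay; the membrane
receptor has no degrees of freedom there.  Lengths are in units of the
lumen radius `rc`, FGF10 in units of its repression Hill constant, and
SHH/Ptc scaled so that Γ is the single binding parameter.

With FGF10 frozen at a constant value (the mesenchyme-free culture limit)
the SHH/Ptc block decouples and, after rescaling `u = λp`, `v = μs`,
`τ = δ_p t`, becomes the classical Schnakenberg activator–substrate
system `u_τ = a − u + u²v`, `v_τ = b − u²v` (activator Ptc, substrate
SHH), which anchors the linear stability analysis with a closed-form
oracle.

The full four-species variant keeps the complex explicit
(`ċ = k_on s p² − (k_off + δ_c) c`, no diffusion) and is used to verify
that the quasi-steady-state reduction does not change the predicted
pattern class when the binding constants are of order one.

## Geometry

The bud is an axial slice of a cylinder: a stadium-shaped domain built
from four nested compartments around the stalk axis — lumen (radius
`rc = 1`), epithelium (thickness `we = 0.2`), mesenchyme (outer radius
`Rc = 2`) and interstitial space extending to a far-field buffer.  The
stalk has length `h`; the tip is a semicircular cap.  The dimensional
anchors are `L = rc = 50 µm` and `T = 1000 s` (fixed by matching the
dimensionless Ptc diffusivity 0.02 to its dimensional estimate
0.05 µm²/s), under which the dimensionless diffusivities (5, 1, 0.02, 40)
map to 12.5, 2.5, 0.05 and 100 µm²/s and the two growth speeds used below
map to 14 and 3.6 µm/h.

Open-boundary runs embed the tissue in a buffer of width
`sqrt(D_cav · t_max)` — the diffusion length over the run horizon — with
the bulk value (zero) imposed on its outer rim; the class of the computed
pattern is insensitive to widening this buffer.  Closed-boundary
(`no_flux`) runs end the domain at the mesenchyme and compensate the
missing leak by rescaling production and decay (×0.5 / ×1.7 for the
lateral protocol, ×0.7 / ×1.5 for the bifurcation protocol).

Robustness deformations scale the tip epithelial radius (+25%), the tip
mesenchymal radius (+10%) — blended smoothly over one length unit below
the shoulder — or truncate the stalk by 80%.

## Parameter provenance and calibration

The kinetic point is pinned to the reported dimensionless value multiset
{D_f = 5 (tissue) / 40 (cavities), D_s = 1/40, D_p = 0.02, ν_f = 5,
ν_s = 1600, and the rates {1.6, 0.2, 1, 5, 3.5, 0.6}}; the assignment of
the six rate values to individual constants is underdetermined in the
available material.  The package fixes one canonical assignment, chosen
by calibration under the constraints that (i) the SHH/Ptc block retains net receptor autocatalysis
(ρ1 > 2 δ_c), (ii) the reference simulation reproduces the lateral
branching pattern and a single documented fold-change produces the
bifurcation pattern, and (iii) the growing-domain protocol reproduces the
fast/slow branching-mode selection.  The calibrated assignment, frozen in
`params.py` and `data/reference.yaml`, is

    δ_f = 5, δ_s = 0.2, δ_c = 1.0, δ_p = 0.6, ρ0 = 1.6, ρ1 = 3.5,

with Hill coefficient n = 2, stoichiometry c = Γ s p² (n_S = 1, m_P = 2),
K_s = 1, and the effective binding constant Γ — a free scale the
non-dimensionalisation leaves open — calibrated once (see
`reference.yaml`).  FGF10 then turns over fast relative to SHH, making
the FGF10 field a sharp read-out of the receptor pattern, and the SHH
substrate is long-lived, as the Schnakenberg limit requires.

## Numerics

Space: linear (P1) finite elements on a boundary-fitted triangular mesh
that follows the stadium-annulus structure of the geometry, with level
curves placed exactly on compartment interfaces (every element carries one
subdomain label; labelled areas converge to the closed forms at
O(hmax²)).  Radial resolution is `hmax` through the tissue and coarsens
geometrically through the buffer.  Production/decay terms are gated by
per-node lumped compartment masses; diffusion is per-element, with zero
Ptc diffusivity in cavities and pure-cavity Ptc nodes pinned to zero.

Time: backward Euler with modified-Newton iterations (analytic coupled
Jacobian, LU factorisation reused across iterations and steps, refreshed
on stall), linear extrapolation as predictor, and step doubling/backoff.
Steady state is declared when the max-norm rate of change falls below
1e−6 per unit time.  All runs start from zero concentrations plus a
seeded 1e−6 perturbation of mesenchymal FGF10 — Turing pattern selection
from uniform data needs a symmetry-breaking seed, and making it explicit
keeps every run bit-reproducible.

Growth: the stalk elongates axially in three modes — uniform exponential
stretching (h = h0·e^{μt}), tip-localised insertion (constant elongation
speed, material created in a zone of depth 1 below the cap), and graded
growth (stalk and tip zone growing at a prescribed rate ratio).  The mesh
moves with the material (arbitrary Lagrangian–Eulerian on the parametric
mesh); the discrete update `M(t₁)c₁ − M(t₀)c₀ = Δt·(−K c₁ − A(w) c₁ + R)`
with the relative-velocity transport operator A conserves ∫c exactly
under pure growth, as the advection–dilution form requires.  When
accumulated stretch exceeds 1.5× the built resolution the stalk is
remeshed and fields (and any noise fields) transfer by interpolation in
the parametric coordinates.

## Phenotyping

FGF10 fields are reduced to spots (mesh-local maxima in the mesenchyme
above a relative threshold θ_rel = 0.3 of the global maximum, merged
within r_merge = 0.3) and classified:

* elongation — a tip maximum only;
* lateral — tip maximum plus flank maxima (domain branching);
* bifurcation — shoulder maxima without a tip maximum;
* none — no maxima near the tip.

The tip zone is the apex cone of half-angle 30° on the cap plus a 0.25
axial margin — a cone rather than the whole cap, because side-of-tip
maxima, the defining feature of the bifurcation class, lie on the cap
itself in this geometry.  Branch spacings are
measured per flank (left/right staggering would otherwise halve the
wavelength), and growing-domain branch events are new spots persisting
beyond a 5%-of-run debounce window, tracked across snapshots.
Classification is invariant to uniform rescaling of the field and stable
from hmax = 0.2 to 0.1; acceptance-grade classifications hold for
θ_rel ∈ {0.2, 0.3, 0.4}.

## Study protocols

* Steady-state reference: stalk length h0 = 6 (the source leaves the
  reference stalk length unreadable; on the longer stalk the reference
  point shows the full lateral phenotype — tip maximum plus flank maxima
  — robustly), open far field, t_max = 400.
* Growth runs: h0 = 2, tip-localised growth at 14 µm/h (0.078
  dimensionless; the bifurcation protocol is the ~4-fold slower
  3.6 µm/h), compared at a fixed simulated time of 51.5 units (the window
  in which the fast protocol elongates by four length units).
* Sensitivity: one-at-a-time multiplicative perturbations of all twelve
  kinetic/transport parameters around the reference, classified per
  point; non-steady runs are flagged, not dropped.
* Spatial noise: every kinetic parameter multiplied by (1 + ξ(x)), ξ an
  independent zero-mean Gaussian field per parameter with standard
  deviation sd ("half width" read as standard deviation) and correlation
  length 0.1 (one cell diameter; nodal white noise would be
  mesh-dependent), clipped so factors stay ≥ 0.05; ten seeded replicates
  per sd on the growing-domain lateral protocol.
* Mutants: ν_f × 0.75, D_s × {2, 6}, Ptc production scaled up, and the
  ν_s series; Ptc onset is the first time mesenchymal Ptc exceeds twice
  its basal level ρ0/δ_p.
* Mesenchyme-free culture: FGF10 clamped uniform (no production, no
  decay) on a closed, tissue-only domain with both production terms
  active everywhere; patterning is read from the Ptc field and
  cross-checked against the Schnakenberg dispersion verdict.

## What the synthetic inputs do and do not capture

All inputs are generated: the idealised geometry, its deformations, and
synthetic fields with planted maxima for testing the phenotype extraction.
The geometry is a smooth two-compartment idealisation — no cellular
granularity, no mechanics, no 3D effects (planar and orthogonal
bifurcations are indistinguishable in a slice), and growth is prescribed
rather than chemotactically coupled to FGF10.  Passing tests therefore
certify the signalling-and-transport mechanism on the idealised domain,
not a quantitative embryo model.

## Known limitations

* The symbol-to-value assignment of the kinetic table and the value of Γ
  are calibrated, not transcribed; other assignments may reproduce subsets
  of the published phenomenology differently (the calibration scan is the
  package's own, documented above).
* At the calibrated reference the *spatially homogeneous* surrogate (all
  production terms active in one well-mixed tissue) is linearly stable:
  the patterning instability on the bud requires the epithelium/
  mesenchyme source separation, i.e. it is geometry-mediated rather than
  a textbook homogeneous Turing band at this point.  The
  diffusion-driven character of the mechanism is certified instead on
  the uncoupled SHH–Ptc (Schnakenberg) block and at the
  surrogate-unstable parameter region (see `turing.py` tests); the
  homogeneous certificate at the reference multiset holds only for
  substantially smaller Γ, where the bud-domain pattern degenerates to a
  tip-only state.
* The growing-domain mode selection is reproduced qualitatively — fast
  growth locks a maximum at the advancing tip, sufficiently slow growth
  loses it (bifurcation mode) — but the measured flip sits near a
  16-fold rather than the published 4-fold speed reduction: the
  dilution of the SHH–Ptc complex by fresh tip material ("tip rescue")
  persists to slower speeds in this implementation.  Relatedly, at the
  fast speed the tip pattern complex (tip plus shoulder maxima) largely
  travels with the tip instead of depositing flank maxima behind it, so
  the branch-event rate on the growing domain (~1 new site per day) is
  below the reported two per day, even though the inter-site spacing
  (~240 µm) is in the reported range.
* The ±20% one-at-a-time robustness holds only for a minority of
  parameters at the strict class level: most switches are
  lateral↔elongation flips — gain or loss of one flank maximum on the
  four-spot reference pattern — rather than regime changes, and both
  candidate receptor-degradation rates (δ_p, δ_c) can produce the
  bifurcation class within a 2-fold scan.  Tip-radius deformations
  (epithelium +25%, mesenchyme +10%) likewise flip the marginal tip
  maximum to the bifurcation state.
* At the calibrated Γ the frozen-FGF10 (mesenchyme-free culture) system
  is linearly stable at every FGF10 level; culture patterning, and its
  agreement with the reduced dispersion relation, is demonstrated in the
  weak-binding regime (Γ = 0.003) instead.
* Centred-Galerkin transport on the growing domain is not strictly
  monotone; small overshoots (<1%) occur where the dilution-rate field is
  discontinuous (stalk–cap junction).
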