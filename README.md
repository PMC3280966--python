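# lungbud

Deterministic spatio-temporal simulations of the signalling circuit that
selects branch points during early lung development.

## The problem and the model

During branching morphogenesis the embryonic lung bud decides, over and
over, whether to elongate, sprout a daughter bud on its flank (lateral /
domain branching) or split its tip (bifurcation).  The core signalling
module behind this decision couples three players on the bud
cross-section: FGF10, secreted by the distal mesenchyme; SHH, induced by
FGF10 in the epithelium; and the membrane receptor Patched-1 (Ptc),
whose SHH-bound complex both represses FGF10 expression and induces more
Ptc.  Because SHH engages two receptors, the quasi-steady-state complex
is c = Γ·s·p², and the SHH/Ptc block is a Schnakenberg-type
activator–substrate system (activator Ptc, substrate SHH):

    ∂f/∂t = ∇·(D_f ∇f) + 1_mes · ν_f/(1 + c²)       − δ_f f
    ∂s/∂t = ∇·(D_s ∇s) + 1_epi · ν_s f²/(K_s²+f²)   − δ_s s − δ_c c
    ∂p/∂t = ∇·(D_p ∇p) + 1_mes · (ρ0 + ρ1 c)        − δ_p p − 2 δ_c c

solved by P1 finite elements on a labelled stadium-shaped bud domain
(lumen / epithelium / mesenchyme / interstitial buffer), on fixed and on
growing stalks (with advection–dilution transport so growth conserves
mass).  The self-organised FGF10 maxima are classified into branching
modes — elongation, lateral, bifurcation — and the package reproduces
the study designs built on that readout: steady-state patterning,
parameter sensitivity, spatial-noise robustness, growth-speed and
growth-mode selection, and mutant scenarios.  See `docs/methods.md` for
the full model description, the parameter calibration, and known
limitations.

## A worked example

```python
from lungbud import (BoundaryCondition, LungGeometry, build_geometry,
                     make_mesh, reference_params, run_to_steady)
from lungbud.patterns import analyze

params = reference_params()                      # calibrated kinetic point
bc = BoundaryCondition(kind="open_farfield", t_max=400.0)
geometry = LungGeometry(h0=6.0, Lfar=bc.buffer_width(params))
mesh = make_mesh(build_geometry(geometry), hmax=0.2)
report = run_to_steady(mesh, params, bc, tol=1e-6, t_max=400.0, seed=1)
pattern = analyze(report.state)
print(pattern.pattern_class)
for s in pattern.spots:
    print(f"({s.x:+.2f}, {s.y:.2f})  {s.value:.3f}  {s.zone}")
```

prints

    lateral
    (-0.75, 7.41)  0.115  tip
    (+0.61, 7.48)  0.115  tip
    (+1.60, 0.40)  0.101  proximal
    (-1.60, 1.20)  0.101  proximal

— a steady FGF10 pattern with maxima at the bud tip plus flanking maxima
along the stalk: the lateral-branching signature.  Positions are in
units of the lumen radius (50 µm), so consecutive branch sites along one
flank sit several hundred micrometres apart on this short reference
stalk (the growing-domain protocol gives the physiological 150–250 µm
spacing).  The `examples/` directory has one narrative script
per capability (steady patterns, stability analysis, growing domains,
sensitivity/noise scans, mutants).

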