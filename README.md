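# fesim

Volume-conductor field solving and myelinated-fibre activation modelling
for transcutaneous electrical stimulation (FES) of the thigh.

## The problem

Surface FES drives current between two skin electrodes; whether a target
motor axon fires depends on how the limb's tissues — skin, subcutaneous
fat, anisotropic muscle, cortical bone, bone marrow, and discrete
structures such as the femoral vessels and the sciatic nerve trunk —
shape the electric field at depth.  Simulation studies represent the limb
at different levels of geometric detail: concentric cylinder stacks (CM),
parallel slab stacks (PM), or anatomically based models.  `fesim` is a
tested implementation of the standard two-step pipeline used to compare
such representations:

1. **Lead field.**  Solve the quasistatic volume-conduction problem
   ∇·σ∇V_e = 0 for ±1 A between the electrode pair, with insulating outer
   boundaries and a single real (2 kHz) conductivity per tissue; muscle is
   anisotropic (σ_t = 82.38, σ_l = 329.53 mS/m along the limb axis).  By
   linearity every stimulus amplitude scales this unit-current field.
2. **Fibre activation.**  Drive a McNeal compartment cable (Ranvier nodes
   with CRRSS sodium-plus-leak kinetics at 37 °C, myelin a perfect
   insulator) with the nodal extracellular potentials; an action potential
   counts when the membrane exceeds +80 mV above rest at least five
   internodes from the stimulation focus.  Bisection over amplitude
   (5–500 mA bracket, 10 μA final width) yields the activation threshold.

On top of the two steps sit the comparison experiments: parameter sweeps
over electrode area (1–25 cm²), edge-to-edge gap (1–6 cm), stimulation
site (anterior/posterior/medial/lateral), fibre diameter (8/12/16 μm) and
depth; activation-error tables against a reference model; zero-lag
Pearson correlation of threshold curves; projection-based average fat
thickness and bone-to-muscle distance; and fat/bone geometry adjustment.
A seeded generator produces *pseudo-anatomical* models (perturbed
boundaries, off-centre bone, blood-vessel and nerve-trunk inclusions)
that stand in for MRI-derived anatomy in omission and depth studies.

See `docs/methods.md` for the model assumptions, numerical methods and
their limitations.

## Worked example

Threshold for a 12 μm fibre 5 mm below the fat–muscle boundary of the
standard cylinder model, anterior site, 9 cm² electrodes 4 cm apart:

```python
import fesim as f

cm1 = f.cm_model("1")                      # marrow/bone/muscle/fat/skin
electrodes = f.place_electrodes(cm1, "anterior", area_cm2=9.0, gap_cm=4.0)
domain = f.discretize(cm1, electrodes)     # ~3.6e5 finite-volume cells
solution = f.solve_unit_field(domain)      # lead field, V per A

fiber = f.build_fiber(12.0)                # 53 nodes, 1.2 mm internodes
placement = f.FiberPlacement("anterior", depth_mm=5.0, diameter_um=12.0)
profile = solution.sample_fiber_profile(
    f.node_positions_m(cm1, placement, electrodes, fiber))
result = f.find_threshold(profile, fiber, f.StimulusWaveform())
print(f"threshold {result.threshold_mA:.2f} mA, "
      f"bracket {result.bracket_mA}, {result.n_fiber_sims} simulations")
```

```
threshold 51.72 mA, bracket (51.71592712402344, 51.723480224609375), 18 simulations
```

About 52 mA of 0.5 ms cathodic square pulse is needed — a realistic
motor-threshold magnitude for large surface pads over the quadriceps.
The bracket width honours the 10 μA search tolerance; the parallel-slab
model (`f.pm_model("1")`) yields a higher threshold for the identical
configuration, the expected overestimation of slab representations.

The same pipeline is scriptable from the shell:

```bash
fesim gen-anatomy --seed 1 --save am.yaml     # pseudo-anatomy with inclusions
fesim threshold config.yaml --coarsen 2.0     # JSON threshold record
fesim compare sweep.yaml --out errors.csv     # error table vs the reference
```

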