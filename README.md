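# innatesim

Spatio-temporal simulation of the innate immune response to a localized
lipopolysaccharide (LPS) injection in a one-dimensional strip of
vascularized tissue.

LPS, the endotoxin of the Gram-negative bacterial wall, triggers acute
inflammation: tissue-resident macrophages recognize it and hyperactivate,
pro-inflammatory cytokines raise the permeability of the local endothelium,
neutrophils and then monocytes extravasate from the blood, phagocytose the
endotoxin, undergo apoptosis and are cleared by macrophages, while
anti-inflammatory cytokines wind the response down.  `innatesim` models
this as eight coupled reaction–diffusion–chemotaxis equations for the
tissue concentrations of LPS, resting macrophages (RM), hyperactivated
macrophages (AM), pro-inflammatory cytokines (CH), neutrophils (N),
apoptotic neutrophils (ND), neutrophil protein granules (G) and
anti-inflammatory cytokines (AC).

The tissue is *homogenized* ("two-domain"): every point exchanges
leukocytes with an overlying vascular compartment through an endothelium
whose permeability is a Hill function of the local stimulus, e.g. for
neutrophils

```
source_N = [ (P_N^max − P_N^min) · CH/(CH + keq_ch) + P_N^min ] · (N^max − N),
```

and for monocytes the sum of a CH-driven and a granule-driven channel.  A
representative balance law (neutrophils) reads

```
∂N/∂t = −μ_N N − λ_LPS|N · LPS · N + D_N ΔN + source_N − ∇·(χ_N N ∇CH),
```

with zero-flux Neumann boundaries on every species.  The full system and
every default parameter are documented in
[`docs/methods.md`](docs/methods.md).

The package ships a five-scenario ablation ladder (Case 1: macrophages
only → Case 5: full model) used to dissect which cell populations drive
which feature of the response, and a grid/time-step refinement study that
verifies the first-order accuracy of the discretization (explicit Euler in
time; central diffusion and conservative upwind chemotaxis in space).

## Worked example

```python
import innatesim as im

p = im.default_parameters()
grid = im.Grid.from_spacing(5.0, 0.1)           # 5 mm strip, dx = 0.1 mm
flags = im.ScenarioFlags.from_case(5)           # full model
times = [i * 0.01 for i in range(501)]          # record every 0.01 day
traj = im.simulate(p, flags, grid, dt=1e-5, t_final=5.0, output_times=times)

tot = traj.totals
print(f"initial LPS load: {tot['lps'].iloc[0]:.1f} conc*mm")
print(f"LPS remaining at day 5: {tot['lps'].iloc[-1]:.4f} conc*mm")
print(f"total CH peaks at {24 * im.peak_time(tot['time'], tot['ch']):.2f} h "
      f"(peak value {tot['ch'].max():.3f} conc*mm)")
print(f"total AM peaks at {24 * im.peak_time(tot['time'], tot['am']):.2f} h "
      f"(peak value {tot['am'].max():.3f} conc*mm)")

report = im.convergence_study("time", t_final=0.25)
print(report.summary())
```

prints

```
initial LPS load: 95.0 conc*mm
LPS remaining at day 5: 0.0194 conc*mm
total CH peaks at 4.32 h (peak value 2.848 conc*mm)
total AM peaks at 36.48 h (peak value 1.662 conc*mm)
time-refinement study (reference dt=1e-06 day, dx=0.1 mm)
  dt=4e-06 dx=0.1: L2 error = 0.000228126
  dt=8e-06 dx=0.1: L2 error = 0.000532302
  error ratio (aggregate) = 2.333
  ...
```

Reading: of the 95 conc·mm of injected endotoxin (concentrations in model
units of 10⁴ cells/mm³, integrated over the strip), essentially all is
cleared within five days.  The pro-inflammatory burst peaks a few hours in
— a broad plateau driven by the neutrophil influx — and macrophage
hyperactivation peaks once the endotoxin level has fallen enough for decay
to outpace activation.  Halving the time step roughly halves the error
against a refined reference (ratio ≈ 7/3 against a dt = 1e-6 day
reference), confirming first-order temporal accuracy.

The same studies are available from the shell:

```
innatesim run --t-final 5 --out out/          # snapshot + totals TSV files
innatesim convergence --axis time             # refinement study with ratios
innatesim compare-cases                       # Cases 1–5 + ordering checks
```

`innatesim compare-cases` reruns the ablation ladder and reports the
qualitative findings it checks, e.g. that neutrophils (Case 3) accelerate
LPS clearance and amplify the cytokine burst, and that the
anti-inflammatory arm (Case 5) damps neutrophil influx and macrophage
activation relative to Case 4.

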