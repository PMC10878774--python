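# ectsim

Simulation of membrane electroporation and small-molecule uptake for
electrochemotherapy (ECT) pulse protocols, with the analysis pipeline for
comparing predicted cisplatin uptake against ICP-MS and clonogenic-survival
measurements.

In ECT a chemotherapeutic such as cisplatin, which crosses intact membranes
poorly, is driven into tumor cells by short high-intensity electric pulses
that transiently permeabilize the membrane. Different pulse shapes —
conventional 8 × 100 μs monopolar pulses, bursts of microsecond bipolar
pulses (less pain and muscle contraction), millisecond pulses (compatible
with gene electrotransfer), nanosecond pulses — turn out to be equivalent in
drug delivery once the field strength is adjusted per protocol. `ectsim`
implements the phenomenological cell-scale model that makes this
quantitative: given any rectangular pulse train it predicts the number of
drug molecules internalized per cell.

## The model

A spherical cell in a uniform field is an RC circuit whose membrane develops
conductive defects in two stages: a first porous state *N* permeable to
small ions, and an expanded state *M* permeable to small molecules. With
normalized time τ = *t*/τ<sub>RC</sub> and normalized transmembrane voltage
*U*:

    dU/dτ = I_s − U (1 + γ(N + M))
    dN/dτ = α U² − δ U² N − β N + η M
    dM/dτ = δ U² N − η M
    dX/dτ = ξ M (1 − X)

where the dimensionless source current
I<sub>s</sub> = τ<sub>RC</sub> σ<sub>ext</sub> h E₀ / (U₀ ε<sub>m</sub>)
is proportional to the applied field E₀, and *X* ∈ [0, 1] is the
intracellular solute concentration normalized by the extracellular one
(diffusive transport only, so *X* can never exceed 1). The permeability
coefficient ξ = 3 H(λ<sub>m</sub>) D τ<sub>RC</sub> / (r h) uses the Renkin
hindrance factor H for a solute of radius ρ<sub>s</sub> in a defect of
radius ρ<sub>d</sub>. The molecule count per cell at readout is
N = X·X<sub>e</sub>·(4/3)πr³·N<sub>A</sub>.

Pulses act on the microsecond scale but uptake is read out 25 minutes later
(~10⁹ τ units); the integrator therefore treats active segments with a stiff
ODE solver and long field-free intervals with the exact linear-relaxation
solution, which agrees with end-to-end numeric integration to ~10⁻⁸
relative. See `docs/methods.md` for parameters, numerics and assumptions.

## Worked example

```python
from ectsim import ModelParameters, run_protocol_grid, grid_to_frame, PRESETS

records = run_protocol_grid(PRESETS, concentrations_uM=(50.0,), p=ModelParameters())
print(grid_to_frame(records)[["protocol_name", "X_final", "molecules"]])
```

prints (molecules per cell at 50 μM extracellular cisplatin, 25 min after
the train):

```
  protocol_name   X_final     molecules
0      hf_50x50  0.999985  5.320922e+07
1  mono_8x100us  0.767630  4.084558e+07
2    mono_8x5ms  0.999497  5.318326e+07
3      ns_1x200  0.125919  6.700154e+06
4     ns_25x400  0.300457  1.598731e+07
```

The diffusion ceiling at 50 μM is 5.32 × 10⁷ molecules (full equilibration);
the millisecond and high-frequency protocols effectively saturate it, the
conventional protocol reaches ~77%, and the nanosecond protocols stay an
order of magnitude lower — all within the 10⁶–10⁸ range observed
experimentally. The `examples/` scripts walk through waveform construction
(`01_pulse_waveforms.py`), these predictions (`02_predict_uptake.py`) and a
full synthetic measure-and-compare experiment (`03_synthetic_experiment.py`).

A thin CLI exposes the same pipeline for shell use:

```sh
ectsim simulate --protocol mono_8x100us --out run/
ectsim synth --config examples/config.yaml --out synth/
ectsim compare --model-grid synth/model_grid.csv \
               --measurements synth/uptake_measurements.csv --out cmp/
ectsim report --comparison cmp/comparison.csv
```

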