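# Methods

## Model

`ectsim` implements a phenomenological, whole-cell (non-spatial) model of
membrane electroporation and diffusive solute transport. The membrane is an
RC element charged by a dimensionless source current
I_s = τ_RC σ_ext h E₀ / (U₀ ε_m), linear in the applied field E₀. Pore
formation is a two-state process: the transmembrane voltage U (normalized by
the threshold U₀) creates a first defect population N permeable to small
ions; N-defects expand into a second population M permeable to small
molecules. Both populations feed back on U through the permeabilized
conductance γ(N+M). Transport of the tracked solute (cisplatin) is purely
diffusive through M, so the normalized intracellular concentration X obeys
dX/dτ = ξM(1−X) and is bounded by 1 — electrophoresis is deliberately
neglected, an assumption that holds best for weakly charged solutes.

Interpretation note: U is treated as the induced transmembrane voltage
*normalized by U₀*, which is what makes I_s and the relaxation term
dimensionless and consistent.

Initial condition: U = N = M = X = 0 (intact membrane). Readout: X at
`t_end` = 25 min after the **end** of the pulse train by default
(`SolverConfig.t_end_reference` can switch to train-start reference). The
reference matters because M relaxes on a ~1/η ≈ 2.5×10⁸ τ ≈ 250 s scale, so
a 50-s-long burst protocol read 25 min after train *start* would lose a few
percent of its late uptake. The molecule count per cell is
X · X_e · (4/3)πr³ · N_A.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| U₀ | electroporation threshold voltage | 258 | mV |
| h | membrane thickness | 5 | nm |
| r | cell radius | 7.5 | μm |
| τ_RC | membrane charging time constant | 1 | μs |
| ε_m | membrane permittivity | 12 × 8.85e−12 | F/m |
| ρ_s | solute (cisplatin) radius | 0.58 | nm |
| ρ_d | membrane defect radius | 0.8 | nm |
| λ_m | ρ_s/ρ_d | 0.7250 | — |
| D | cisplatin diffusivity | 1.670e−9 | m²/s |
| α | N formation rate | 2e−6 | 1/τ |
| β | N relaxation rate | 4e−8 | 1/τ |
| γ | relative permeabilized conductance | 1e6 | — |
| δ | M formation rate | 1e−3 | 1/τ |
| η | M relaxation rate | 4e−9 | 1/τ |
| ξ | permeability coefficient | 8.45e−4 | 1/τ |
| σ_ext | medium conductivity | 1.4 | S/m |

The kinetic constants are literature values calibrated on quantitative
propidium-iodide uptake in CHO cells; the solute-specific entries (ρ_s, D,
ξ) are adapted to cisplatin and σ_ext to DMEM. The same σ_ext is assumed for
all five preset protocols, including the nanosecond ones.

**ξ discrepancy.** Recomputing ξ = 3 H(λ_m) D τ_RC/(r h) with the standard
Renkin polynomial H(λ) = (1−λ)²(1 − 2.104λ + 2.09λ³ − 0.95λ⁵) gives
8.16e−4, ~3.5% below the adopted constant 8.45e−4 (the Renkin variant or
rounding behind the adopted value is not documented). The default
`ModelParameters.xi` is the adopted constant; `permeability_coefficient()`
exposes the first-principles value, and neither is silently substituted for
the other. The difference propagates sub-percent into saturated protocols
and ~3% into unsaturated ones.

## Pulse-train representation

Protocols are ordered lists of (duration, signed field) segments starting at
t = 0, with explicit zero-field gaps; field lookup uses half-open
[start, end) intervals. Monopolar trains place pulse starts 1/f apart and
drop the trailing gap. The high-frequency bipolar unit is +phase /
interphase gap / −phase / interpulse gap (2/2/2/2 μs by default); burst
starts are likewise spaced start-to-start at 1/f and the trailing interpulse
gap is trimmed. Under this micro-structure one 50-pulse burst has exactly
200 μs of on-time; note the 50-burst protocol then totals 10 ms on-time,
whereas the protocol is sometimes quoted with 20 ms — the per-burst figure
is the one this implementation reproduces, and the discrepancy is flagged
here deliberately.

Preset names: `hf_50x50` (1.4 kV/cm), `mono_8x100us` (1.2 kV/cm),
`mono_8x5ms` (0.6 kV/cm), `ns_1x200` (12.6 kV/cm), `ns_25x400` (3.9 kV/cm,
10 Hz). Fields are stored in V/m; kV/cm appears only at interfaces
(1 kV/cm = 10⁵ V/m).

## Numerics

A 25-min readout spans ~1.5×10⁹ τ units — intractable for direct fine
stepping — so `simulate` is a hybrid:

- **Active and short segments**: LSODA with the analytic Jacobian,
  rtol 1e−8, atol 1e−12 (the U equation is stiff: its relaxation rate is
  1 + γ(N+M) ≈ 10–100 per τ once permeabilized).
- **Field-free intervals longer than 100 τ**: the membrane first discharges
  (numerically, in chunks, until |U| < 1e−6; U's decay rate is ≥ 1 per τ so
  this takes a few tens of τ), then U is pinned to 0 and the remaining
  linear system is advanced in closed form:
  M(Δτ) = M₀e^(−ηΔτ); N(Δτ) = (N₀ − c)e^(−βΔτ) + c e^(−ηΔτ) with
  c = ηM₀/(β−η) (analytic limit (N₀+ηM₀Δτ)e^(−βΔτ) when β = η); and
  1−X(Δτ) = (1−X₀)·exp(−ξM₀(1−e^(−ηΔτ))/η).

The hybrid and a brute-force end-to-end numeric integration agree to ~1e−8
relative in final X on all five presets over a 60 s horizon (the test suite
asserts ≤ 1e−4; the 60 s truncation keeps the brute-force reference to
seconds of CPU). Halving tolerances moves final X by far less than 0.1%.
Solver tolerance-level undershoots of N, M ≥ 0 and X ∈ [0, 1] are clipped at
segment boundaries. Trajectories are sampled at segment boundaries plus 25
log-spaced points across the final relaxation tail.

Polarity symmetry (all pore/transport dynamics depend on U²) and exact
linearity of the molecule count in X_e (the normalized dynamics never see
the concentration) are exploited: a protocol is simulated once and scaled
across concentrations.

## Measurement reduction

- Pt mass per cell (pg, ICP-MS) → molecules: blank-subtract the untreated
  control, floor at zero, divide by M_Pt = 195.084 g/mol, multiply by N_A
  (1 mol Pt ≡ 1 mol cisplatin).
- Electroporative uptake: mean treated minus mean no-pulse baseline at the
  same concentration, floored at 0 with a warning (physical nonnegativity).
- Model-vs-measurement: per (protocol, concentration) ratio model/measured;
  the per-protocol aggregate is the **geometric mean** over nonzero
  concentrations — ratios are multiplicative, and no other aggregation is
  canonical. Zero measured means at nonzero concentration are flagged NaN
  and excluded from the aggregate.
- Replicates aggregate as arithmetic mean ± sample SD (ddof = 1), the
  convention of the emulated assays.
- Survival-vs-molecules pairing is an inner join on (protocol,
  concentration) of the two aggregated tables.

## Synthetic data

No public dataset exists for the emulated measurements, so the generator
produces replicate-level stand-ins with a *known* ground truth:

- **Uptake**: replicate = distortion(protocol) × model truth ×
  LogNormal(mean 1, CV 0.2) + baseline_slope × concentration. Lognormal
  noise reflects that per-cell ICP-MS quantities are positive with roughly
  constant CV; the baseline (default 1e5 molecules/μM) emulates passive
  no-pulse uptake, small next to the ~10⁷ electroporative signal. Defaults:
  4 replicates, concentrations 0/10/30/50 μM.
- **Survival**: single-hit kill S = exp(−k·molecules) with k = 7e−8 per
  molecule by default, chosen so survival falls to a few percent at ~5×10⁷
  molecules — the observed cytotoxic range. Colony counts are
  Binomial(100 cells plated, pe₀·S) per well, 3 wells, control plating
  efficiency pe₀ = 0.8. Survival is recovered exactly as in the clonogenic
  assay: per-well plating efficiency, group mean, normalization to the
  no-pulse/no-drug control.

Everything is deterministic under a fixed seed (byte-identical CSVs).

What the generator does *not* emulate: the distinct dose–response of
no-pulse controls (real passive uptake kills far less per molecule than
electroporative uptake — here one exponential applies to both), cell-to-cell
heterogeneity in permeabilization, chemical degradation of the drug under
millisecond pulses, and flow-cytometry or metabolic-assay readouts. Passing
recovery tests therefore demonstrates that the *pipeline arithmetic* is
correct and well-conditioned at realistic noise levels, not that the model
fits real cells.

## Validation problem sizes

The test suite integrates all five presets to the full 25-min readout once
per session; brute-force/hybrid cross-checks run on a 60 s horizon;
distortion-recovery uses 10³ replicates (recovery asserted within 3 standard
errors of the configured factors 2.5× and 2×); kill-rate recovery uses the
default 4-replicate, 3-well design and is asserted within 15%. The
acceptance script mirrors these sizes.

## Known limitations

- Non-spatial: parameters are whole-cell effective values; no pole-dependent
  permeabilization, no field inhomogeneity, no cell-size distribution.
- Diffusion-only transport; no electrophoresis, endocytosis or transporter
  contribution (visible experimentally as nonzero no-pulse uptake, which the
  pipeline subtracts rather than models).
- Rectangular pulses only; generator nonidealities (rise time, droop) are
  out of scope.
- The kinetic constants were calibrated on a different tracer molecule and
  pulse set than some preset protocols; predictions are order-of-magnitude
  accurate, with protocol-dependent 2–2.5× overestimation plausible.
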