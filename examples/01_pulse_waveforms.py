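"""Build the standard electroporation pulse protocols and inspect them.

Each protocol is a piecewise-constant field time course. The printed on-time
is the total time the field is nonzero — the quantity pulse protocols are
usually quoted by — and the field values come from the generator voltage over
the 2 mm cuvette gap.
"""

from ectsim import PRESETS, field_from_voltage, get_preset, make_hf_bipolar_train

print("voltage -> field over a 2 mm cuvette:")
for volts in (280.0, 240.0, 120.0):
    E = field_from_voltage(volts, 2e-3)
    print(f"  {volts:5.0f} V  ->  {E / 1e5:.2f} kV/cm")

print("\npreset protocols:")
print(f"{'name':<14} {'segments':>8} {'duration':>12} {'on-time':>12} {'peak field':>12}")
for name in PRESETS:
    train = get_preset(name)
    peak = max(abs(s.field) for s in train.segments)
    print(
        f"{name:<14} {len(train.segments):>8} {train.duration:>11.4g}s "
        f"{train.on_time * 1e6:>10.4g}us {peak / 1e5:>9.1f} kV/cm"
    )

burst = make_hf_bipolar_train(1, 50, 2e-6, 2e-6, 2e-6, 1.0, 1.4e5)
print(
    f"\none high-frequency burst: {len(burst.segments)} segments, "
    f"{burst.on_time * 1e6:.0f} us on-time "
    "(50 bipolar pulses of 2 us positive + 2 us negative phases)"
)
print("first 6 segments (duration_s, field_V_per_m):")
print(burst.to_table().head(6).to_string(index=False))
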