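"""FRAP double normalization and recovery kinetics.

Simulates two photobleaching experiments mimicking the two telomeric
R-loop populations — a fast-exchanging one that recovers 80% of its
fluorescence in ~8 s, and a slow one that plateaus at 65% — then
normalizes each curve (pre-bleach mean = 1, first post-bleach = 0,
with acquisition-photobleaching correction) and reads out t50, t80,
plateau and the fast/slow label.  Finally the fold-over-diffusion
ratios are computed from the published recovery times of the
binding-dead sensor mutants.
"""

from rloopkit import (
    FrapSimConfig,
    classify_population,
    compute_kinetics,
    fold_over_reference,
    normalize_frap,
    simulate_frap_experiment,
)
from rloopkit.simulate import FAST_TELOMERIC, SLOW_TELOMERIC

for name, params in [("fast", FAST_TELOMERIC), ("slow", SLOW_TELOMERIC)]:
    cfg = FrapSimConfig(**params, seed=7)
    exp, truth = simulate_frap_experiment(cfg)
    curve = normalize_frap(exp)
    kin = compute_kinetics(curve)
    label = classify_population(kin)
    t50 = f"{kin.t50_s:.2f} s" if kin.t50_s is not None else "never"
    t80 = f"{kin.t80_s:.2f} s" if kin.t80_s is not None else "never"
    print(
        f"{name} population: t50 = {t50}, t80 = {t80}, "
        f"plateau = {kin.plateau:.2f}, classified {label}"
    )

# Turnover corrected for diffusion: recovery time over the mean
# recovery time of binding-dead mutants (2.4 s and 2.1 s at 80%).
fold = fold_over_reference(8.1, [2.4, 2.1])
print(f"fast telomeric fold over mutants (t80): {fold:.1f}")
# A fold well above 1 means the sensor dwells on its target much
# longer than free diffusion alone would explain.
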