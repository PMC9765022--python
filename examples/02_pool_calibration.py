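"""Simulate sequencing a spike-in pool and fit its calibration curve.

The panel is assigned in pairs to a five-level serial dilution
(1 to 1e-4 ng/µL), 500,000 reads are drawn with a ±20% GC amplification
bias, and the standard curve log10(mass) ~ log10(CPM) is fitted.
"""

from syndna import (
    SimulationConfig,
    assign_pool,
    build_dilution_series,
    cpm,
    design_panel,
    fit_all,
    simulate_pool_counts,
)

panel = design_panel(seed=42)
series = build_dilution_series(top=1.0, factor=10.0, n_levels=5)
pool = assign_pool([r.id for r in panel], series, pool_id="pool1")

config = SimulationConfig(depth=500_000, gc_bias_strength=0.2, seed=7)
counts, truth = simulate_pool_counts(pool, config,
                                     {r.id: r.realized_gc for r in panel})

print(f"{'synDNA':<6} {'assigned ng/uL':>14} {'reads':>8} {'CPM':>10}")
for sid in sorted(pool.assignments, key=pool.assignments.get, reverse=True):
    print(f"{sid:<6} {pool.assignments[sid]:>14.4g} "
          f"{counts.counts[sid]:>8.0f} {cpm(counts, sid):>10.1f}")

model = fit_all(counts, pool)
print(f"\nfit: slope={model.slope:.3f} intercept={model.intercept:.3f} "
      f"R^2={model.r_squared:.4f} p={model.p_value:.2e}")

# A slope near 1 means CPM scales linearly with input mass across four
# decades of dilution; R^2 >= 0.94 even under GC bias is what makes the
# pool usable as a per-sample standard curve.
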