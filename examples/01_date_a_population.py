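"""Date one admixed population from its tract-length distribution.

Builds a synthetic dataset with a known time since introgression (t = 800
generations, admixture fraction f = 0.31) over five recombination-rate
groups, then recovers the date with both estimators: the windowed
mean-length inversion (Method 1) and the lambda-versus-r regression
(Method 2).
"""

from admixclock import (
    FixtureSpec,
    assign_tracts_to_windows,
    date_population_regression,
    date_population_windowed,
    generate_fixture,
)
from admixclock.tract_io import WindowRecord


def make_windows(rates, n_per_rate=10):
    windows = []
    for gi, r in enumerate(rates):
        for j in range(n_per_rate):
            windows.append(
                WindowRecord(f"chr{gi}", j * 100_000, (j + 1) * 100_000,
                             rho_per_kb=1.0, r_morgans_per_bp=r)
            )
    return windows


spec = FixtureSpec(
    true_t=800, f=0.31,
    windows=make_windows([2e-8, 3e-8, 4e-8, 5e-8, 6e-8]),
    tracts_per_window=100, n_haplotypes=400, seed=7,
)

tracts, windows = generate_fixture(spec)
assign_tracts_to_windows(tracts, windows)

windowed = date_population_windowed(windows, f=0.31, population="demo",
                                    n_boot=1_000, seed=7)
slope_fit, category_fits = date_population_regression(windows, f=0.31,
                                                      n_categories=5)

print(f"true time since introgression: {spec.true_t} generations")
print(f"Method 1 (windowed mode):   t = {windowed.mode_estimate:7.1f}  "
      f"95% CI [{windowed.ci_95[0]:.1f}, {windowed.ci_95[1]:.1f}]")
print(f"Method 2 (slope regression): t = {slope_fit.t_generations:7.1f}  "
      f"95% CI [{slope_fit.ci_95[0]:.1f}, {slope_fit.ci_95[1]:.1f}]")
print()
print("Method 2 reads the date from the slope a = (1-f)(t-1) of the")
print("exponential rate lambda against local recombination rate r; Method 1")
print("inverts the mean tract length window by window and reports the mode")
print("of the per-window dates (here biased low because long tracts are")
print("counted in every window they overlap).")
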