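"""Closed-form tract fixtures with known (t, f, r-map) for fast estimator tests.

Under the single-pulse model, tract lengths in a window of recombination rate
r are exponential with rate lambda = (1 - f) * r * (t - 1).  The generator
draws i.i.d. lengths from that law per window (optionally left-truncated at a
minimum length, which by memorylessness just shifts the mean by the
truncation point), places the tracts at non-overlapping uniform positions on
synthetic haplotypes, and emits data in the standard tract/window formats —
so the dating estimators can be exercised end-to-end in milliseconds without
running the population simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tract_dating import mean_tract_length
from .tract_io import (
    AncestryTract,
    WindowRecord,
    write_tracts,
    write_window_table,
)


class PackingError(RuntimeError):
    """Requested tract density cannot be placed without overlaps."""


@dataclass
class FixtureSpec:
    """Recipe for one synthetic dataset with a known true time."""

    true_t: float
    f: float
    windows: list[WindowRecord]
    tracts_per_window: int = 20
    n_haplotypes: int = 8
    min_length: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_t <= 1:
            raise ValueError("true_t must exceed 1 generation")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("f must lie in [0, 1)")
        if self.tracts_per_window < 1 or self.n_haplotypes < 1:
            raise ValueError("need >= 1 tract per window and >= 1 haplotype")
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")


_MAX_PLACEMENT_TRIES = 200


def generate_fixture(
    spec: FixtureSpec, out_prefix: str | None = None
) -> tuple[list[AncestryTract], list[WindowRecord]]:
    """Draw tracts per window from the exponential law implied by the spec.

    Lengths for a window of rate r_w are Exponential with mean
    1/((1-f) r_w (t-1)), shifted by ``min_length`` when truncation is
    requested.  Each tract is placed on one of ``n_haplotypes`` synthetic
    haplotypes (round-robin) at a uniform position overlapping its source
    window, rejecting overlaps with previously placed tracts on the same
    haplotype.  With ``out_prefix`` the tract and window files are also
    written as ``<prefix>.tracts.tsv`` / ``<prefix>.windows.tsv``.
    """
    rng = np.random.default_rng(spec.seed)
    tracts: list[AncestryTract] = []
    # per (haplotype, chromosome) occupied intervals for rejection sampling
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    hap_cycle = 0
    for w in spec.windows:
        if w.r_morgans_per_bp <= 0:
            raise ValueError(f"window {w.chromosome}:{w.start} has r <= 0")
        mean = mean_tract_length(spec.true_t, w.r_morgans_per_bp, spec.f)
        lengths = rng.exponential(mean, size=spec.tracts_per_window)
        lengths = np.maximum(1, np.rint(lengths)).astype(int) + spec.min_length
        for length in lengths:
            placed = False
            for attempt in range(_MAX_PLACEMENT_TRIES):
                hap = f"h{hap_cycle % spec.n_haplotypes}"
                hap_cycle += 1
                start = _draw_start(rng, w, int(length))
                end = start + int(length)
                key = (hap, w.chromosome)
                if _free(occupied.get(key, []), start, end):
                    occupied.setdefault(key, []).append((start, end))
                    tracts.append(
                        AncestryTract(
                            haplotype_id=hap,
                            chromosome=w.chromosome,
                            start=start,
                            end=end,
                            ancestry="donor",
                        )
                    )
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not place a {length}-bp tract near window "
                    f"{w.chromosome}:{w.start} after {_MAX_PLACEMENT_TRIES} "
                    "tries; lower tracts_per_window or raise n_haplotypes"
                )
    tracts.sort(key=lambda t: (t.chromosome, t.start, t.haplotype_id))
    fresh_windows = [
        WindowRecord(
            chromosome=w.chromosome, start=w.start, end=w.end,
            rho_per_kb=w.rho_per_kb, r_morgans_per_bp=w.r_morgans_per_bp,
            rnd_min=w.rnd_min,
        )
        for w in spec.windows
    ]
    if out_prefix is not None:
        write_tracts(tracts, f"{out_prefix}.tracts.tsv")
        write_window_table(fresh_windows, f"{out_prefix}.windows.tsv")
    return tracts, fresh_windows


def _draw_start(rng: np.random.Generator, w: WindowRecord, length: int) -> int:
    """Uniform start so the tract overlaps window w (fully inside when it fits)."""
    if length <= w.width:
        return int(rng.integers(w.start, w.end - length + 1))
    # longer than the window: any start that still overlaps it, clamped to 0
    lo = max(0, w.end - length)
    return int(rng.integers(lo, w.start + 1))


def _free(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return all(end <= s or start >= e for s, e in intervals)


@dataclass
class RecoveryReport:
    """Outcome of running one dating method on a known-truth fixture."""

    method: str
    true_t: float
    t_hat: float
    error: float
    details: dict = field(default_factory=dict)


def recovery_report(
    spec: FixtureSpec,
    method: str = "regression",
    n_categories: int = 11,
    n_boot: int = 200,
    seed: int | None = None,
) -> RecoveryReport:
    """Generate a fixture and date it end-to-end with the chosen method.

    ``method`` is ``"window"`` (Method 1: per-window inversion, reported as
    the KDE mode of window times) or ``"regression"`` (Method 2: lambda-vs-r
    zero-intercept slope).  Returns the estimate and its signed error.
    """
    from .tract_dating import date_population_regression, date_population_windowed
    from .tract_io import assign_tracts_to_windows

    tracts, windows = generate_fixture(spec)
    assign_tracts_to_windows(tracts, windows)
    if method == "window":
        dist = date_population_windowed(
            windows, spec.f, population="fixture", n_boot=n_boot, seed=seed
        )
        t_hat = dist.mode_estimate
        details = {"ci_95": dist.ci_95, "n_windows": dist.window_times.size}
    elif method == "regression":
        slope_fit, fits = date_population_regression(
            windows, spec.f, n_categories=n_categories
        )
        t_hat = slope_fit.t_generations
        details = {
            "slope_a": slope_fit.slope_a,
            "se_a": slope_fit.se_a,
            "ci_95": slope_fit.ci_95,
            "n_usable_categories": sum(f.usable for f in fits),
        }
    else:
        raise ValueError(f"unknown method {method!r}")
    return RecoveryReport(
        method=method,
        true_t=spec.true_t,
        t_hat=t_hat,
        error=t_hat - spec.true_t,
        details=details,
    )
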