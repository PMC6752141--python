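"""Window and tract filters applied before dating.

Three screens extract the informative, neutrally-introgressing fraction of the
data:

* a minimum tract length (default 50 kb) — short tracts are both old (hence
  uninformative about recent diffusion) and hard to call reliably;
* a ceiling on the population-scaled recombination rate (default rho = 10 per
  kb) — in highly recombining regions the tract-length differential between
  locations decays too fast to be usable;
* an RND_min ceiling (default 0.03, or a 95th-percentile rule) — windows with
  unusually low minimum relative node depth are candidate barrier loci under
  selection against introgression and are excluded so the neutral-erosion
  model applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tract_io import AncestryTract, DxySummary, WindowRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three screens.

    ``rnd_rule`` selects between the fixed-value ceiling (``"fixed"``,
    threshold = ``rnd_min_threshold``) and the empirical-quantile rule
    (``"quantile"``, threshold = the ``rnd_quantile`` quantile of observed
    rnd_min values).  The two coincide on the study data but not on arbitrary
    inputs, so both are exposed.
    """

    min_tract_length: int = 50_000
    max_rho_per_kb: float = 10.0
    rnd_min_threshold: float = 0.03
    rnd_rule: str = "fixed"
    rnd_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.min_tract_length <= 0 or self.max_rho_per_kb <= 0:
            raise ValueError("thresholds must be > 0")
        if self.rnd_min_threshold <= 0 or not 0 < self.rnd_quantile < 1:
            raise ValueError("RND threshold/quantile out of range")
        if self.rnd_rule not in ("fixed", "quantile"):
            raise ValueError(f"unknown rnd_rule {self.rnd_rule!r}")


def compute_rnd_min(dxy: DxySummary) -> float:
    """Minimum relative node depth: d_min / d_out.

    Low values flag windows where the closest donor/recipient sequences are
    far more similar than expected from the outgroup-calibrated divergence —
    the signature of a region resisting introgression.
    """
    if dxy.d_out <= 0:
        raise ValueError("d_out must be > 0")
    return dxy.d_min / dxy.d_out


def filter_tracts(
    tracts: list[AncestryTract], cfg: FilterConfig
) -> list[AncestryTract]:
    """Keep tracts strictly longer than ``cfg.min_tract_length``."""
    return [t for t in tracts if t.length > cfg.min_tract_length]


def filter_windows(
    windows: list[WindowRecord], cfg: FilterConfig
) -> list[WindowRecord]:
    """Keep windows with rho strictly below the ceiling and RND_min at or
    below the threshold.

    If no window carries an rnd_min value the RND screen is skipped with a
    warning; individual windows lacking rnd_min pass the screen (they cannot
    be judged).
    """
    kept = [w for w in windows if w.rho_per_kb < cfg.max_rho_per_kb]

    observed = [w.rnd_min for w in kept if w.rnd_min is not None]
    if not observed:
        if kept:
            logger.warning("no rnd_min values present; RND_min screen skipped")
        return kept
    if cfg.rnd_rule == "quantile":
        threshold = float(np.quantile(np.asarray(observed), cfg.rnd_quantile))
    else:
        threshold = cfg.rnd_min_threshold
    return [w for w in kept if w.rnd_min is None or w.rnd_min <= threshold]


def drop_empty_windows(windows: list[WindowRecord]) -> list[WindowRecord]:
    """Remove windows with no assigned tracts (run after assignment/filtering)."""
    kept = [w for w in windows if w.assigned_tracts]
    if windows and not kept:
        logger.warning("every window is empty after filtering")
    return kept


def apply_filters(
    tracts: list[AncestryTract],
    windows: list[WindowRecord],
    cfg: FilterConfig,
):
    """Full screening pipeline: tracts > length floor, windows under the rho
    and RND ceilings, tracts assigned, empty windows dropped.

    Returns ``(kept_tracts, kept_windows)`` and logs input/output counts per
    stage.
    """
    from .tract_io import assign_tracts_to_windows

    kept_tracts = filter_tracts(tracts, cfg)
    logger.info("tract length filter: %d -> %d", len(tracts), len(kept_tracts))
    kept_windows = filter_windows(windows, cfg)
    logger.info("window filters: %d -> %d", len(windows), len(kept_windows))
    assign_tracts_to_windows(kept_tracts, kept_windows)
    final_windows = drop_empty_windows(kept_windows)
    logger.info(
        "windows with >=1 tract: %d of %d", len(final_windows), len(kept_windows)
    )
    return kept_tracts, final_windows
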