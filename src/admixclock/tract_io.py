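"""Data model and readers/writers for ancestry tracts and genomic window tables.

Coordinates are 0-based, half-open (BED convention) throughout; lengths are in
base pairs.  A tract is one contiguous run of donor ancestry on one haplotype,
as called upstream by any local-ancestry-inference tool.  Windows are
fixed-width (100 kb) genomic bins carrying the population-scaled recombination
rate rho = 4*Ne*r (per kb) used for filtering and the physical rate r
(Morgans/bp) that enters the recombination clock.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANCESTRY_LABELS = ("donor", "recipient")

WINDOW_SIZE = 100_000

TRACT_COLUMNS = ["chromosome", "start", "end", "haplotype_id", "ancestry"]
WINDOW_COLUMNS = ["chromosome", "start", "end", "rho_per_kb", "r_morgans_per_bp"]


class TractParseError(ValueError):
    """Malformed tract/window input; message names the offending line."""


class TractValidationError(ValueError):
    """Structurally valid input that violates a model invariant."""


@dataclass(frozen=True, slots=True)
class AncestryTract:
    """A contiguous run of one ancestry on one haplotype, 0-based half-open."""

    haplotype_id: str
    chromosome: str
    start: int
    end: int
    ancestry: str = "donor"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise TractValidationError(
                f"tract end must exceed start, got {self.chromosome}:"
                f"{self.start}-{self.end}"
            )
        if self.start < 0:
            raise TractValidationError(f"negative start {self.start}")
        if self.ancestry not in ANCESTRY_LABELS:
            raise TractValidationError(
                f"ancestry must be one of {ANCESTRY_LABELS}, got {self.ancestry!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PopulationSample:
    """A named set of haplotypes with their tract calls and admixture fraction f.

    ``admixture_fraction_f`` is the genome-wide proportion of donor ancestry
    observed for the population (a supplied scalar, not recomputed per window).
    """

    name: str
    tracts: list[AncestryTract]
    n_haplotypes: int
    admixture_fraction_f: float
    genome_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture_fraction_f <= 1.0:
            raise TractValidationError(
                f"admixture fraction must lie in [0, 1], got {self.admixture_fraction_f}"
            )
        hap_ids = {t.haplotype_id for t in self.tracts}
        if len(hap_ids) > self.n_haplotypes:
            raise TractValidationError(
                f"{len(hap_ids)} distinct haplotype ids exceed declared "
                f"n_haplotypes={self.n_haplotypes}"
            )
        per_hap: dict[tuple[str, str], int] = {}
        for t in self.tracts:
            key = (t.haplotype_id, t.chromosome)
            per_hap[key] = per_hap.get(key, 0) + t.length
        for key, total in per_hap.items():
            if total > self.genome_length:
                raise TractValidationError(
                    f"tract lengths on haplotype {key[0]} ({key[1]}) sum to {total} "
                    f"> genome_length {self.genome_length}"
                )


@dataclass
class WindowRecord:
    """A genomic window (100 kb) with recombination rates and assigned tracts.

    ``assigned_tracts`` holds references to every tract overlapping the window
    by >= 1 bp; tracts keep their full genomic length, they are never clipped
    to the window.
    """

    chromosome: str
    start: int
    end: int
    rho_per_kb: float
    r_morgans_per_bp: float
    rnd_min: float | None = None
    assigned_tracts: list[AncestryTract] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise TractValidationError(
                f"window end must exceed start: {self.chromosome}:{self.start}-{self.end}"
            )
        if self.r_morgans_per_bp < 0:
            raise TractValidationError("r_morgans_per_bp must be >= 0")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class DxySummary:
    """Per-window absolute-divergence summaries feeding the RND_min screen.

    ``d_min`` is the minimum between-lineage d_XY over all donor/recipient
    pairs in the window; ``d_out`` the mean d_XY to the outgroup.
    """

    chromosome: str
    start: int
    end: int
    d_min: float
    d_out: float

    def __post_init__(self) -> None:
        if self.d_min < 0:
            raise TractValidationError("d_min must be >= 0")
        if self.d_out <= 0:
            raise TractValidationError("d_out must be > 0")


# ---------------------------------------------------------------------------
# readers / writers


def _merge_adjacent(tracts: list[AncestryTract]) -> list[AncestryTract]:
    """Merge exactly-adjacent same-ancestry intervals on each haplotype.

    Overlapping same-haplotype same-ancestry intervals are a validation error:
    a haplotype has one ancestry per position, so overlapping calls are
    contradictory upstream output.
    """
    ordered = sorted(
        tracts, key=lambda t: (t.haplotype_id, t.chromosome, t.ancestry, t.start)
    )
    merged: list[AncestryTract] = []
    for t in ordered:
        if merged:
            p = merged[-1]
            same = (
                p.haplotype_id == t.haplotype_id
                and p.chromosome == t.chromosome
                and p.ancestry == t.ancestry
            )
            if same and t.start < p.end:
                raise TractValidationError(
                    f"overlapping {t.ancestry} intervals on haplotype "
                    f"{t.haplotype_id} at {t.chromosome}:{t.start}-{t.end}"
                )
            if same and t.start == p.end:
                merged[-1] = replace(p, end=t.end)
                continue
        merged.append(t)
    merged.sort(key=lambda t: (t.chromosome, t.start, t.haplotype_id))
    return merged


def read_tracts(path) -> list[AncestryTract]:
    """Read a BED-like tract file (chrom, start, end, haplotype_id, ancestry).

    Tab-separated, no header, 0-based half-open coordinates.  Adjacent
    same-ancestry intervals on a haplotype are merged; malformed rows raise
    :class:`TractParseError` naming the line number.
    """
    tracts: list[AncestryTract] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise TractParseError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, start_s, end_s, hap, anc = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise TractParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            try:
                tracts.append(
                    AncestryTract(
                        haplotype_id=hap, chromosome=chrom, start=start,
                        end=end, ancestry=anc,
                    )
                )
            except TractValidationError as exc:
                raise TractParseError(f"{path}: line {lineno}: {exc}") from exc
    return _merge_adjacent(tracts)


def write_tracts(tracts, path) -> None:
    """Write tracts in the BED-like layout accepted by :func:`read_tracts`."""
    ordered = sorted(tracts, key=lambda t: (t.chromosome, t.start, t.haplotype_id))
    with open(path, "w") as fh:
        for t in ordered:
            fh.write(
                f"{t.chromosome}\t{t.start}\t{t.end}\t{t.haplotype_id}\t{t.ancestry}\n"
            )


def read_window_table(path) -> list[WindowRecord]:
    """Read the tab-separated window table (header required).

    Required columns: chromosome, start, end, rho_per_kb, r_morgans_per_bp;
    optional: rnd_min (missing values allowed).  Windows come back sorted by
    (chromosome, start); duplicate windows are a validation error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise TractParseError(f"{path}: missing required column(s): {missing}")
    if df.duplicated(subset=["chromosome", "start"]).any():
        dups = df[df.duplicated(subset=["chromosome", "start"], keep=False)]
        raise TractValidationError(
            f"{path}: duplicate windows: "
            + ", ".join(f"{r.chromosome}:{r.start}" for r in dups.itertuples())
        )
    has_rnd = "rnd_min" in df.columns
    df = df.sort_values(["chromosome", "start"], kind="mergesort")
    windows = []
    for row in df.itertuples(index=False):
        rnd = None
        if has_rnd and not pd.isna(row.rnd_min):
            rnd = float(row.rnd_min)
        windows.append(
            WindowRecord(
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                rho_per_kb=float(row.rho_per_kb),
                r_morgans_per_bp=float(row.r_morgans_per_bp),
                rnd_min=rnd,
            )
        )
    return windows


def write_window_table(windows, path) -> None:
    rows = [
        {
            "chromosome": w.chromosome,
            "start": w.start,
            "end": w.end,
            "rho_per_kb": w.rho_per_kb,
            "r_morgans_per_bp": w.r_morgans_per_bp,
            "rnd_min": np.nan if w.rnd_min is None else w.rnd_min,
        }
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def assign_tracts_to_windows(
    tracts, windows: list[WindowRecord]
) -> list[WindowRecord]:
    """Assign each tract to EVERY window it overlaps by >= 1 bp.

    The tract keeps its full length in every window it touches (it is not
    clipped), so long tracts are deliberately counted once per overlapped
    window.  Tracts on chromosomes absent from the window table are skipped
    with a warning.  Returns the same window objects with
    ``assigned_tracts`` (re)filled.
    """
    by_chrom: dict[str, tuple[list[int], list[int], list[WindowRecord]]] = {}
    for w in windows:
        w.assigned_tracts = []
        starts, ends, recs = by_chrom.setdefault(w.chromosome, ([], [], []))
        starts.append(w.start)
        ends.append(w.end)
        recs.append(w)
    for chrom, (starts, ends, recs) in by_chrom.items():
        order = sorted(range(len(recs)), key=lambda i: starts[i])
        by_chrom[chrom] = (
            [starts[i] for i in order],
            [ends[i] for i in order],
            [recs[i] for i in order],
        )

    n_skipped = 0
    for t in tracts:
        entry = by_chrom.get(t.chromosome)
        if entry is None:
            n_skipped += 1
            continue
        starts, ends, recs = entry
        # half-open overlap: window.start < tract.end and window.end > tract.start
        lo = bisect_right(ends, t.start)
        hi = bisect_left(starts, t.end)
        for i in range(lo, hi):
            recs[i].assigned_tracts.append(t)
    if n_skipped:
        logger.warning(
            "%d tract(s) on chromosomes absent from the window table were skipped",
            n_skipped,
        )
    return windows


def make_window_grid(
    chromosome: str,
    chrom_length: int,
    r_morgans_per_bp: float,
    rho_per_kb: float | None = None,
    window_size: int = WINDOW_SIZE,
) -> list[WindowRecord]:
    """Tile a chromosome with fixed-width windows at a uniform recombination rate.

    Convenience for simulated/synthetic data; rho defaults to a value safely
    under the filtering ceiling.
    """
    if rho_per_kb is None:
        rho_per_kb = 1.0
    windows = []
    for start in range(0, chrom_length, window_size):
        end = min(start + window_size, chrom_length)
        windows.append(
            WindowRecord(
                chromosome=chromosome,
                start=start,
                end=end,
                rho_per_kb=rho_per_kb,
                r_morgans_per_bp=r_morgans_per_bp,
            )
        )
    return windows
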