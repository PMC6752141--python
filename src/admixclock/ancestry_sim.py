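"""Ancestry-tract simulators for the secondary-contact scenario.

The demographic scenario is a secondary contact: after divergence in
isolation, a donor lineage sends migrants into a recipient population for
``t_c`` generations; gene flow then stops and tract erosion continues for
``t_diff`` further generations (the diffusion period).  The recipient
population is sampled twice — at the end of contact (``Date_Tdiff``) and
``t_diff`` generations later (``Date_T0``) — and the difference of the two
Eq.-based dates estimates ``t_diff``, emulating the travel time of tracts
between two sites at different distances from a contact zone without
spatially explicit structure.

Two engines realize the scenario:

* :func:`simulate` — an explicit forward-in-time Wright-Fisher population.
  Only ancestry is tracked, not sequence: each haplotype is a sorted list of
  junction positions at which ancestry flips, plus the ancestry of its first
  segment.  Each offspring haplotype is built from two uniformly chosen
  parent haplotypes with a Poisson(r*L) number of crossovers at uniform
  positions; migrants are whole individuals descending from all-donor
  parents.  The generation loop runs in a numba kernel and is
  bit-reproducible from one seed.  Forward simulation carries the full drift
  process, which makes it the right tool for validating the closed-form
  tract-length law (single pulse, modest time depths) — but it also means
  the *population size is a real model parameter*: once the time span
  approaches N generations, within-population genealogies coalesce, visible
  junction formation stalls, and the recombination clock saturates.  Desk-
  scale populations therefore cannot represent a large marine population
  over thousands of generations.

* :func:`simulate_coalescent` — the same scenario run backward in time at
  the *full-scale* population size (tens of thousands of diploids, where the
  clock suppression is negligible), which is tractable because only the
  sampled genealogies are simulated.  Donor tracts are read off as the
  sample segments whose lineage sat in the donor population when contact
  began, using a census at that time.  This engine drives the
  diffusion-time recovery validation and the parameter sweeps.

Both engines emit :class:`SimulatedSample` objects in the package's tract
format, so simulated data feed the dating pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import msprime
import numpy as np
from numba import njit

from .tract_dating import time_from_mean_length
from .tract_io import AncestryTract

SIM_CHROMOSOME = "chr_sim"

# Sea bass study conditions: observed western-Mediterranean admixture and
# contact duration, and the full-scale migrant flow N_MED*m1 = 7.
SEA_BASS_F_OBS = 0.31
SEA_BASS_T_C = 2_300
SEA_BASS_FULL_SCALE_MIGRANTS = 7.0
SEA_BASS_R_PER_BP = 6.84e-8
SEA_BASS_CHROM_LENGTH = 25_000_000

# Recipient population size consistent with the study conditions: the
# per-generation migrant fraction m1 that yields the observed admixture
# (f = 0.31) after 2,300 generations of contact, combined with the stated
# flow of 7 migrant individuals per generation, fixes N_MED = 7/m1.
SEA_BASS_M1 = 1.0 - (1.0 - SEA_BASS_F_OBS) ** (1.0 / SEA_BASS_T_C)
SEA_BASS_N_HAPLOTYPES = 2 * round(SEA_BASS_FULL_SCALE_MIGRANTS / SEA_BASS_M1)


class EmptySampleError(RuntimeError):
    """A sampled date contains no donor tracts."""


@dataclass(frozen=True)
class SecondaryContactModel:
    """Parameters of the secondary-contact scenario.

    ``migrants_per_generation`` is the expected number of migrant
    *individuals* entering the recipient population per generation during
    contact; integral values are taken as an exact per-generation count,
    fractional values as a Poisson mean.  ``migration_rate_m2``
    (recipient-to-donor back-migration) is accepted for completeness but has
    no effect on recipient tracts and defaults to 0.
    """

    n_recipient_haplotypes: int = 1_000
    t_c: int = SEA_BASS_T_C
    t_diff: int = 550
    migrants_per_generation: float = 7.0
    chromosome_length: int = SEA_BASS_CHROM_LENGTH
    r_per_bp: float = SEA_BASS_R_PER_BP
    seed: int | None = None
    migration_rate_m2: float = 0.0

    def __post_init__(self) -> None:
        if self.n_recipient_haplotypes < 2 or self.n_recipient_haplotypes % 2:
            raise ValueError("need an even number (>= 2) of recipient haplotypes")
        if self.t_c < 0 or self.t_diff < 0:
            raise ValueError("durations must be >= 0")
        if self.migrants_per_generation < 0:
            raise ValueError("migrants_per_generation must be >= 0")
        if self.migrants_per_generation > self.n_recipient_haplotypes / 2:
            raise ValueError(
                "migrants_per_generation exceeds the number of individuals"
            )
        if self.chromosome_length <= 0 or self.r_per_bp < 0:
            raise ValueError("invalid chromosome length or recombination rate")

    @property
    def n_individuals(self) -> int:
        return self.n_recipient_haplotypes // 2


@dataclass
class SimulatedSample:
    """Donor tracts of the haplotypes sampled at one date."""

    label: str
    tracts: list[AncestryTract]
    n_haplotypes: int
    realized_f: float
    chromosome_length: int

    @property
    def mean_tract_length(self) -> float:
        if not self.tracts:
            raise EmptySampleError(
                f"sample {self.label!r} has no donor tracts; increase the "
                "sample size or the migration intensity"
            )
        return float(np.mean([t.length for t in self.tracts]))


def expected_admixture(m: float, generations: int) -> float:
    """Deterministic admixture after ``generations`` of replacement fraction m."""
    return 1.0 - (1.0 - m) ** generations


def migration_rate_for_admixture(f_end: float, t_c: int) -> float:
    """Per-generation migrant fraction reaching admixture ``f_end`` after t_c."""
    if not 0.0 < f_end < 1.0 or t_c <= 0:
        raise ValueError("need 0 < f_end < 1 and t_c > 0")
    return 1.0 - (1.0 - f_end) ** (1.0 / t_c)


def scaled_migrants_per_generation(
    full_scale_migrants: float,
    n_haplotypes: int,
    f_ref: float = SEA_BASS_F_OBS,
    t_c_ref: int = SEA_BASS_T_C,
    full_scale_reference: float = SEA_BASS_FULL_SCALE_MIGRANTS,
) -> float:
    """Convert a full-scale migrant count to its equivalent at a desk-scale N.

    The study's migrant flow (e.g. 7 individuals/generation) refers to a
    natural population orders of magnitude larger than what a forward
    simulation can carry.  What shapes tract erosion is the per-generation
    migrant *fraction* m1, pinned down by the realized admixture proportion:
    m1_ref = 1 - (1 - f_ref)^(1/t_c_ref).  A desk-scale population of
    ``n_haplotypes`` then receives m1 * n_individuals expected migrants per
    generation, with counts scaled linearly for sweeps around the reference
    flow.
    """
    m1 = migration_rate_for_admixture(f_ref, t_c_ref) * (
        full_scale_migrants / full_scale_reference
    )
    return m1 * (n_haplotypes / 2)


def sea_bass_model(
    n_haplotypes: int = SEA_BASS_N_HAPLOTYPES,
    t_diff: int = 550,
    t_c: int = SEA_BASS_T_C,
    full_scale_migrants: float = SEA_BASS_FULL_SCALE_MIGRANTS,
    seed: int | None = None,
) -> SecondaryContactModel:
    """The sea-bass-like secondary-contact scenario.

    At the default (full-scale) population size the migrant flow equals the
    study's 7 individuals per generation; passing a smaller ``n_haplotypes``
    (for forward-engine desk runs) scales the expected migrant count so the
    per-generation migrant fraction — and hence the realized admixture — is
    preserved.
    """
    return SecondaryContactModel(
        n_recipient_haplotypes=n_haplotypes,
        t_c=t_c,
        t_diff=t_diff,
        migrants_per_generation=scaled_migrants_per_generation(
            full_scale_migrants, n_haplotypes
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# population state and the generation loop
#
# state = (data, offs, a0): haplotype h owns junction positions
# data[offs[h]:offs[h+1]] (strictly increasing int32, in (0, L)) and starts
# with ancestry a0[h] (0 = recipient, 1 = donor).  The whole generation loop
# runs inside one numba function: per offspring haplotype, two uniform
# parents, Poisson crossovers at uniform positions, and an ancestry-aware
# merge of the parent junction lists.  numba's global RNG is seeded once per
# call, so a run is fully determined by its seed.

_MAX_XOVERS = 64  # Poisson(r*L) is ~1.7 here; 64 is unreachable in practice


@njit(cache=True)
def _evolve_nb(
    data, offs, a0, n_generations, migrants_mean, exact_migrants, L,
    xover_mean, seed,
):
    np.random.seed(seed)
    n = a0.shape[0]
    n_ind = n // 2
    cap = max(2 * (data.shape[0] + n * 4) + 1024, 1 << 16)
    buf_a = np.empty(cap, dtype=np.int32)
    buf_a[: data.shape[0]] = data
    cur_data = buf_a
    cur_len = data.shape[0]
    buf_b = np.empty(cap, dtype=np.int32)
    cur_offs = offs.copy()
    out_offs = np.empty(n + 1, dtype=np.int64)
    cur_a0 = a0.copy()
    out_a0 = np.empty(n, dtype=np.uint8)
    pa = np.empty(n, dtype=np.int64)
    pb = np.empty(n, dtype=np.int64)
    xcount = np.empty(n, dtype=np.int64)
    xbuf = np.empty(n * _MAX_XOVERS, dtype=np.int32)
    migrant_inds = np.empty(n_ind, dtype=np.int64)
    is_migrant = np.empty(n, dtype=np.uint8)

    for _ in range(n_generations):
        total_x = 0
        req = 0
        for i in range(n):
            pa[i] = np.random.randint(0, n)
            pb[i] = np.random.randint(0, n)
            k = np.random.poisson(xover_mean)
            if k > _MAX_XOVERS:
                k = _MAX_XOVERS
            xcount[i] = k
            # draw and insertion-sort this child's crossover positions
            base = total_x
            for j in range(k):
                x = np.int32(np.random.randint(1, L))
                m = base + j
                while m > base and xbuf[m - 1] > x:
                    xbuf[m] = xbuf[m - 1]
                    m -= 1
                xbuf[m] = x
            total_x += k
            req += (
                (cur_offs[pa[i] + 1] - cur_offs[pa[i]])
                + (cur_offs[pb[i] + 1] - cur_offs[pb[i]])
                + k
            )

        for i in range(n):
            is_migrant[i] = 0
        if migrants_mean > 0.0:
            if exact_migrants:
                k_mig = int(round(migrants_mean))
            else:
                k_mig = np.random.poisson(migrants_mean)
            if k_mig > n_ind:
                k_mig = n_ind
            n_chosen = 0
            while n_chosen < k_mig:
                cand = np.random.randint(0, n_ind)
                dup = False
                for j in range(n_chosen):
                    if migrant_inds[j] == cand:
                        dup = True
                        break
                if not dup:
                    migrant_inds[n_chosen] = cand
                    n_chosen += 1
                    is_migrant[2 * cand] = 1
                    is_migrant[2 * cand + 1] = 1

        if req > buf_b.shape[0]:
            new_cap = 2 * req + 1024
            buf_b = np.empty(new_cap, dtype=np.int32)
        out_data = buf_b

        ptr = 0
        out_offs[0] = 0
        xs_start = 0
        for i in range(n):
            k = xcount[i]
            if is_migrant[i]:
                out_a0[i] = 1
                out_offs[i + 1] = ptr
                xs_start += k
                continue
            if k == 0:
                # no crossover: child is a verbatim copy of parent A
                p = pa[i]
                j0 = cur_offs[p]
                j1 = cur_offs[p + 1]
                out_data[ptr : ptr + (j1 - j0)] = cur_data[j0:j1]
                ptr += j1 - j0
                out_a0[i] = cur_a0[p]
                out_offs[i + 1] = ptr
                continue
            child_a0 = np.uint8(0)
            last_anc = np.uint8(0)
            lo = np.int32(0)
            use_a = True
            start_ptr = ptr
            for s in range(k + 1):
                hi = xbuf[xs_start + s] if s < k else np.int32(L)
                p = pa[i] if use_a else pb[i]
                j0 = cur_offs[p]
                j1 = cur_offs[p + 1]
                seg = cur_data[j0:j1]
                i0 = np.searchsorted(seg, lo, side="right")
                i1 = np.searchsorted(seg, hi, side="left")
                anc_lo = np.uint8(cur_a0[p] ^ (i0 & 1))
                if s == 0:
                    child_a0 = anc_lo
                elif anc_lo != last_anc:
                    # junction at the crossover; a duplicate position cancels
                    if ptr > start_ptr and out_data[ptr - 1] == lo:
                        ptr -= 1
                    else:
                        out_data[ptr] = lo
                        ptr += 1
                out_data[ptr : ptr + (i1 - i0)] = seg[i0:i1]
                ptr += i1 - i0
                last_anc = np.uint8(cur_a0[p] ^ (i1 & 1))
                lo = hi
                use_a = not use_a
            out_a0[i] = child_a0
            out_offs[i + 1] = ptr
            xs_start += k

        # swap buffers
        tmp = cur_data
        cur_data = out_data
        buf_b = tmp
        cur_len = ptr
        for i in range(n + 1):
            cur_offs[i] = out_offs[i]
        for i in range(n):
            cur_a0[i] = out_a0[i]

    return cur_data[:cur_len].copy(), cur_offs.copy(), cur_a0.copy()


def _new_population(n_haplotypes: int):
    return (
        np.empty(0, dtype=np.int32),
        np.zeros(n_haplotypes + 1, dtype=np.int64),
        np.zeros(n_haplotypes, dtype=np.uint8),
    )


def _evolve(
    state,
    n_generations: int,
    migrants_per_generation: float,
    rng: np.random.Generator,
    chromosome_length: int,
    r_per_bp: float,
):
    """Advance the population ``n_generations``; returns the new state.

    The phase seed for the compiled loop is drawn from ``rng``, keeping the
    whole run reproducible from the model seed.
    """
    data, offs, a0 = state
    if n_generations == 0:
        return data, offs, a0
    phase_seed = int(rng.integers(0, 2**31 - 1))
    return _evolve_nb(
        data,
        offs,
        a0,
        n_generations,
        float(migrants_per_generation),
        float(migrants_per_generation).is_integer(),
        np.int64(chromosome_length),
        r_per_bp * chromosome_length,
        phase_seed,
    )


def haplotype_segments(state, h: int, chromosome_length: int):
    """All (start, end, ancestry) segments of haplotype ``h``, tiling [0, L)."""
    data, offs, a0 = state
    bounds = [0, *data[offs[h] : offs[h + 1]].tolist(), chromosome_length]
    anc = int(a0[h])
    segments = []
    for i in range(len(bounds) - 1):
        segments.append((bounds[i], bounds[i + 1], "donor" if anc else "recipient"))
        anc ^= 1
    return segments


def _extract_sample(
    state, hap_indices, chromosome_length: int, label: str
) -> SimulatedSample:
    tracts: list[AncestryTract] = []
    donor_mass = 0
    for out_idx, h in enumerate(hap_indices):
        hap_id = f"{label}_h{out_idx}"
        for start, end, anc in haplotype_segments(state, int(h), chromosome_length):
            if anc == "donor":
                tracts.append(
                    AncestryTract(
                        haplotype_id=hap_id,
                        chromosome=SIM_CHROMOSOME,
                        start=int(start),
                        end=int(end),
                        ancestry="donor",
                    )
                )
                donor_mass += end - start
    return SimulatedSample(
        label=label,
        tracts=tracts,
        n_haplotypes=len(hap_indices),
        realized_f=donor_mass / (len(hap_indices) * chromosome_length),
        chromosome_length=chromosome_length,
    )


def simulate(
    model: SecondaryContactModel, n_sampled_per_date: int
) -> tuple[SimulatedSample, SimulatedSample]:
    """Run the scenario in the forward Wright-Fisher engine and sample both dates.

    Returns ``(sample_tdiff, sample_t0)``: ``n_sampled_per_date`` diploid
    individuals drawn without replacement at the end of contact
    (``Date_Tdiff``) and again after the diffusion period (``Date_T0``).
    Population size here is a real model parameter — over time spans
    approaching ``n_recipient_haplotypes`` generations the recombination
    clock saturates (see module docstring); use :func:`simulate_coalescent`
    for full-scale time depths.
    """
    if n_sampled_per_date < 1:
        raise ValueError("must sample at least one individual per date")
    if n_sampled_per_date > model.n_individuals:
        raise ValueError(
            f"cannot sample {n_sampled_per_date} individuals from "
            f"{model.n_individuals}"
        )
    rng = np.random.default_rng(model.seed)
    state = _new_population(model.n_recipient_haplotypes)
    state = _evolve(
        state, model.t_c, model.migrants_per_generation, rng,
        model.chromosome_length, model.r_per_bp,
    )
    chosen = rng.choice(model.n_individuals, size=n_sampled_per_date, replace=False)
    haps = np.stack([2 * chosen, 2 * chosen + 1], axis=1).ravel()
    sample_tdiff = _extract_sample(
        state, haps, model.chromosome_length, "Date_Tdiff"
    )
    state = _evolve(
        state, model.t_diff, 0.0, rng, model.chromosome_length, model.r_per_bp
    )
    chosen = rng.choice(model.n_individuals, size=n_sampled_per_date, replace=False)
    haps = np.stack([2 * chosen, 2 * chosen + 1], axis=1).ravel()
    sample_t0 = _extract_sample(state, haps, model.chromosome_length, "Date_T0")
    return sample_tdiff, sample_t0


def simulate_coalescent(
    model: SecondaryContactModel, n_sampled_per_date: int
) -> tuple[SimulatedSample, SimulatedSample]:
    """Coalescent realization of the secondary-contact scenario.

    Backward-in-time simulation of the sampled genealogies only, so the
    recipient population can be run at its full-scale size (where clock
    saturation by within-population coalescence is negligible) at a cost
    that depends on the sample, not the population.  During the contact
    window, recipient lineages trace back into the donor population at the
    per-generation migrant fraction; a census planted at the onset of
    contact labels every lineage, and a sampled segment is a donor tract
    exactly when its censused ancestor sits in the donor population.

    Sampling, labels and return order match :func:`simulate`:
    ``(sample_tdiff, sample_t0)``, with ``n_sampled_per_date`` diploid
    individuals per date.
    """
    if n_sampled_per_date < 1:
        raise ValueError("must sample at least one individual per date")
    if model.t_c < 1:
        raise ValueError("coalescent engine needs a contact period t_c >= 1")
    n_med = model.n_individuals
    m1 = model.migrants_per_generation / n_med
    t_contact_start = model.t_diff + model.t_c  # backward time
    census_time = t_contact_start - 0.5

    demog = msprime.Demography()
    demog.add_population(name="MED", initial_size=n_med)
    demog.add_population(name="ATL", initial_size=n_med)
    if model.t_diff > 0:
        demog.add_migration_rate_change(
            time=model.t_diff, rate=m1, source="MED", dest="ATL"
        )
    else:
        demog.set_migration_rate(source="MED", dest="ATL", rate=m1)
    demog.add_census(time=census_time)
    demog.add_migration_rate_change(
        time=t_contact_start, rate=0.0, source="MED", dest="ATL"
    )
    demog.sort_events()

    rng = np.random.default_rng(model.seed)
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n_sampled_per_date, population="MED", time=0),
            msprime.SampleSet(
                n_sampled_per_date, population="MED", time=model.t_diff
            ),
        ],
        demography=demog,
        sequence_length=model.chromosome_length,
        recombination_rate=model.r_per_bp,
        end_time=t_contact_start,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )

    tables = ts.tables
    node_time = tables.nodes.time
    node_pop = tables.nodes.population
    census_nodes = np.where(node_time == census_time)[0].astype(np.int32)
    atl_id = [p.id for p in demog.populations if p.name == "ATL"][0]
    link = tables.link_ancestors(samples=ts.samples(), ancestors=census_nodes)
    donor_segments: dict[int, list[tuple[int, int]]] = {}
    for left, right, parent, child in zip(
        link.left, link.right, link.parent, link.child
    ):
        if node_pop[parent] == atl_id:
            donor_segments.setdefault(int(child), []).append(
                (int(left), int(right))
            )

    samples = ts.samples()
    sample_times = node_time[samples]
    out: list[SimulatedSample] = []
    for label, haps in (
        ("Date_Tdiff", samples[sample_times > 0] if model.t_diff > 0
         else samples[n_sampled_per_date * 2 :]),
        ("Date_T0", samples[sample_times == 0] if model.t_diff > 0
         else samples[: n_sampled_per_date * 2]),
    ):
        tracts: list[AncestryTract] = []
        donor_mass = 0
        for out_idx, h in enumerate(haps):
            hap_id = f"{label}_h{out_idx}"
            merged: list[list[int]] = []
            for s, e in sorted(donor_segments.get(int(h), [])):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(e, merged[-1][1])
                else:
                    merged.append([s, e])
            for s, e in merged:
                tracts.append(
                    AncestryTract(
                        haplotype_id=hap_id,
                        chromosome=SIM_CHROMOSOME,
                        start=s,
                        end=e,
                        ancestry="donor",
                    )
                )
                donor_mass += e - s
        out.append(
            SimulatedSample(
                label=label,
                tracts=tracts,
                n_haplotypes=len(haps),
                realized_f=donor_mass / (len(haps) * model.chromosome_length),
                chromosome_length=model.chromosome_length,
            )
        )
    return out[0], out[1]


def simulate_pulse(
    n_haplotypes: int,
    pulse_fraction: float,
    t: int,
    chromosome_length: int = SEA_BASS_CHROM_LENGTH,
    r_per_bp: float = SEA_BASS_R_PER_BP,
    seed: int | None = None,
    n_sampled_haplotypes: int | None = None,
) -> SimulatedSample:
    """Single admixture pulse followed by erosion: the closed-form test case.

    A fraction ``pulse_fraction`` of haplotypes is replaced by unbroken donor
    chromosomes, then the population reproduces for ``t - 1`` generations (the
    pulse generation counts as generation 1, when tracts are still whole
    chromosomes).  In the large-population limit the sampled donor tract
    lengths are exponential with rate ``(1 - f) * r * (t - 1)``.
    """
    if not 0.0 < pulse_fraction < 1.0:
        raise ValueError("pulse_fraction must lie in (0, 1)")
    if t < 1:
        raise ValueError("t must be >= 1 generation")
    rng = np.random.default_rng(seed)
    data, offs, a0 = _new_population(n_haplotypes)
    n_donor = round(pulse_fraction * n_haplotypes)
    donor_haps = rng.choice(n_haplotypes, size=n_donor, replace=False)
    a0[donor_haps] = 1
    state = _evolve(
        (data, offs, a0), t - 1, 0.0, rng, chromosome_length, r_per_bp
    )
    if n_sampled_haplotypes is None:
        haps = np.arange(n_haplotypes)
    else:
        haps = rng.choice(n_haplotypes, size=n_sampled_haplotypes, replace=False)
    return _extract_sample(state, haps, chromosome_length, f"pulse_t{t}")


# ---------------------------------------------------------------------------
# estimation harness


def estimate_tdiff(
    sample_t0: SimulatedSample,
    sample_tdiff: SimulatedSample,
    r_per_bp: float,
) -> float:
    """Difference of the Eq.-based dates of the two sampling dates.

    Each date is estimated from its sample's realized admixture fraction and
    mean donor tract length; the difference estimates the diffusion-period
    length ``t_diff``.
    """
    for sample in (sample_t0, sample_tdiff):
        if not sample.tracts:
            raise EmptySampleError(
                f"sample {sample.label!r} has no donor tracts; increase the "
                "sample size or the migration intensity"
            )
    t0 = time_from_mean_length(
        sample_t0.mean_tract_length, r_per_bp, sample_t0.realized_f
    )
    t1 = time_from_mean_length(
        sample_tdiff.mean_tract_length, r_per_bp, sample_tdiff.realized_f
    )
    return t0 - t1


def replicate_tdiff_estimates(
    model: SecondaryContactModel,
    n_sampled_per_date: int,
    n_reps: int,
    seed: int | None = None,
    backend: str = "coalescent",
) -> np.ndarray:
    """``n_reps`` independent seeded replicates of the t_diff estimate."""
    run = _get_backend(backend)
    root = np.random.default_rng(
        seed if seed is not None else model.seed
    )
    estimates = np.empty(n_reps)
    for i in range(n_reps):
        rep_seed = int(root.integers(0, 2**31 - 1))
        s_tdiff, s_t0 = run(
            replace(model, seed=rep_seed), n_sampled_per_date
        )
        estimates[i] = estimate_tdiff(s_t0, s_tdiff, model.r_per_bp)
    return estimates


def _get_backend(backend: str):
    try:
        return {"forward": simulate, "coalescent": simulate_coalescent}[backend]
    except KeyError:
        raise ValueError(
            f"unknown backend {backend!r}; choose 'forward' or 'coalescent'"
        ) from None


SWEEPABLE = ("t_diff", "t_c", "migrants_per_generation", "n_sampled")


def run_sweep(
    base_model: SecondaryContactModel,
    vary: str,
    values,
    n_reps: int = 10,
    n_sampled: int = 4,
    seed: int | None = None,
    backend: str = "coalescent",
):
    """Replicated t_diff estimation across one swept parameter.

    ``vary`` is one of ``t_diff``, ``t_c``, ``migrants_per_generation`` or
    ``n_sampled``.  Returns a pandas DataFrame with one row per (value,
    replicate); summarize with :func:`sweep_summary`.
    """
    import pandas as pd

    if vary not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {vary!r}; choose from {SWEEPABLE}")
    root = np.random.default_rng(seed if seed is not None else base_model.seed)
    rows = []
    for value in values:
        sweep_seed = int(root.integers(0, 2**31 - 1))
        if vary == "n_sampled":
            model, n_samp = base_model, int(value)
        else:
            model, n_samp = replace(base_model, **{vary: value}), n_sampled
        estimates = replicate_tdiff_estimates(
            model, n_samp, n_reps, seed=sweep_seed, backend=backend
        )
        for rep, est in enumerate(estimates):
            rows.append({"parameter": vary, "value": value,
                         "replicate": rep, "estimate": est})
    return pd.DataFrame(rows)


def sweep_summary(sweep_df):
    """Per-value median and interquartile spread of sweep estimates."""
    g = sweep_df.groupby("value")["estimate"]
    out = g.agg(median="median", q25=lambda s: s.quantile(0.25),
                q75=lambda s: s.quantile(0.75), n="size").reset_index()
    out["iqr"] = out["q75"] - out["q25"]
    return out
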