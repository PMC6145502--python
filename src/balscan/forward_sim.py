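"""Wright-Fisher forward simulation with a selected focal mutation, and the
grid-rejection inference of (selection coefficient, mutation age).

The forward engine shares the demography object with the coalescent engine:
per-generation migration fractions equal the backward lineage-migration
rates, sizes and growth follow the same epochs. A single focal mutation is
introduced at a configurable backward time (its "age") into a configurable
population -- resolved through the split tree, so an age older than a
population's origin places the copy in its ancestor -- and evolves under
genotype fitnesses (1, 1+h*s, 1+s); h = 0.5 is the additive default and an
explicit fitness triple expresses heterozygote advantage.

Two tiers share the same focal-allele dynamics:

* frequency-only: tracks per-population derived counts with deterministic
  selection + migration followed by binomial resampling. This is the grid
  workhorse (microseconds per replicate after early loss exit).
* haplotype-level: additionally carries the full population haplotype
  matrices so linked neutral variation hitchhikes realistically; standing
  variation is initialized from a coalescent sample of the whole population
  at the introduction time (the stationary distribution, orders of
  magnitude faster than a long forward burn-in).

The grid-rejection step mirrors an ABC rejection sampler: enumerate the
Cartesian (s, age) grid, run replicates, and accept replicates whose final
per-population focal frequencies fall within the acceptance rule's
tolerance (percentage points) of the observed frequencies in every
population simultaneously.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from balscan.demography import DemographyConfig
from balscan.panel import GenomicWindow, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class AcceptanceRule:
    """Accept replicates whose focal frequencies approximate the observed ones."""

    observed: dict  # pop -> derived-allele frequency
    tolerance_pp: float = 5.0  # percentage points

    def __post_init__(self) -> None:
        if self.tolerance_pp <= 0:
            raise ValueError("tolerance must be > 0")
        for pop, f in self.observed.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"observed frequency for {pop} outside [0, 1]")

    def accepts(self, freqs: dict) -> bool:
        tol = self.tolerance_pp / 100.0
        return all(
            abs(freqs.get(pop, 0.0) - obs) <= tol for pop, obs in self.observed.items()
        )


@dataclass
class WfResult:
    """Outcome of one forward replicate."""

    final_freqs: dict  # pop -> derived frequency at present
    lost: bool
    fixed: bool  # fixed in every population
    panel: HaplotypePanel | None = None
    trajectory: dict | None = None  # pop -> list[(t, freq)] when recorded


@dataclass
class GridCell:
    """One (s, age) grid point with its replicate outcomes."""

    s: float
    age: float
    n_reps: int
    final_freqs: np.ndarray  # (n_reps, n_pops) in pop order
    pops: list
    lost: np.ndarray
    fixed: np.ndarray
    accepted: np.ndarray

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.age <= 0:
            raise ValueError("mutation age must be > 0")

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())


def _genotype_fitness(s: float, h: float, fitness=None) -> tuple[float, float, float]:
    if fitness is not None:
        w0, w1, w2 = fitness
        if min(w0, w1, w2) <= 0:
            raise ValueError("fitness values must be positive")
        return float(w0), float(w1), float(w2)
    return 1.0, 1.0 + h * s, 1.0 + s


def _selected_freq(p: float, w: tuple[float, float, float]) -> float:
    """Deterministic post-selection derived-allele frequency."""
    if p <= 0.0 or p >= 1.0:
        return p
    w0, w1, w2 = w
    q = 1.0 - p
    wbar = p * p * w2 + 2 * p * q * w1 + q * q * w0
    return (p * p * w2 + p * q * w1) / wbar


def _parent_sources(dem: DemographyConfig, child_pops, t_parent: float) -> dict:
    """For each child population, the (source pop, fraction) parent mixture."""
    ep = dem.epoch_at(t_parent)
    out = {}
    for p in child_pops:
        src = dem.resolve_pop(p, t_parent)
        if src != p:
            out[p] = [(src, 1.0)]
            continue
        mix = []
        away = 0.0
        for (a, b), rate in ep.migration.items():
            if a == p and b in ep.active and rate > 0:
                mix.append((b, rate))
                away += rate
        mix.append((p, 1.0 - away))
        out[p] = mix
    return out


# ---------------------------------------------------------------------------
# frequency-only tier


def _fitness_in(pop: str, w, selected_pops, dem: DemographyConfig, t: float):
    """Genotype fitnesses acting in ``pop`` at backward time t.

    ``selected_pops=None`` applies selection everywhere; otherwise only in
    the listed populations (resolved through the split tree, so selection
    configured for a daughter population also acts in its bottleneck-era
    ancestor when that ancestor is the same deme relabelled).
    """
    if selected_pops is None:
        return w
    for sp in selected_pops:
        try:
            if dem.resolve_pop(sp, t) == pop:
                return w
        except ValueError:
            continue
    return _NEUTRAL_W


_NEUTRAL_W = (1.0, 1.0, 1.0)


def _wf_frequency(
    dem: DemographyConfig,
    w: tuple[float, float, float],
    age: float,
    intro_pop: str,
    intro_count: int,
    rng: np.random.Generator,
    record_trajectory: bool,
    selected_pops=None,
    selection_start: float | None = None,
) -> WfResult:
    t = int(math.ceil(age))
    pop0 = dem.resolve_pop(intro_pop, t)
    sizes = {p: max(1, round(dem.size_at(p, t))) for p in dem.epoch_at(t).active}
    counts = {p: 0 for p in sizes}
    counts[pop0] = min(int(intro_count), 2 * sizes[pop0])
    traj: dict | None = {p: [] for p in dem.pop_names()} if record_trajectory else None
    while t > 0:
        t_child = t - 1
        child_pops = dem.epoch_at(t_child).active
        sources = _parent_sources(dem, child_pops, t)
        new_sizes = {p: max(1, round(dem.size_at(p, t_child))) for p in child_pops}
        new_counts = {}
        any_seg = False
        w_t = w if (selection_start is None or t <= selection_start) else _NEUTRAL_W
        for p in child_pops:
            mean = 0.0
            for src, frac in sources[p]:
                f = counts.get(src, 0) / (2.0 * sizes[src])
                mean += frac * _selected_freq(
                    f, _fitness_in(src, w_t, selected_pops, dem, t)
                )
            n2 = 2 * new_sizes[p]
            c = int(rng.binomial(n2, min(max(mean, 0.0), 1.0)))
            new_counts[p] = c
            if 0 < c:
                any_seg = True
        counts, sizes, t = new_counts, new_sizes, t_child
        if traj is not None:
            for p in counts:
                traj[p].append((t, counts[p] / (2.0 * sizes[p])))
        if not any_seg:
            break  # lost everywhere; frequency stays 0
        if all(counts[p] == 2 * sizes[p] for p in counts):
            break  # fixed everywhere; frequency stays 1
    # roll forward to present with zero frequency if lost early
    present = dem.epoch_at(0.0).active
    final = {
        p: (counts.get(p, 0) / (2.0 * sizes[p]) if p in sizes else 0.0)
        for p in present
    }
    lost = all(f == 0.0 for f in final.values())
    fixed = all(f == 1.0 for f in final.values())
    return WfResult(final_freqs=final, lost=lost, fixed=fixed, trajectory=traj)


# ---------------------------------------------------------------------------
# haplotype tier


class _PopState:
    __slots__ = ("haps",)

    def __init__(self, haps: np.ndarray) -> None:
        self.haps = haps  # (2N, n_sites) int8


def _init_standing_variation(
    dem: DemographyConfig, t0: float, region_length: float, rng: np.random.Generator
):
    """Whole-population haplotypes at backward time t0 from the coalescent."""
    from balscan.coalescent_sim import simulate_sample

    shifted = dem.shifted(t0)
    sizes = {p: max(1, round(shifted.size_at(p, 0.0))) for p in shifted.pop_names()}
    sample = simulate_sample(
        shifted,
        {p: 2 * n for p, n in sizes.items()},
        region_length,
        seed=rng,
    )
    panel = sample.panel
    positions = panel.positions.astype(float)
    states = {}
    for p in sizes:
        rows = panel.rows_for(p)
        states[p] = _PopState(panel.matrix[rows].copy())
    return states, positions, sizes


def _wf_haplotypes(
    dem: DemographyConfig,
    w: tuple[float, float, float],
    age: float,
    intro_pop: str,
    intro_count: int,
    region_length: float,
    sample_sizes: dict,
    rng: np.random.Generator,
    record_trajectory: bool,
    selected_pops=None,
    selection_start: float | None = None,
    stem_age: float | None = None,
    abort_on_loss: bool = False,
) -> WfResult:
    t = int(math.ceil(age))
    L = float(region_length)
    mu, r = dem.mutation_rate, dem.recombination_rate
    states, positions, sizes = _init_standing_variation(dem, t, L, rng)

    # introduce the focal mutation at the region centre
    pop0 = dem.resolve_pop(intro_pop, t)
    focal_pos = L / 2.0 + 0.5  # non-integer: cannot collide with standing sites
    insert_at = int(np.searchsorted(positions, focal_pos))
    positions = np.insert(positions, insert_at, focal_pos)
    for p, st in states.items():
        col = np.zeros((st.haps.shape[0], 1), dtype=np.int8)
        st.haps = np.concatenate(
            [st.haps[:, :insert_at], col, st.haps[:, insert_at:]], axis=1
        )
    focal = insert_at
    carriers = rng.choice(
        states[pop0].haps.shape[0],
        size=min(int(intro_count), states[pop0].haps.shape[0]),
        replace=False,
    )
    states[pop0].haps[carriers, focal] = 1
    if stem_age is not None and stem_age > age:
        # the allele originated stem_age generations ago and persisted at low
        # copy number until the simulated window: the mutations private to
        # that stem lineage ride on the founding haplotype(s)
        n_stem = rng.poisson(mu * L * (stem_age - age))
        stem_pos = np.sort(rng.uniform(0, L, size=n_stem))
        ins = np.searchsorted(positions, stem_pos)
        positions = np.insert(positions, ins, stem_pos)
        for p, st in states.items():
            st.haps = np.insert(st.haps, ins, 0, axis=1)
        focal = int(np.searchsorted(positions, focal_pos))
        for pos in stem_pos:
            j = int(np.searchsorted(positions, pos))
            states[pop0].haps[carriers, j] = 1

    traj: dict | None = {p: [] for p in dem.pop_names()} if record_trajectory else None

    while t > 0:
        t_child = t - 1
        child_pops = dem.epoch_at(t_child).active
        sources = _parent_sources(dem, child_pops, t)
        new_sizes = {p: max(1, round(dem.size_at(p, t_child))) for p in child_pops}
        # parental fitness per source population
        w_t = w if (selection_start is None or t <= selection_start) else _NEUTRAL_W
        fitness = {}
        for p, st in states.items():
            g = st.haps[0::2, focal] + st.haps[1::2, focal]
            fit = np.choose(g, _fitness_in(p, w_t, selected_pops, dem, t))
            fitness[p] = fit / fit.sum()
        new_states = {}
        all_new_muts = []
        for p in child_pops:
            n_gam = 2 * new_sizes[p]
            mix = sources[p]
            src_counts = rng.multinomial(n_gam, [frac for _, frac in mix])
            gametes = []
            for (src, _), cnt in zip(mix, src_counts):
                if cnt == 0:
                    continue
                parents = rng.choice(
                    len(fitness[src]), size=cnt, p=fitness[src], replace=True
                )
                hap_choice = rng.integers(0, 2, size=cnt)
                rows = 2 * parents + hap_choice
                block = states[src].haps[rows]
                # rare crossovers: re-build those gametes from both parent haps
                n_cross = rng.poisson(r * L, size=cnt)
                for k in np.flatnonzero(n_cross):
                    bps = np.sort(rng.uniform(0, L, size=n_cross[k]))
                    h_a = states[src].haps[2 * parents[k] + hap_choice[k]]
                    h_b = states[src].haps[2 * parents[k] + 1 - hap_choice[k]]
                    gam = h_a.copy()
                    use_b = False
                    lo = 0
                    for bp in bps:
                        hi = int(np.searchsorted(positions, bp))
                        if use_b:
                            gam[lo:hi] = h_b[lo:hi]
                        use_b = not use_b
                        lo = hi
                    if use_b:
                        gam[lo:] = h_b[lo:]
                    block[k] = gam
                gametes.append(block)
            child = np.concatenate(gametes, axis=0)
            perm = rng.permutation(child.shape[0])
            child = child[perm]
            n_mut = rng.poisson(n_gam * mu * L)
            muts = [
                (rng.uniform(0, L), p, int(rng.integers(n_gam))) for _ in range(n_mut)
            ]
            all_new_muts.extend(muts)
            new_states[p] = _PopState(child)
        # append this generation's new mutations as fresh columns
        if all_new_muts:
            all_new_muts.sort()
            new_pos = np.array([m[0] for m in all_new_muts])
            insert_idx = np.searchsorted(positions, new_pos)
            positions = np.insert(positions, insert_idx, new_pos)
            focal = int(np.searchsorted(positions, focal_pos))
            for p, st in new_states.items():
                st.haps = np.insert(st.haps, insert_idx, 0, axis=1)
            for col_offset, (pos, p, row) in enumerate(all_new_muts):
                j = int(np.searchsorted(positions, pos))
                new_states[p].haps[row, j] = 1
        states, sizes, t = new_states, new_sizes, t_child
        if abort_on_loss and not any(
            st.haps[:, focal].any() for st in states.values()
        ):
            final = {p: 0.0 for p in states}
            return WfResult(
                final_freqs=final, lost=True, fixed=False, panel=None,
                trajectory=traj,
            )
        if traj is not None:
            for p, st in states.items():
                traj[p].append((t, float(st.haps[:, focal].mean())))
        # periodic cleanup of globally lost / globally fixed columns
        if t % 32 == 0 and positions.size:
            tot = sum(st.haps.sum(axis=0) for st in states.values())
            n_all = sum(st.haps.shape[0] for st in states.values())
            keep = (tot > 0) & (tot < n_all)
            keep[focal] = True
            if not keep.all():
                positions = positions[keep]
                for st in states.values():
                    st.haps = st.haps[:, keep]
                focal = int(np.flatnonzero(np.isclose(positions, focal_pos))[0])

    final = {p: float(st.haps[:, focal].mean()) for p, st in states.items()}
    lost = all(f == 0.0 for f in final.values())
    fixed = all(f == 1.0 for f in final.values())
    panel = _sample_panel(states, positions, focal, sample_sizes, L, rng)
    return WfResult(
        final_freqs=final, lost=lost, fixed=fixed, panel=panel, trajectory=traj
    )


def _sample_panel(
    states: dict,
    positions: np.ndarray,
    focal: int,
    sample_sizes: dict,
    region_length: float,
    rng: np.random.Generator,
) -> HaplotypePanel:
    """Draw diploid individuals per population and assemble a panel."""
    rows, pops = [], []
    for p, n_hap in sample_sizes.items():
        if n_hap % 2:
            raise ValueError("per-population sample sizes must be even (diploids)")
        n_ind_avail = states[p].haps.shape[0] // 2
        ids = rng.choice(n_ind_avail, size=n_hap // 2, replace=False)
        for i in ids:
            rows.append(states[p].haps[2 * i])
            rows.append(states[p].haps[2 * i + 1])
            pops.extend([p, p])
    matrix = np.stack(rows)
    # keep sites segregating in the sample, plus the focal column
    tot = matrix.sum(axis=0)
    keep = (tot > 0) & (tot < matrix.shape[0])
    keep[focal] = True
    matrix = matrix[:, keep]
    kept_pos = positions[keep]
    focal_new = int(np.flatnonzero(np.flatnonzero(keep) == focal)[0])
    # discretize to unique integer bp
    int_pos, prev = [], 0
    keep2 = []
    for k, pos in enumerate(kept_pos):
        bp = max(int(math.floor(pos)) + 1, prev + 1)
        if bp > region_length and k != focal_new:
            keep2.append(False)
            continue
        prev = bp
        int_pos.append(bp)
        keep2.append(True)
    keep2 = np.array(keep2, dtype=bool)
    matrix = matrix[:, keep2]
    focal_new = int(keep2[:focal_new].sum())
    return HaplotypePanel(
        matrix=matrix,
        positions=np.array(int_pos, dtype=np.int64),
        populations=np.array(pops, dtype=object),
        chrom="sim",
        region_length=int(region_length),
        focal_index=focal_new,
    )


def wf_simulate(
    demography: DemographyConfig,
    s: float,
    age: float,
    region_length: float = 10_000,
    seed: int | np.random.Generator | None = None,
    sample_sizes: dict | None = None,
    h: float = 0.5,
    fitness: tuple[float, float, float] | None = None,
    intro_pop: str = "EUR",
    intro_count: int = 1,
    record_trajectory: bool = False,
    selected_pops=None,
    selection_start: float | None = None,
    stem_age: float | None = None,
    abort_on_loss: bool = False,
) -> WfResult:
    """One forward replicate: focal mutation of age ``age`` under selection ``s``.

    With ``sample_sizes=None`` only the focal-allele frequency trajectory is
    simulated; passing per-population haplotype counts switches on the full
    haplotype-level engine and returns a sampled panel for statistic
    computation. ``selected_pops`` restricts selection to the listed
    populations (environment-dependent fitness); default is selection
    everywhere. ``selection_start`` delays the onset of selection to that
    backward time, so an allele can segregate neutrally before the selective
    regime begins. Note that any age > 0 is valid: the root epoch extends
    indefinitely, and a focal population is resolved to its ancestor at
    times before its origin. ``stem_age`` (haplotype tier only) declares the
    allele's true origin earlier than the simulated window: the mutations
    private to the intervening low-frequency stem lineage are placed on the
    founding haplotype(s), the coalescent equivalent of simulating the
    latent phase explicitly (their linkage at onset is complete, a slight
    overstatement the stem's own recombination would erode).
    """
    if s < 0:
        raise ValueError("selection coefficient must be >= 0 (use fitness= for "
                         "heterozygote advantage)")
    if age <= 0:
        raise ValueError("mutation age must be > 0 generations")
    demography.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = _genotype_fitness(s, h, fitness)
    if sample_sizes is None:
        return _wf_frequency(
            demography, w, age, intro_pop, intro_count, rng, record_trajectory,
            selected_pops=selected_pops, selection_start=selection_start,
        )
    return _wf_haplotypes(
        demography, w, age, intro_pop, intro_count, region_length,
        sample_sizes, rng, record_trajectory, selected_pops=selected_pops,
        selection_start=selection_start, stem_age=stem_age,
        abort_on_loss=abort_on_loss,
    )


# ---------------------------------------------------------------------------
# grid rejection


def grid_values(grid: tuple[float, float, float]) -> np.ndarray:
    """Inclusive arithmetic grid (min, max, step), robust to float step."""
    lo, hi, step = grid
    if step <= 0 or hi < lo:
        raise ValueError("grid must be (min, max, step) with step > 0 and max >= min")
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 12)


def scheduled_simulations(
    s_grid: tuple[float, float, float],
    age_grid: tuple[float, float, float],
    n_reps: int,
) -> int:
    """Bookkeeping: total replicates the full grid schedules."""
    return len(grid_values(s_grid)) * len(grid_values(age_grid)) * int(n_reps)


def grid_rejection_inference(
    demography: DemographyConfig,
    s_grid: tuple[float, float, float],
    age_grid: tuple[float, float, float],
    n_reps: int,
    rule: AcceptanceRule,
    seed: int | None = None,
    intro_pop: str = "EUR",
    h: float = 0.5,
) -> list[GridCell]:
    """Run the full Cartesian (s, age) grid and mark accepted replicates.

    Each cell runs ``n_reps`` independent frequency-tier replicates; a
    replicate is accepted when its final focal frequency is within the
    rule's tolerance of the observed frequency in every population
    simultaneously (lost and fixed replicates fail that test except under
    vacuously wide tolerances).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    s_vals, age_vals = grid_values(s_grid), grid_values(age_grid)
    present = demography.epoch_at(0.0).active
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(s_vals) * len(age_vals))
    cells: list[GridCell] = []
    k = 0
    for s in s_vals:
        for age in age_vals:
            rng = np.random.default_rng(children[k])
            k += 1
            freqs = np.empty((n_reps, len(present)))
            lost = np.empty(n_reps, dtype=bool)
            fixed = np.empty(n_reps, dtype=bool)
            accepted = np.empty(n_reps, dtype=bool)
            for rep in range(n_reps):
                res = wf_simulate(
                    demography, float(s), float(age), seed=rng,
                    intro_pop=intro_pop, h=h,
                )
                freqs[rep] = [res.final_freqs[p] for p in present]
                lost[rep], fixed[rep] = res.lost, res.fixed
                accepted[rep] = rule.accepts(res.final_freqs)
            cells.append(
                GridCell(
                    s=float(s), age=float(age), n_reps=n_reps,
                    final_freqs=freqs, pops=list(present),
                    lost=lost, fixed=fixed, accepted=accepted,
                )
            )
    if not any(c.n_accepted for c in cells):
        warnings.warn("grid rejection accepted no replicates", stacklevel=2)
    return cells


def sample_accepted_panels(
    demography: DemographyConfig,
    cells: list,
    rule: AcceptanceRule,
    sample_sizes: dict,
    region_length: float,
    max_panels: int = 20,
    seed: int | None = None,
    intro_pop: str = "EUR",
    h: float = 0.5,
    max_attempts_per_cell: int = 50,
) -> list[HaplotypePanel]:
    """Haplotype-level panels for accepted grid cells.

    Re-runs the forward engine with full haplotype tracking at (s, age)
    values of cells that had acceptances, keeping replicates that again
    satisfy the acceptance rule, until ``max_panels`` panels are collected.
    """
    rng = np.random.default_rng(seed)
    pool = [c for c in cells if c.n_accepted > 0]
    if not pool:
        raise ValueError("no accepted cells to draw panels from")
    weights = np.array([c.n_accepted for c in pool], dtype=float)
    panels: list[HaplotypePanel] = []
    attempts = 0
    budget = max_attempts_per_cell * len(pool)
    while len(panels) < max_panels and attempts < budget:
        attempts += 1
        cell = pool[rng.choice(len(pool), p=weights / weights.sum())]
        res = wf_simulate(
            demography, cell.s, cell.age, region_length=region_length,
            seed=rng, sample_sizes=sample_sizes, intro_pop=intro_pop, h=h,
        )
        if rule.accepts(res.final_freqs):
            panels.append(res.panel)
    if not panels:
        warnings.warn("no haplotype replicate re-satisfied the rule", stacklevel=2)
    return panels


def accepted_statistics(panels: list) -> dict:
    """Tajima's D (window = whole region) and focal nSL per population.

    Returns {pop: {"tajima_d": array, "nsl": array, "quantiles": {...}}};
    replicates whose focal SNP is monomorphic in a population are excluded
    from that population's nSL distribution and logged.
    """
    from balscan.haplotype_scan import nsl_unstandardized
    from balscan.sfs_scan import tajimas_d_components

    if not panels:
        raise ValueError("empty accepted set")
    pops = panels[0].population_names()
    out = {p: {"tajima_d": [], "nsl": []} for p in pops}
    n_mono = 0
    for panel in panels:
        if panel.focal_index is None:
            raise ValueError("accepted panels must designate a focal SNP")
        win = GenomicWindow(panel.chrom, 0, panel.region_length)
        for p in pops:
            st = tajimas_d_components(panel, win, population=p)
            if st.defined:
                out[p]["tajima_d"].append(st.tajima_d)
            res = nsl_unstandardized(panel, panel.focal_index, population=p)
            if res.defined:
                out[p]["nsl"].append(res.nsl)
            else:
                n_mono += 1
    if n_mono:
        logger.info(
            "accepted_statistics: %d population-replicates had an undefined "
            "focal nSL (monomorphic or near-monomorphic focal)", n_mono,
        )
    result = {}
    for p in pops:
        td = np.array(out[p]["tajima_d"])
        ns = np.array(out[p]["nsl"])
        result[p] = {
            "tajima_d": td,
            "nsl": ns,
            "quantiles": {
                stat: (
                    dict(zip((5, 25, 50, 75, 95),
                             np.percentile(vals, (5, 25, 50, 75, 95))))
                    if vals.size else {}
                )
                for stat, vals in (("tajima_d", td), ("nsl", ns))
            },
        }
    return result
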