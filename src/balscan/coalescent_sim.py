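"""Structured-coalescent simulation under a configurable demography.

The engine runs the ancestral process backward in time over the epochs of a
:class:`~balscan.demography.DemographyConfig`: lineages coalesce within
demes at rate k(k-1)/(4N_p(t)) per generation (with the exponential-growth
inhomogeneity handled by closed-form inversion of the cumulative hazard),
migrate between demes at the configured backward rates, and recombine along
the sequence following Hudson's ancestral-recombination-graph construction
-- each lineage carries its intervals of ancestral material, a
recombination event splits a lineage at a uniform breakpoint inside its
material span, and a coalescence merges material. Sequence intervals whose
ancestral material has reached the sample MRCA are retired, so the process
ends when no active material remains.

Mutation follows the infinite-sites model on the continuous interval:
mutations rain onto ancestral material with intensity mu per bp per
generation and are discretized to integer positions when the haplotype
panel is assembled. One coalescent time unit of the classic scaling equals
2N generations here; the engine works directly in generations to keep the
demography's units unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from balscan.demography import DemographyConfig
from balscan.panel import HaplotypePanel


@dataclass
class CoalescentSample:
    """A simulated panel plus its genealogical metadata."""

    panel: HaplotypePanel
    mutation_ages: np.ndarray  # generations, aligned with panel columns
    tmrca: float  # generations; grand MRCA time over the region
    seed: int | None

    def __post_init__(self) -> None:
        if self.mutation_ages.size and self.tmrca < self.mutation_ages.max() - 1e-9:
            raise ValueError("TMRCA must be >= every mutation age")


@dataclass
class _Lineage:
    pop: str
    segments: list  # [ [left, right, mask], ... ] sorted, disjoint
    birth: float = 0.0

    def material(self) -> float:
        return sum(s[1] - s[0] for s in self.segments)

    def span(self) -> tuple[float, float]:
        return self.segments[0][0], self.segments[-1][1]


def _merge_segment_lists(sa: list, sb: list, full_mask: int):
    """Union two ancestral-material segment lists.

    Returns (merged_segments, mrca_intervals): overlapping material gets the
    union of descendant sets; intervals whose union covers the whole sample
    have found their MRCA and are retired.
    """
    bounds = sorted({x for seg in sa for x in (seg[0], seg[1])}
                    | {x for seg in sb for x in (seg[0], seg[1])})
    merged: list = []
    mrca: list = []
    ia = ib = 0
    for x0, x1 in zip(bounds, bounds[1:]):
        while ia < len(sa) and sa[ia][1] <= x0:
            ia += 1
        while ib < len(sb) and sb[ib][1] <= x0:
            ib += 1
        m = 0
        if ia < len(sa) and sa[ia][0] <= x0:
            m |= sa[ia][2]
        if ib < len(sb) and sb[ib][0] <= x0:
            m |= sb[ib][2]
        if m == 0:
            continue
        if m == full_mask:
            mrca.append((x0, x1))
        elif merged and merged[-1][1] == x0 and merged[-1][2] == m:
            merged[-1][1] = x1
        else:
            merged.append([x0, x1, m])
    return merged, mrca


class CoalescentEngine:
    """One realization of the structured ancestral process.

    Parameters
    ----------
    record_branches
        Store every (descendant set, birth time, death time) branch of the
        genealogy; only available on the no-recombination fast path, where
        a lineage's descendant set is constant over its lifetime.
    """

    def __init__(
        self,
        demography: DemographyConfig,
        sample_sizes: dict,
        region_length: float,
        rng: np.random.Generator,
        mutation_rate: float | None = None,
        recombination_rate: float | None = None,
        record_branches: bool = False,
    ) -> None:
        demography.validate()
        self.dem = demography
        self.L = float(region_length)
        if self.L <= 0:
            raise ValueError("region_length must be > 0")
        self.rng = rng
        self.mu = demography.mutation_rate if mutation_rate is None else mutation_rate
        self.r = (
            demography.recombination_rate
            if recombination_rate is None
            else recombination_rate
        )
        if record_branches and self.r > 0:
            raise ValueError(
                "branch recording requires the no-recombination fast path"
            )
        self.record_branches = record_branches
        self.sample_sizes = dict(sample_sizes)
        self.n_total = int(sum(self.sample_sizes.values()))
        if self.n_total < 2:
            raise ValueError("total sample size must be >= 2")
        self.full_mask = (1 << self.n_total) - 1
        self.sample_pops: list[str] = []
        self.lineages: list[_Lineage] = []
        idx = 0
        ep0 = demography.epoch_at(0.0)
        for pop, n in self.sample_sizes.items():
            if n < 0:
                raise ValueError("sample sizes must be >= 0")
            if n and pop not in ep0.active:
                raise ValueError(f"population {pop} not active at present")
            for _ in range(int(n)):
                self.lineages.append(
                    _Lineage(pop=pop, segments=[[0.0, self.L, 1 << idx]])
                )
                self.sample_pops.append(pop)
                idx += 1
        self.mutations: list = []  # (continuous pos, mask, age)
        self.branches: list = []  # (mask, birth, death) when recording
        self.tmrca = 0.0
        self.time = 0.0

    # -- event-time sampling ----------------------------------------------

    def _coal_time(self, k: int, size0: float, growth: float) -> float:
        """Waiting time to the next coalescence in one deme.

        The pair rate at lag u is R0 * exp(g*u) with R0 = k(k-1)/(4 N(t));
        the cumulative hazard inverts in closed form.
        """
        if k < 2:
            return math.inf
        r0 = k * (k - 1) / (4.0 * size0)
        e = self.rng.exponential()
        if growth == 0.0:
            return e / r0
        val = 1.0 + growth * e / r0
        if val <= 0.0:
            return math.inf
        return math.log(val) / growth

    # -- mutation overlay --------------------------------------------------

    def _overlay_mutations(self, t0: float, t1: float) -> None:
        if self.mu is None or self.mu <= 0 or not self.lineages:
            return
        weights = np.array([lin.material() for lin in self.lineages])
        total = weights.sum()
        if total <= 0:
            return
        n_mut = self.rng.poisson(self.mu * total * (t1 - t0))
        for _ in range(n_mut):
            lin = self.lineages[self.rng.choice(len(self.lineages), p=weights / total)]
            seg_w = np.array([s[1] - s[0] for s in lin.segments])
            seg = lin.segments[self.rng.choice(len(lin.segments), p=seg_w / seg_w.sum())]
            pos = self.rng.uniform(seg[0], seg[1])
            age = self.rng.uniform(t0, t1)
            self.mutations.append((pos, seg[2], age))

    # -- event application -------------------------------------------------

    def _coalesce(self, pop: str, t: float) -> None:
        idxs = [i for i, lin in enumerate(self.lineages) if lin.pop == pop]
        i, j = self.rng.choice(len(idxs), size=2, replace=False)
        a, b = self.lineages[idxs[i]], self.lineages[idxs[j]]
        merged, mrca = _merge_segment_lists(a.segments, b.segments, self.full_mask)
        if self.record_branches:
            self.branches.append((a.segments[0][2], a.birth, t))
            self.branches.append((b.segments[0][2], b.birth, t))
        if mrca:
            self.tmrca = max(self.tmrca, t)
        for k in sorted((idxs[i], idxs[j]), reverse=True):
            del self.lineages[k]
        if merged:
            self.lineages.append(_Lineage(pop=pop, segments=merged, birth=t))

    def _recombine(self, lineage_idx: int, t: float) -> None:
        lin = self.lineages[lineage_idx]
        lo, hi = lin.span()
        bp = self.rng.uniform(lo, hi)
        left, right = [], []
        for seg in lin.segments:
            if seg[1] <= bp:
                left.append(seg)
            elif seg[0] >= bp:
                right.append(seg)
            else:
                left.append([seg[0], bp, seg[2]])
                right.append([bp, seg[1], seg[2]])
        if not left or not right:  # breakpoint grazed an edge; no-op
            return
        del self.lineages[lineage_idx]
        self.lineages.append(_Lineage(pop=lin.pop, segments=left, birth=t))
        self.lineages.append(_Lineage(pop=lin.pop, segments=right, birth=t))

    # -- main loop ---------------------------------------------------------

    def run(self, max_events: int = 10_000_000) -> None:
        epochs = self.dem.epochs()
        ep_idx = 0
        for _ in range(max_events):
            if not self.lineages:
                return
            ep = epochs[ep_idx]
            # pop counts
            counts: dict[str, int] = {}
            for lin in self.lineages:
                counts[lin.pop] = counts.get(lin.pop, 0) + 1
            # candidate waiting times
            best_dt, best_kind, best_arg = math.inf, None, None
            for pop, k in counts.items():
                dt = self._coal_time(k, ep.size_at(pop, self.time), ep.growth[pop])
                if dt < best_dt:
                    best_dt, best_kind, best_arg = dt, "coal", pop
            out_rate = {
                p: sum(
                    rate
                    for (a, b), rate in ep.migration.items()
                    if a == p and b in ep.active and rate > 0
                )
                for p in counts
            }
            m_tot = sum(counts[p] * out_rate[p] for p in counts)
            if m_tot > 0:
                dt = self.rng.exponential() / m_tot
                if dt < best_dt:
                    best_dt, best_kind, best_arg = dt, "mig", None
            if self.r > 0:
                spans = [lin.span() for lin in self.lineages]
                weights = np.array([hi - lo for lo, hi in spans])
                r_tot = self.r * weights.sum()
                if r_tot > 0:
                    dt = self.rng.exponential() / r_tot
                    if dt < best_dt:
                        best_dt, best_kind, best_arg = (
                            dt,
                            "rec",
                            int(self.rng.choice(len(self.lineages),
                                                p=weights / weights.sum())),
                        )
            event_time = self.time + best_dt
            if best_dt is math.inf and ep.next_time is math.inf:
                raise RuntimeError(
                    "lineages can no longer coalesce (no events possible in the "
                    "oldest epoch); check the demography"
                )
            if event_time >= ep.next_time:
                # advance to the epoch boundary and apply demographic change
                self._overlay_mutations(self.time, ep.next_time)
                self.time = ep.next_time
                ep_idx += 1
                nxt = epochs[ep_idx]
                for lin in self.lineages:
                    if lin.pop not in nxt.active:
                        lin.pop = nxt.merged_into[lin.pop]
                        while lin.pop not in nxt.active:
                            lin.pop = nxt.merged_into[lin.pop]
                continue
            self._overlay_mutations(self.time, event_time)
            self.time = event_time
            if best_kind == "coal":
                self._coalesce(best_arg, event_time)
            elif best_kind == "mig":
                w = np.array([counts[p] * out_rate[p] for p in counts], dtype=float)
                pops = list(counts)
                src = pops[self.rng.choice(len(pops), p=w / w.sum())]
                cand = [i for i, lin in enumerate(self.lineages) if lin.pop == src]
                lin = self.lineages[cand[self.rng.integers(len(cand))]]
                dests, rates = [], []
                for (a, b), rate in ep.migration.items():
                    if a == src and b in ep.active and rate > 0:
                        dests.append(b)
                        rates.append(rate)
                rates = np.array(rates)
                lin.pop = dests[self.rng.choice(len(dests), p=rates / rates.sum())]
            else:
                self._recombine(best_arg, event_time)
        raise RuntimeError("coalescent did not complete (event budget exhausted)")

    # -- output ------------------------------------------------------------

    def build_panel(self, chrom: str = "sim") -> tuple[HaplotypePanel, np.ndarray]:
        """Assemble the panel, discretizing continuous positions to bp.

        Sites are sorted by position and assigned the next free integer bp
        (collisions are nudged to the adjacent free base, which preserves
        linkage structure); sites pushed past the region end are dropped.
        """
        muts = sorted(self.mutations)
        cols, positions, ages = [], [], []
        prev_bp = 0
        for pos, mask, age in muts:
            bp = max(int(math.floor(pos)) + 1, prev_bp + 1)
            if bp > self.L:
                continue
            prev_bp = bp
            col = np.fromiter(
                ((mask >> i) & 1 for i in range(self.n_total)),
                dtype=np.int8,
                count=self.n_total,
            )
            cols.append(col)
            positions.append(bp)
            ages.append(age)
        matrix = (
            np.column_stack(cols)
            if cols
            else np.empty((self.n_total, 0), dtype=np.int8)
        )
        panel = HaplotypePanel(
            matrix=matrix,
            positions=np.array(positions, dtype=np.int64),
            populations=np.array(self.sample_pops, dtype=object),
            chrom=chrom,
            region_length=int(self.L),
        )
        return panel, np.array(ages)


def simulate_sample(
    demography: DemographyConfig,
    sample_sizes: dict,
    region_length: float,
    seed: int | np.random.Generator | None = None,
    mutation_rate: float | None = None,
    recombination_rate: float | None = None,
) -> CoalescentSample:
    """Simulate one neutral sample of haplotypes under the demography.

    ``sample_sizes`` maps population name to haplotype count. Mutation and
    recombination rates default to the demography's values; pass 0 for the
    no-recombination fast path.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eng = CoalescentEngine(
        demography,
        sample_sizes,
        region_length,
        rng,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
    )
    eng.run()
    panel, ages = eng.build_panel()
    return CoalescentSample(
        panel=panel,
        mutation_ages=ages,
        tmrca=eng.tmrca,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class NullDistribution:
    """Per-population neutral Tajima's D values and their percentile threshold."""

    values: dict  # pop -> np.ndarray of defined D values
    thresholds: dict  # pop -> float
    percentile: float
    n_reps: int


def null_tajima_distribution(
    demography: DemographyConfig,
    sample_sizes: dict,
    window: int,
    n_reps: int,
    seed: int | None = None,
    percentile: float = 0.95,
) -> NullDistribution:
    """Neutral null distribution of windowed Tajima's D per population.

    Simulates ``n_reps`` independent windows under the demography, computes
    each population's D over the whole window, and returns the empirical
    distributions with their upper-percentile thresholds.
    """
    from balscan.panel import GenomicWindow
    from balscan.sfs_scan import empirical_threshold, tajimas_d_components

    if n_reps < 100:
        raise ValueError("need at least 100 replicates for a stable percentile")
    rng = np.random.default_rng(seed)
    values: dict[str, list] = {p: [] for p in sample_sizes}
    for _ in range(n_reps):
        samp = simulate_sample(demography, sample_sizes, window, seed=rng)
        win = GenomicWindow(samp.panel.chrom, 0, window)
        for pop in sample_sizes:
            st = tajimas_d_components(samp.panel, win, population=pop)
            if st.defined:
                values[pop].append(st.tajima_d)
    arr = {p: np.array(v) for p, v in values.items()}
    thresholds = {p: empirical_threshold(v, percentile) for p, v in arr.items()}
    return NullDistribution(
        values=arr, thresholds=thresholds, percentile=percentile, n_reps=n_reps
    )


@dataclass
class AlleleAgeEstimate:
    """Conditional age / TMRCA estimate from accepted genealogies."""

    age_mean: float  # generations
    age_se: float
    tmrca_mean: float
    tmrca_se: float
    generation_time: float
    n_accepted: int
    n_attempts: int

    @property
    def age_years(self) -> float:
        return self.age_mean * self.generation_time

    @property
    def age_se_years(self) -> float:
        return self.age_se * self.generation_time

    @property
    def tmrca_years(self) -> float:
        return self.tmrca_mean * self.generation_time


def conditional_allele_age(
    demography: DemographyConfig,
    sample_sizes: dict,
    observed_derived_count: dict,
    n_accepted: int = 200,
    seed: int | None = None,
    match: str = "per_population",
    max_attempts: int = 2_000_000,
) -> AlleleAgeEstimate:
    """Rejection-sampling estimate of a derived allele's age and sample TMRCA.

    Simulates neutral genealogies (no recombination: the single-locus
    assumption), places a mutation uniformly on the branches whose
    descendant sets match the observed configuration -- exactly per
    population, or summed over populations with ``match="total"`` -- and
    accepts each genealogy with probability proportional to its matching
    branch length. That is the low-mutation-rate conditional distribution
    of genealogies given that a segregating mutation with the observed
    count was seen: under infinite sites the chance a genealogy shows such
    a mutation is proportional to the branch length able to carry it. (A
    pilot batch calibrates the proportionality cap; genealogies exceeding
    it -- a vanishing tail -- are accepted outright.) Reports the mean and
    standard error of mutation age and TMRCA over accepted genealogies, in
    generations; years follow from the demography's generation time.
    """
    total_obs = int(sum(observed_derived_count.values()))
    n_total = int(sum(sample_sizes.values()))
    if not (0 < total_obs < n_total):
        raise ValueError("derived count must be strictly between 0 and the sample size")
    if match not in ("per_population", "total"):
        raise ValueError("match must be 'per_population' or 'total'")
    rng = np.random.default_rng(seed)
    # bit offset per population, in sample_sizes order
    offsets = {}
    off = 0
    for pop, n in sample_sizes.items():
        offsets[pop] = off
        off += int(n)

    def one_genealogy():
        eng = CoalescentEngine(
            demography,
            sample_sizes,
            region_length=1.0,
            rng=rng,
            mutation_rate=0.0,
            recombination_rate=0.0,
            record_branches=True,
        )
        eng.run()
        matching = []
        for mask, birth, death in eng.branches:
            if mask.bit_count() != total_obs:
                continue
            if match == "per_population":
                ok = all(
                    ((mask >> offsets[pop]) & ((1 << int(n)) - 1)).bit_count()
                    == int(observed_derived_count.get(pop, 0))
                    for pop, n in sample_sizes.items()
                )
                if not ok:
                    continue
            matching.append((birth, death, death - birth))
        return matching, eng.tmrca

    # pilot: calibrate the acceptance cap from matching-length magnitudes
    pilot_w, attempts = [], 0
    n_pilot = max(50, n_accepted // 4)
    while len(pilot_w) < n_pilot and attempts < max_attempts // 4:
        attempts += 1
        matching, _ = one_genealogy()
        if matching:
            pilot_w.append(sum(m[2] for m in matching))
    if not pilot_w:
        raise RuntimeError(
            f"no genealogy produced a matching branch in {attempts} attempts; "
            "consider match='total'"
        )
    cap = 3.0 * max(pilot_w)

    ages, tmrcas = [], []
    while len(ages) < n_accepted:
        if attempts >= max_attempts:
            rate = len(ages) / max(attempts, 1)
            if rate < 1e-6 or not ages:
                raise RuntimeError(
                    f"acceptance rate {rate:.2e} too low after {attempts} attempts; "
                    "consider match='total' or a larger tolerance"
                )
            break
        attempts += 1
        matching, tmrca = one_genealogy()
        if not matching:
            continue
        w = sum(m[2] for m in matching)
        if rng.uniform() >= min(1.0, w / cap):
            continue
        weights = np.array([m[2] for m in matching])
        birth, death, _ = matching[rng.choice(len(matching), p=weights / weights.sum())]
        ages.append(rng.uniform(birth, death))
        tmrcas.append(tmrca)

    ages_a, tm_a = np.array(ages), np.array(tmrcas)
    return AlleleAgeEstimate(
        age_mean=float(ages_a.mean()),
        age_se=float(ages_a.std(ddof=1) / math.sqrt(len(ages_a))) if len(ages_a) > 1 else math.nan,
        tmrca_mean=float(tm_a.mean()),
        tmrca_se=float(tm_a.std(ddof=1) / math.sqrt(len(tm_a))) if len(tm_a) > 1 else math.nan,
        generation_time=demography.generation_time,
        n_accepted=len(ages_a),
        n_attempts=attempts,
    )
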