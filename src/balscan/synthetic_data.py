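"""Synthetic haplotype panels with controlled focal-SNP frequencies.

Generates the study's input data shapes without any download: three
populations with a shared out-of-Africa-style split history, a designated
biallelic focal SNP whose per-population derived-allele frequency is
conditioned to a target (differentiated like the motivating variant:
single-digit percent in the African population, tens of percent outside),
surrounded by linked neutral polymorphism, plus independent neutral
genome-background windows for empirical null distributions.

Neutral panels come from the structured-coalescent engine; partial-sweep
and balancing panels come from the forward engine (additive selection, or
heterozygote advantage for balancing). Focal-frequency conditioning is by
exact stratified sampling: the simulated population is rejection-sampled on
a broad viability window, then the panel's haplotypes are drawn stratified
by focal allele class, which is the conditional distribution of a random
sample given its focal count and hits the target to sampling granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from balscan.demography import DemographyConfig, toy_ooa
from balscan.panel import HaplotypePanel

_SCENARIOS = ("neutral", "partial_sweep", "balancing")


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic panel.

    Default target frequencies (AFR 0.07, EUR 0.45, ASN 0.30) sit inside
    the frequency ranges the analysis is designed around; they are
    illustrative conditions, not ground truth. The default demography is
    the desk-scale ``toy_ooa`` preset.
    """

    scenario_name: str = "neutral"
    sample_sizes: dict = field(
        default_factory=lambda: {"AFR": 50, "EUR": 50, "ASN": 50}
    )
    target_freqs: dict = field(
        default_factory=lambda: {"AFR": 0.07, "EUR": 0.45, "ASN": 0.30}
    )
    region_length: int = 20_000
    mutation_rate: float | None = None  # None: demography default
    recombination_rate: float | None = None
    seed: int = 0
    demography: DemographyConfig | None = None
    # selection parameters (forward scenarios)
    selection_coefficient: float | None = None  # scenario default when None
    dominance: float = 0.5
    mutation_age: float | None = None
    selection_start: float | None = None  # onset of selection; scenario default
    intro_pop: str = "EUR"
    intro_count: int | None = None  # founding copies; scenario default when None
    selected_pops: tuple | None = None  # scenario default when None
    focal_tolerance: float = 0.02  # max |realized - target| per population
    pool_window: float = 0.20  # population-frequency viability window
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.scenario_name not in _SCENARIOS:
            raise ValueError(f"scenario_name must be one of {_SCENARIOS}")
        if self.region_length <= 0:
            raise ValueError("region_length must be > 0")
        for pop, n in self.sample_sizes.items():
            if n < 2:
                raise ValueError(f"sample size for {pop} must be >= 2")
            if n % 2:
                raise ValueError(f"sample size for {pop} must be even (diploids)")
        for pop, f in self.target_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"target frequency for {pop} outside [0, 1]")

    def resolved_demography(self) -> DemographyConfig:
        dem = self.demography
        if dem is None:
            dem = toy_ooa()
        elif isinstance(dem, str):
            from balscan.demography import _load_preset, load_demography

            try:
                dem = _load_preset(dem)
            except FileNotFoundError:
                dem = load_demography(dem)
        if self.mutation_rate is not None or self.recombination_rate is not None:
            import copy

            dem = copy.deepcopy(dem)
            if self.mutation_rate is not None:
                dem.mutation_rate = self.mutation_rate
            if self.recombination_rate is not None:
                dem.recombination_rate = self.recombination_rate
        return dem


class FrequencyTargetError(RuntimeError):
    """Raised when focal-frequency targets cannot be met."""


def _target_counts(spec: ScenarioSpec) -> dict:
    """Per-population derived counts realizing the targets, or raise."""
    counts = {}
    for pop, n in spec.sample_sizes.items():
        target = spec.target_freqs.get(pop, 0.0)
        k = round(n * target)
        if abs(k / n - target) > spec.focal_tolerance:
            raise FrequencyTargetError(
                f"target {target:.3f} for {pop} unattainable with n={n} "
                f"(granularity 1/{n} exceeds tolerance {spec.focal_tolerance})"
            )
        counts[pop] = int(k)
    return counts


def _stratified_rows(
    pool_col: np.ndarray, rows: np.ndarray, k: int, n: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Sample k derived and n-k ancestral haplotype rows, or None if short."""
    derived = rows[pool_col[rows] == 1]
    ancestral = rows[pool_col[rows] == 0]
    if derived.size < k or ancestral.size < n - k:
        return None
    pick_d = rng.choice(derived, size=k, replace=False)
    pick_a = rng.choice(ancestral, size=n - k, replace=False)
    out = np.concatenate([pick_d, pick_a])
    rng.shuffle(out)
    return out


def _assemble(
    matrix: np.ndarray,
    positions: np.ndarray,
    focal_col: int,
    spec: ScenarioSpec,
    row_pops: list,
) -> HaplotypePanel:
    """Restrict to segregating-in-sample columns (keeping focal) and build."""
    tot = matrix.sum(axis=0)
    keep = (tot > 0) & (tot < matrix.shape[0])
    keep[focal_col] = True
    matrix = matrix[:, keep]
    positions = positions[keep]
    focal_new = int(keep[:focal_col].sum())
    return HaplotypePanel(
        matrix=matrix,
        positions=positions,
        populations=np.array(row_pops, dtype=object),
        chrom="sim",
        region_length=spec.region_length,
        focal_index=focal_new,
    )


def _neutral_panel(spec: ScenarioSpec, rng: np.random.Generator) -> HaplotypePanel:
    from balscan.coalescent_sim import simulate_sample

    dem = spec.resolved_demography()
    counts = _target_counts(spec)
    all_zero = all(k == 0 for k in counts.values())
    if all_zero:
        samp = simulate_sample(dem, spec.sample_sizes, spec.region_length, seed=rng)
        panel = samp.panel
        # insert an explicitly monomorphic-ancestral focal column at the centre
        centre = spec.region_length // 2
        j = int(np.searchsorted(panel.positions, centre))
        matrix = np.insert(panel.matrix, j, 0, axis=1)
        positions = np.insert(panel.positions, j, centre)
        if j + 1 < positions.size and positions[j + 1] == centre:
            positions[j] = centre - 1
        return HaplotypePanel(
            matrix=matrix,
            positions=positions,
            populations=panel.populations,
            chrom=panel.chrom,
            region_length=spec.region_length,
            focal_index=j,
        )
    pool_sizes = {p: 4 * n for p, n in spec.sample_sizes.items()}
    for _ in range(spec.max_attempts):
        samp = simulate_sample(dem, pool_sizes, spec.region_length, seed=rng)
        panel = samp.panel
        if panel.n_sites == 0:
            continue
        rows_by_pop = {p: panel.rows_for(p) for p in spec.sample_sizes}
        # candidate focal columns: pool frequency near target in every pop
        ok = np.ones(panel.n_sites, dtype=bool)
        score = np.zeros(panel.n_sites)
        for p, rows in rows_by_pop.items():
            f = panel.matrix[rows].mean(axis=0)
            dev = np.abs(f - spec.target_freqs.get(p, 0.0))
            ok &= dev <= spec.pool_window
            score = np.maximum(score, dev)
        candidates = np.flatnonzero(ok)
        rng.shuffle(candidates)
        candidates = candidates[np.argsort(score[candidates], kind="stable")]
        for j in candidates:
            picked, pops = [], []
            for p, n in spec.sample_sizes.items():
                sel = _stratified_rows(
                    panel.matrix[:, j], rows_by_pop[p], counts[p], n, rng
                )
                if sel is None:
                    break
                picked.append(sel)
                pops.extend([p] * n)
            else:
                rows = np.concatenate(picked)
                return _assemble(
                    panel.matrix[rows].copy(), panel.positions.copy(),
                    int(j), spec, pops,
                )
    raise FrequencyTargetError(
        f"no neutral focal column met the targets in {spec.max_attempts} attempts"
    )


def _forward_panel(spec: ScenarioSpec, rng: np.random.Generator) -> HaplotypePanel:
    from balscan.forward_sim import wf_simulate

    dem = spec.resolved_demography()
    counts = _target_counts(spec)
    if spec.scenario_name == "partial_sweep":
        # additive positive selection in the non-African environment; founded
        # by several copies so the sweep is mid-flight rather than lost or
        # fixed in the small bottleneck deme
        s = 0.025 if spec.selection_coefficient is None else spec.selection_coefficient
        fitness = (1.0, 1.0 + spec.dominance * s, 1.0 + s)
        age = spec.mutation_age if spec.mutation_age is not None else 300.0
        selected = (
            spec.selected_pops
            if spec.selected_pops is not None
            else tuple(p for p in spec.sample_sizes if p != "AFR") or None
        )
        intro_count = 16 if spec.intro_count is None else spec.intro_count
        sel_start = spec.selection_start
        stem = None
    else:
        # balancing: an old allele that persisted at low copy number and was
        # then lifted to intermediate frequency by heterozygote advantage
        # when the selective regime began -- the history that yields both
        # deep between-class divergence (positive Tajima's D, via the
        # stem-private mutations) and a recently expanded homogeneous
        # derived class (negative nSL). Selection is restricted to the
        # non-African environment when the demography has an AFR deme (the
        # G x E / emergent-overdominance reading on an out-of-Africa
        # timescale). The simulated window starts at selection onset; the
        # earlier latent phase enters through stem_age.
        s = 0.5 if spec.selection_coefficient is None else spec.selection_coefficient
        fitness = (1.0, 1.0 + s, 1.0)
        stem = spec.mutation_age if spec.mutation_age is not None else 1800.0
        selected = (
            spec.selected_pops
            if spec.selected_pops is not None
            else tuple(p for p in spec.sample_sizes if p != "AFR") or None
        )
        intro_count = 1 if spec.intro_count is None else spec.intro_count
        age = spec.selection_start if spec.selection_start is not None else 590.0
        sel_start = None  # selection runs for the whole simulated window
        if stem <= age:
            raise ValueError(
                "balancing scenario needs mutation_age (origin) later than "
                "selection_start (onset)"
            )
    pool_sizes = {p: 4 * n for p, n in spec.sample_sizes.items()}
    for _ in range(spec.max_attempts):
        res = wf_simulate(
            dem, s=0.0, age=age, region_length=spec.region_length, seed=rng,
            sample_sizes=pool_sizes, fitness=fitness, intro_pop=spec.intro_pop,
            intro_count=intro_count, selected_pops=selected,
            selection_start=sel_start, stem_age=stem, abort_on_loss=True,
        )
        if res.lost:
            continue
        panel = res.panel
        # viability: population frequency near each target
        viable = all(
            abs(res.final_freqs.get(p, 0.0) - spec.target_freqs.get(p, 0.0))
            <= spec.pool_window
            for p in spec.sample_sizes
        )
        if not viable or panel.focal_index is None:
            continue
        picked, pops = [], []
        for p, n in spec.sample_sizes.items():
            sel = _stratified_rows(
                panel.matrix[:, panel.focal_index],
                panel.rows_for(p), counts[p], n, rng,
            )
            if sel is None:
                break
            picked.append(sel)
            pops.extend([p] * n)
        else:
            rows = np.concatenate(picked)
            return _assemble(
                panel.matrix[rows].copy(), panel.positions.copy(),
                int(panel.focal_index), spec, pops,
            )
    raise FrequencyTargetError(
        f"{spec.scenario_name} scenario: focal-frequency targets not met in "
        f"{spec.max_attempts} attempts"
    )


def generate_panel(spec: ScenarioSpec) -> HaplotypePanel:
    """Generate one phased panel with a frequency-conditioned focal SNP.

    The realized per-population derived-allele frequency of the focal SNP
    is within ``spec.focal_tolerance`` of the target in every population
    (exact to sampling granularity). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.scenario_name == "neutral":
        panel = _neutral_panel(spec, rng)
    else:
        panel = _forward_panel(spec, rng)
    for pop in spec.sample_sizes:
        realized = panel.derived_frequency(panel.focal_index, population=pop)
        if abs(realized - spec.target_freqs.get(pop, 0.0)) > spec.focal_tolerance:
            raise FrequencyTargetError(
                f"realized focal frequency {realized:.3f} in {pop} misses "
                f"target {spec.target_freqs.get(pop, 0.0):.3f}"
            )
    return panel


def generate_genome_background(
    n_windows: int, spec: ScenarioSpec
) -> list[HaplotypePanel]:
    """Independent neutral windows under the scenario's demography.

    These windows feed the empirical percentile threshold of the scan; they
    use the spec's region length as the window length and carry no focal
    conditioning. Deterministic given ``spec.seed``.
    """
    from balscan.coalescent_sim import simulate_sample

    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    dem = spec.resolved_demography()
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(n_windows):
        samp = simulate_sample(dem, spec.sample_sizes, spec.region_length, seed=rng)
        out.append(samp.panel)
    return out
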