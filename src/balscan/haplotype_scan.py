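"""Haplotype-homozygosity statistics around a focal SNP.

Unstandardized nSL measures the log-ratio of mean haplotype identity-tract
lengths (in SNP units) between the carriers of the ancestral and the derived
allele at a focal site: nsl = ln(SL_A / SL_D). A negative value means pairs
of derived-allele haplotypes stay identical over longer SNP stretches than
ancestral pairs do -- the signature of recent positive selection on the
derived allele. Because nSL depends strongly on allele frequency, the focal
score is ranked against SNPs of (almost) the same derived-allele frequency.

Tract lengths count SNP columns including the focal one (minimum 1) with no
physical-distance truncation, i.e. the pure SNP-index form of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from balscan.panel import HaplotypePanel


@dataclass
class NslResult:
    """Unstandardized nSL at one focal site for one haplotype set."""

    focal_index: int
    population: str
    derived_frequency: float
    sl_a: float | None  # mean identity-tract length over ancestral pairs
    sl_d: float | None  # same over derived pairs
    nsl: float | None
    reason: str | None = None  # set when undefined

    @property
    def defined(self) -> bool:
        return self.nsl is not None


def pair_tract_length(
    panel: HaplotypePanel, i: int, j: int, focal: int
) -> int:
    """Length (SNP count) of the maximal identity tract containing ``focal``.

    The number of columns in the largest contiguous column interval that
    contains the focal column and over which haplotypes i and j are
    identical; truncated at the panel edges. The two haplotypes must agree
    at the focal site (pairs are drawn within one allele class).
    """
    if i == j:
        raise ValueError("pair must consist of two distinct haplotypes")
    a, b = panel.matrix[i], panel.matrix[j]
    if a[focal] != b[focal]:
        raise ValueError("haplotypes differ at the focal site")
    left = focal
    while left > 0 and a[left - 1] == b[left - 1]:
        left -= 1
    right = focal
    last = panel.n_sites - 1
    while right < last and a[right + 1] == b[right + 1]:
        right += 1
    return right - left + 1


def _mean_tract_length(block: np.ndarray, focal: int) -> float:
    """Mean identity-tract length over all haplotype pairs in ``block``.

    Vectorized: for every pair, the tract is bounded by the nearest
    disagreeing column on each side of the focal column.
    """
    k, L = block.shape
    iu, ju = np.triu_indices(k, 1)
    diff = block[iu] != block[ju]  # (n_pairs, L)
    left_cols = diff[:, :focal]
    if left_cols.shape[1]:
        rev = left_cols[:, ::-1]
        any_left = rev.any(axis=1)
        # index (from focal-1 leftwards) of first disagreement
        first = rev.argmax(axis=1)
        left_bound = np.where(any_left, focal - 1 - first, -1)
    else:
        left_bound = np.full(iu.shape, -1)
    right_cols = diff[:, focal + 1:]
    if right_cols.shape[1]:
        any_right = right_cols.any(axis=1)
        first = right_cols.argmax(axis=1)
        right_bound = np.where(any_right, focal + 1 + first, L)
    else:
        right_bound = np.full(iu.shape, L)
    tracts = right_bound - left_bound - 1
    return float(tracts.mean())


def nsl_unstandardized(
    panel: HaplotypePanel,
    focal: int,
    population: str | None = None,
) -> NslResult:
    """nsl = ln(SL_A / SL_D) at the focal column.

    SL_A and SL_D are the mean pair tract lengths within the ancestral and
    derived allele classes. Undefined (with a reason) when either class has
    fewer than two haplotypes.
    """
    rows = (
        np.arange(panel.n_haplotypes)
        if population is None
        else panel.rows_for(population)
    )
    sub = panel.matrix[rows]
    pop_label = population if population is not None else "ALL"
    derived = sub[:, focal] == 1
    freq = float(derived.mean())
    n_d, n_a = int(derived.sum()), int((~derived).sum())
    if n_a < 2 or n_d < 2:
        return NslResult(
            focal_index=focal,
            population=pop_label,
            derived_frequency=freq,
            sl_a=None,
            sl_d=None,
            nsl=None,
            reason=f"allele class too small (ancestral={n_a}, derived={n_d})",
        )
    sl_a = _mean_tract_length(sub[~derived], focal)
    sl_d = _mean_tract_length(sub[derived], focal)
    return NslResult(
        focal_index=focal,
        population=pop_label,
        derived_frequency=freq,
        sl_a=sl_a,
        sl_d=sl_d,
        nsl=float(np.log(sl_a / sl_d)),
    )


def matched_frequency_percentile(
    panel: HaplotypePanel,
    focal: int,
    n_draws: int = 10_000,
    tol: float = 0.01,
    population: str | None = None,
    rng: np.random.Generator | int | None = None,
    two_sided: bool = False,
    pool: list | None = None,
) -> tuple[float, np.ndarray]:
    """Empirical percentile of the focal nsl against frequency-matched SNPs.

    Draws ``n_draws`` candidate SNPs (with replacement) whose derived-allele
    frequency is within ``tol`` of the focal SNP's, computes nsl for each,
    and returns the fraction of draws strictly below the focal score (the
    lower-tail percentile; with ``two_sided`` the smaller tail is doubled),
    together with the null sample.

    ``pool`` supplies the candidate panels. By default candidates come from
    the focal panel itself (excluding the focal column); passing a list of
    independent panels -- e.g. neutral genome-background windows -- gives a
    null of unlinked SNPs, which is preferable because candidates inside
    the focal panel can be in strong LD with the focal SNP and so echo its
    own haplotype structure.
    """
    rng = np.random.default_rng(rng)
    focal_res = nsl_unstandardized(panel, focal, population=population)
    if not focal_res.defined:
        raise ValueError(f"focal nsl undefined: {focal_res.reason}")

    def _matched_columns(pnl: HaplotypePanel) -> np.ndarray:
        rows = (
            np.arange(pnl.n_haplotypes)
            if population is None
            else pnl.rows_for(population)
        )
        freqs = pnl.matrix[rows].mean(axis=0)
        return np.flatnonzero(np.abs(freqs - focal_res.derived_frequency) <= tol)

    candidates: list[tuple[int, HaplotypePanel, int]] = []
    if pool is None:
        cols = _matched_columns(panel)
        candidates = [(0, panel, int(c)) for c in cols if c != focal]
    else:
        for k, pnl in enumerate(pool):
            candidates.extend((k, pnl, int(c)) for c in _matched_columns(pnl))
    if not candidates:
        raise ValueError(
            "no frequency-matched candidate SNPs; use a larger panel/pool or tolerance"
        )
    drawn = rng.integers(len(candidates), size=n_draws)
    # compute each distinct candidate once, then expand to the drawn sample
    cache: dict[tuple[int, int], float] = {}
    null = np.empty(n_draws)
    for k, idx in enumerate(drawn):
        key_panel, pnl, col = candidates[int(idx)]
        key = (key_panel, col)
        if key not in cache:
            res = nsl_unstandardized(pnl, col, population=population)
            cache[key] = res.nsl if res.defined else np.nan
        null[k] = cache[key]
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("all frequency-matched candidates had undefined nsl")
    lower = float(np.mean(null < focal_res.nsl))
    if two_sided:
        upper = float(np.mean(null > focal_res.nsl))
        return 2.0 * min(lower, upper), null
    return lower, null


def ld_pairwise(panel: HaplotypePanel, site_a: int, site_b: int) -> tuple[float, float]:
    """Two-locus LD from phased haplotypes: returns (r^2, D').

    D = p_AB - p_A p_B; r^2 = D^2 / (p_A q_A p_B q_B); D' = D / D_max with
    the usual sign-dependent bound on D.
    """
    a = panel.matrix[:, site_a].astype(float)
    b = panel.matrix[:, site_b].astype(float)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("both sites must be polymorphic")
    p_ab = float((a * b).mean())
    D = p_ab - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d_max == 0 else abs(D) / d_max
    return float(r2), float(dprime)
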