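"""Windowed site-frequency-spectrum statistics and scan thresholds.

Tajima's D contrasts two estimators of the population mutation rate over a
window: Watterson's theta_W = S / a1 (segregating sites) and theta_pi (mean
pairwise differences). An excess of intermediate-frequency variants drives
pi above theta_W and D positive -- the classic balancing-selection
signature; a sweep or expansion drives D negative. The normalization uses
Tajima's (1989) constants so that D is approximately standard normal under
the neutral constant-size model.

Windows with no segregating sites (or fewer than two haplotypes) have an
undefined D: they are flagged, not set to zero, and excluded from null
distributions to avoid spurious mass at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from balscan.panel import GenomicWindow, HaplotypePanel
from balscan.variant_io import iter_windows


@dataclass
class WindowStat:
    """Per-window summary: S, Watterson's theta, pi and Tajima's D."""

    window: GenomicWindow
    population: str
    n: int
    S: int
    theta_w: float
    pi: float
    tajima_d: float | None  # None when undefined (S == 0 or n < 2)

    @property
    def defined(self) -> bool:
        return self.tajima_d is not None


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's (1989) normalization constants for sample size n."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _site_stats(submatrix: np.ndarray) -> tuple[int, float]:
    """(S, pi) from a (n, sites) 0/1 matrix via derived-allele counts.

    pi is the mean pairwise Hamming distance over all C(n, 2) pairs; per
    column a site with d derived copies contributes d * (n - d) differences.
    """
    n = submatrix.shape[0]
    d = submatrix.sum(axis=0, dtype=np.int64)
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0:
        return 0, 0.0
    diffs = float(np.sum(d[seg] * (n - d[seg])))
    pi = diffs / (n * (n - 1) / 2.0)
    return S, pi


def tajimas_d_components(
    panel: HaplotypePanel,
    window: GenomicWindow,
    population: str | None = None,
) -> WindowStat:
    """Compute (S, theta_W, pi, D) for one window, optionally one population.

    D = (pi - theta_W) / sqrt(e1*S + e2*S*(S-1)); undefined (None) when the
    window holds no segregating sites.
    """
    rows = (
        np.arange(panel.n_haplotypes)
        if population is None
        else panel.rows_for(population)
    )
    n = rows.size
    if n < 2:
        raise ValueError("Tajima's D needs at least 2 haplotypes")
    cols = panel.site_columns_in(window)
    S, pi = _site_stats(panel.matrix[np.ix_(rows, cols)])
    c = tajima_constants(n)
    theta_w = S / c["a1"]
    if S == 0:
        d = None
    else:
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        if var <= 0:
            # n <= 3: pi and theta_w coincide identically, so D = 0
            d = 0.0
        else:
            d = float((pi - theta_w) / np.sqrt(var))
    return WindowStat(
        window=window,
        population=population if population is not None else "ALL",
        n=n,
        S=S,
        theta_w=theta_w,
        pi=pi,
        tajima_d=d,
    )


def window_scan(
    panel: HaplotypePanel,
    window: int,
    step: int,
    populations: Sequence[str] | None = None,
) -> list[WindowStat]:
    """Sliding-window scan, one statistic track per population.

    Windows tile ``[0, region_length)`` with the given width and shift;
    each population's track is computed independently from its own rows.
    """
    if panel.n_haplotypes == 0:
        raise ValueError("empty panel")
    pops = list(populations) if populations is not None else panel.population_names()
    stats: list[WindowStat] = []
    for win in iter_windows(panel.region_length, window, step, chrom=panel.chrom):
        for pop in pops:
            stats.append(tajimas_d_components(panel, win, population=pop))
    return stats


def empirical_threshold(
    background: Iterable[WindowStat | float],
    percentile: float = 0.95,
    min_defined: int = 20,
) -> float:
    """Percentile threshold of defined background Tajima's D values.

    Uses the linear-interpolation (type-7) percentile so thresholds are
    reproducible; undefined windows are excluded, not imputed.
    """
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    values = []
    for item in background:
        if isinstance(item, WindowStat):
            if item.defined:
                values.append(item.tajima_d)
        elif item is not None and np.isfinite(item):
            values.append(float(item))
    if not values:
        raise ValueError("no defined background values to take a percentile of")
    if len(values) < min_defined:
        raise ValueError(
            f"only {len(values)} defined background values; need >= {min_defined}"
        )
    return float(np.percentile(values, 100.0 * percentile, method="linear"))


def scan_rows(
    stats: Sequence[WindowStat],
    threshold: float | None = None,
) -> list[dict]:
    """Flatten WindowStats into TSV-ready rows with a significance flag."""
    rows = []
    for st in stats:
        rows.append(
            {
                "chrom": st.window.chrom,
                "start": st.window.start,
                "end": st.window.end,
                "population": st.population,
                "n": st.n,
                "S": st.S,
                "theta_w": st.theta_w,
                "pi": st.pi,
                "tajima_d": st.tajima_d,
                "significant": (
                    None
                    if threshold is None or st.tajima_d is None
                    else int(st.tajima_d > threshold)
                ),
            }
        )
    return rows
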