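"""Coding-site classification, MK/DoS tests, LRT arithmetic and q-values.

The McDonald-Kreitman contrast compares nonsynonymous vs synonymous fixed
differences between species (D_N, D_S) against nonsynonymous vs synonymous
polymorphisms within a species (P_N, P_S). Under neutrality the two ratios
agree; an excess of nonsynonymous divergence indicates adaptive fixation
while an excess of nonsynonymous polymorphism indicates segregating
(slightly deleterious or balanced) variation. DoS condenses the table into
D_N/(D_N+D_S) - P_N/(P_N+P_S): positive = adaptive, zero = neutral,
negative = polymorphism excess.

Branch-site likelihood-ratio arithmetic converts a pair of fitted codon-
model log-likelihoods into the 2*delta-lnL statistic and its upper-tail
chi-square p-value (df = 1 for the standard branch-site contrast); model
fitting itself is out of scope. Multiple-test correction follows Storey's
q-value with the smoother pi0 estimate, falling back to pi0 = 1 (which
makes q-values identical to Benjamini-Hochberg adjusted p-values) for small
input sets where the pi0 estimator is unstable.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, stats

logger = logging.getLogger(__name__)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class MKCounts:
    """A 2x2 MK table: fixed differences vs polymorphisms, N vs S."""

    d_n: float
    d_s: float
    p_n: float
    p_s: float
    gene: str = ""
    comparison: str = ""

    def __post_init__(self) -> None:
        for v in (self.d_n, self.d_s, self.p_n, self.p_s):
            if v < 0:
                raise ValueError("MK counts must be non-negative")


@dataclass
class LrtResult:
    """Likelihood-ratio test of a branch-site alternative vs its null."""

    lnl_null: float
    lnl_alt: float
    chi2: float
    df: int
    p_value: float
    q_value: float | None = None
    gene: str = ""


def classify_coding_change(cds: str, position: int, alt_base: str) -> str:
    """Classify a point change in a CDS: synonymous / nonsynonymous / nonsense.

    ``position`` is 0-based within the CDS; the codon containing it is
    mutated to ``alt_base`` and translated with the standard genetic code.
    """
    cds = cds.upper()
    alt_base = alt_base.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    if not (0 <= position < len(cds)):
        raise ValueError("position outside the CDS")
    if alt_base not in "ACGT":
        raise ValueError(f"ambiguous or invalid base {alt_base!r}")
    if any(b not in "ACGT" for b in cds):
        raise ValueError("CDS contains ambiguous bases")
    codon_start = 3 * (position // 3)
    codon = cds[codon_start:codon_start + 3]
    offset = position - codon_start
    mutated = codon[:offset] + alt_base + codon[offset + 1:]
    aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutated]
    if aa_alt == "*" and aa_ref != "*":
        return "nonsense"
    if aa_ref == aa_alt:
        return "synonymous"
    return "nonsynonymous"


def _codon_pathways(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(N, S) for one codon pair, averaged over all mutational pathways.

    Pathways passing through a stop codon are excluded; returns None when
    every pathway is blocked (the codon is then skipped by the caller).
    """
    diffs = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        n = s = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*":
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            results.append((n, s))
    if not results:
        return None
    n_mean = sum(r[0] for r in results) / len(results)
    s_mean = sum(r[1] for r in results) / len(results)
    return n_mean, s_mean


def count_divergence(cds_a: str, cds_b: str) -> tuple[float, float]:
    """(D_N, D_S) between two codon-aligned, gap-stripped CDS sequences.

    Single-difference codons are classified directly; codons with k >= 2
    differences average the N/S split over all k! mutational pathways, with
    pathways through stop codons excluded. Codons that contain a stop or an
    ambiguous base in either sequence are skipped and logged.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be equal length (codon-aligned)")
    if len(cds_a) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    d_n = d_s = 0.0
    skipped = 0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k:k + 3], cds_b[k:k + 3]
        if any(b not in "ACGT" for b in ca + cb):
            skipped += 1
            continue
        if CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*":
            skipped += 1
            continue
        res = _codon_pathways(ca, cb)
        if res is None:
            skipped += 1
            continue
        d_n += res[0]
        d_s += res[1]
    if skipped:
        logger.info("count_divergence: skipped %d codons (stop/ambiguous)", skipped)
    return d_n, d_s


def mk_test(
    counts: MKCounts, alternative: str = "two-sided"
) -> tuple[str, float, float | None]:
    """MK 2x2 Fisher's exact test plus the DoS statistic.

    Returns ``(direction, fisher_p, dos)`` where direction is "adaptive"
    (DoS > 0), "polymorphism_excess" (DoS < 0), "neutral" (DoS == 0) or
    "undefined"; dos is None when either DoS denominator is zero.
    """
    table = np.array(
        [[counts.d_n, counts.d_s], [counts.p_n, counts.p_s]], dtype=float
    )
    if table.sum() == 0:
        raise ValueError("all-zero MK table")
    _, p = stats.fisher_exact(np.round(table).astype(int), alternative=alternative)
    div, poly = counts.d_n + counts.d_s, counts.p_n + counts.p_s
    if div == 0 or poly == 0:
        return "undefined", float(p), None
    dos = counts.d_n / div - counts.p_n / poly
    if dos > 0:
        direction = "adaptive"
    elif dos < 0:
        direction = "polymorphism_excess"
    else:
        direction = "neutral"
    return direction, float(p), float(dos)


def branch_site_lrt(
    lnl_null: float, lnl_alt: float, df: int = 1, gene: str = ""
) -> LrtResult:
    """2*(lnL_alt - lnL_null) against the upper tail of chi-square(df).

    A fitted alternative can come out marginally below the null through
    optimizer noise; differences more negative than -1e-6 are clamped to a
    zero statistic with a warning.
    """
    if not (np.isfinite(lnl_null) and np.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    chi2 = 2.0 * (lnl_alt - lnl_null)
    if chi2 < 0:
        if chi2 < -1e-6:
            warnings.warn(
                f"alternative log-likelihood below null by {-chi2 / 2:.3g}; "
                "statistic clamped to 0",
                stacklevel=2,
            )
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df))
    return LrtResult(
        lnl_null=lnl_null, lnl_alt=lnl_alt, chi2=float(chi2), df=df,
        p_value=p, gene=gene,
    )


def qvalues(
    p_values, pi0: float | None = None, min_n_for_pi0: int = 100
) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0 (the proportion of true nulls) is estimated by fitting a cubic
    smoothing spline to pi0(lambda) over lambda = 0.05..0.95 and evaluating
    at the largest lambda. For fewer than ``min_n_for_pi0`` p-values the
    estimator is unstable and pi0 = 1 is used, in which case the output
    equals Benjamini-Hochberg adjusted p-values. An explicit ``pi0``
    overrides estimation.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < min_n_for_pi0:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
            spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(np.clip(spline(lam[-1]), 1.0 / m, 1.0))
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def lrt_table(
    likelihoods: list[tuple[str, float, float]], df: int = 1
) -> list[LrtResult]:
    """Run the branch-site LRT over genes and attach q-values.

    ``likelihoods`` is a list of (gene, lnL_null, lnL_alt).
    """
    results = [branch_site_lrt(l0, l1, df=df, gene=g) for g, l0, l1 in likelihoods]
    qs = qvalues([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
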