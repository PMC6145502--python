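"""Phased-VCF ingestion, allele polarization, and sliding-window arithmetic.

Coordinate conventions, stated once: VCF positions are 1-based; all window
arithmetic is 0-based half-open (the BED convention). Sites are polarized
against the ``AA`` (ancestral allele) INFO tag so that 1 means derived;
records without usable ancestral information are dropped and counted rather
than guessed. Only phased, biallelic SNPs are accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pysam

from balscan.panel import GenomicWindow, HaplotypePanel

logger = logging.getLogger(__name__)

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass
class ReadReport:
    """Counters for records dropped while reading a VCF."""

    n_kept: int = 0
    n_no_ancestral: int = 0
    n_multiallelic: int = 0
    n_not_snp: int = 0
    n_outside_region: int = 0


def polarize_reference(
    ref_allele_freq: float,
    ancestral_present_as_derived: bool,
    ancestral_freq: float | None = None,
) -> str:
    """Decide whether a CDS reference allele should be replaced by the derived one.

    The reference base is swapped out when it is essentially absent from the
    population (frequency < 1%), or when the recorded ancestral allele still
    segregates -- registered as a "derived" allele -- above 1% frequency,
    which indicates the reference carries the derived state.

    Returns ``"replace"`` or ``"keep"``.
    """
    if not (0.0 <= ref_allele_freq <= 1.0):
        raise ValueError("ref_allele_freq must be in [0, 1]")
    if ref_allele_freq < 0.01:
        return "replace"
    if ancestral_present_as_derived:
        if ancestral_freq is None:
            raise ValueError(
                "ancestral_freq required when the ancestral allele segregates"
            )
        if not (0.0 <= ancestral_freq <= 1.0):
            raise ValueError("ancestral_freq must be in [0, 1]")
        if ancestral_freq > 0.01:
            return "replace"
    return "keep"


def iter_windows(
    region_length: int,
    window: int,
    step: int,
    chrom: str = "1",
    include_partial: bool = False,
) -> Iterator[GenomicWindow]:
    """Sliding windows ``[k*step, k*step + window)`` over ``[0, region_length)``.

    Consecutive windows overlap by ``window - step`` bp. The trailing partial
    window is emitted only when ``include_partial`` is set.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > region_length:
        warnings.warn(
            f"window ({window} bp) exceeds region length ({region_length} bp); "
            "no windows emitted",
            stacklevel=2,
        )
        return
    start = 0
    while start + window <= region_length:
        yield GenomicWindow(chrom, start, start + window)
        start += step
    if include_partial and start < region_length:
        yield GenomicWindow(chrom, start, region_length)


def read_popmap(popmap_path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id -> population label."""
    popmap: dict[str, str] = {}
    with open(popmap_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{popmap_path}:{line_no}: expected 'sample<TAB>population'"
                )
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise ValueError(f"{popmap_path}: empty population map")
    return popmap


def write_popmap(panel: HaplotypePanel, popmap_path: str | Path) -> None:
    """Write the panel's diploid sample -> population map as TSV."""
    with open(popmap_path, "w") as fh:
        for name, pop in zip(_sample_names(panel), panel.populations[::2]):
            fh.write(f"{name}\t{pop}\n")


def _sample_names(panel: HaplotypePanel) -> list[str]:
    if panel.n_haplotypes % 2:
        raise ValueError("panel must have an even haplotype count (diploids)")
    names = []
    counters: dict[str, int] = {}
    for pop in panel.populations[::2]:
        k = counters.get(str(pop), 0)
        counters[str(pop)] = k + 1
        names.append(f"{pop}_{k:04d}")
    return names


def write_vcf(panel: HaplotypePanel, vcf_path: str | Path) -> None:
    """Write the panel as a minimal phased VCF 4.2 file with AA INFO tags.

    Alleles are written with REF = ancestral ("A") and ALT = derived ("T"),
    which is lossless for a polarized binary panel; the AA tag always names
    the ancestral allele so a round trip restores the original matrix.
    """
    names = _sample_names(panel)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={max(panel.region_length, 1)}>\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        if panel.focal_index is not None:
            fh.write(
                '##INFO=<ID=FOCAL,Number=0,Type=Flag,Description="Designated focal SNP">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j in range(panel.n_sites):
            info = "AA=A"
            if panel.focal_index is not None and j == panel.focal_index:
                info += ";FOCAL"
            gts = "\t".join(
                f"{panel.matrix[2 * i, j]}|{panel.matrix[2 * i + 1, j]}"
                for i in range(len(names))
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t.\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_haplotype_panel(
    vcf_path: str | Path,
    popmap_path: str | Path,
    region: GenomicWindow | None = None,
    report: ReadReport | None = None,
) -> HaplotypePanel:
    """Read a phased VCF into a polarized haplotype panel.

    Sites are polarized with the AA INFO tag: when AA equals ALT the column
    is flipped so 1 is always the derived allele. Records with no usable AA,
    multi-allelic records and non-SNP records are dropped and counted in
    ``report``. Unphased genotypes and samples missing from the population
    map are hard errors.
    """
    popmap = read_popmap(popmap_path)
    report = report if report is not None else ReadReport()

    columns: list[np.ndarray] = []
    positions: list[int] = []
    focal_index: int | None = None
    chrom = None
    region_length = None

    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            if s not in popmap:
                raise KeyError(
                    f"sample {s!r} in {vcf_path} is missing from the population map"
                )
        for contig in vcf.header.contigs.values():
            if region is None or contig.name == region.chrom:
                region_length = contig.length
        populations = np.array(
            [popmap[s] for s in samples for _ in range(2)], dtype=object
        )
        for rec in vcf:
            if region is not None:
                if rec.chrom != region.chrom or not region.contains_position(rec.pos):
                    report.n_outside_region += 1
                    continue
            if chrom is None:
                chrom = rec.chrom
            if rec.alts is None or len(rec.alts) != 1:
                report.n_multiallelic += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
                report.n_not_snp += 1
                continue
            aa = rec.info.get("AA")
            if isinstance(aa, tuple):
                aa = aa[0]
            aa = (aa or "").upper().strip(".")
            if aa == ref:
                derived_is_alt = True
            elif aa == alt:
                derived_is_alt = False
            else:
                report.n_no_ancestral += 1
                continue
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                sample = rec.samples[s]
                alleles = sample["GT"]
                if len(alleles) != 2 or None in alleles:
                    raise ValueError(
                        f"{vcf_path}: {rec.chrom}:{rec.pos}: genotype for {s!r} "
                        "is not a called diploid genotype"
                    )
                if not sample.phased:
                    raise ValueError(
                        f"{vcf_path}: {rec.chrom}:{rec.pos}: unphased genotype "
                        f"for sample {s!r}; phased haplotypes are required"
                    )
                col[2 * i] = alleles[0]
                col[2 * i + 1] = alleles[1]
            if not derived_is_alt:
                col = 1 - col
            try:
                is_focal = bool(rec.info.get("FOCAL", False))
            except ValueError:  # FOCAL flag absent from the header entirely
                is_focal = False
            if is_focal:
                focal_index = len(positions)
            positions.append(rec.pos)
            columns.append(col)
            report.n_kept += 1

    if report.n_no_ancestral or report.n_multiallelic or report.n_not_snp:
        logger.info(
            "read_haplotype_panel: dropped %d sites without ancestral state, "
            "%d multi-allelic, %d non-SNP",
            report.n_no_ancestral,
            report.n_multiallelic,
            report.n_not_snp,
        )
    matrix = (
        np.column_stack(columns)
        if columns
        else np.empty((len(populations), 0), dtype=np.int8)
    )
    return HaplotypePanel(
        matrix=matrix,
        positions=np.array(positions, dtype=np.int64),
        populations=populations,
        chrom=chrom if chrom is not None else (region.chrom if region else "1"),
        region_length=region_length,
        focal_index=focal_index,
    )


def write_scan_tsv(rows: Sequence[dict], path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a BED-like TSV report (chrom, start, end, ... statistic columns)."""
    if not rows:
        raise ValueError("no rows to write")
    keys = list(rows[0])
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[k]) for k in keys) + "\n")


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
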