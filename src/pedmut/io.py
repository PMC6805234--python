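"""Standard-format readers and writers.

All-sites trio data travel as VCF with per-sample DP / AD / PL (and GL, kept
for lossless round trips — PL is integer phred-scaled) plus site-level INFO
annotations QD, MQRankSum and the two pileup statistics the filters need
(GAPR: reads with alignment gaps, DELF: fraction of spanning reads with
deletions).  References are FASTA (indexed via pyfaidx), repeat annotations
BED (0-based half-open).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .genotype_model import gl_field_to_loglik, pl_to_loglik
from .site_filters import RepeatMask, TrioDataset

__all__ = [
    "DEFAULT_SAMPLES",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_trio_vcf",
    "read_trio_vcf",
]

DEFAULT_SAMPLES = ("offspring", "mother", "father")

_LN10 = math.log(10.0)


def write_fasta(reference: Mapping[str, str], path, line_width: int = 60) -> None:
    """Write sequences as FASTA and build a .fai index."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(path))  # builds <path>.fai


def read_fasta(path) -> Dict[str, str]:
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_bed(intervals: Iterable[Tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path) -> RepeatMask:
    return RepeatMask.from_bed(path)


def _vcf_header(contig_lengths: Mapping[str, int], samples: Sequence[str]):
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=int(length))
    header.info.add("QD", 1, "Float", "Quality by depth")
    header.info.add("MQRankSum", 1, "Float", "Mapping quality rank-sum statistic")
    header.info.add("GAPR", 1, "Integer", "Reads with alignment gaps at the site")
    header.info.add("DELF", 1, "Float", "Fraction of spanning reads containing deletions")
    header.formats.add("GT", 1, "String", "Genotype call")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.formats.add("GL", "G", "Float", "Log10-scaled genotype likelihoods")
    for s in samples:
        header.add_sample(s)
    return header


def write_trio_vcf(
    dataset: TrioDataset,
    path,
    contig_lengths: Mapping[str, int],
    samples: Sequence[str] = DEFAULT_SAMPLES,
) -> None:
    """Write an all-sites trio VCF (uncompressed text)."""
    import pysam

    header = _vcf_header(contig_lengths, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(dataset.n_sites):
            rec = vcf.new_record(
                contig=str(dataset.chrom[i]),
                start=int(dataset.pos[i]) - 1,
                stop=int(dataset.pos[i]),
                alleles=(str(dataset.ref[i]), str(dataset.alt[i])),
            )
            if np.isfinite(dataset.qd[i]):
                rec.info["QD"] = float(dataset.qd[i])
            if np.isfinite(dataset.mq_rank_sum[i]):
                rec.info["MQRankSum"] = float(dataset.mq_rank_sum[i])
            rec.info["GAPR"] = int(dataset.gap_read_count[i])
            rec.info["DELF"] = float(dataset.deletion_read_fraction[i])
            for j, name in enumerate(samples):
                smp = rec.samples[name]
                depth = int(dataset.depth[i, j])
                alt = int(dataset.alt_count[i, j])
                # GT: the maximum-likelihood call, as a genotyper would emit
                # (it also fixes the ploidy for the Number=G fields below)
                g = int(np.argmax(dataset.gl[i, j]))
                smp["GT"] = ((0, 0), (0, 1), (1, 1))[g]
                smp["DP"] = depth
                smp["AD"] = (depth - alt, alt)
                log10 = dataset.gl[i, j] / _LN10
                log10 = log10 - log10.max()
                smp["GL"] = tuple(float(v) for v in log10)
                pl = np.rint(-10.0 * log10).astype(int)
                smp["PL"] = tuple(int(v) for v in pl)
            vcf.write(rec)


def read_trio_vcf(
    path,
    samples: Sequence[str] = DEFAULT_SAMPLES,
) -> TrioDataset:
    """Read an all-sites trio VCF into a :class:`TrioDataset`.

    Likelihoods come from GL when present (lossless) and otherwise from PL
    (phred-scaled: log-lik = -PL * ln(10) / 10).  Sample order follows the
    ``samples`` argument (offspring, mother, father).
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    order = [vcf.samples.index(s) for s in samples]

    chrom: List[str] = []
    pos: List[int] = []
    ref: List[str] = []
    alt: List[str] = []
    depth: List[List[int]] = []
    alt_count: List[List[int]] = []
    gl: List[List[np.ndarray]] = []
    qd: List[float] = []
    mqrs: List[float] = []
    gapr: List[int] = []
    delf: List[float] = []

    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else "N")
        dp = var.format("DP")[:, 0].astype(int)
        ad = var.format("AD").astype(int)
        depth.append([int(dp[k]) for k in order])
        alt_count.append([int(ad[k, 1]) for k in order])
        try:
            gl_field = var.format("GL")
        except KeyError:
            gl_field = None
        if gl_field is not None:
            triples = [gl_field_to_loglik(gl_field[k]) for k in order]
        else:
            triples = [pl_to_loglik(var.format("PL")[k]) for k in order]
        gl.append(triples)
        qd.append(var.INFO.get("QD", math.nan))
        mqrs.append(var.INFO.get("MQRankSum", math.nan))
        gapr.append(int(var.INFO.get("GAPR", 0)))
        delf.append(float(var.INFO.get("DELF", 0.0)))
    vcf.close()

    n = len(pos)
    return TrioDataset(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype="U1"),
        alt=np.array(alt, dtype="U1"),
        depth=np.array(depth, dtype=np.int64).reshape(n, 3),
        alt_count=np.array(alt_count, dtype=np.int64).reshape(n, 3),
        gl=np.array(gl, dtype=float).reshape(n, 3, 3),
        qd=np.array(qd, dtype=float),
        mq_rank_sum=np.array(mqrs, dtype=float),
        gap_read_count=np.array(gapr, dtype=np.int64),
        deletion_read_fraction=np.array(delf, dtype=float),
    )
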