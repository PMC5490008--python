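"""Pileup construction, binomial SNP calling and the SNP-frequency statistic.

Reads mapped to a reference at >=95% identity and >=70% read coverage are
piled up per position; at each site the most frequent non-reference allele is
tested against an exact binomial sequencing-error model: under the null the
alternative count at depth *d* is Binomial(d, error_rate), and a site is a
SNP when its upper-tail probability falls below ``max_p`` (default 1e-6) at a
minimum depth of 5x.  SNP burden is normalized as SNPs per kb of *effective*
genome (positions at >=5x) per Mb of mapped read sequence, which makes the
statistic comparable across genomes and sequencing depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.stats import binom

from .align import _parse_cigar, reverse_complement
from .errors import ConsistencyError, InputError, UndefinedStatisticError
from .popgen import Genome

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class PileupParams:
    min_map_identity_pct: float = 95.0
    min_read_coverage_pct: float = 70.0

    def __post_init__(self) -> None:
        for v in (self.min_map_identity_pct, self.min_read_coverage_pct):
            if not 0 <= v <= 100:
                raise InputError("pileup thresholds must be percentages in [0, 100]")


@dataclass(frozen=True)
class SnpCallerParams:
    min_coverage: int = 5
    max_p: float = 1e-6
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise InputError("min_coverage must be >= 1")
        if not 0 < self.max_p < 1:
            raise InputError("max_p must be in (0, 1)")
        if not 0 < self.error_rate < 0.5:
            raise InputError("error_rate must be in (0, 0.5)")


@dataclass(frozen=True)
class SiteCall:
    position: int  # 1-based
    depth: int
    allele_counts: tuple[int, int, int, int]  # A, C, G, T
    ref_base: str
    alt_base: str
    alt_count: int
    p_value: float
    is_snp: bool


@dataclass
class Pileup:
    """Per-position allele counts for one reference genome."""

    reference_id: str
    reference_seq: str
    counts: np.ndarray  # (4, L) allele counts
    mapped_bases: int = 0  # aligned query bases contributing to the pileup
    n_reads: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def effective_positions(self, min_coverage: int = 5) -> int:
        return int(np.count_nonzero(self.depth >= min_coverage))


@dataclass
class SnpFrequencyStat:
    n_snps: int
    effective_kb: float
    mapped_mb: float
    frequency: float


def build_pileup(
    hits: pd.DataFrame,
    reads,
    reference: Genome,
    params: PileupParams | None = None,
) -> Pileup:
    """Accumulate per-position allele counts from retained hits.

    Only hits at >= ``min_map_identity_pct`` identity and >=
    ``min_read_coverage_pct`` query coverage contribute.  The aligned read
    segment is re-aligned to its reference window and counts accumulated
    column-by-column; gap columns contribute nothing.
    """
    params = params or PileupParams()
    seqs: dict[str, str] = {}
    for r in reads:
        if hasattr(r, "read_id"):
            rid = f"{r.read_id}/{r.mate}" if getattr(r, "mate", None) else r.read_id
            seqs[rid] = r.sequence
        else:
            rid, seq = r
            seqs[rid] = seq

    L = len(reference.sequence)
    counts = np.zeros((4, L), dtype=np.int32)
    mapped = 0
    n_reads = 0
    sub = hits[hits["sseqid"] == reference.id] if len(hits) else hits
    for row in sub.itertuples(index=False):
        if row.pident < params.min_map_identity_pct:
            continue
        if row.qcovs < params.min_read_coverage_pct:
            continue
        if row.qseqid not in seqs:
            raise ConsistencyError(f"hit references unknown read {row.qseqid!r}")
        read_seq = seqs[row.qseqid]
        qseg = read_seq[row.qstart - 1 : row.qend]
        if row.sstart <= row.send:
            s_lo, s_hi = row.sstart, row.send
        else:  # minus strand stored BLAST-style with flipped subject coords
            s_lo, s_hi = row.send, row.sstart
            qseg = reverse_complement(qseg)
        ref_seg = reference.sequence[s_lo - 1 : s_hi]
        res = edlib.align(qseg, ref_seg, mode="NW", task="path")
        qi, ti = 0, s_lo - 1  # ti: 0-based on reference
        for n, op in _parse_cigar(res["cigar"]):
            if op in "=X":
                for k in range(n):
                    b = qseg[qi + k]
                    if b in _BASE_INDEX:
                        counts[_BASE_INDEX[b], ti + k] += 1
                qi += n
                ti += n
            elif op == "I":
                qi += n
            else:
                ti += n
        mapped += row.qend - row.qstart + 1
        n_reads += 1
    return Pileup(
        reference_id=reference.id,
        reference_seq=reference.sequence,
        counts=counts,
        mapped_bases=int(mapped),
        n_reads=n_reads,
    )


def binomial_tail(alt_count: int | np.ndarray, depth: int | np.ndarray, error_rate: float):
    """Exact upper-tail P(X >= alt_count) for X ~ Binomial(depth, error_rate)."""
    return binom.sf(np.asarray(alt_count) - 1, depth, error_rate)


def call_snps(pileup: Pileup, params: SnpCallerParams | None = None) -> list[SiteCall]:
    """Test the top non-reference allele at every covered site.

    A site is a SNP iff depth >= ``min_coverage`` and the exact binomial
    upper-tail probability of its alternative-allele count under the
    sequencing-error null is below ``max_p``.
    """
    params = params or SnpCallerParams()
    depth = pileup.depth
    covered = np.flatnonzero(depth > 0)
    ref_idx = np.array(
        [_BASE_INDEX.get(b, -1) for b in pileup.reference_seq], dtype=np.int64
    )
    calls: list[SiteCall] = []
    counts = pileup.counts
    # mask reference allele, take the argmax of the remainder per covered site
    masked = counts[:, covered].astype(np.int64).copy()
    ok = ref_idx[covered] >= 0
    masked[ref_idx[covered][ok], np.flatnonzero(ok)] = -1
    alt_idx = masked.argmax(axis=0)
    alt_cnt = np.maximum(masked[alt_idx, np.arange(len(covered))], 0)
    pvals = binomial_tail(alt_cnt, depth[covered], params.error_rate)
    pvals = np.where(alt_cnt > 0, pvals, 1.0)
    for j, pos0 in enumerate(covered):
        d = int(depth[pos0])
        is_snp = d >= params.min_coverage and pvals[j] < params.max_p
        calls.append(
            SiteCall(
                position=int(pos0) + 1,
                depth=d,
                allele_counts=tuple(int(c) for c in counts[:, pos0]),
                ref_base=pileup.reference_seq[pos0],
                alt_base=_BASES[int(alt_idx[j])] if alt_cnt[j] > 0 else ".",
                alt_count=int(alt_cnt[j]),
                p_value=float(pvals[j]),
                is_snp=bool(is_snp),
            )
        )
    return calls


def snp_frequency(
    calls: list[SiteCall],
    pileup: Pileup,
    mapped_read_bases: int | None = None,
    min_coverage: int = 5,
) -> SnpFrequencyStat:
    """SNPs per kb of effective genome per Mb of mapped read sequence."""
    mapped = pileup.mapped_bases if mapped_read_bases is None else mapped_read_bases
    if mapped <= 0:
        raise InputError("mapped_read_bases must be positive")
    eff_kb = pileup.effective_positions(min_coverage) / 1000.0
    if eff_kb == 0:
        raise UndefinedStatisticError(
            "no reference positions at the minimum coverage; frequency undefined"
        )
    n_snps = sum(1 for c in calls if c.is_snp)
    mapped_mb = mapped / 1e6
    return SnpFrequencyStat(
        n_snps=n_snps,
        effective_kb=eff_kb,
        mapped_mb=mapped_mb,
        frequency=n_snps / eff_kb / mapped_mb,
    )


def write_vcf(calls: list[SiteCall], reference_id: str, path) -> None:
    """Emit called SNPs as minimal VCF v4.2 (QUAL = -10*log10 p)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt allele depth">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if not c.is_snp:
                continue
            qual = -10.0 * np.log10(max(c.p_value, 1e-300))
            fh.write(
                f"{reference_id}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}\t"
                f"{qual:.1f}\tPASS\tDP={c.depth};AD={c.alt_count}\n"
            )
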