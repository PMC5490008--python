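"""Fragment recruitment of reads against reference genomes.

Reads are recruited as single ends against every reference with the local
aligner, then filtered: hits below the identity search floor or with query
coverage under the threshold (default 80%) are dropped, and an assignment
mode decides how multi-mapping reads are resolved.  Abundance is summarized
as KPKG — kilobases of recruited read sequence per kilobase of genome per
gigabase of metagenome — at a stated identity cutoff (95% ~ species level,
70% ~ genus level), and per-genome identity histograms ("diversity curves")
expose population microdiversity as low-identity recruitment mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .align import AlignParams, align_local
from .errors import ConsistencyError, InputError, UndefinedStatisticError

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "score",
    "qcovs",
]


class AssignmentMode(str, Enum):
    ALL = "all"
    BEST_HIT = "best_hit"
    RECIPROCAL_BEST_HIT = "reciprocal_best_hit"


@dataclass(frozen=True)
class RecruitParams:
    """Filters and assignment policy for fragment recruitment."""

    min_identity_pct: float = 50.0
    min_qcov_pct: float = 80.0
    assignment_mode: AssignmentMode = AssignmentMode.BEST_HIT
    species_cutoff_pct: float = 95.0
    genus_cutoff_pct: float = 70.0
    aln_params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity_pct <= self.species_cutoff_pct <= 100:
            raise InputError(
                "require 0 <= min_identity_pct <= species_cutoff_pct <= 100"
            )


@dataclass
class RecruitmentStat:
    """Per-genome normalized recruitment at one identity cutoff."""

    genome_id: str
    identity_cutoff_pct: float
    recruited_kb: float
    genome_kb: float
    metagenome_gb: float
    kpkg: float
    n_reads: int


@dataclass
class DiversityCurve:
    """Percent of recruited reads per nucleotide-identity bin for one genome."""

    genome_id: str
    bin_edges: np.ndarray
    pct_reads: np.ndarray
    n_hits: int


def recruit_reads(
    reads,
    references,
    params: RecruitParams | None = None,
) -> pd.DataFrame:
    """Align every read to every reference; filter and assign.

    ``reads`` is an iterable of objects with ``read_id``/``mate``/``sequence``
    (or ``(id, sequence)`` tuples); ``references`` an iterable of genomes.
    Returns a hit table in 12-column BLAST-tabular layout (score replaces
    e-value, qcovs appended).
    """
    params = params or RecruitParams()
    references = list(references)
    if not references:
        raise InputError("reference set is empty")

    rows = []
    for r in reads:
        if hasattr(r, "read_id"):
            rid = f"{r.read_id}/{r.mate}" if getattr(r, "mate", None) else r.read_id
            seq = r.sequence
        else:
            rid, seq = r
        for ref in references:
            ref_id = getattr(ref, "id", None) or getattr(ref, "name", "ref")
            ref_seq = getattr(ref, "sequence", ref)
            hits = align_local(seq, ref_seq, params.aln_params, query_id=rid, subject_id=ref_id)
            if not hits:
                continue
            best = hits[0]  # best placement of this read on this genome
            if best.query_coverage_pct < params.min_qcov_pct:
                continue
            if best.identity_pct < params.min_identity_pct:
                continue
            rows.append(
                (
                    rid,
                    ref_id,
                    best.identity_pct,
                    best.aln_length,
                    best.mismatches,
                    best.gap_columns,
                    best.q_start,
                    best.q_end,
                    best.s_start if best.strand == "+" else best.s_end,
                    best.s_end if best.strand == "+" else best.s_start,
                    best.score,
                    best.query_coverage_pct,
                )
            )
    table = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return _assign(table, params.assignment_mode)


def _assign(table: pd.DataFrame, mode: AssignmentMode) -> pd.DataFrame:
    if table.empty or mode == AssignmentMode.ALL:
        return table.reset_index(drop=True)
    # deterministic best-hit: highest score, then lexicographically smallest
    # genome id (reciprocal best-hit tie-break)
    ordered = table.sort_values(
        ["qseqid", "score", "sseqid"], ascending=[True, False, True], kind="mergesort"
    )
    return ordered.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def compute_kpkg(
    hits: pd.DataFrame,
    genome_lengths: dict[str, int],
    metagenome_bases: int,
    identity_cutoff_pct: float = 95.0,
) -> list[RecruitmentStat]:
    """KPKG per genome at one identity cutoff.

    recruited kb = sum of aligned query spans (qend - qstart + 1) over hits at
    or above the cutoff; KPKG = recruited_kb / genome_kb / metagenome_gb.
    """
    if metagenome_bases <= 0:
        raise InputError("metagenome_bases must be positive")
    unknown = set(hits["sseqid"]) - set(genome_lengths) if len(hits) else set()
    if unknown:
        raise ConsistencyError(f"hits reference unknown genome(s): {sorted(unknown)}")
    gb = metagenome_bases / 1e9
    stats = []
    for gid, glen in genome_lengths.items():
        sub = hits[(hits["sseqid"] == gid) & (hits["pident"] >= identity_cutoff_pct)] if len(hits) else hits
        recruited_kb = float((sub["qend"] - sub["qstart"] + 1).sum()) / 1000.0 if len(sub) else 0.0
        genome_kb = glen / 1000.0
        stats.append(
            RecruitmentStat(
                genome_id=gid,
                identity_cutoff_pct=identity_cutoff_pct,
                recruited_kb=recruited_kb,
                genome_kb=genome_kb,
                metagenome_gb=gb,
                kpkg=recruited_kb / genome_kb / gb,
                n_reads=int(len(sub)) if len(sub) else 0,
            )
        )
    return stats


def relative_recruitment(mean_kpkg: dict[str, float]) -> dict[str, float]:
    """Normalize per-set mean KPKG by the sum over sets (shares sum to 1)."""
    total = float(sum(mean_kpkg.values()))
    if total <= 0:
        raise UndefinedStatisticError("all recruitment means are zero")
    return {k: v / total for k, v in mean_kpkg.items()}


def diversity_curve(
    hits: pd.DataFrame,
    genome_id: str,
    bin_edges: np.ndarray | None = None,
) -> DiversityCurve:
    """Identity histogram of retained hits for one genome, as percentages.

    Default bins are 1-point wide from 70 to 100.  Hits outside the bin range
    are counted in the nearest terminal bin (with a warning).
    """
    edges = np.asarray(bin_edges if bin_edges is not None else np.arange(70.0, 101.0, 1.0))
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise InputError("bin_edges must be strictly increasing with >= 2 edges")
    sub = hits[hits["sseqid"] == genome_id] if len(hits) else hits
    ident = sub["pident"].to_numpy(dtype=float) if len(sub) else np.array([])
    n = ident.size
    counts = np.zeros(len(edges) - 1)
    if n:
        if ident.min() < edges[0] or ident.max() > edges[-1]:
            warnings.warn(
                "hit identities outside bin range; counted in terminal bins",
                stacklevel=2,
            )
        clipped = np.clip(ident, edges[0], edges[-1])
        idx = np.clip(np.searchsorted(edges, clipped, side="right") - 1, 0, len(counts) - 1)
        np.add.at(counts, idx, 1)
    pct = counts / n * 100.0 if n else counts
    return DiversityCurve(genome_id=genome_id, bin_edges=edges, pct_reads=pct, n_hits=n)


def write_hits_tsv(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_hits_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"hit table missing column(s): {sorted(missing)}")
    return table
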