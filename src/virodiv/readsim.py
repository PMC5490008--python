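"""Paired-end read simulation with per-read truth provenance.

Every simulated read keeps a truth record (source genome, 1-based start,
strand, number of injected errors) so downstream stages — recruitment
specificity, SNP-caller recall, assembly chimera detection — can be scored
against ground truth.  The error model is substitution-only and uniform along
the read; quality strings are constant Q40 ('I') and the SNP caller takes the
error rate as an explicit parameter instead.

A background community of mutually unrelated genomes stands in for the
natural virome that focal populations are spiked into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import reverse_complement
from .errors import ConfigurationError, InputError
from .popgen import Genome, Population, generate_reference

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate: int
    sequence: str
    quality: str
    truth_genome_id: str
    truth_start: int  # 1-based on the source genome (leftmost aligned base)
    truth_strand: str
    n_errors: int


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    coverage: float | None = None
    n_pairs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.2:
            raise InputError("error_rate must be in [0, 0.2]")
        if self.insert_mean < self.read_length:
            raise InputError("insert_mean must be >= read_length")
        if self.coverage is not None and self.n_pairs is not None:
            raise ConfigurationError("give either coverage or n_pairs, not both")


def make_background(
    n_genomes: int,
    length_range: tuple[int, int] = (5000, 50000),
    gc: float = 0.45,
    seed: int = 0,
) -> list[Genome]:
    """Mutually unrelated random genomes standing in for a natural virome."""
    if n_genomes < 0:
        raise InputError("n_genomes must be >= 0")
    lo, hi = length_range
    if lo < 1000 or hi < lo:
        raise InputError("length_range must satisfy 1000 <= lo <= hi")
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(n_genomes):
        length = int(rng.integers(lo, hi + 1))
        g = generate_reference(length, gc, seed=int(rng.integers(0, 2**31 - 1)))
        genomes.append(Genome(id=f"bg_{i:03d}", sequence=g.sequence))
    return genomes


def _inject_errors(seq: str, rng, error_rate: float) -> tuple[str, int]:
    if error_rate <= 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    for pos in hit:
        alts = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(alts)
    return arr.tobytes().decode(), int(hit.size)


def simulate_reads(
    population: Population,
    background: list[Genome] | None = None,
    params: ReadSimParams | None = None,
) -> list[ReadRecord]:
    """Simulate paired-end reads from a population plus optional background.

    The source genome of each pair is drawn with probability proportional to
    abundance x genome length; fragment starts are uniform along the genome.
    Background genomes share the population's total abundance-weighted mass
    proportionally to their lengths (each background genome behaves like one
    more community member at uniform per-base sampling).
    """
    params = params or ReadSimParams()
    if abs(float(np.sum(population.abundances)) - 1.0) > 1e-9:
        raise ConfigurationError("population abundances must sum to 1")

    genomes = list(population.genomes)
    weights = [a * len(g) for a, g in zip(population.abundances, genomes)]
    if background:
        # background genomes enter at uniform abundance equal to the mean
        # population abundance, i.e. one community-member share each
        mean_ab = float(np.mean(population.abundances))
        for g in background:
            genomes.append(g)
            weights.append(mean_ab * len(g))
    weights = np.asarray(weights, dtype=float)
    probs = weights / weights.sum()

    if params.n_pairs is not None:
        n_pairs = params.n_pairs
    else:
        coverage = params.coverage if params.coverage is not None else 20.0
        total_bases = coverage * sum(len(g) for g in genomes)
        n_pairs = int(round(total_bases / (2 * params.read_length)))

    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    reads: list[ReadRecord] = []
    choices = rng.choice(len(genomes), size=n_pairs, p=probs)
    for i in range(n_pairs):
        g = genomes[int(choices[i])]
        glen = len(g.sequence)
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(rl, min(insert, glen))
        start = int(rng.integers(0, glen - insert + 1))  # 0-based fragment start
        frag = g.sequence[start : start + insert]
        fwd_first = bool(rng.integers(0, 2))  # which mate sits on the forward strand

        left = frag[:rl]
        right = reverse_complement(frag[-rl:])
        if fwd_first:
            seq1, st1, strand1 = left, start + 1, "+"
            seq2, st2, strand2 = right, start + insert - rl + 1, "-"
        else:
            seq1, st1, strand1 = right, start + insert - rl + 1, "-"
            seq2, st2, strand2 = left, start + 1, "+"

        seq1, e1 = _inject_errors(seq1, rng, params.error_rate)
        seq2, e2 = _inject_errors(seq2, rng, params.error_rate)
        rid = f"read_{i:07d}"
        qual = "I" * rl
        reads.append(ReadRecord(rid, 1, seq1, qual, g.id, st1, strand1, e1))
        reads.append(ReadRecord(rid, 2, seq2, qual, g.id, st2, strand2, e2))
    return reads


def write_fastq(reads: list[ReadRecord], path1, path2) -> None:
    """Write mate-1 and mate-2 FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            fh = f1 if r.mate == 1 else f2
            fh.write(f"@{r.read_id}/{r.mate}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_table(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tgenome_id\tstart\tstrand\tn_errors\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.mate}\t{r.truth_genome_id}\t"
                f"{r.truth_start}\t{r.truth_strand}\t{r.n_errors}\n"
            )


def total_bases(reads: list[ReadRecord]) -> int:
    return sum(len(r.sequence) for r in reads)
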