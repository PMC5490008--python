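"""Synthetic viral populations with controlled microdiversity.

Generates a focal dsDNA-phage-like reference genome, derives variant genomes
by dosing substitutions (an exact SNP count, or iterative calibration to a
target fragment-ANI), optionally with an elevated-divergence hypervariable
island, and bundles the three canonical population presets:

* ``A`` — no microdiversity: the focal genome plus one variant differing by
  exactly 20 SNPs.
* ``B`` — low microdiversity: five genomes, every variant at >= 95% ANI to
  the focal genome, no extra island divergence.
* ``C`` — high microdiversity: ten genomes spanning 75-95% ANI to the focal
  genome with an elevated-divergence island.

Substitutions are drawn uniformly among the three alternative bases (no
transition bias) and population abundances default to uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AniParams, DiffSet, Substitution, fragment_ani
from .errors import ConfigurationError, ConvergenceError, InputError

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_DEFAULT_ISLAND_SPAN = (9000, 9700)  # observed hypervariable island coordinates
_REFERENCE_GENOME_LENGTH = 18000  # focal genome scale the island span refers to


@dataclass(frozen=True)
class Island:
    """A hypervariable genomic island: 1-based inclusive span + extra divergence."""

    start: int
    end: int
    divergence: float = 0.10

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError("island start must be < end")
        if not 0.0 <= self.divergence <= 1.0:
            raise InputError("island divergence must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """A named nucleotide sequence with mutation provenance."""

    id: str
    sequence: str
    parent_id: str | None = None
    mutations: DiffSet = field(default_factory=DiffSet)
    islands: list[Island] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    n_genomes: int
    snp_count: int | None = None
    ani_range: tuple[float, float] | None = None
    island: Island | None = None
    abundances: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in {"A", "B", "C"}:
            raise ConfigurationError("preset name must be one of A, B, C")
        if self.abundances is not None:
            if len(self.abundances) != self.n_genomes:
                raise ConfigurationError("abundances must have one entry per genome")
            if abs(sum(self.abundances) - 1.0) > 1e-9:
                raise ConfigurationError("abundances must sum to 1")


def default_island(genome_length: int, divergence: float = 0.10) -> Island:
    """Island at the canonical coordinates, scaled down for short genomes."""
    start, end = _DEFAULT_ISLAND_SPAN
    if genome_length < end:
        scale = genome_length / _REFERENCE_GENOME_LENGTH
        start = max(1, int(round(start * scale)))
        end = min(genome_length, int(round(end * scale)))
    return Island(start=start, end=end, divergence=divergence)


def preset(name: str, genome_length: int = _REFERENCE_GENOME_LENGTH) -> ScenarioPreset:
    """The three built-in population presets."""
    name = name.upper()
    if name == "A":
        return ScenarioPreset(name="A", n_genomes=2, snp_count=20)
    if name == "B":
        return ScenarioPreset(name="B", n_genomes=5, ani_range=(95.0, 100.0))
    if name == "C":
        return ScenarioPreset(
            name="C",
            n_genomes=10,
            ani_range=(75.0, 95.0),
            island=default_island(genome_length),
        )
    raise ConfigurationError(f"unknown preset {name!r}")


def generate_reference(length: int, gc: float = 0.40, seed: int = 0) -> Genome:
    """A random genome of exactly ``length`` bases at the given GC content."""
    if length < 1000:
        raise InputError("reference genomes must be >= 1,000 bp")
    if not 0.0 <= gc <= 1.0:
        raise InputError("gc must be a fraction in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode()
    return Genome(id=f"ref_{length}_{seed}", sequence=seq)


def _substitute(seq_arr: np.ndarray, positions: np.ndarray, rng) -> list[Substitution]:
    """Apply one random non-identical base at each 0-based position, in place."""
    subs = []
    for pos in positions:
        ref = seq_arr[pos]
        alts = _BASES[_BASES != ref]
        alt = rng.choice(alts)
        seq_arr[pos] = alt
        subs.append(
            Substitution(position=int(pos) + 1, ref=ref.decode(), alt=alt.decode())
        )
    return subs


def mutate_genome(
    parent: Genome,
    n_snps: int,
    island: Island | None = None,
    seed: int = 0,
    child_id: str | None = None,
) -> Genome:
    """Child differing from ``parent`` by exactly ``n_snps`` substitutions.

    With an island, island sites additionally mutate at rate
    ``island.divergence`` (binomially), and the ``n_snps`` exact substitutions
    are drawn outside the island so the backbone count stays exact.
    """
    length = len(parent.sequence)
    if n_snps >= length:
        raise InputError("n_snps must be smaller than the genome length")
    if island is not None and island.end > length:
        raise InputError("island extends past the genome end")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(parent.sequence.encode(), dtype="S1").copy()

    candidates = np.arange(length)
    if island is not None:
        in_island = (candidates >= island.start - 1) & (candidates <= island.end - 1)
        backbone = candidates[~in_island]
    else:
        backbone = candidates
    positions = rng.choice(backbone, size=n_snps, replace=False) if n_snps else np.array([], int)
    subs = _substitute(arr, np.sort(positions), rng)

    if island is not None and island.divergence > 0:
        island_pos = np.arange(island.start - 1, island.end)
        hit = island_pos[rng.random(island_pos.size) < island.divergence]
        subs.extend(_substitute(arr, hit, rng))

    subs.sort(key=lambda s: s.position)
    child = Genome(
        id=child_id or f"{parent.id}_snp{n_snps}_s{seed}",
        sequence=arr.tobytes().decode(),
        parent_id=parent.id,
        mutations=DiffSet(substitutions=subs),
        islands=[island] if island else [],
    )
    return child


def _dose(
    parent: Genome,
    backbone_rate: float,
    island: Island | None,
    seed: int,
    child_id: str,
) -> Genome:
    """One substitution dosing pass: backbone at ``backbone_rate``, island elevated."""
    rng = np.random.default_rng(seed)
    length = len(parent.sequence)
    arr = np.frombuffer(parent.sequence.encode(), dtype="S1").copy()
    rates = np.full(length, backbone_rate)
    if island is not None:
        # the island is elevated *above* the backbone, so it stays the most
        # divergent region even when the backbone itself is highly diverged
        rates[island.start - 1 : island.end] = min(1.0, backbone_rate + island.divergence)
    hit = np.flatnonzero(rng.random(length) < rates)
    subs = _substitute(arr, hit, rng)
    return Genome(
        id=child_id,
        sequence=arr.tobytes().decode(),
        parent_id=parent.id,
        mutations=DiffSet(substitutions=subs),
        islands=[island] if island else [],
    )


def evolve_to_ani(
    parent: Genome,
    target_ani_pct: float,
    island: Island | None = None,
    seed: int = 0,
    tol_pct: float = 1.0,
    ani_params: AniParams | None = None,
    max_iter: int = 20,
    child_id: str | None = None,
) -> Genome:
    """Variant whose fragment-ANI to ``parent`` hits ``target_ani_pct`` +/- tol.

    Substitution dosing is calibrated iteratively: apply a rate, measure with
    :func:`fragment_ani`, rescale the rate by the ratio of target to measured
    divergence. Raises :class:`ConvergenceError` after ``max_iter`` failed
    passes.
    """
    if not 70.0 <= target_ani_pct <= 100.0:
        raise InputError("target_ani_pct must be in [70, 100]")
    child_id = child_id or f"{parent.id}_ani{target_ani_pct:g}_s{seed}"
    if target_ani_pct >= 100.0 and island is None:
        return Genome(
            id=child_id,
            sequence=parent.sequence,
            parent_id=parent.id,
            mutations=DiffSet(),
        )
    ani_params = ani_params or AniParams()
    rate = 1.0 - target_ani_pct / 100.0
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=max_iter)
    for i in range(max_iter):
        child = _dose(parent, rate, island, int(seeds[i]), child_id)
        measured = fragment_ani(child, parent, ani_params).ani_pct
        if abs(measured - target_ani_pct) <= tol_pct:
            return child
        measured_div = max(1e-4, 100.0 - measured)
        target_div = 100.0 - target_ani_pct
        rate = min(0.75, max(0.0, rate * target_div / measured_div))
    raise ConvergenceError(
        f"failed to reach ANI {target_ani_pct}% within {max_iter} dosing passes"
    )


@dataclass
class Population:
    """A set of co-occurring genomes with relative abundances."""

    genomes: list[Genome]
    abundances: np.ndarray
    preset_name: str | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.abundances) != len(self.genomes):
            raise ConfigurationError("one abundance per genome required")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ConfigurationError("abundances must sum to 1")

    @property
    def focal(self) -> Genome:
        return self.genomes[0]


def build_scenario(
    preset_spec: ScenarioPreset | str,
    focal: Genome,
    seed: int = 0,
) -> Population:
    """Materialize a population preset around a focal genome.

    The focal genome is always the first member; variants follow.
    """
    ps = preset(preset_spec, len(focal)) if isinstance(preset_spec, str) else preset_spec
    if ps.island is not None and ps.island.end > len(focal):
        raise ConfigurationError("preset island extends past the focal genome end")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=ps.n_genomes)
    genomes = [focal]
    if ps.name == "A":
        genomes.append(
            mutate_genome(focal, ps.snp_count, seed=int(seeds[1]), child_id=f"{focal.id}_varA1")
        )
    elif ps.name == "B":
        targets = np.linspace(96.0, 99.0, ps.n_genomes - 1)
        for i, t in enumerate(targets):
            genomes.append(
                evolve_to_ani(
                    focal, float(t), seed=int(seeds[i + 1]), child_id=f"{focal.id}_varB{i+1}"
                )
            )
    else:  # C
        targets = np.linspace(75.0, 95.0, ps.n_genomes - 1)
        for i, t in enumerate(targets):
            genomes.append(
                evolve_to_ani(
                    focal,
                    float(t),
                    island=ps.island,
                    seed=int(seeds[i + 1]),
                    child_id=f"{focal.id}_varC{i+1}",
                )
            )
    abundances = (
        np.asarray(ps.abundances)
        if ps.abundances is not None
        else np.full(ps.n_genomes, 1.0 / ps.n_genomes)
    )
    return Population(genomes=genomes, abundances=abundances, preset_name=ps.name)


def replay_mutations(parent: Genome, child: Genome) -> str:
    """Reconstruct the child sequence from the parent and the mutation record."""
    arr = np.frombuffer(parent.sequence.encode(), dtype="S1").copy()
    for sub in child.mutations.substitutions:
        if arr[sub.position - 1].decode() != sub.ref:
            raise ConfigurationError(
                f"mutation record inconsistent at position {sub.position}"
            )
        arr[sub.position - 1] = sub.alt.encode()
    return arr.tobytes().decode()
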