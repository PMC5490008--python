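"""End-to-end scenario runner: configuration, artifacts, manifest.

``run_scenario`` wires the stages together — population generation, read
simulation, fragment recruitment (KPKG + diversity curve), SNP calling and
assembly evaluation — writes every intermediate artifact as a plain-text
file, and records a JSON manifest with a SHA-256 digest per file.  A single
global seed is expanded into per-stage seeds by a fixed splitting rule that
is itself recorded in the manifest, so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import popgen, readsim, recruit, snps
from .assembly import AssemblyParams, debruijn_assemble, evaluate_contigs
from .errors import ConfigurationError
from .recruit import RecruitParams
from .readsim import ReadSimParams
from .snps import PileupParams, SnpCallerParams

log = logging.getLogger("virodiv")

_STAGES = ("popgen", "background", "readsim", "recruit", "snpstat", "asmeval")


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed, manifest-recorded seed-splitting rule."""
    idx = _STAGES.index(stage)
    return (global_seed * 1_000_003 + 7919 * (idx + 1)) % (2**31 - 1)


@dataclass
class ScenarioConfig:
    preset: str = "A"
    genome_length: int = 15000
    gc: float = 0.40
    focal_fasta: str | None = None
    n_background: int = 3
    background_length_range: tuple[int, int] = (5000, 10000)
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    coverage: float | None = 10.0
    n_pairs: int | None = None
    min_qcov_pct: float = 80.0
    assignment_mode: str = "best_hit"
    snp_min_coverage: int = 5
    snp_max_p: float = 1e-6
    snp_error_rate: float = 0.01
    k: int = 31
    min_kmer_count: int = 2
    bubble_policy: str = "pop"
    seed: int = 0
    out_dir: str = "scenario_run"

    def validate(self) -> None:
        if self.preset.upper() not in {"A", "B", "C"}:
            raise ConfigurationError("preset must be A, B or C")
        if self.coverage is not None and self.n_pairs is not None:
            raise ConfigurationError("give either coverage or n_pairs, not both")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_population(pop: popgen.Population, out: Path) -> list[Path]:
    """Population as multi-FASTA + mutations TSV + islands BED + abundances TSV."""
    paths = []
    fasta = out / "population.fasta"
    with open(fasta, "w") as fh:
        for g in pop.genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i : i + 80] + "\n")
    paths.append(fasta)

    mut = out / "mutations.tsv"
    with open(mut, "w") as fh:
        fh.write("genome_id\tposition\tref\talt\n")
        for g in pop.genomes:
            for s in g.mutations.substitutions:
                fh.write(f"{g.id}\t{s.position}\t{s.ref}\t{s.alt}\n")
    paths.append(mut)

    bed = out / "islands.bed"
    with open(bed, "w") as fh:
        for g in pop.genomes:
            for isl in g.islands:
                fh.write(f"{g.id}\t{isl.start - 1}\t{isl.end}\tisland\t{isl.divergence}\n")
    paths.append(bed)

    ab = out / "abundances.tsv"
    with open(ab, "w") as fh:
        fh.write("genome_id\tabundance\n")
        for g, a in zip(pop.genomes, pop.abundances):
            fh.write(f"{g.id}\t{a:.6f}\n")
    paths.append(ab)
    return paths


def run_scenario(config: ScenarioConfig) -> dict:
    """Execute all stages for one scenario; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "files": {},
        "stages": {},
    }
    paths: list[Path] = []

    def run_stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed (inputs in {out})") from exc
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 3)}
        log.info("stage %s done in %.2fs", name, time.time() - t0)
        return result

    # --- popgen -----------------------------------------------------------
    def _popgen():
        if config.focal_fasta:
            from Bio import SeqIO

            rec = next(SeqIO.parse(config.focal_fasta, "fasta"))
            focal = popgen.Genome(id=rec.id, sequence=str(rec.seq).upper())
        else:
            focal = popgen.generate_reference(
                config.genome_length, config.gc, seed=stage_seed(config.seed, "popgen")
            )
        pop = popgen.build_scenario(
            config.preset.upper(), focal, seed=stage_seed(config.seed, "popgen")
        )
        paths.extend(write_population(pop, out))
        return pop

    pop = run_stage("popgen", _popgen)

    background = run_stage(
        "background",
        lambda: readsim.make_background(
            config.n_background,
            config.background_length_range,
            seed=stage_seed(config.seed, "background"),
        ),
    )

    # --- readsim ----------------------------------------------------------
    def _readsim():
        params = ReadSimParams(
            read_length=config.read_length,
            insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            error_rate=config.error_rate,
            coverage=config.coverage,
            n_pairs=config.n_pairs,
            seed=stage_seed(config.seed, "readsim"),
        )
        reads = readsim.simulate_reads(pop, background, params)
        readsim.write_fastq(reads, out / "reads_1.fastq", out / "reads_2.fastq")
        readsim.write_truth_table(reads, out / "truth.tsv")
        paths.extend([out / "reads_1.fastq", out / "reads_2.fastq", out / "truth.tsv"])
        return reads

    reads = run_stage("readsim", _readsim)
    metagenome_bases = readsim.total_bases(reads)

    # --- recruit ----------------------------------------------------------
    def _recruit():
        params = RecruitParams(
            min_qcov_pct=config.min_qcov_pct,
            assignment_mode=recruit.AssignmentMode(config.assignment_mode),
        )
        hits = recruit.recruit_reads(reads, pop.genomes, params)
        recruit.write_hits_tsv(hits, out / "hits.tsv")
        paths.append(out / "hits.tsv")
        lengths = {g.id: len(g.sequence) for g in pop.genomes}
        with open(out / "kpkg.tsv", "w") as fh:
            fh.write("genome_id\tidentity_cutoff\trecruited_kb\tkpkg\tn_reads\n")
            for cutoff in (95.0, 70.0):
                for st in recruit.compute_kpkg(hits, lengths, metagenome_bases, cutoff):
                    fh.write(
                        f"{st.genome_id}\t{cutoff:.0f}\t{st.recruited_kb:.3f}\t"
                        f"{st.kpkg:.3f}\t{st.n_reads}\n"
                    )
        paths.append(out / "kpkg.tsv")
        curve = recruit.diversity_curve(hits, pop.focal.id)
        with open(out / "diversity_curve.tsv", "w") as fh:
            fh.write("bin_low\tbin_high\tpct_reads\n")
            for lo, hi, pct in zip(curve.bin_edges[:-1], curve.bin_edges[1:], curve.pct_reads):
                fh.write(f"{lo:.1f}\t{hi:.1f}\t{pct:.4f}\n")
        paths.append(out / "diversity_curve.tsv")
        return hits

    hits = run_stage("recruit", _recruit)

    # --- snpstat ----------------------------------------------------------
    def _snpstat():
        pileup = snps.build_pileup(hits, reads, pop.focal, PileupParams())
        calls = snps.call_snps(
            pileup,
            SnpCallerParams(
                min_coverage=config.snp_min_coverage,
                max_p=config.snp_max_p,
                error_rate=config.snp_error_rate,
            ),
        )
        snps.write_vcf(calls, pop.focal.id, out / "snps.vcf")
        paths.append(out / "snps.vcf")
        try:
            stat = snps.snp_frequency(calls, pileup, min_coverage=config.snp_min_coverage)
            payload = asdict(stat)
        except Exception as exc:  # no effective genome at this depth
            payload = {"error": str(exc)}
        (out / "snp_frequency.json").write_text(json.dumps(payload, indent=2) + "\n")
        paths.append(out / "snp_frequency.json")
        return calls

    run_stage("snpstat", _snpstat)

    # --- asmeval ----------------------------------------------------------
    def _asmeval():
        params = AssemblyParams(
            k=config.k,
            min_kmer_count=config.min_kmer_count,
            bubble_policy=config.bubble_policy,
        )
        contigs = debruijn_assemble(reads, params)
        with open(out / "contigs.fasta", "w") as fh:
            for c in contigs:
                fh.write(f">{c.id} cov={c.mean_kmer_coverage:.1f}\n{c.sequence}\n")
        paths.append(out / "contigs.fasta")
        report = evaluate_contigs(contigs, pop)
        payload = {
            "recovery_fraction": {k: round(v, 6) for k, v in report.recovery_fraction.items()},
            "n_contigs": report.n_contigs,
            "contigs": [
                {
                    "contig_id": c.contig_id,
                    "assigned_genome": c.assigned_genome,
                    "identity_pct": round(c.identity_pct, 3),
                    "chimera": c.chimera,
                    "n_sites": len(c.alleles),
                }
                for c in report.contigs
            ],
        }
        (out / "assembly_report.json").write_text(json.dumps(payload, indent=2) + "\n")
        with open(out / "assembly_report.tsv", "w") as fh:
            fh.write("genome_id\trecovery_fraction\n")
            for gid, frac in report.recovery_fraction.items():
                fh.write(f"{gid}\t{frac:.6f}\n")
        paths.extend([out / "assembly_report.json", out / "assembly_report.tsv"])
        return report

    run_stage("asmeval", _asmeval)

    for p in paths:
        manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
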