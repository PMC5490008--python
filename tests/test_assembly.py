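"""De Bruijn assembly, bubble counting, chimera-aware contig evaluation."""

import numpy as np
import pytest

from virodiv.align import DiffSet, Substitution
from virodiv.assembly import (
    AssemblyParams,
    Contig,
    count_bubbles,
    debruijn_assemble,
    evaluate_contigs,
)
from virodiv.errors import InputError
from virodiv.popgen import Genome, Population, generate_reference, mutate_genome
from virodiv.readsim import ReadSimParams, simulate_reads

from conftest import mutate_at

K = 31
SINGLE_COPY = AssemblyParams(min_kmer_count=1)


def spaced_haplotypes(length=15000, n_snps=20, spacing=700, seed=50):
    """Two haplotypes whose SNPs are all > k apart (isolated bubbles)."""
    parent = generate_reference(length, 0.40, seed=seed)
    positions = [500 + i * spacing for i in range(n_snps)]
    child_seq = mutate_at(parent.sequence, positions)
    subs = [
        Substitution(position=p + 1, ref=parent.sequence[p], alt=child_seq[p])
        for p in positions
    ]
    child = Genome(
        id="hap2",
        sequence=child_seq,
        parent_id=parent.id,
        mutations=DiffSet(substitutions=subs),
    )
    return parent, child


class TestParams:
    @pytest.mark.parametrize("k", [14, 16, 129])
    def test_bad_k_rejected(self, k):
        with pytest.raises(InputError):
            AssemblyParams(k=k)


class TestAssemble:
    def test_no_reads_gives_no_contigs(self):
        assert debruijn_assemble([]) == []

    def test_single_genome_single_contig(self, focal_genome, single_population):
        """50x error-free reads from one 15-kb genome -> one near-full contig."""
        reads = simulate_reads(
            single_population, params=ReadSimParams(n_pairs=2500, seed=51)
        )
        contigs = debruijn_assemble(reads)
        assert len(contigs) == 1
        report = evaluate_contigs(contigs, Population([focal_genome], [1.0]))
        assert report.recovery_fraction[focal_genome.id] >= 0.99
        assert not report.contigs[0].chimera

    def test_reassembly_idempotent(self, single_population):
        """Reads simulated from an emitted contig reassemble to the same
        length within +/- k."""
        reads = simulate_reads(
            single_population, params=ReadSimParams(n_pairs=2500, seed=52)
        )
        (contig,) = debruijn_assemble(reads)
        pop2 = Population([Genome(id="c", sequence=contig.sequence)], [1.0])
        reads2 = simulate_reads(pop2, params=ReadSimParams(n_pairs=2500, seed=53))
        (contig2,) = debruijn_assemble(reads2)
        assert abs(len(contig2) - len(contig)) <= K


class TestBubbles:
    def test_single_genome_no_bubbles(self, focal_genome):
        assert count_bubbles([focal_genome.sequence], SINGLE_COPY) == 0

    def test_one_isolated_snp_one_bubble(self):
        parent, child = spaced_haplotypes(n_snps=1, seed=54)
        assert count_bubbles([parent.sequence, child.sequence], SINGLE_COPY) == 1

    def test_twenty_spaced_snps_twenty_bubbles(self):
        """Scenario-A-like haplotypes with 20 SNPs spaced > k apart give a
        graph with exactly 20 simple bubbles."""
        parent, child = spaced_haplotypes(n_snps=20, seed=55)
        assert count_bubbles([parent.sequence, child.sequence], SINGLE_COPY) == 20

    def test_popping_removes_all_bubbles(self):
        parent, child = spaced_haplotypes(n_snps=5, seed=56)
        contigs = debruijn_assemble([parent.sequence, child.sequence], SINGLE_COPY)
        assert len(contigs) == 1  # collapsed consensus


class TestEvaluateContigs:
    def _population(self, seed=57):
        parent = generate_reference(6000, 0.45, seed=seed)
        child = mutate_genome(parent, 20, seed=seed + 1)
        return Population([parent, child], [0.5, 0.5])

    def test_exact_parent_contig_not_chimeric(self):
        pop = self._population()
        contig = Contig("c0", pop.genomes[0].sequence, 30.0)
        report = evaluate_contigs([contig], pop)
        assert report.recovery_fraction[pop.genomes[0].id] == pytest.approx(1.0)
        assert not report.contigs[0].chimera

    def test_constructed_mixed_allele_contig_is_chimeric(self):
        """A contig carrying parent-1 alleles at half the discriminating sites
        and parent-2 alleles at the other half is flagged."""
        pop = self._population()
        parent, child = pop.genomes
        positions = sorted(s.position for s in child.mutations.substitutions)
        mixed = list(parent.sequence)
        for p in positions[10:]:
            mixed[p - 1] = child.sequence[p - 1]
        report = evaluate_contigs([Contig("mix", "".join(mixed), 30.0)], pop)
        assert report.contigs[0].chimera

    def test_pure_child_contig_assigned_to_child(self):
        pop = self._population()
        report = evaluate_contigs([Contig("c", pop.genomes[1].sequence, 30.0)], pop)
        assert report.contigs[0].assigned_genome == pop.genomes[1].id
        assert not report.contigs[0].chimera

    def test_external_contigs_accepted(self):
        """Contig objects built from an external FASTA-style source produce
        the same report schema."""
        pop = self._population()
        external = [Contig("ext_1", pop.genomes[0].sequence[1000:4000], 1.0)]
        report = evaluate_contigs(external, pop)
        assert set(report.recovery_fraction) == {g.id for g in pop.genomes}
        assert report.n_contigs == 1


class TestScenarioChimerism:
    def test_scenario_a_assembly_mixes_alleles(self, focal_genome):
        """Across 10 seeded 50x scenario-A assemblies with bubble popping, at
        least one run emits a contig mixing alleles of both haplotypes."""
        from virodiv.popgen import build_scenario

        pop = build_scenario("A", focal_genome, seed=58)
        observed = 0
        for seed in range(10):
            reads = simulate_reads(pop, params=ReadSimParams(n_pairs=5000, seed=seed))
            contigs = debruijn_assemble(reads)
            report = evaluate_contigs(contigs, pop)
            if any(c.chimera for c in report.contigs):
                observed += 1
        assert observed >= 1
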