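"""Pileup construction, binomial SNP calling, SNP-frequency statistic."""

import math

import numpy as np
import pytest

from virodiv.errors import InputError, UndefinedStatisticError
from virodiv.popgen import Population, generate_reference, mutate_genome
from virodiv.readsim import ReadSimParams, simulate_reads
from virodiv.recruit import RecruitParams, recruit_reads
from virodiv.snps import (
    Pileup,
    PileupParams,
    SnpCallerParams,
    binomial_tail,
    build_pileup,
    call_snps,
    snp_frequency,
)


def exact_binom_sf(k: int, n: int, p: float) -> float:
    """Independent closed-form oracle: P(X >= k), X ~ Binomial(n, p)."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


@pytest.fixture(scope="module")
def ref_genome():
    return generate_reference(3000, 0.45, seed=40)


class TestBuildPileup:
    def test_single_read_depth_span(self, ref_genome):
        read = ("r1", ref_genome.sequence[100:250])  # positions 101..250
        hits = recruit_reads([read], [ref_genome])
        pileup = build_pileup(hits, [read], ref_genome)
        depth = pileup.depth
        assert (depth[100:250] == 1).all()
        assert depth[:100].sum() == 0 and depth[250:].sum() == 0

    def test_low_identity_read_excluded(self, ref_genome):
        # ~10% divergence: passes recruitment search floor, fails mapping filter
        child = mutate_genome(ref_genome, 300, seed=41)
        read = ("r_div", child.sequence[1000:1150])
        hits = recruit_reads([read], [ref_genome])
        assert len(hits) == 1 and hits["pident"].iloc[0] < 95.0
        pileup = build_pileup(hits, [read], ref_genome, PileupParams())
        assert pileup.depth.sum() == 0

    def test_effective_genome_counts_min_coverage(self, ref_genome):
        reads = [(f"r{i}", ref_genome.sequence[500:650]) for i in range(6)]
        hits = recruit_reads(reads, [ref_genome])
        pileup = build_pileup(hits, reads, ref_genome)
        assert pileup.effective_positions(min_coverage=5) == 150
        assert pileup.effective_positions(min_coverage=7) == 0


class TestCallSnps:
    @pytest.mark.parametrize("depth", [5, 10, 20, 50])
    @pytest.mark.parametrize("alt", [1, 2, 5, 10])
    def test_pvalue_matches_closed_form_oracle(self, depth, alt):
        if alt > depth:
            pytest.skip("alt cannot exceed depth")
        got = float(binomial_tail(alt, depth, 0.01))
        assert got == pytest.approx(exact_binom_sf(alt, depth, 0.01), rel=1e-9)

    def _pileup_single_site(self, depth, alt_count):
        ref_seq = "A" * 11
        counts = np.zeros((4, 11), dtype=np.int32)
        counts[0, 5] = depth - alt_count  # A (reference)
        counts[1, 5] = alt_count  # C
        return Pileup("p", ref_seq, counts, mapped_bases=depth * 11, n_reads=depth)

    def test_strong_site_called(self):
        calls = call_snps(self._pileup_single_site(20, 10))
        (site,) = calls
        assert site.is_snp and site.p_value < 1e-6
        assert site.alt_base == "C" and site.alt_count == 10

    def test_below_min_coverage_never_called(self):
        for alt in (1, 2, 3, 4):
            calls = call_snps(self._pileup_single_site(4, alt))
            assert not calls[0].is_snp

    def test_single_alt_read_not_significant(self):
        (site,) = call_snps(self._pileup_single_site(20, 1))
        assert site.p_value == pytest.approx(1 - 0.99**20, rel=1e-9)
        assert not site.is_snp

    def test_pvalue_monotone_in_alt_count(self):
        ps = [
            call_snps(self._pileup_single_site(30, a))[0].p_value for a in range(1, 15)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bad_error_rate_rejected(self):
        with pytest.raises(InputError):
            SnpCallerParams(error_rate=0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_snp_recovery(self, seed):
        """30 planted SNPs at population frequency 0.5, 20x error-free
        coverage of each haplotype: recall >= 0.9 and zero calls outside
        planted sites."""
        parent = generate_reference(15000, 0.40, seed=100 + seed)
        child = mutate_genome(parent, 30, seed=200 + seed)
        pop = Population(genomes=[parent, child], abundances=[0.5, 0.5])
        n_pairs = int(2 * 15000 * 20 / 300)
        reads = simulate_reads(pop, params=ReadSimParams(n_pairs=n_pairs, seed=seed))
        hits = recruit_reads(reads, [parent], RecruitParams())
        pileup = build_pileup(hits, reads, parent)
        calls = call_snps(pileup)
        called = {c.position for c in calls if c.is_snp}
        planted = {s.position for s in child.mutations.substitutions}
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9
        assert not (called - planted), "false SNP calls outside planted sites"


class TestSnpFrequency:
    def test_arithmetic(self):
        """30 SNPs over 15 effective kb and 3 Mb mapped -> 30/15/3 = 0.667."""
        counts = np.zeros((4, 15000), dtype=np.int32)
        counts[0, :] = 5  # uniform 5x A coverage
        pileup = Pileup("p", "A" * 15000, counts, mapped_bases=3_000_000)
        calls = call_snps(self._with_snps(pileup, 30))
        stat = snp_frequency(calls, pileup)
        assert stat.n_snps == 30
        assert stat.effective_kb == pytest.approx(15.0)
        assert stat.frequency == pytest.approx(30 / 15 / 3, rel=1e-9)

    @staticmethod
    def _with_snps(pileup, n):
        # plant unambiguous variant columns at the first n positions
        pileup.counts[0, :n] = 0
        pileup.counts[2, :n] = 20
        pileup.counts[0, n:] = 20
        return pileup

    def test_zero_snps(self):
        counts = np.zeros((4, 2000), dtype=np.int32)
        counts[0, :] = 6
        pileup = Pileup("p", "A" * 2000, counts, mapped_bases=500_000)
        stat = snp_frequency(call_snps(pileup), pileup)
        assert stat.n_snps == 0 and stat.frequency == 0.0

    def test_doubling_mapped_halves_frequency(self):
        counts = np.zeros((4, 1000), dtype=np.int32)
        counts[0, :] = 10
        counts[2, :5] = 10
        counts[0, :5] = 0
        pileup = Pileup("p", "A" * 1000, counts, mapped_bases=1)
        calls = call_snps(pileup)
        f1 = snp_frequency(calls, pileup, mapped_read_bases=1_000_000).frequency
        f2 = snp_frequency(calls, pileup, mapped_read_bases=2_000_000).frequency
        assert f1 == pytest.approx(2 * f2)

    def test_no_effective_genome_rejected(self):
        pileup = Pileup("p", "A" * 100, np.zeros((4, 100), dtype=np.int32), mapped_bases=10)
        with pytest.raises(UndefinedStatisticError):
            snp_frequency([], pileup)
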