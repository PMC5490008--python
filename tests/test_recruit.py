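"""Fragment recruitment: filters, assignment, KPKG, diversity curves."""

import numpy as np
import pandas as pd
import pytest

from virodiv.errors import ConsistencyError, InputError, UndefinedStatisticError
from virodiv.popgen import Population, generate_reference, mutate_genome
from virodiv.readsim import ReadSimParams, simulate_reads
from virodiv.recruit import (
    HIT_COLUMNS,
    AssignmentMode,
    RecruitParams,
    compute_kpkg,
    diversity_curve,
    recruit_reads,
    relative_recruitment,
)


@pytest.fixture(scope="module")
def small_genome():
    return generate_reference(3000, 0.45, seed=30)


@pytest.fixture(scope="module")
def roundtrip_hits(small_genome):
    pop = Population(genomes=[small_genome], abundances=[1.0])
    reads = simulate_reads(pop, params=ReadSimParams(n_pairs=150, seed=6))
    return reads, recruit_reads(reads, [small_genome])


class TestRecruitReads:
    def test_error_free_roundtrip(self, roundtrip_hits):
        reads, hits = roundtrip_hits
        assert len(hits) == len(reads)
        assert (hits["pident"] == 100.0).all()
        assert (hits["qcovs"] == 100.0).all()

    def test_divergent_read_passes_genus_not_species(self, small_genome):
        child = mutate_genome(small_genome, 300, seed=7)  # ~10% divergence
        read = ("div_read", child.sequence[1000:1150])
        hits = recruit_reads([read], [small_genome])
        assert len(hits) == 1
        ident = hits["pident"].iloc[0]
        assert 70.0 <= ident < 95.0

    def test_end_overlap_read_filtered_by_qcov(self, small_genome):
        # half the read hangs off the genome end
        tail = small_genome.sequence[-75:]
        read = ("edge_read", tail + "ACGT" * 19)  # 151 bp, 75 alignable
        hits = recruit_reads([read], [small_genome])
        assert hits.empty

    def test_best_hit_unique_per_read(self, small_genome):
        variant = mutate_genome(small_genome, 30, seed=8)
        pop = Population(genomes=[small_genome, variant], abundances=[0.5, 0.5])
        reads = simulate_reads(pop, params=ReadSimParams(n_pairs=100, seed=9))
        hits = recruit_reads(reads, pop.genomes, RecruitParams())
        assert hits["qseqid"].is_unique

    def test_all_mode_keeps_multimappers(self, small_genome):
        variant = mutate_genome(small_genome, 5, seed=10)
        reads = [("r1", small_genome.sequence[500:650])]
        hits = recruit_reads(
            reads,
            [small_genome, variant],
            RecruitParams(assignment_mode=AssignmentMode.ALL),
        )
        assert len(hits) == 2

    def test_empty_reference_set_rejected(self):
        with pytest.raises(InputError):
            recruit_reads([("r", "ACGT" * 40)], [])


def _toy_hits(n, seed, genomes=("g1", "g2")):
    rng = np.random.default_rng(seed)
    spans = rng.integers(80, 151, size=n)
    qstart = rng.integers(1, 5, size=n)
    return pd.DataFrame(
        {
            "qseqid": [f"r{i}" for i in range(n)],
            "sseqid": rng.choice(genomes, size=n),
            "pident": rng.uniform(70, 100, size=n).round(2),
            "length": spans,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": qstart,
            "qend": qstart + spans - 1,
            "sstart": 1,
            "send": spans,
            "score": spans,
            "qcovs": 100.0,
        },
        columns=HIT_COLUMNS,
    )


class TestKpkg:
    def test_hand_arithmetic(self):
        """100 reads x 200 aligned bp on a 10-kb genome from a 1-Mb metagenome:
        recruited 20 kb, KPKG = 20 / 10 / 0.001 = 2000."""
        hits = pd.DataFrame(
            {
                "qseqid": [f"r{i}" for i in range(100)],
                "sseqid": "g",
                "pident": 100.0,
                "length": 200,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": 1,
                "qend": 200,
                "sstart": 1,
                "send": 200,
                "score": 200,
                "qcovs": 100.0,
            },
            columns=HIT_COLUMNS,
        )
        (stat,) = compute_kpkg(hits, {"g": 10000}, 1_000_000, 95.0)
        assert stat.recruited_kb == pytest.approx(20.0)
        assert stat.kpkg == pytest.approx(2000.0)

    def test_zero_hits(self):
        stats = compute_kpkg(_toy_hits(0, 0), {"g1": 5000}, 10_000, 95.0)
        assert stats[0].kpkg == 0.0

    def test_doubling_metagenome_halves_kpkg(self):
        hits = _toy_hits(200, 1)
        a = compute_kpkg(hits, {"g1": 5000, "g2": 8000}, 1_000_000, 70.0)
        b = compute_kpkg(hits, {"g1": 5000, "g2": 8000}, 2_000_000, 70.0)
        for sa, sb in zip(a, b):
            assert sa.kpkg == pytest.approx(2 * sb.kpkg)

    @pytest.mark.parametrize("cutoff", [70.0, 95.0])
    def test_matches_bruteforce_accumulation(self, cutoff):
        """KPKG equals an independent per-row accumulation on a 1,000-hit table."""
        hits = _toy_hits(1000, 42)
        lengths = {"g1": 5000, "g2": 8000}
        meta = 5_000_000
        stats = {s.genome_id: s for s in compute_kpkg(hits, lengths, meta, cutoff)}
        brute = {g: 0.0 for g in lengths}
        for row in hits.itertuples(index=False):
            if row.pident >= cutoff:
                brute[row.sseqid] += (row.qend - row.qstart + 1) / 1000.0
        for g in lengths:
            expected = brute[g] / (lengths[g] / 1000.0) / (meta / 1e9)
            assert stats[g].kpkg == pytest.approx(expected, rel=1e-12)

    def test_unknown_genome_rejected(self):
        with pytest.raises(ConsistencyError):
            compute_kpkg(_toy_hits(10, 2), {"g1": 5000}, 1000, 95.0)


class TestRelativeRecruitment:
    def test_arithmetic(self):
        shares = relative_recruitment({"a": 2.0, "b": 1.0, "c": 1.0})
        assert shares == {"a": 0.5, "b": 0.25, "c": 0.25}

    def test_single_set(self):
        assert relative_recruitment({"only": 3.7}) == {"only": 1.0}

    def test_permutation_invariant(self):
        x = {"a": 1.0, "b": 2.0, "c": 5.0}
        y = dict(reversed(list(x.items())))
        assert relative_recruitment(x) == relative_recruitment(y)

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            relative_recruitment({"a": 0.0, "b": 0.0})


class TestDiversityCurve:
    def test_all_reads_at_identity_100(self, roundtrip_hits):
        _, hits = roundtrip_hits
        curve = diversity_curve(hits, hits["sseqid"].iloc[0])
        assert curve.pct_reads[-1] == pytest.approx(100.0)
        assert curve.pct_reads[:-1].sum() == pytest.approx(0.0)

    def test_bins_sum_to_100(self):
        hits = _toy_hits(500, 3)
        curve = diversity_curve(hits, "g1")
        assert curve.pct_reads.sum() == pytest.approx(100.0)

    def test_out_of_range_counted_in_terminal_bin(self):
        hits = _toy_hits(5, 4)
        hits.loc[:, "pident"] = 55.0
        hits.loc[:, "sseqid"] = "g1"
        with pytest.warns(UserWarning):
            curve = diversity_curve(hits, "g1")
        assert curve.pct_reads[0] == pytest.approx(100.0)

    def test_bad_edges_rejected(self):
        with pytest.raises(InputError):
            diversity_curve(_toy_hits(5, 5), "g1", np.array([100.0, 70.0]))
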