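"""Toy de Bruijn assembler and provenance-aware contig evaluation.

The assembler is a deliberately small stand-in for production metagenomic
assemblers, built to expose their consensus-collapsing behaviour on
microdiverse populations: k-mers (default k=31) are counted on both strands,
low-count k-mers dropped, unbranched paths compacted to unitigs, and simple
two-path bubbles — the graph signature of an isolated SNP between co-occurring
haplotypes — optionally popped, keeping the higher-coverage branch.  Popping
decides each bubble independently, which is exactly what lets a consensus
contig mix alleles from different source genomes.

The evaluator aligns contigs back to the truth genomes, reports per-genome
recovery at a strict 99% identity (so a collapsed consensus of <=95%-ANI
variants cannot count as recovering any one of them), reads off the allele
each contig carries at every truth-discriminating SNP site, and flags a
contig as chimeric when no single truth genome is consistent with all of its
covered discriminating sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .align import _parse_cigar, reverse_complement
from .errors import InputError
from .popgen import Population

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
_DECODE = "ACGT"


@dataclass(frozen=True)
class AssemblyParams:
    k: int = 31
    min_kmer_count: int = 2
    bubble_policy: str = "pop"  # "pop" | "keep"

    def __post_init__(self) -> None:
        if not (15 <= self.k <= 127) or self.k % 2 == 0:
            raise InputError("k must be odd and in [15, 127]")
        if self.bubble_policy not in ("pop", "keep"):
            raise InputError("bubble_policy must be 'pop' or 'keep'")


@dataclass
class Contig:
    id: str
    sequence: str
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContigEvaluation:
    contig_id: str
    assigned_genome: str | None
    identity_pct: float
    alleles: dict  # site position -> (contig base, tuple of matching genome ids)
    chimera: bool


@dataclass
class AssemblyReport:
    recovery_fraction: dict  # genome_id -> fraction covered at >=99% identity
    contigs: list  # list[ContigEvaluation]
    n_contigs: int


def _canonical(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def _kmer_values(seqs: list[str], k: int) -> np.ndarray:
    """All k-mer codes (2 bits/base, uint64) over both strands of ``seqs``."""
    big = "N".join(s for s in seqs if len(s) >= k)
    if not big:
        return np.empty(0, dtype=np.uint64)
    codes = _ENCODE[np.frombuffer(big.encode(), dtype=np.uint8)]
    n = len(codes)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    # rolling 2-bit encoding: k vectorized shift-or passes over the array
    codes64 = codes.astype(np.uint64)
    vals = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for i in range(k):
        vals <<= two
        vals |= codes64[i : i + m]
    bad = (codes == 255).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad, dtype=np.int32)))
    valid = (cum[k:] - cum[:-k]) == 0  # window contains no separator
    fwd = vals[valid]
    return np.concatenate([fwd, _revcomp_kmers(fwd, k)])


def _revcomp_kmers(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement 2-bit-packed k-mers, vectorized."""
    mask = np.uint64((1 << (2 * k)) - 1)
    v = (~vals) & mask  # A<->T, C<->G is XOR 0b11 per base
    # reverse the order of the 32 2-bit groups, then drop the unused low end
    m1 = np.uint64(0x3333333333333333)
    m2 = np.uint64(0x0F0F0F0F0F0F0F0F)
    m3 = np.uint64(0x00FF00FF00FF00FF)
    m4 = np.uint64(0x0000FFFF0000FFFF)
    v = ((v & m1) << np.uint64(2)) | ((v >> np.uint64(2)) & m1)
    v = ((v & m2) << np.uint64(4)) | ((v >> np.uint64(4)) & m2)
    v = ((v & m3) << np.uint64(8)) | ((v >> np.uint64(8)) & m3)
    v = ((v & m4) << np.uint64(16)) | ((v >> np.uint64(16)) & m4)
    v = (v << np.uint64(32)) | (v >> np.uint64(32))
    return v >> np.uint64(64 - 2 * k)


def _decode_kmer(val: int, k: int) -> str:
    return "".join(_DECODE[(val >> (2 * (k - 1 - i))) & 3] for i in range(k))


class _Graph:
    """De Bruijn graph over a sorted array of solid k-mers."""

    def __init__(self, kmers: np.ndarray, counts: np.ndarray, k: int):
        self.k = k
        self.kmers = kmers  # sorted uint64
        self.counts = counts
        self.mask = np.uint64((1 << (2 * k)) - 1)
        n = len(kmers)
        # successor/predecessor index tables: succ[b][i] = index of kmer
        # following kmers[i] with appended base b, or -1
        self.succ = np.full((4, n), -1, dtype=np.int64)
        self.pred = np.full((4, n), -1, dtype=np.int64)
        if n == 0:
            self.out_deg = np.zeros(0, dtype=np.int64)
            self.in_deg = np.zeros(0, dtype=np.int64)
            return
        shifted = (kmers << np.uint64(2)) & self.mask
        high = np.uint64(2 * (k - 1))
        down = kmers >> np.uint64(2)
        for b in range(4):
            cand = shifted | np.uint64(b)
            idx = np.searchsorted(kmers, cand)
            idx[idx >= n] = n - 1
            ok = kmers[idx] == cand
            self.succ[b, ok] = idx[ok]
            cand = down | (np.uint64(b) << high)
            idx = np.searchsorted(kmers, cand)
            idx[idx >= n] = n - 1
            ok = kmers[idx] == cand
            self.pred[b, ok] = idx[ok]
        self.out_deg = (self.succ >= 0).sum(axis=0)
        self.in_deg = (self.pred >= 0).sum(axis=0)

    def sole_successor(self, i: int) -> int:
        if self.out_deg[i] != 1:
            return -1
        return int(self.succ[:, i].max())

    def unitigs(self) -> list[dict]:
        """Compact unbranched paths; returns node dicts with sequence/coverage."""
        n = len(self.kmers)
        if n == 0:
            return []
        pred_max = self.pred.max(axis=0)
        succ_max = self.succ.max(axis=0)
        is_start = self.in_deg != 1
        one_in = ~is_start
        is_start[one_in] |= self.out_deg[pred_max[one_in]] != 1
        # plain Python lists make the walk loop cheap
        succ_next = np.where(self.out_deg == 1, succ_max, -1).tolist()
        in_deg = self.in_deg.tolist()
        visited = np.zeros(n, dtype=bool)
        units = []

        def walk(s: int) -> None:
            path = [s]
            visited[s] = True
            cur = s
            while True:
                nxt = succ_next[cur]
                if nxt < 0 or visited[nxt] or in_deg[nxt] != 1:
                    break
                path.append(nxt)
                visited[nxt] = True
                cur = nxt
            units.append(self._unit_from_path(path))

        for s in np.flatnonzero(is_start):
            walk(int(s))
        for s in range(n):  # anything left lives on an isolated cycle
            if not visited[s]:
                walk(s)
        return units

    def _unit_from_path(self, path: list[int]) -> dict:
        k = self.k
        seq = _decode_kmer(int(self.kmers[path[0]]), k) + "".join(
            _DECODE[int(self.kmers[i]) & 3] for i in path[1:]
        )
        return {
            "path": path,
            "seq": seq,
            "cov": float(self.counts[path].mean()),
            "first": path[0],
            "last": path[-1],
        }


def _build_graph(kmers: np.ndarray, counts: np.ndarray, k: int) -> _Graph:
    # np.unique already returns kmers sorted; keep that invariant
    return _Graph(kmers, counts, k)


def _unitig_graph(g: _Graph) -> tuple[list[dict], dict]:
    units = g.unitigs()
    first_of = {u["first"]: ui for ui, u in enumerate(units)}
    for u in units:
        succs = []
        for b in range(4):
            j = int(g.succ[b, u["last"]])
            if j >= 0 and j in first_of:
                succs.append(first_of[j])
        u["succs"] = succs
        u["preds"] = []
    for ui, u in enumerate(units):
        for s in u["succs"]:
            units[s]["preds"].append(ui)
    return units, first_of


def _find_bubbles(units: list[dict]) -> list[tuple[int, int]]:
    """Pairs of parallel unitigs (same single predecessor and successor)."""
    groups: dict[tuple[int, int], list[int]] = {}
    for ui, u in enumerate(units):
        if len(u["preds"]) == 1 and len(u["succs"]) == 1:
            key = (u["preds"][0], u["succs"][0])
            if key[0] != ui and key[1] != ui:
                groups.setdefault(key, []).append(ui)
    bubbles = []
    for (p, s), members in groups.items():
        if len(members) >= 2 and p != s:
            members = sorted(members)
            for m in members[1:]:
                bubbles.append((members[0], m))
    return bubbles


def count_bubbles(reads, params: AssemblyParams | None = None) -> int:
    """Number of distinct simple bubbles in the read de Bruijn graph.

    Both strands of every read enter the graph, so each biological bubble
    appears as a forward and a reverse-complement twin; twins are collapsed
    by canonical branch sequence before counting.
    """
    params = params or AssemblyParams()
    seqs = [getattr(r, "sequence", r) for r in reads]
    kmers, counts = _solid_kmers(seqs, params)
    if len(kmers) == 0:
        return 0
    g = _build_graph(kmers, counts, params.k)
    units, _ = _unitig_graph(g)
    seen = set()
    for a, b in _find_bubbles(units):
        key = frozenset((_canonical(units[a]["seq"]), _canonical(units[b]["seq"])))
        seen.add(key)
    return len(seen)


def _solid_kmers(seqs: list[str], params: AssemblyParams) -> tuple[np.ndarray, np.ndarray]:
    vals = _kmer_values(seqs, params.k)
    if vals.size == 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    kmers, counts = np.unique(vals, return_counts=True)
    keep = counts >= params.min_kmer_count
    return kmers[keep], counts[keep]


def debruijn_assemble(reads, params: AssemblyParams | None = None) -> list[Contig]:
    """Assemble reads into contigs (unitigs after optional bubble popping).

    Bubble popping keeps the higher-mean-coverage branch; exact coverage ties
    keep the branch with the lexicographically smaller canonical sequence, so
    results are deterministic and strand-consistent.  Contigs shorter than 2k
    are suppressed, and each contig is reported once (canonical orientation).
    """
    params = params or AssemblyParams()
    seqs = [getattr(r, "sequence", r) for r in reads]
    kmers, counts = _solid_kmers(seqs, params)
    if len(kmers) == 0:
        return []
    while True:  # each popping round strictly removes k-mers, so this terminates
        g = _build_graph(kmers, counts, params.k)
        units, _ = _unitig_graph(g)
        if params.bubble_policy != "pop":
            break
        bubbles = _find_bubbles(units)
        if not bubbles:
            break
        drop: set[int] = set()
        for a, b in bubbles:
            ua, ub = units[a], units[b]
            if ua["cov"] != ub["cov"]:
                loser = a if ua["cov"] < ub["cov"] else b
            else:
                loser = a if _canonical(ua["seq"]) > _canonical(ub["seq"]) else b
            drop.add(loser)
        dead = np.zeros(len(kmers), dtype=bool)
        for ui in drop:
            dead[units[ui]["path"]] = True
        kmers, counts = kmers[~dead], counts[~dead]
        if len(kmers) == 0:
            return []
    contigs = []
    seen = set()
    for u in sorted(units, key=lambda u: (-len(u["seq"]), u["seq"])):
        if len(u["seq"]) < 2 * params.k:
            continue
        canon = _canonical(u["seq"])
        if canon in seen:
            continue
        seen.add(canon)
        contigs.append(
            Contig(id=f"contig_{len(contigs):04d}", sequence=canon, mean_kmer_coverage=u["cov"])
        )
    return contigs


def _best_placement(contig_seq: str, genome_seq: str):
    """Best whole-contig placement on either strand; returns
    (identity_pct, t_start0, t_end0, cigar_ops, oriented_query)."""
    best = None
    for qseq in (contig_seq, reverse_complement(contig_seq)):
        res = edlib.align(qseq, genome_seq, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        ops = _parse_cigar(res["cigar"])
        cols = sum(n for n, _ in ops)
        matches = sum(n for n, op in ops if op == "=")
        ident = 100.0 * matches / cols if cols else 0.0
        if best is None or ident > best[0]:
            t0, t1 = res["locations"][0]
            best = (ident, t0, t1, ops, qseq)
    return best


def _discriminating_sites(population: Population) -> dict[int, dict[str, str]]:
    """Truth alleles per genome at every site where population members differ.

    Positions are 1-based on the focal (parent) genome.  Only substitution
    records are considered; genomes without a record at a site carry the
    focal allele.
    """
    focal = population.focal
    sites: dict[int, dict[str, str]] = {}
    for g in population.genomes[1:]:
        for sub in g.mutations.substitutions:
            sites.setdefault(sub.position, {})[g.id] = sub.alt
    for pos, alleles in sites.items():
        ref = focal.sequence[pos - 1]
        for g in population.genomes:
            alleles.setdefault(g.id, ref)
    return sites


def evaluate_contigs(
    contigs: list[Contig],
    population: Population,
    recovery_identity_pct: float = 99.0,
    min_assign_identity_pct: float = 80.0,
) -> AssemblyReport:
    """Score contigs against the truth population.

    ``recovery_fraction[g]`` is the fraction of genome ``g`` covered by
    contig placements at >= ``recovery_identity_pct`` identity.  A contig is
    chimeric when every covered truth-discriminating site matches some
    genome's allele but no single genome matches at all of them.
    """
    sites = _discriminating_sites(population)
    genomes = population.genomes
    covered = {g.id: np.zeros(len(g.sequence), dtype=bool) for g in genomes}
    evaluations = []
    for contig in contigs:
        best_genome, best_ident = None, -1.0
        focal_placement = None
        rc = reverse_complement(contig.sequence)
        for g in genomes:
            # cheap distance-only screen; full path alignment only where the
            # placement might matter (recovery marking or focal allele calls)
            approx = -1.0
            for qseq in (contig.sequence, rc):
                res = edlib.align(qseq, g.sequence, mode="HW", task="distance")
                if res["editDistance"] >= 0:
                    approx = max(
                        approx,
                        100.0 * (len(qseq) - res["editDistance"]) / len(qseq),
                    )
            if approx > best_ident:
                best_ident, best_genome = approx, g.id
            needs_path = approx >= recovery_identity_pct - 1.0 or (
                g.id == population.focal.id and approx >= min_assign_identity_pct
            )
            if not needs_path:
                continue
            placement = _best_placement(contig.sequence, g.sequence)
            if placement is None:
                continue
            ident, t0, t1, _, _ = placement
            if ident > best_ident:
                best_ident, best_genome = ident, g.id
            if ident >= recovery_identity_pct:
                covered[g.id][t0 : t1 + 1] = True
            if g.id == population.focal.id:
                focal_placement = placement
        alleles: dict[int, tuple[str, tuple[str, ...]]] = {}
        chimera = False
        if focal_placement is not None and sites:
            ident, t0, _, ops, qseq = focal_placement
            # map focal positions -> contig base via the placement path
            base_at: dict[int, str] = {}
            qi, ti = 0, t0
            for n, op in ops:
                if op in "=X":
                    for k in range(n):
                        base_at[ti + k + 1] = qseq[qi + k]
                    qi += n
                    ti += n
                elif op == "I":
                    qi += n
                else:
                    ti += n
            consistent = {g.id for g in genomes}
            matched_any = []
            for pos, truth in sorted(sites.items()):
                b = base_at.get(pos)
                if b is None:
                    continue
                matches = tuple(gid for gid, allele in truth.items() if allele == b)
                alleles[pos] = (b, matches)
                if matches:
                    matched_any.append(set(matches))
                    consistent &= set(matches)
            if len(matched_any) >= 2 and not consistent:
                chimera = True
        evaluations.append(
            ContigEvaluation(
                contig_id=contig.id,
                assigned_genome=best_genome if best_ident >= min_assign_identity_pct else None,
                identity_pct=best_ident,
                alleles=alleles,
                chimera=chimera,
            )
        )
    recovery = {gid: float(mask.mean()) for gid, mask in covered.items()}
    return AssemblyReport(
        recovery_fraction=recovery, contigs=evaluations, n_contigs=len(contigs)
    )
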