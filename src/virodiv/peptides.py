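"""ORF finding, in-silico tryptic digestion and exact peptide recruitment.

Proteomic recruitment here is sequence-level: predicted proteins are digested
with trypsin rules (cleave after K or R, never before P, up to a bounded
number of missed cleavages) and peptides are matched against target proteomes
by exact, full-length substring identity only — one mismatching residue is a
miss.  Per-genome hit counts are normalized by genome size in kb.  Peptide
masses and post-translational modifications are deliberately not modelled:
the comparison is between predicted peptide sequences, not spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import pandas as pd
from Bio.Seq import Seq

from .align import reverse_complement
from .errors import InputError
from .popgen import Genome

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_START_CODONS = ("ATG", "GTG")
_STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
_TRANSLATION_TABLE = 11  # bacterial/archaeal/phage code


@dataclass(frozen=True)
class DigestParams:
    max_missed_cleavages: int = 4
    min_peptide_length: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_cleavages <= 10:
            raise InputError("max_missed_cleavages must be in [0, 10]")
        if self.min_peptide_length < 1:
            raise InputError("min_peptide_length must be >= 1")


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str  # amino acids, no stop
    genome_id: str
    strand: str
    start: int  # 1-based nt coords on the forward strand, inclusive
    end: int    # includes the stop codon


def _orfs_one_strand(seq: str, min_len_aa: int, strand: str, genome_len: int):
    """Stop-to-stop segments per frame; first ATG/GTG opens the ORF."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        seg_start = frame  # first codon index (nt) of the current open segment
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in _STOP_CODONS:
                orfs.extend(
                    _orf_in_segment(seq, seg_start, i + 3, min_len_aa, strand, genome_len)
                )
                seg_start = i + 3
            i += 3
    return orfs


def _orf_in_segment(seq, seg_start, seg_end, min_len_aa, strand, genome_len):
    """The ORF opened by the first start codon of a stop-bounded segment."""
    for i in range(seg_start, seg_end - 3, 3):
        if seq[i : i + 3] in _START_CODONS:
            aa_len = (seg_end - i) // 3 - 1  # stop codon excluded
            if aa_len < min_len_aa:
                return []
            nt = seq[i : seg_end - 3]
            prot = str(Seq(nt).translate(table=_TRANSLATION_TABLE))
            prot = "M" + prot[1:]  # alternative starts read as Met
            if strand == "+":
                start, end = i + 1, seg_end
            else:
                start, end = genome_len - seg_end + 1, genome_len - i
            return [(prot, strand, start, end)]
    return []


def find_orfs(genome: Genome, min_len_aa: int = 60) -> list[Protein]:
    """Predicted proteins from stop-to-stop ORFs on both strands.

    Start codons ATG/GTG; translation table 11; ordered by genomic position.
    """
    seq = genome.sequence
    if not seq:
        raise InputError("genome sequence is empty")
    raw = _orfs_one_strand(seq, min_len_aa, "+", len(seq))
    raw += _orfs_one_strand(reverse_complement(seq), min_len_aa, "-", len(seq))
    raw.sort(key=lambda t: (t[2], t[3], t[1]))
    return [
        Protein(
            id=f"{genome.id}_orf{i+1:03d}",
            sequence=prot,
            genome_id=genome.id,
            strand=strand,
            start=start,
            end=end,
        )
        for i, (prot, strand, start, end) in enumerate(raw)
    ]


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cleaves (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(protein, params: DigestParams | None = None) -> list[str]:
    """Tryptic peptides with up to ``max_missed_cleavages`` retained sites.

    Accepts a :class:`Protein` or a raw amino-acid string.  Output is
    deduplicated and sorted, hence deterministic.
    """
    params = params or DigestParams()
    seq = getattr(protein, "sequence", protein)
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise InputError(
            "protein contains non-standard residue(s): " + ", ".join(sorted(bad))
        )
    sites = cleavage_sites(seq)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    peptides = set()
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + params.max_missed_cleavages + 1, n_frag)):
            pep = seq[bounds[i] : bounds[j + 1]]
            if len(pep) >= params.min_peptide_length:
                peptides.add(pep)
    return sorted(peptides)


def peptide_recruit(
    peptides: list[str],
    proteomes: dict[str, list],
    genome_lengths: dict[str, int],
) -> pd.DataFrame:
    """Exact-match peptide recruitment against per-genome proteomes.

    ``proteomes`` maps genome id to its proteins (Protein objects or raw
    strings).  Returns one row per (peptide, protein) exact occurrence with
    the per-genome count normalized by genome length in kb.
    """
    if not peptides:
        warn("empty peptide list; nothing to recruit", stacklevel=2)
        return pd.DataFrame(
            columns=["peptide", "genome_id", "protein_id", "position", "normalized_count"]
        )
    rows = []
    for gid, proteins in proteomes.items():
        for pi, prot in enumerate(proteins):
            pseq = getattr(prot, "sequence", prot)
            pid = getattr(prot, "id", f"{gid}_prot{pi}")
            for pep in peptides:
                pos = pseq.find(pep)
                while pos >= 0:
                    rows.append((pep, gid, pid, pos, 0.0))
                    pos = pseq.find(pep, pos + 1)
    table = pd.DataFrame(
        rows, columns=["peptide", "genome_id", "protein_id", "position", "normalized_count"]
    )
    if len(table):
        per_genome = table.groupby("genome_id").size()
        for gid, count in per_genome.items():
            if gid not in genome_lengths:
                raise InputError(f"no genome length for {gid!r}")
            table.loc[table["genome_id"] == gid, "normalized_count"] = count / (
                genome_lengths[gid] / 1000.0
            )
    return table


def six_frame_proteome(genome: Genome) -> list[Protein]:
    """All six frame translations, split at stops — the permissive target set."""
    out = []
    n = len(genome.sequence)
    for strand, seq in (("+", genome.sequence), ("-", reverse_complement(genome.sequence))):
        for frame in range(3):
            sub = seq[frame : frame + 3 * ((n - frame) // 3)]
            aa = str(Seq(sub).translate(table=_TRANSLATION_TABLE))
            for k, chunk in enumerate(aa.split("*")):
                if chunk:
                    out.append(
                        Protein(
                            id=f"{genome.id}_6f_{strand}{frame}_{k}",
                            sequence=chunk,
                            genome_id=genome.id,
                            strand=strand,
                            start=0,
                            end=0,
                        )
                    )
    return out


def write_proteins_fasta(proteins: list[Protein], path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id} {p.genome_id} {p.strand} {p.start}-{p.end}\n{p.sequence}\n")
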