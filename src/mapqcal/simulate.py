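"""Synthetic references, SNP implantation and Illumina-like read simulation.

This module provides the truth-annotated training data for mapping-quality
recalibration: a synthetic reference sequence (optionally carrying diverged
segmental duplications, so that a realistic fraction of reads is ambiguous
to map), a "donor" genome derived from it by implanting SNPs, and
single-end reads whose per-base quality declines linearly along the read,
as observed on Illumina instruments. Substitution errors are injected at
each base with the Phred-implied probability 10**(-q/10), so base
qualities are correct by construction and every read carries its true
origin (reference name, 1-based leftmost position, strand).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import ALPHABET, decode, encode, revcomp_codes

MAX_QUALITY = 40


@dataclass(frozen=True)
class ReferenceSequence:
    """A named reference sequence over the {A,C,G,T} alphabet."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if self.bases.strip("ACGT"):
            raise ValueError("reference bases must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.bases)

    def codes(self) -> np.ndarray:
        return encode(self.bases)


@dataclass(frozen=True)
class SnpSpec:
    """An implanted single-nucleotide polymorphism (1-based position)."""

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele must differ from ref allele")
        if self.position < 1:
            raise ValueError("SNP position is 1-based")


@dataclass(frozen=True)
class QualityModel:
    """Linear-decay model of per-base Phred quality along a read.

    Mean quality at 0-based base index i is ``intercept_mean +
    slope_mean * i``; each read additionally receives a normal intercept
    jitter (sd ``per_read_jitter_sd``) and each base independent normal
    noise (sd ``per_base_noise_sd``). Emitted qualities are rounded and
    clipped to [0, 40]. ``n_rate`` is the per-base probability of an
    uncalled (N) base, which is emitted with quality 0.
    """

    intercept_mean: float = 34.0
    slope_mean: float = -0.25
    per_read_jitter_sd: float = 2.0
    per_base_noise_sd: float = 2.0
    n_rate: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read together with its true origin."""

    read_id: str
    sequence: str
    base_qualities: tuple[int, ...]
    true_ref_name: str
    true_start: int  # 1-based leftmost position on the forward strand
    true_strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and quality lengths differ")


def generate_reference(length: int, seed: int, name: str = "synthetic_ref") -> ReferenceSequence:
    """Generate a uniform-random reference of ``length`` bases."""
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return ReferenceSequence(name=name, bases=decode(codes))


def generate_repetitive_reference(
    length: int,
    seed: int,
    n_families: int = 15,
    repeat_length: int = 500,
    copies_per_family: int = 3,
    divergence: float = 0.01,
    name: str = "synthetic_ref",
) -> ReferenceSequence:
    """Generate a reference carrying diverged segmental duplications.

    Starts from a uniform-random backbone, then for each repeat family
    copies one randomly chosen segment to ``copies_per_family - 1``
    additional random locations, substituting each copied base with
    probability ``divergence``. The result mimics the near-identical
    repeats that make short-read mapping ambiguous.
    """
    if repeat_length > length:
        raise ValueError("repeat_length exceeds reference length")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    for _ in range(n_families):
        src = int(rng.integers(0, length - repeat_length + 1))
        segment = codes[src : src + repeat_length].copy()
        for _ in range(copies_per_family - 1):
            copy = segment.copy()
            mut = rng.random(repeat_length) < divergence
            copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            dst = int(rng.integers(0, length - repeat_length + 1))
            codes[dst : dst + repeat_length] = copy
    return ReferenceSequence(name=name, bases=decode(codes))


def implant_snps(
    ref: ReferenceSequence, n: int, seed: int
) -> tuple[ReferenceSequence, list[SnpSpec]]:
    """Substitute ``n`` distinct random positions with random alt alleles.

    Returns the altered reference (the "donor" genome reads are simulated
    from) and the list of implanted SNPs, sorted by position.
    """
    if n > ref.length:
        raise ValueError("cannot implant more SNPs than reference positions")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(ref.length, size=n, replace=False))
    codes = ref.codes()
    snps = []
    for pos0 in positions:
        ref_code = int(codes[pos0])
        alt_code = (ref_code + int(rng.integers(1, 4))) % 4
        codes[pos0] = alt_code
        snps.append(
            SnpSpec(
                position=int(pos0) + 1,
                ref_allele=ALPHABET[ref_code],
                alt_allele=ALPHABET[alt_code],
            )
        )
    return dataclasses.replace(ref, bases=decode(codes)), snps


def simulate_reads(
    ref: ReferenceSequence,
    n_reads: int,
    read_len: int = 50,
    qmodel: QualityModel | None = None,
    seed: int = 0,
    id_prefix: str = "read",
) -> list[SimulatedRead]:
    """Simulate single-end reads with linearly declining base quality.

    Start positions are uniform over valid windows and strands uniform.
    Per-base qualities follow ``qmodel``; a substitution error is injected
    at each base independently with probability 10**(-q/10) (replacing the
    base with a uniform choice among the other three), then uncalled bases
    are injected at rate ``n_rate`` with quality forced to 0.
    Reverse-strand reads are reverse-complemented; truth fields record the
    origin window before error injection.
    """
    if qmodel is None:
        qmodel = QualityModel()
    if read_len > ref.length:
        raise ValueError("read length exceeds reference length")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    rng = np.random.default_rng(seed)
    ref_codes = ref.codes()

    starts = rng.integers(0, ref.length - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5  # True -> reverse

    # qualities in sequencing order (index 0 = first sequenced base)
    idx = np.arange(read_len)
    mean_q = (
        qmodel.intercept_mean
        + qmodel.slope_mean * idx[None, :]
        + rng.normal(0.0, qmodel.per_read_jitter_sd, size=(n_reads, 1))
    )
    quals = mean_q + rng.normal(0.0, qmodel.per_base_noise_sd, size=(n_reads, read_len))
    quals = np.clip(np.rint(quals), 0, MAX_QUALITY).astype(np.int16)

    # origin windows, oriented into sequencing order
    windows = ref_codes[starts[:, None] + idx[None, :]]
    oriented = windows.copy()
    if n_reads:
        rev = np.nonzero(strands)[0]
        for i in rev:
            oriented[i] = revcomp_codes(windows[i])

    err = rng.random((n_reads, read_len)) < 10.0 ** (-quals / 10.0)
    shift = rng.integers(1, 4, size=(n_reads, read_len), dtype=np.int16)
    seq = oriented.astype(np.int16)
    seq[err] = (seq[err] + shift[err]) % 4

    n_mask = rng.random((n_reads, read_len)) < qmodel.n_rate
    seq[n_mask] = 4
    quals[n_mask] = 0

    width = max(1, len(str(max(n_reads - 1, 0))))
    reads = []
    for i in range(n_reads):
        reads.append(
            SimulatedRead(
                read_id=f"{id_prefix}{i:0{width}d}",
                sequence=decode(seq[i].astype(np.uint8)),
                base_qualities=tuple(int(q) for q in quals[i]),
                true_ref_name=ref.name,
                true_start=int(starts[i]) + 1,
                true_strand="-" if strands[i] else "+",
            )
        )
    return reads


# ---------------------------------------------------------------------------
# file I/O


def write_fasta(ref: ReferenceSequence, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(ref.bases), id=ref.name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceSequence:
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceSequence(name=record.id, bases=str(record.seq).upper())


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Write reads as Sanger FASTQ (Phred+33)."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.base_qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_truth_table(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Write the truth annotations as a TSV with a fixed header."""
    with open(path, "w") as handle:
        handle.write("read_id\tref_name\tstart_1based\tstrand\n")
        for read in reads:
            handle.write(
                f"{read.read_id}\t{read.true_ref_name}\t{read.true_start}\t{read.true_strand}\n"
            )


def read_truth_table(path: str | Path) -> dict[str, tuple[str, int, str]]:
    """Read a truth table back as read_id -> (ref_name, start, strand)."""
    truth: dict[str, tuple[str, int, str]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["read_id", "ref_name", "start_1based", "strand"]:
            raise ValueError(f"unexpected truth table header: {header}")
        for line in handle:
            read_id, ref_name, start, strand = line.rstrip("\n").split("\t")
            truth[read_id] = (ref_name, int(start), strand)
    return truth


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    """Read FASTQ records; truth fields are filled from a side table if given."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SimulatedRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                base_qualities=tuple(rec.letter_annotations["phred_quality"]),
                true_ref_name="",
                true_start=1,
                true_strand="+",
            )
        )
    return reads


def attach_truth(
    reads: Sequence[SimulatedRead], truth: dict[str, tuple[str, int, str]]
) -> list[SimulatedRead]:
    out = []
    for read in reads:
        ref_name, start, strand = truth[read.read_id]
        out.append(
            dataclasses.replace(
                read, true_ref_name=ref_name, true_start=start, true_strand=strand
            )
        )
    return out
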