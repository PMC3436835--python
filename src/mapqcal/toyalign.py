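"""Brute-force ungapped read aligner used as a fully verifiable fixture.

The aligner reports every position on either strand whose Hamming
distance to the read is at most ``max_mismatches`` (N bases never match).
Exhaustiveness is achieved with the pigeonhole seeding scheme: a read
with at most m mismatches split into m+1 contiguous segments has at
least one segment matching the reference exactly, so candidate positions
from exact seed lookups cover every valid hit; each candidate is then
verified base by base.

Heuristic MAPQ for the primary hit: 30 for a unique hit, 0 when the best
distance is tied, otherwise min(30, 10 * (d2 - d1)) where d1 and d2 are
the best and second-best distances. Non-primary hits get MAPQ 0 and the
secondary flag.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._seq import decode, encode, revcomp_codes
from .samio import (
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    MappingRecord,
)
from .simulate import ReferenceSequence, SimulatedRead

UNIQUE_MAPQ = 30


class _SeedIndex:
    """Sorted-array exact k-mer index over the forward reference."""

    def __init__(self, ref_codes: np.ndarray, k: int):
        self.k = k
        n = ref_codes.size - k + 1
        if n <= 0:
            self.values = np.empty(0, dtype=np.int64)
            self.positions = np.empty(0, dtype=np.int64)
            return
        powers = 4 ** np.arange(k, dtype=np.int64)
        vals = np.zeros(n, dtype=np.int64)
        for j in range(k):
            vals += ref_codes[j : j + n].astype(np.int64) * powers[j]
        order = np.argsort(vals, kind="stable")
        self.values = vals[order]
        self.positions = order.astype(np.int64)
        self.powers = powers

    def lookup(self, kmer_codes: np.ndarray) -> np.ndarray:
        if self.values.size == 0 or kmer_codes.max(initial=0) > 3:
            return np.empty(0, dtype=np.int64)
        value = int((kmer_codes.astype(np.int64) * self.powers).sum())
        lo = np.searchsorted(self.values, value, side="left")
        hi = np.searchsorted(self.values, value, side="right")
        return self.positions[lo:hi]


def _make_md(read_codes: np.ndarray, ref_window: np.ndarray) -> tuple[str, int]:
    """MD tag and mismatch count for an ungapped alignment."""
    mismatch_pos = np.nonzero(read_codes != ref_window)[0]
    parts = []
    prev = -1
    for j in mismatch_pos:
        parts.append(str(int(j) - prev - 1))
        parts.append(decode(ref_window[j : j + 1]))
        prev = int(j)
    parts.append(str(read_codes.size - prev - 1))
    return "".join(parts), mismatch_pos.size


def _candidate_positions(
    codes: np.ndarray, index: _SeedIndex, n_segments: int, ref_len: int
) -> set[int]:
    k = codes.size
    s = index.k
    candidates: set[int] = set()
    for seg in range(n_segments):
        off = seg * s
        if off + s > k:
            break
        for hit in index.lookup(codes[off : off + s]):
            pos = int(hit) - off
            if 0 <= pos <= ref_len - k:
                candidates.add(pos)
    return candidates


def toy_align(
    reads: Sequence[SimulatedRead],
    ref: ReferenceSequence,
    max_mismatches: int = 5,
    max_hits: int = 10,
) -> list[MappingRecord]:
    """Exhaustively align reads on both strands, best hits first.

    Returns one record per hit (up to ``max_hits`` per read, ordered by
    (mismatches, position, strand)) with NM and MD tags; reads with no
    hit yield a single unmapped record. Truth annotations on the reads
    are ignored.
    """
    if ref.length == 0:
        raise ValueError("empty reference")
    ref_codes = ref.codes()
    indexes: dict[int, _SeedIndex] = {}
    records: list[MappingRecord] = []

    for read in reads:
        k = len(read.sequence)
        if k > ref.length:
            raise ValueError(f"read {read.read_id} longer than the reference")
        n_segments = max_mismatches + 1
        s = max(1, k // n_segments)
        if s not in indexes:
            indexes[s] = _SeedIndex(ref_codes, s)
        index = indexes[s]

        fwd = encode(read.sequence)
        rev = revcomp_codes(fwd)
        hits: list[tuple[int, int, int]] = []  # (distance, pos0, strand_rev)
        for strand_rev, codes in ((0, fwd), (1, rev)):
            # N bases (code 4) break seed exactness; widen segments is not
            # needed because an N counts as a mismatch, so reads with
            # errors+N <= max_mismatches still leave one clean segment.
            for pos in _candidate_positions(codes, index, n_segments, ref.length):
                d = int(np.count_nonzero(ref_codes[pos : pos + k] != codes))
                if d <= max_mismatches:
                    hits.append((d, pos, strand_rev))
        hits = sorted(set(hits))

        if not hits:
            records.append(
                MappingRecord(
                    read_id=read.read_id,
                    flag=FLAG_UNMAPPED,
                    ref_name="*",
                    pos=0,
                    mapq=0,
                    cigar=[],
                    sequence=read.sequence,
                    base_qualities=list(read.base_qualities),
                )
            )
            continue

        d1 = hits[0][0]
        if len(hits) == 1:
            primary_mapq = UNIQUE_MAPQ
        elif hits[1][0] == d1:
            primary_mapq = 0
        else:
            primary_mapq = min(UNIQUE_MAPQ, 10 * (hits[1][0] - d1))

        for rank, (d, pos, strand_rev) in enumerate(hits[:max_hits]):
            codes = rev if strand_rev else fwd
            md, n_mismatch = _make_md(codes, ref_codes[pos : pos + k])
            flag = (FLAG_REVERSE if strand_rev else 0) | (FLAG_SECONDARY if rank else 0)
            quals = list(read.base_qualities)
            records.append(
                MappingRecord(
                    read_id=read.read_id,
                    flag=flag,
                    ref_name=ref.name,
                    pos=pos + 1,
                    mapq=primary_mapq if rank == 0 else 0,
                    cigar=[(k, "M")],
                    sequence=decode(codes),
                    base_qualities=quals[::-1] if strand_rev else quals,
                    nm=d,
                    md=md,
                )
            )
    return records
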