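"""Mapping-quality-aware pileup SNP calling.

A deliberately simple consensus caller: primary alignments with MAPQ at
or above a threshold contribute their aligned bases to per-position
counts; a SNP is called where depth and the leading non-reference allele
fraction clear their thresholds. It exists so the effect of raw versus
recalibrated mapping qualities on variant calling can be measured
end-to-end without external callers; it makes no attempt at genotype
likelihoods or base-quality weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import ALPHABET, encode
from .samio import MappingRecord
from .simulate import ReferenceSequence


@dataclass(frozen=True)
class SnpCall:
    ref_name: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    alt_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise ValueError("alt depth cannot exceed total depth")
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele must differ from ref allele")


def _aligned_pairs(record: MappingRecord) -> Iterable[tuple[int, int]]:
    """(query index, 0-based reference position) pairs from the CIGAR."""
    q = 0
    r = record.pos - 1
    for length, op in record.cigar:
        if op in "M=X":
            for j in range(length):
                yield q + j, r + j
            q += length
            r += length
        elif op in "IS":
            q += length
        elif op in "DN":
            r += length
        # H and P consume neither

def pileup_snp_call(
    records: Sequence[MappingRecord],
    ref: ReferenceSequence,
    min_mapq: float = 20,
    min_depth: int = 3,
    min_alt_frac: float = 0.5,
) -> list[SnpCall]:
    """Call SNPs from stacked read bases filtered by mapping quality.

    Only primary mapped alignments on the given reference with
    MAPQ >= ``min_mapq`` contribute (a missing MAPQ never passes the
    filter). At each position with called-base depth >= ``min_depth``,
    the most common non-reference base is reported as a SNP when its
    fraction of the depth is >= ``min_alt_frac``. Ties between alt
    alleles break alphabetically. Output is ordered by position and does
    not depend on input record order.
    """
    counts = np.zeros((4, ref.length), dtype=np.int64)
    for record in records:
        if not record.mapped or record.is_secondary or record.ref_name != ref.name:
            continue
        if record.mapq is None or record.mapq < min_mapq:
            continue
        codes = encode(record.sequence)
        for qi, ri in _aligned_pairs(record):
            if 0 <= ri < ref.length and codes[qi] < 4:  # skip N bases
                counts[codes[qi], ri] += 1

    ref_codes = ref.codes()
    depth = counts.sum(axis=0)
    calls = []
    for pos0 in np.nonzero(depth >= min_depth)[0]:
        col = counts[:, pos0].copy()
        ref_code = int(ref_codes[pos0])
        col[ref_code] = -1
        alt_code = int(np.argmax(col))  # argmax takes the first (alphabetical) tie
        alt_depth = int(counts[alt_code, pos0])
        if alt_depth > 0 and alt_depth / depth[pos0] >= min_alt_frac:
            calls.append(
                SnpCall(
                    ref_name=ref.name,
                    position=int(pos0) + 1,
                    ref_allele=ALPHABET[ref_code],
                    alt_allele=ALPHABET[alt_code],
                    alt_depth=alt_depth,
                    total_depth=int(depth[pos0]),
                )
            )
    return calls
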