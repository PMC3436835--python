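"""Classification features for read-mapping pairs.

Three groups of features feed the mapping-correctness classifier:

* alignment-independent read statistics — an ordinary-least-squares line
  fitted to the per-base qualities (intercept = fitted quality of the
  first base, slope = rate of quality decline, Pearson r) plus the count
  of uncalled (N) bases;
* alignment statistics — matches, mismatches, insertions and deletions,
  from the CIGAR string together with the MD (preferred) or NM tag;
* aligner-specific statistics — the aligner's own MAPQ (with a missing
  indicator for the SAM sentinel 255) and the number of mappings the
  aligner returned for the read.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .samio import MappingRecord

logger = logging.getLogger(__name__)

#: Stable feature order used by the model and the TSV export.
FEATURE_NAMES = (
    "intercept",
    "slope",
    "r_value",
    "n_count",
    "n_matches",
    "n_mismatches",
    "n_insertions",
    "n_deletions",
    "raw_mapq",
    "mapq_missing",
    "n_mappings",
)

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


@dataclass(frozen=True)
class ReadQualityFit:
    """OLS line through (0-based base index, base quality)."""

    intercept: float
    slope: float
    r_value: float


@dataclass(frozen=True)
class FeatureVector:
    intercept: float
    slope: float
    r_value: float
    n_count: int
    n_matches: int
    n_mismatches: int
    n_insertions: int
    n_deletions: int
    raw_mapq: float
    mapq_missing: int
    n_mappings: int

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def fit_base_quality_line(base_qualities: Sequence[int]) -> ReadQualityFit:
    """Least-squares fit of quality on 0-based base index.

    For a read with constant qualities the Pearson correlation is
    undefined; by convention the fit is then (constant, slope 0, r 0).
    """
    q = np.asarray(base_qualities, dtype=float)
    k = q.size
    if k < 2:
        raise ValueError("need at least 2 base qualities to fit a line")
    x = np.arange(k, dtype=float)
    x_mean = x.mean()
    q_mean = q.mean()
    cov = np.dot(x - x_mean, q - q_mean)
    var_x = np.dot(x - x_mean, x - x_mean)
    var_q = np.dot(q - q_mean, q - q_mean)
    if var_q == 0.0:
        return ReadQualityFit(intercept=q_mean, slope=0.0, r_value=0.0)
    slope = cov / var_x
    intercept = q_mean - slope * x_mean
    r = cov / np.sqrt(var_x * var_q)
    return ReadQualityFit(intercept=intercept, slope=slope, r_value=float(np.clip(r, -1.0, 1.0)))


def count_uncalled(sequence: str) -> int:
    """Number of uncalled (N) bases, case-insensitive."""
    return sequence.count("N") + sequence.count("n")


def count_md_mismatches(md: str) -> int:
    """Mismatch count encoded by an MD tag (deletion runs excluded)."""
    mismatches = 0
    pos = 0
    for match in _MD_TOKEN.finditer(md):
        if match.start() != pos:
            raise ValueError(f"malformed MD tag {md!r}")
        pos = match.end()
        if match.group(3):
            mismatches += 1
    if pos != len(md):
        raise ValueError(f"malformed MD tag {md!r}")
    return mismatches


def alignment_counts(record: MappingRecord) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions, deletions) for a mapped record.

    Insertions/deletions are total I/D CIGAR lengths. Mismatches come
    from the MD tag when present, otherwise from NM minus indel bases
    (floored at 0); with neither tag they are reported as 0 with a
    warning. Matches are the aligned (M/=/X) length minus mismatches.
    """
    if not record.mapped:
        raise ValueError("alignment counts are defined for mapped records only")
    aligned = sum(n for n, op in record.cigar if op in "M=X")
    insertions = sum(n for n, op in record.cigar if op == "I")
    deletions = sum(n for n, op in record.cigar if op == "D")
    if record.md is not None:
        mismatches = count_md_mismatches(record.md)
    elif record.nm is not None:
        mismatches = max(record.nm - insertions - deletions, 0)
    else:
        logger.warning(
            "record %s has neither MD nor NM tag; mismatch count set to 0", record.read_id
        )
        mismatches = 0
    mismatches = min(mismatches, aligned)
    return aligned - mismatches, mismatches, insertions, deletions


def count_mappings(records: Iterable[MappingRecord]) -> int:
    """Number of mapped alignment lines in a group sharing one read id."""
    return sum(1 for record in records if record.mapped)


def extract_features(record: MappingRecord, multiplicity: int) -> FeatureVector:
    """Compose the full feature vector for one mapped alignment line.

    ``multiplicity`` is the number of mappings the aligner returned for
    this read (primary + secondary). A MAPQ of 255 in the SAM file is
    treated as missing: raw_mapq 0 with the indicator set.
    """
    if not record.mapped:
        raise ValueError("features are extracted for mapped records only")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1 for a scored mapping")
    fit = fit_base_quality_line(record.base_qualities)
    matches, mismatches, insertions, deletions = alignment_counts(record)
    missing = record.mapq is None
    return FeatureVector(
        intercept=fit.intercept,
        slope=fit.slope,
        r_value=fit.r_value,
        n_count=count_uncalled(record.sequence),
        n_matches=matches,
        n_mismatches=mismatches,
        n_insertions=insertions,
        n_deletions=deletions,
        raw_mapq=0.0 if missing else float(record.mapq),
        mapq_missing=1 if missing else 0,
        n_mappings=multiplicity,
    )


def multiplicity_by_read(records: Sequence[MappingRecord]) -> Counter:
    """Mapped-line count per read id across a whole SAM file."""
    counts: Counter = Counter()
    for record in records:
        if record.mapped:
            counts[record.read_id] += 1
    return counts


def features_for_records(
    records: Sequence[MappingRecord],
) -> tuple[list[MappingRecord], list[FeatureVector]]:
    """Feature vectors for every mapped line, in file order.

    Returns the scored records alongside their vectors; unmapped records
    are passed over (they carry no alignment to score).
    """
    counts = multiplicity_by_read(records)
    scored = [record for record in records if record.mapped]
    vectors = [extract_features(record, counts[record.read_id]) for record in scored]
    return scored, vectors


def features_to_frame(
    records: Sequence[MappingRecord], vectors: Sequence[FeatureVector]
) -> pd.DataFrame:
    """One row per scored alignment, feature columns in documented order."""
    data = {
        "read_id": [record.read_id for record in records],
        "ref_name": [record.ref_name for record in records],
        "pos": [record.pos for record in records],
        "strand": [record.strand for record in records],
    }
    matrix = np.array([vector.to_array() for vector in vectors]).reshape(
        len(vectors), len(FEATURE_NAMES)
    )
    for j, name in enumerate(FEATURE_NAMES):
        data[name] = matrix[:, j]
    return pd.DataFrame(data)
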