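"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately written by direct enumeration or textbook
formulas, independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"


def random_alignment_fixture(rng: np.random.Generator):
    """Build a random gapped alignment and its ground-truth counts.

    Constructs read/reference pairs edit by edit (match, mismatch,
    insertion, deletion, optional soft clips), then derives the CIGAR and
    MD strings from the construction. Returns
    (cigar_string, md_string, read_seq, expected (matches, mismatches,
    insertions, deletions)).
    """
    n_blocks = int(rng.integers(1, 8))
    cigar_ops: list[tuple[int, str]] = []
    md_parts: list[str] = []
    read_parts: list[str] = []
    matches = mismatches = insertions = deletions = 0
    match_run = 0  # run of matches pending for MD

    def flush_md_run():
        nonlocal match_run
        md_parts.append(str(match_run))
        match_run = 0

    def add_cigar(op: str, length: int):
        if cigar_ops and cigar_ops[-1][1] == op:
            cigar_ops[-1] = (cigar_ops[-1][0] + length, op)
        else:
            cigar_ops.append((length, op))

    if rng.random() < 0.3:
        clip = int(rng.integers(1, 6))
        add_cigar("S", clip)
        read_parts.append("".join(rng.choice(list(BASES), clip)))

    prev_was_aligned = True
    for _ in range(n_blocks):
        kind = rng.choice(["match", "mismatch", "ins", "del"], p=[0.5, 0.25, 0.125, 0.125])
        length = int(rng.integers(1, 12))
        if kind == "match":
            add_cigar("M", length)
            read_parts.append("".join(rng.choice(list(BASES), length)))
            matches += length
            match_run += length
            prev_was_aligned = True
        elif kind == "mismatch":
            add_cigar("M", length)
            for _ in range(length):
                ref_base, read_base = rng.choice(list(BASES), 2, replace=False)
                read_parts.append(read_base)
                flush_md_run()
                md_parts.append(ref_base)
            mismatches += length
            prev_was_aligned = True
        elif kind == "ins":
            if not prev_was_aligned:
                continue
            add_cigar("I", length)
            read_parts.append("".join(rng.choice(list(BASES), length)))
            insertions += length
            prev_was_aligned = False
        else:
            if not prev_was_aligned:
                continue
            add_cigar("D", length)
            flush_md_run()
            md_parts.append("^" + "".join(rng.choice(list(BASES), length)))
            # MD requires a (possibly 0) match count after a deletion only
            # when a mismatch or another deletion follows; emitting the run
            # lazily handles this.
            deletions += length
            prev_was_aligned = False

    # ensure the alignment ends (and starts) with an aligned block
    if cigar_ops[-1][1] in "ID":
        add_cigar("M", 1)
        read_parts.append(str(rng.choice(list(BASES))))
        matches += 1
        match_run += 1
    if cigar_ops[0][1] in "ID":
        cigar_ops.insert(0, (1, "M"))
        read_parts.insert(0, str(rng.choice(list(BASES))))
        matches += 1
        md_parts.insert(0, "1")
    else:
        flush_md_run()

    if rng.random() < 0.3:
        clip = int(rng.integers(1, 6))
        add_cigar("S", clip)
        read_parts.append("".join(rng.choice(list(BASES), clip)))

    cigar = "".join(f"{n}{op}" for n, op in cigar_ops)
    # canonical MD: merge adjacent numbers
    md_tokens: list[str] = []
    for part in md_parts:
        if part.isdigit() and md_tokens and md_tokens[-1].isdigit():
            md_tokens[-1] = str(int(md_tokens[-1]) + int(part))
        else:
            md_tokens.append(part)
    if not md_tokens or not md_tokens[0].isdigit():
        md_tokens.insert(0, "0")
    if not md_tokens[-1].isdigit():
        md_tokens.append("0")
    md = "".join(md_tokens)
    read = "".join(read_parts)
    return cigar, md, read, (matches, mismatches, insertions, deletions)


def hamming_scan(read_codes: np.ndarray, ref_codes: np.ndarray, max_mismatches: int):
    """All (pos0, distance) with Hamming distance <= max on one strand."""
    k = read_codes.size
    out = []
    for pos in range(ref_codes.size - k + 1):
        d = int(np.count_nonzero(ref_codes[pos : pos + k] != read_codes))
        if d <= max_mismatches:
            out.append((pos, d))
    return out


def sweep_enumeration(scores, labels, thresholds):
    """Per-threshold TP/FP/FN/precision/recall by direct loops."""
    out = []
    for t in thresholds:
        tp = fp = fn = 0
        for s, correct in zip(scores, labels):
            if s >= t:
                if correct:
                    tp += 1
                else:
                    fp += 1
            elif correct:
                fn += 1
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn) if tp + fn else 1.0
        out.append((t, tp, fp, fn, precision, recall))
    return out


def irls_penalized(X, y, l2, n_iter=200):
    """Textbook penalized IRLS on standardized features (intercept free).

    Solves the same objective as the package's fit: binomial deviance
    plus (l2/2)*||beta_std||^2 on zero-mean unit-sd features.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    spread[spread == 0] = 1.0
    Z = np.hstack([np.ones((X.shape[0], 1)), (X - center) / spread])
    p_dim = Z.shape[1]
    pen = np.full(p_dim, l2)
    pen[0] = 0.0
    beta = np.zeros(p_dim)
    for _ in range(n_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z_work = eta + (y - mu) / w
        lhs = (Z * w[:, None]).T @ Z + np.diag(pen)
        rhs = (Z * w[:, None]).T @ z_work
        beta_new = np.linalg.solve(lhs, rhs)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta[0], beta[1:], center, spread
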