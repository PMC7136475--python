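"""Greedy identity clustering of seed proteins to remove near-duplicates.

This stands in for the 90 % identity / 90 % coverage deduplication step
applied to YcaO seed proteins before neighborhood analysis: genomes of some
taxa are heavily overrepresented in public databases and would otherwise
dominate every downstream family.

The aligner is a global Needleman-Wunsch/Gotoh with match +1, mismatch 0,
gap open -5 (first gap column) and gap extend -1 (each further column).
Identity is matches / alignment columns (gap columns included); coverage is
aligned (both-non-gap) columns / length of the shorter sequence.  Traceback
ties are broken diagonal > up > left, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG = -1e12


def _gotoh_matrices(a: str, b: str, match: float, mismatch: float,
                    go: float, ge: float):
    """Fill global-alignment DP matrices M (diagonal), E (gap in a, consumes
    b) and F (gap in b, consumes a).  E is vectorized via the prefix-max
    identity E[i,j] = go + ge*(j-1) + max_{j'<j}(M[i,j'] - ge*j')."""
    m, n = len(a), len(b)
    M = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    j_idx = np.arange(n + 1, dtype=float)
    if n:
        E[0, 1:] = go + ge * (j_idx[1:] - 1)
    if m:
        F[1:, 0] = go + ge * (np.arange(1, m + 1, dtype=float) - 1)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, m + 1):
        s = np.where(b_arr == ord(a[i - 1]), match, mismatch)
        best_prev = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        M[i, 1:] = best_prev[:-1] + s
        F[i, 1:] = np.maximum(M[i - 1, 1:] + go, F[i - 1, 1:] + ge)
        u = M[i] - ge * j_idx
        prefix = np.maximum.accumulate(u)
        E[i, 1:] = go + ge * (j_idx[1:] - 1) + prefix[:-1]
    return M, E, F


def _traceback(a: str, b: str, M, E, F, match: float, mismatch: float,
               go: float, ge: float) -> tuple[float, int, int, int]:
    """Return (score, matches, columns, aligned_columns) along the optimal
    path, ties broken M (diag) > F (up) > E (left)."""
    eps = 1e-6
    i, j = len(a), len(b)
    finals = [("M", M[i, j]), ("F", F[i, j]), ("E", E[i, j])]
    state, score = max(finals, key=lambda t: t[1])
    for name, val in finals:  # deterministic tie preference in listed order
        if val >= score - eps:
            state, score = name, val
            break
    matches = columns = aligned = 0
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 and j == 0:
                break
            columns += 1
            aligned += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = [("M", M[i - 1, j - 1]), ("F", F[i - 1, j - 1]), ("E", E[i - 1, j - 1])]
            target = M[i, j] - (match if a[i - 1] == b[j - 1] else mismatch)
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for name, val in prev:
                if abs(val - target) <= eps:
                    state = name
                    break
        elif state == "F":  # gap in b, consumes a[i-1]
            columns += 1
            if abs(F[i, j] - (M[i - 1, j] + go)) <= eps:
                state = "M"
            i -= 1
        else:  # E: gap in a, consumes b[j-1]
            columns += 1
            if abs(E[i, j] - (M[i, j - 1] + go)) <= eps:
                state = "M"
            j -= 1
    return float(score), matches, columns, aligned


def global_alignment_stats(a: str, b: str, *, match: float = 1.0,
                           mismatch: float = 0.0, gap_open: float = -5.0,
                           gap_extend: float = -1.0) -> tuple[float, int, int, int]:
    """Optimal global alignment score plus (matches, columns, aligned columns)."""
    if not a or not b:
        raise ValueError("empty sequence")
    M, E, F = _gotoh_matrices(a, b, match, mismatch, gap_open, gap_extend)
    return _traceback(a, b, M, E, F, match, mismatch, gap_open, gap_extend)


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Fractional identity and coverage of a global alignment of two proteins.

    identity = matches / alignment columns; coverage = both-non-gap columns /
    length of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    _, matches, columns, aligned = global_alignment_stats(a, b)
    identity = matches / columns if columns else 0.0
    coverage = aligned / min(len(a), len(b))
    return identity, coverage


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_fraction(a: str, b: str, k: int = 5) -> float:
    ka, kb = _kmers(a, k), _kmers(b, k)
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


@dataclass
class ProteinCluster:
    """One greedy cluster: a representative and its near-identical members."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def greedy_cluster(proteins: dict[str, str], id_threshold: float = 0.9,
                   cov_threshold: float = 0.9, *, use_prefilter: bool = True,
                   prefilter_k: int = 5,
                   prefilter_min_shared: float = 0.5) -> list[ProteinCluster]:
    """CD-HIT-style greedy clustering at identity/coverage thresholds.

    Proteins are processed longest first (ties by id); each joins the first
    existing representative (in founding order) meeting both thresholds,
    else founds a new cluster.  The optional shared-k-mer prefilter only
    skips alignments that could not reach the identity threshold; disable it
    when exact agreement with a full-DP oracle is required.
    """
    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    clusters: list[ProteinCluster] = []
    for pid in order:
        seq = proteins[pid]
        if not seq:
            raise ValueError(f"empty sequence for {pid}")
        placed = False
        for cluster in clusters:
            rep_seq = proteins[cluster.representative_id]
            if use_prefilter and shared_kmer_fraction(seq, rep_seq, prefilter_k) < prefilter_min_shared:
                continue
            identity, coverage = pairwise_identity(seq, rep_seq)
            if identity >= id_threshold and coverage >= cov_threshold:
                cluster.member_ids.append(pid)
                cluster.identities[pid] = identity
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(pid, [pid], {pid: 1.0}))
    clusters.sort(key=lambda c: c.representative_id)
    for cluster in clusters:
        cluster.member_ids.sort()
    return clusters


def write_membership_tsv(clusters: list[ProteinCluster], path) -> None:
    """Two-column member -> representative table."""
    with open(path, "w") as fh:
        for cluster in clusters:
            for member in cluster.member_ids:
                fh.write(f"{member}\t{cluster.representative_id}\n")
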