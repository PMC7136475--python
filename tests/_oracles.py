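"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (no numpy, no shared code
with the package) so agreement with the package is meaningful.
"""

from __future__ import annotations

NEG = float("-inf")


def global_align_oracle(a: str, b: str, match=1.0, mismatch=0.0,
                        gap_open=-5.0, gap_extend=-1.0):
    """Plain-python Gotoh global alignment returning
    (score, matches, columns, aligned_columns) with tie priority
    diagonal > up (gap in b) > left (gap in a)."""
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for j in range(1, n + 1):
        E[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        F[i][0] = gap_open + gap_extend * (i - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + s
            F[i][j] = max(M[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            E[i][j] = max(M[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
    i, j = m, n
    state = max((("M", M[i][j]), ("F", F[i][j]), ("E", E[i][j])),
                key=lambda t: t[1])[1]
    for name, val in (("M", M[i][j]), ("F", F[i][j]), ("E", E[i][j])):
        if val == state:
            score, state = val, name
            break
    matches = columns = aligned = 0
    while i > 0 or j > 0:
        if state == "M":
            columns += 1
            aligned += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for name, val in (("M", M[i][j]), ("F", F[i][j]), ("E", E[i][j])):
                if val == target:
                    state = name
                    break
        elif state == "F":
            columns += 1
            if F[i][j] == M[i - 1][j] + gap_open:
                state = "M"
            i -= 1
        else:
            columns += 1
            if E[i][j] == M[i][j - 1] + gap_open:
                state = "M"
            j -= 1
    return score, matches, columns, aligned


def identity_oracle(a: str, b: str):
    score, matches, columns, aligned = global_align_oracle(a, b)
    return matches / columns, aligned / min(len(a), len(b))


def greedy_cluster_oracle(proteins: dict[str, str], id_thr=0.9, cov_thr=0.9):
    """Greedy longest-first clustering with full-DP identities; returns the
    partition as a mapping member -> representative."""
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for pid in order:
        for rep in reps:
            ident, cov = identity_oracle(proteins[pid], proteins[rep])
            if ident >= id_thr and cov >= cov_thr:
                assign[pid] = rep
                break
        else:
            reps.append(pid)
            assign[pid] = pid
    return assign


def strand_run_oracle(genes, seed_idx: int, max_gap: int):
    """genes: sorted list of (start, end, strand).  Returns the member index
    range of the same-strand <=max_gap run containing the seed."""
    strand = genes[seed_idx][2]
    lo = hi = seed_idx
    while hi + 1 < len(genes) and genes[hi + 1][2] == strand \
            and genes[hi + 1][0] - genes[hi][1] <= max_gap:
        hi += 1
    while lo > 0 and genes[lo - 1][2] == strand \
            and genes[lo][0] - genes[lo - 1][1] <= max_gap:
        lo -= 1
    return lo, hi


def stride_chain_oracle(peptide: str, stride: int, residue: str):
    """Enumerate every arithmetic chain start and take the longest
    (leftmost on ties)."""
    best = (0, None)
    for start in range(len(peptide)):
        if peptide[start] != residue:
            continue
        if start - stride >= 0 and peptide[start - stride] == residue:
            continue
        count, last = 1, start
        while last + stride < len(peptide) and peptide[last + stride] == residue:
            last += stride
            count += 1
        if count > best[0]:
            best = (count, (start, last + 1))
    return best


def local_align_score_oracle(a: str, b: str, match=2, mismatch=-1, gap=-2,
                             min_diag_offset=0):
    """Best Smith-Waterman score only (no traceback)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        row = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if min_diag_offset and abs(i - j) < min_diag_offset:
                continue
            s = match if a[i - 1] == b[j - 1] else mismatch
            row[j] = max(0, prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
            best = max(best, row[j])
        prev = row
    return best


def components_oracle(nodes, edges):
    """Connected components by repeated reachability expansion."""
    adjacency = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    seen: set = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adjacency[x] - comp)
        seen |= comp
        comps.append(comp)
    return sorted(comps, key=lambda c: sorted(c)[0])
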