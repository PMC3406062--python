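"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
implementation: a plain-Python three-state DP for scores, an exhaustive
enumeration of alignment paths for tiny pairs, and brute-force tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

DIAG, UP, LEFT = 0, 1, 2  # same op encoding as the package


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
                gap_extend=-1.0, free_ends=True) -> float:
    """Score-only affine-gap DP, independent of the package kernel."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if free_ends else gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if free_ends else gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_open,
                          Y[i][j - 1] + gap_extend)
    if not free_ends:
        return max(M[n][m], X[n][m], Y[n][m])
    best = NEG
    for j in range(1, m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    for i in range(1, n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    return best


def enumerate_paths(n: int, m: int):
    """All monotone alignment paths from (0,0) to (n,m) as op tuples."""
    path: list[int] = []

    def rec(i: int, j: int):
        if i == n and j == m:
            yield tuple(path)
            return
        if i < n and j < m:
            path.append(DIAG)
            yield from rec(i + 1, j + 1)
            path.pop()
        if i < n:
            path.append(UP)
            yield from rec(i + 1, j)
            path.pop()
        if j < m:
            path.append(LEFT)
            yield from rec(i, j + 1)
            path.pop()

    yield from rec(0, 0)


def _terminal_runs(ops):
    """(lead_run, trail_run) lengths of the same-type terminal gap runs."""
    L = len(ops)
    lead = 0
    if ops and ops[0] != DIAG:
        t = ops[0]
        while lead < L and ops[lead] == t:
            lead += 1
    trail = 0
    if ops and ops[-1] != DIAG:
        t = ops[-1]
        while trail < L - lead and ops[L - 1 - trail] == t:
            trail += 1
    return lead, trail


def score_path(ops, a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
               gap_extend=-1.0, free_ends=True) -> float:
    """Affine score of one explicit path; terminal same-type runs free."""
    lead, trail = (_terminal_runs(ops) if free_ends else (0, 0))
    L = len(ops)
    score = 0.0
    i = j = 0
    prev_gap = None  # None / UP / LEFT, tracked across the scored region
    for k, op in enumerate(ops):
        in_free = k < lead or k >= L - trail
        if op == DIAG:
            score += match if a[i] == b[j] else mismatch
            i += 1
            j += 1
            prev_gap = None
        elif op == UP:
            if not in_free:
                score += gap_extend if prev_gap == UP else gap_open
            prev_gap = UP
            i += 1
        else:
            if not in_free:
                score += gap_extend if prev_gap == LEFT else gap_open
            prev_gap = LEFT
            j += 1
        if in_free:
            prev_gap = None if op == DIAG else op
    return score


def path_identity(ops, a: str, b: str) -> float:
    """Identity of one path, per the package's definition (floored denominator)."""
    L = len(ops)
    diag_idx = [k for k, op in enumerate(ops) if op == DIAG]
    if not diag_idx:
        return 0.0
    lead, trail = diag_idx[0], L - diag_idx[-1] - 1
    i = j = 0
    n_id = 0
    for op in ops:
        if op == DIAG:
            if a[i] == b[j]:
                n_id += 1
            i += 1
            j += 1
        elif op == UP:
            i += 1
        else:
            j += 1
    counted = L - lead - trail
    return n_id / max(counted, min(len(a), len(b)))


@dataclass
class EnumResult:
    best_score: float
    identities: set[float]  # identities of all optimal paths
    n_optimal: int


def best_by_enumeration(a: str, b: str, free_ends=True, **scores) -> EnumResult:
    """Optimal score and the identity set of optimal paths, by brute force.

    Paths without any substitution column are skipped under free end gaps
    (the aligner never emits an alignment that aligns nothing).
    """
    best = float("-inf")
    idents: set[float] = set()
    n_opt = 0
    for ops in enumerate_paths(len(a), len(b)):
        if free_ends and not any(op == DIAG for op in ops):
            continue
        s = score_path(ops, a, b, free_ends=free_ends, **scores)
        if s > best + 1e-9:
            best = s
            idents = {path_identity(ops, a, b)}
            n_opt = 1
        elif abs(s - best) <= 1e-9:
            idents.add(path_identity(ops, a, b))
            n_opt += 1
    return EnumResult(best, idents, n_opt)


def bimera_brute_force(query: str, parent_a: str, parent_b: str, profile_fn):
    """Exhaustive breakpoint maximization given a per-position profile function."""
    pa = list(profile_fn(query, parent_a))
    pb = list(profile_fn(query, parent_b))
    L = len(query)
    best = -1.0
    for first, second in ((pa, pb), (pb, pa)):
        for i in range(L + 1):
            v = (sum(first[:i]) + sum(second[i:])) / L
            if v > best:
                best = v
    return best


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
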