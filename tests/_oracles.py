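"""Independent brute-force oracles used by the test suite and the
acceptance script.  Everything here is implemented directly from the
published formulas / definitions, deliberately avoiding the package's own
code paths (plain Python loops, no shared helpers)."""

from __future__ import annotations

import math

from Bio.Seq import Seq

DNA = "ACGT"
MISSING = set("N-X")


def pi_bruteforce(seqs: list[str]) -> float | None:
    """Mean over pairs of (differences / compared sites), pairwise deletion."""
    vals = []
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            diff = comp = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in MISSING or b in MISSING:
                    continue
                comp += 1
                if a != b:
                    diff += 1
            if comp:
                vals.append(diff / comp)
    if not vals:
        return None
    return sum(vals) / len(vals)


def dxy_bruteforce(seqs_a: list[str], seqs_b: list[str]) -> float | None:
    vals = []
    for sa in seqs_a:
        for sb in seqs_b:
            diff = comp = 0
            for a, b in zip(sa, sb):
                if a in MISSING or b in MISSING:
                    continue
                comp += 1
                if a != b:
                    diff += 1
            if comp:
                vals.append(diff / comp)
    if not vals:
        return None
    return sum(vals) / len(vals)


def segregating_sites_bruteforce(seqs: list[str]) -> int:
    S = 0
    for col in zip(*seqs):
        if any(c in MISSING for c in col):
            continue
        if len(set(col)) > 1:
            S += 1
    return S


def mean_pairwise_diff_bruteforce(seqs: list[str]) -> float:
    """Pairwise difference count on complete-deletion columns."""
    keep = [
        col for col in zip(*seqs) if not any(c in MISSING for c in col)
    ]
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for col in keep if col[i] != col[j])
    return total / (n * (n - 1) / 2)


def tajima_d_transcription(S: int, k_hat: float, n: int) -> float | None:
    """Second, independent transcription of the Tajima (1989) formulas."""
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# NG86 oracle (exhaustive enumeration over the standard genetic code)

_STOP_AA = "*"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str) -> float:
    """Synonymous site count of one codon by explicit neighbour enumeration."""
    syn = 0.0
    for pos in range(3):
        for b in DNA:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _aa(alt) != _STOP_AA and _aa(alt) == _aa(codon):
                syn += 1.0
    return syn / 3.0


def ng86_diffs_oracle(c1: str, c2: str):
    """Pathway-averaged (syn, nonsyn) differences via recursive enumeration;
    None when every path crosses a stop codon."""
    if c1 == c2:
        return (0.0, 0.0)
    paths = []

    def walk(cur: str, sd: int, nd: int):
        if cur == c2:
            paths.append((sd, nd))
            return
        for pos in range(3):
            if cur[pos] == c2[pos]:
                continue
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == _STOP_AA:
                continue
            walk(nxt, sd + (_aa(cur) == _aa(nxt)), nd + (_aa(cur) != _aa(nxt)))

    # enumerate with path multiplicity equal to orderings: recursion above
    # explores each ordering exactly once because at every step it branches
    # over the remaining differing positions
    walk(c1, 0, 0)
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def ng86_oracle(seq1: str, seq2: str):
    """(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs, dS, dN)."""
    s1 = s2 = sd = nd = 0.0
    ncod = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(ch not in DNA for ch in c1 + c2):
            continue
        d = ng86_diffs_oracle(c1, c2)
        if d is None:
            continue
        s1 += ng86_sites_oracle(c1)
        s2 += ng86_sites_oracle(c2)
        sd += d[0]
        nd += d[1]
        ncod += 1
    syn = (s1 + s2) / 2.0
    nonsyn = 3.0 * ncod - syn

    def jc(p):
        if p is None or p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    pS = sd / syn if syn > 0 else None
    pN = nd / nonsyn if nonsyn > 0 else None
    return syn, nonsyn, sd, nd, jc(pS), jc(pN)


# ---------------------------------------------------------------------------
# HKA T-hat oracle


def hka_T_grid_oracle(inputs, t_max=50.0, steps=2_000_001) -> float:
    """Dense-grid minimiser of |g(T)| for the HKA moment fit."""

    def g(T):
        pred = 0.0
        obs = 0.0
        for row in inputs:
            a = sum(1.0 / j for j in range(1, row.nsam))
            theta = (row.S + row.D) / (row.L_pol * a + row.L_div * (T + 1.0))
            pred += theta * row.L_div * (T + 1.0)
            obs += row.D
        return obs - pred

    if g(0.0) <= 0:
        return 0.0
    best_t, best = 0.0, abs(g(0.0))
    # coarse-to-fine grid
    lo, hi = 0.0, t_max
    for _ in range(4):
        ts = [lo + (hi - lo) * i / 1000.0 for i in range(1001)]
        vals = [abs(g(t)) for t in ts]
        i = vals.index(min(vals))
        best_t, best = ts[i], vals[i]
        lo = ts[max(0, i - 1)]
        hi = ts[min(len(ts) - 1, i + 1)]
    return best_t
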