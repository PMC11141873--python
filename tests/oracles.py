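"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: naive
set-membership motif matching, explicit rank computation for Spearman,
closed-form 2x2 binomial log-likelihoods for the logistic LR test, and
the step-up definition of Benjamini-Hochberg.
"""

import math

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_match(consensus: str, window: str) -> bool:
    for c, b in zip(consensus, window):
        if b == "N":
            if c != "N":
                return False
        elif b not in IUPAC[c]:
            return False
    return True


def naive_scan(seq: str, consensus_strings) -> list[tuple[int, int]]:
    """Collapsed (start0, length) occurrences, both strands, all variants."""
    hits = set()
    for cons in consensus_strings:
        L = len(cons)
        for i in range(len(seq) - L + 1):
            win = seq[i : i + L]
            if naive_match(cons, win) or naive_match(cons, naive_revcomp(win)):
                hits.add((i, L))
    return sorted(hits)


def naive_spearman(x, y) -> float:
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def lr_test_2x2(n11, n10, n01, n00):
    """LR test of association in a 2x2 table via binomial log-likelihoods.

    Rows: member/background; columns: motif present/absent.  Returns
    (log-odds-ratio, LR statistic, p from chi2 df=1).  Equivalent to the
    logistic regression of membership on presence.
    """
    from scipy import stats

    def ll(k, n):
        if k == 0 or k == n:
            return 0.0
        p = k / n
        return k * math.log(p) + (n - k) * math.log(1 - p)

    n_present = n11 + n01
    n_absent = n10 + n00
    n = n_present + n_absent
    k = n11 + n10  # total members
    ll_full = ll(n11, n_present) + ll(n10, n_absent)
    ll_null = ll(k, n)
    lr = 2.0 * (ll_full - ll_null)
    log_or = math.log((n11 * n00) / (n10 * n01))
    return log_or, lr, float(stats.chi2.sf(lr, df=1))


def random_iupac_motif(rng: np.random.Generator, min_len=4, max_len=8, max_degenerate=3):
    codes = "ACGT"
    deg = "RYSWKMBDHVN"
    L = int(rng.integers(min_len, max_len + 1))
    s = [codes[rng.integers(4)] for _ in range(L)]
    for pos in rng.choice(L, size=min(int(rng.integers(0, max_degenerate + 1)), L), replace=False):
        s[pos] = deg[rng.integers(len(deg))]
    return "".join(s)


def random_sequence(rng: np.random.Generator, n: int, with_n=False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=n, p=probs))
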