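"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scanning/statistics code paths: the
seed-site oracle scans every window with explicit string comparison, and the
rank-sum oracle enumerates the full permutation null.
"""

from itertools import combinations

import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def bruteforce_seed_sites(ccr_seq: str, family) -> list[tuple[str, int]]:
    """All (site_type, offset) calls for one family in one CCR by naive scan.

    Site definitions: 8mer = revcomp(seed 2-8)+A, 7mer-m8 = revcomp(seed 2-8),
    7mer-1A = revcomp(seed 2-7)+A, 6mer-1-7 = revcomp(mature positions 1-7).
    A biological occurrence is identified by the position of the hexamer
    complementary to seed positions 2-7 (offset+1 for 8mer/7mer-m8, offset for
    the others); only the most specific type per occurrence is kept.
    """
    seed = family.seed_2_8.replace("U", "T")
    patterns = [
        ("8mer", _rc(seed) + "A"),
        ("7mer-m8", _rc(seed)),
        ("7mer-1A", _rc(seed[:6]) + "A"),
    ]
    mature = family.mature_sequence
    if mature is not None and len(mature) >= 7:
        patterns.append(("6mer-1-7", _rc(mature[:7].replace("U", "T"))))

    claimed: dict[int, tuple[str, int]] = {}
    for site_type, pattern in patterns:  # ordered most specific first
        width = len(pattern)
        for offset in range(len(ccr_seq) - width + 1):
            window = ccr_seq[offset : offset + width]
            if all(a == b for a, b in zip(window, pattern)):
                core = offset + 1 if site_type in ("8mer", "7mer-m8") else offset
                if core not in claimed:
                    claimed[core] = (site_type, offset)
    return [claimed[core] for core in sorted(claimed)]


def exact_ranksum_two_sided_p(x, y) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(x, y)
    total = 0
    ge = 0
    le = 0
    indices = range(len(pooled))
    for combo in combinations(indices, n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in indices if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        ge += u >= u_obs
        le += u <= u_obs
    return min(1.0, 2 * min(ge / total, le / total))


def irls_ridge_logistic(X, y, lam, n_iter=200):
    """Ridge-penalized logistic regression by damped Newton iterations.

    Minimizes sum(nll)/1 + (n*lam/2)*||beta||^2 with an unpenalized intercept
    (the glmnet-style objective at alpha=0, scaled by n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(m + 1)
    penalty = n * lam * np.diag([0.0] + [1.0] * m)
    for _ in range(n_iter):
        eta = Xa @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = Xa.T @ (y - p) - penalty @ beta
        hess = (Xa * W[:, None]).T @ Xa + penalty
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta[0], beta[1:]
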