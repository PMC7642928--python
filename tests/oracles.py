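"""Independent brute-force reference implementations used to validate the
package.  Everything here is written from first principles and shares no
code with satevol internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

GAP_OPEN = -8
GAP_EXTEND = -1
MATCH = 2
MISMATCH = -3


def gotoh_score(a: str, b: str) -> float:
    """Global affine-gap alignment score; gap of length L costs
    open + L*extend (same convention as the package)."""
    n, m = len(a), len(b)
    neg = -1e18
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * i
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + GAP_OPEN + GAP_EXTEND, X[i - 1][j] + GAP_EXTEND
            )
            Y[i][j] = max(
                M[i][j - 1] + GAP_OPEN + GAP_EXTEND, Y[i][j - 1] + GAP_EXTEND
            )
    return max(M[n][m], X[n][m], Y[n][m])


def p_distance_oracle(a: str, b: str) -> float:
    """Site-by-site difference count with pairwise deletion."""
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            if x != y:
                diffs += 1
    return math.nan if compared == 0 else diffs / compared


def k2p_oracle(a: str, b: str, gamma_shape: float | None = None) -> float:
    purines = {"A", "G"}
    compared = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        compared += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    if compared == 0:
        return math.nan
    P, Q = ts / compared, tv / compared
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    if gamma_shape is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return (gamma_shape / 2) * (
        w1 ** (-1 / gamma_shape) + 0.5 * w2 ** (-1 / gamma_shape) - 1.5
    )


def tajimas_d_oracle(seqs: list[str]) -> float:
    """Direct transcription of the published formulas, complete deletion."""
    n = len(seqs)
    if n < 4:
        return math.nan
    keep = [
        j
        for j in range(len(seqs[0]))
        if all(s[j] in "ACGT" for s in seqs)
    ]
    if not keep:
        return math.nan
    S = 0
    total_diffs = 0
    for j in keep:
        col = [s[j] for s in seqs]
        if len(set(col)) > 1:
            S += 1
        for x, y in itertools.combinations(col, 2):
            total_diffs += x != y
    if S == 0:
        return math.nan
    pi = total_diffs / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    return (pi - S / a1) / denom


def divergence_table_oracle(
    seqs: dict[str, str], species_of: dict[str, str]
) -> dict[tuple[str, str], float]:
    """All-pairs average p-distance per (species, species) cell."""
    sums: dict[tuple[str, str], list[float]] = {}
    for a, b in itertools.combinations(sorted(seqs), 2):
        d = p_distance_oracle(seqs[a], seqs[b])
        if math.isnan(d):
            continue
        key = tuple(sorted((species_of[a], species_of[b])))
        sums.setdefault(key, []).append(d)
    return {k: sum(v) / len(v) for k, v in sums.items()}


def tree_path_lengths(newick: str) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a newick tree, via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        key = tuple(sorted((t1.label, t2.label)))
        out[key] = pdm.distance(t1, t2)
    return out


def substitution_matrix(p_site: float, kappa: float) -> np.ndarray:
    """One-branch site transition matrix of the simulator's mutation model
    (order ACGT): with probability p_site the base changes, transitions
    weighted kappa against 1 for each transversion."""
    bases = "ACGT"
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    P = np.zeros((4, 4))
    for i, x in enumerate(bases):
        P[i, i] = 1 - p_site
        for j, y in enumerate(bases):
            if x == y:
                continue
            w = kappa if transition[x] == y else 1.0
            P[i, j] = p_site * w / (kappa + 2.0)
    return P


def expected_p_distance(branch_ps: list[float], kappa: float) -> float:
    """Expected p-distance between two leaves whose lineages apply the
    per-branch matrices in ``branch_ps`` (split evenly, uniform root)."""
    half = len(branch_ps) // 2
    left = np.eye(4)
    for p in branch_ps[:half]:
        left = left @ substitution_matrix(p, kappa)
    right = np.eye(4)
    for p in branch_ps[half:]:
        right = right @ substitution_matrix(p, kappa)
    match = 0.0
    for x in range(4):
        match += 0.25 * float((left[x] * right[x]).sum())
    return 1.0 - match
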