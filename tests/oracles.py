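"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and
dictionaries, independent of the package's vectorized code paths.
"""

from collections import Counter
from itertools import combinations
from math import log2

import numpy as np

MISSING = -1


def tally_maf(column):
    """Allele frequency by explicit allele counting."""
    alleles = 0
    seen = 0
    for g in column:
        if g == MISSING:
            continue
        alleles += g
        seen += 1
    return alleles / (2 * seen)


def tally_cells(genotypes, phenotype, loci):
    """(cases, controls) per multilocus genotype cell, via dict counting."""
    counts = {}
    for row, y in zip(genotypes, phenotype):
        cell = tuple(int(row[i]) for i in loci)
        if any(g == MISSING for g in cell):
            continue
        ca, co = counts.get(cell, (0, 0))
        counts[cell] = (ca + 1, co) if y == 1 else (ca, co + 1)
    return counts


def label_cells_oracle(genotypes, phenotype, loci, threshold):
    """high/low/empty label per cell, by the ratio rule."""
    counts = tally_cells(genotypes, phenotype, loci)
    labels = {}
    for cell, (ca, co) in counts.items():
        if ca + co == 0:
            labels[cell] = "empty"
        elif co == 0 or ca / co >= threshold:
            labels[cell] = "high"
        else:
            labels[cell] = "low"
    return labels


def balanced_accuracy_oracle(genotypes, phenotype, loci, train_mask, test_mask, threshold):
    """Training/testing balanced accuracy of the MDR reduction, by loops."""
    labels = label_cells_oracle(genotypes[train_mask], phenotype[train_mask], loci, threshold)

    def score(mask):
        tp = fn = fp = tn = 0
        for row, y in zip(genotypes[mask], phenotype[mask]):
            cell = tuple(int(row[i]) for i in loci)
            if any(g == MISSING for g in cell):
                continue
            pred = 1 if labels.get(cell, "low") == "high" else 0
            if y == 1 and pred == 1:
                tp += 1
            elif y == 1:
                fn += 1
            elif pred == 1:
                fp += 1
            else:
                tn += 1
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return (sens + spec) / 2

    return score(train_mask), score(test_mask)


def search_oracle(genotypes, phenotype, k, folds, threshold):
    """Mean training/testing BA for every k-combination, by nested loops."""
    p = genotypes.shape[1]
    out = {}
    for combo in combinations(range(p), k):
        tr_scores, te_scores = [], []
        for f in sorted(set(folds)):
            tr = folds != f
            te = folds == f
            tr_ba, te_ba = balanced_accuracy_oracle(
                genotypes, phenotype, combo, tr, te, threshold
            )
            tr_scores.append(tr_ba)
            te_scores.append(te_ba)
        out[combo] = (np.nanmean(tr_scores), np.nanmean(te_scores))
    return out


def entropy_oracle(values):
    """Plug-in Shannon entropy from a Counter."""
    counts = Counter(values)
    n = sum(counts.values())
    return -sum((c / n) * log2(c / n) for c in counts.values())


def mutual_information_oracle(a, y):
    """I(A;Y) from the contingency table, by dict counting."""
    pairs = [(ai, yi) for ai, yi in zip(a, y) if ai != MISSING and yi != MISSING]
    return (
        entropy_oracle([p[0] for p in pairs])
        + entropy_oracle([p[1] for p in pairs])
        - entropy_oracle(pairs)
    )


def interaction_information_oracle(a, b, y):
    """IG via the inclusion-exclusion identity over joint entropies."""
    rows = [
        (ai, bi, yi)
        for ai, bi, yi in zip(a, b, y)
        if MISSING not in (ai, bi, yi)
    ]
    A = [r[0] for r in rows]
    B = [r[1] for r in rows]
    Y = [r[2] for r in rows]
    AB = list(zip(A, B))
    AY = list(zip(A, Y))
    BY = list(zip(B, Y))
    ABY = rows
    return (
        entropy_oracle(AB) + entropy_oracle(AY) + entropy_oracle(BY)
        - entropy_oracle(A) - entropy_oracle(B) - entropy_oracle(Y)
        - entropy_oracle(ABY)
    )


def betweenness_oracle(adjacency):
    """Unnormalized shortest-path betweenness by explicit path enumeration.

    ``adjacency``: dict node -> set of neighbours.  Suitable for <= 8 nodes.
    """
    nodes = sorted(adjacency)

    def all_shortest_paths(s, t):
        # breadth-first enumeration of all shortest s-t paths
        paths = [[s]]
        found = []
        best = None
        while paths:
            nxt = []
            for path in paths:
                if best is not None and len(path) > best:
                    continue
                last = path[-1]
                if last == t:
                    found.append(path)
                    best = len(path)
                    continue
                for nb in adjacency[last]:
                    if nb not in path:
                        nxt.append(path + [nb])
            paths = nxt
        shortest = min((len(p) for p in found), default=0)
        return [p for p in found if len(p) == shortest]

    betw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                betw[v] += through / len(paths)
    return betw
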