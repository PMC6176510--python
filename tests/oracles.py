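"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's own code paths (plain Python loops,
``math.log2``, exhaustive enumeration) so that agreement is evidence, not
tautology.
"""

from collections import Counter
from itertools import chain, combinations
from math import log2, sqrt


def mi_brute_force(symbols_x, symbols_y):
    """Mutual information in bits from raw symbol counts, by direct tally."""
    n = len(symbols_x)
    assert n == len(symbols_y)
    cx = Counter(symbols_x)
    cy = Counter(symbols_y)
    cxy = Counter(zip(symbols_x, symbols_y))
    h_x = -sum((c / n) * log2(c / n) for c in cx.values())
    h_y = -sum((c / n) * log2(c / n) for c in cy.values())
    h_xy = -sum((c / n) * log2(c / n) for c in cxy.values())
    return h_x + h_y - h_xy


def entropy_brute_force(symbols):
    n = len(symbols)
    return -sum((c / n) * log2(c / n) for c in Counter(symbols).values())


def ap_exemplar_oracle(values, preference):
    """Best exemplar subset by exhaustive search over all 2^n - 1 candidates.

    Maximizes sum of preferences of chosen exemplars plus, for every other
    point, its best (negated squared distance) similarity to an exemplar.
    Returns the grouping as a frozenset of frozensets of point indices.
    """
    n = len(values)
    best_score, best_subset = -float("inf"), None
    subsets = chain.from_iterable(
        combinations(range(n), k) for k in range(1, n + 1)
    )
    for subset in subsets:
        score = preference * len(subset)
        for i in range(n):
            if i in subset:
                continue
            score += max(-((values[i] - values[k]) ** 2) for k in subset)
        if score > best_score:
            best_score, best_subset = score, subset
    groups = {k: [k] for k in best_subset}
    for i in range(n):
        if i in best_subset:
            continue
        k = max(best_subset, key=lambda k: -((values[i] - values[k]) ** 2))
        groups[k].append(i)
    return frozenset(frozenset(g) for g in groups.values())


def auc_brute_force(scores, labels):
    """All positive-negative pair concordance count (ties count half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def gmean_brute_force(tp, fp, tn, fn):
    return sqrt((tp / (tp + fn)) * (tn / (tn + fp)))
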