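"""Naive one-vs-one SVM evaluator used as an independent test oracle.

Implements the pairwise decision function and vote tally with plain
Python loops and ``math.exp``, straight from the textbook definition
f(x) = sum_i C_i * K(x, s_i) - rho, deliberately sharing no code with the
package's vectorised prediction path.
"""

import math


def oracle_kernel(x, s, gamma):
    d2 = sum((xi - si) ** 2 for xi, si in zip(x, s))
    return math.exp(-gamma * d2)


def oracle_pair_decision(x, model, j, k):
    """f(x) for pair (j, k) using only loops over the two SV blocks."""
    starts = [0]
    for c in model.sv_counts:
        starts.append(starts[-1] + int(c))
    f = 0.0
    for i in range(starts[j], starts[j + 1]):
        f += float(model.coefficients[i, k - 1]) * oracle_kernel(
            x, model.support_vectors[i], model.gamma)
    for i in range(starts[k], starts[k + 1]):
        f += float(model.coefficients[i, j]) * oracle_kernel(
            x, model.support_vectors[i], model.gamma)
    # rho index: position of (j, k) in the lexicographic pair list
    p = 0
    for a in range(model.n_classes):
        for b in range(a + 1, model.n_classes):
            if (a, b) == (j, k):
                return f - float(model.rho[p])
            p += 1
    raise AssertionError("pair not found")


def oracle_predict(x, model):
    """Vote tally over all pairs; ties go to the lowest class index."""
    votes = [0] * model.n_classes
    for j in range(model.n_classes):
        for k in range(j + 1, model.n_classes):
            if oracle_pair_decision(x, model, j, k) > 0:
                votes[j] += 1
            else:
                votes[k] += 1
    best = max(votes)
    return model.class_labels[votes.index(best)]
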