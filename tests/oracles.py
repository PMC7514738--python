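"""Independent brute-force oracles, written with naive Python loops.

These deliberately avoid numpy vectorisation and the library code
paths: plain accumulation over nested loops, so they can arbitrate the
library's entropy quantities.
"""

import math


def naive_normalize(grid):
    flat = [float(v) for row in grid for v in row]
    total = sum(flat)
    return [v / total for v in flat]


def naive_shannon(p):
    s = 0.0
    for pi in p:
        if pi > 0:
            s -= pi * math.log(pi)
    return s


def naive_renyi(p, order):
    if order == 0:
        return math.log(sum(1 for pi in p if pi > 0))
    if order == 1:
        return naive_shannon(p)
    acc = 0.0
    for pi in p:
        if pi > 0:
            acc += pi**order
    return math.log(acc) / (1.0 - order)


def naive_participation_ratio(p):
    acc = 0.0
    for pi in p:
        acc += pi * pi
    return 1.0 / acc


def naive_filling_factor(p):
    return naive_participation_ratio(p) / len(p)


def naive_structural_entropy(p):
    return naive_shannon(p) - math.log(naive_participation_ratio(p))
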