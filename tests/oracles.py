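"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def brute_force_c(scores, time, event):
    """O(n^2) pair enumeration of Harrell's C, written independently of the
    package implementation: a pair is comparable when the smaller time is an
    event (tied times only when exactly one is an event); the earlier-event
    subject should carry the higher score; tied scores earn half credit.

    Returns (n_comparable, n_concordant, C).
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    comparable = 0
    concordant = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if event[i] + event[j] != 1:
                    continue
                first, second = (i, j) if event[i] == 1 else (j, i)
            elif time[i] < time[j]:
                if event[i] == 0:
                    continue
                first, second = i, j
            else:
                if event[j] == 0:
                    continue
                first, second = j, i
            comparable += 1
            if scores[first] > scores[second]:
                concordant += 1.0
            elif scores[first] == scores[second]:
                concordant += 0.5
    c = concordant / comparable if comparable else float("nan")
    return comparable, concordant, c
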