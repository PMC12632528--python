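"""Independent test-side oracles, kept free of the implementation paths."""

import numpy as np


def bh_brute_force(p):
    """Benjamini-Hochberg step-up straight from its definition.

    adj_i = min over all thresholds t = p_j with p_j >= p_i of
    ``p_j * n / #{k : p_k <= p_j}``, clipped at 1.  Quadratic, but
    independent of any cumulative-minimum shortcut.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    counts = (p[None, :] <= p[:, None]).sum(axis=1)  # counts[j] = #{p<=p[j]}
    vals = p * n / counts
    return np.array([min(1.0, vals[p >= pi].min()) for pi in p])
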