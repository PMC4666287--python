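"""Scripted p-value fixtures for exercising the selection loop without model fits."""

import numpy as np


def make_pvec(m: int, n_small: int) -> np.ndarray:
    """p-vector with exactly ``n_small`` tiny p-values and the rest at 0.95.

    By construction its p05 relevance equals ``n_small`` and, fed through the
    histogram-m0 / q-value machinery, the number of q <= 0.05 rejections is
    also exactly ``n_small`` (tiny p-values get tiny q; 0.95 maps to q near 1).
    """
    p = np.full(m, 0.95)
    p[:n_small] = 1e-4
    return p


def scripted_provider(script: dict, m: int = 100):
    """Provider for ``select_from_pvalues`` driven by a score table.

    ``script`` maps ``frozenset(S)`` to ``{j: p05_count}``; every requested
    ``S`` must be scripted.
    """

    def provider(S):
        key = frozenset(S)
        table = script[key]
        return {j: make_pvec(m, int(table[j])) for j in S}

    return provider
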