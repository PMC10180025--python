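"""Deterministic per-sample reduction kernel for the genomic estimators.

Every estimator sum has the form Σ_j t_{X_ij}(j) with per-SNP term values
that depend only on the dosage code.  A fixed left-to-right summation order
makes results bit-reproducible regardless of array layout, which the
concordance pipeline relies on (identical inputs must give correlations of
exactly 1).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dosage_weighted_sums(dosage, terms):
    """Return out[i, t] = Σ_j terms[code_ij, t, j] over non-missing dosages.

    ``dosage``: int8 (n, m) with codes {0, 1, 2} and -1 for missing;
    ``terms``: float64 (3, k, m).
    """
    n, m = dosage.shape
    k = terms.shape[1]
    out = np.zeros((n, k))
    for i in range(n):
        for j in range(m):
            c = dosage[i, j]
            if c >= 0:
                for t in range(k):
                    out[i, t] += terms[c, t, j]
    return out
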