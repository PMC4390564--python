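"""Single-site Gibbs sweep over the mixed model equations.

The kernel replaces each coordinate of s, in ascending equation order, by
a draw from N((r_i - sum_{j!=i} c_ij s_j)/c_ii, sigma_e2/c_ii), consuming
one pre-drawn standard normal per equation so that all randomness stays
in the caller's seeded generator.  Compiled with numba when available;
the pure-Python fallback is exact but slow.
"""

from __future__ import annotations

import math

import numpy as np


def _sweep_py(indptr, indices, data, r, s, z, sigma_e2):
    n = len(r)
    for i in range(n):
        acc = 0.0
        cii = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            if j == i:
                cii = data[k]
            else:
                acc += data[k] * s[j]
        if cii <= 0.0:
            raise ValueError("nonpositive diagonal in mixed model equations")
        s[i] = (r[i] - acc) / cii + z[i] * math.sqrt(sigma_e2 / cii)


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=False)
    def _sweep_body(indptr, indices, data, r, s, z, sigma_e2):
        n = len(r)
        for i in range(n):
            acc = 0.0
            cii = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                if j == i:
                    cii = data[k]
                else:
                    acc += data[k] * s[j]
            s[i] = (r[i] - acc) / cii + z[i] * math.sqrt(sigma_e2 / cii)

    def gauss_seidel_sample(indptr, indices, data, r, s, z, sigma_e2):
        _sweep_body(indptr, indices, data, r, s, z, sigma_e2)
        if not np.isfinite(s).all():
            raise ValueError(
                "non-finite draw in location sweep (nonpositive or zero "
                "diagonal in the mixed model equations?)")

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    gauss_seidel_sample = _sweep_py
    HAVE_NUMBA = False
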