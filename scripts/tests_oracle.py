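"""Exhaustive triple-loop PCIT oracle, kept independent of the package's
vectorized implementation so acceptance can score agreement between the two.
"""

import numpy as np


def oracle_pcit(R: np.ndarray, guard: float = 1e-9) -> np.ndarray:
    n = R.shape[0]
    sig = np.ones((n, n), dtype=bool)
    np.fill_diagonal(sig, False)

    def partial(x, y, z):
        return (R[x, y] - R[x, z] * R[y, z]) / np.sqrt(
            (1 - R[x, z] ** 2) * (1 - R[y, z] ** 2)
        )

    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z in (x, y):
                    continue
                terms = []
                for a, b, c in ((x, y, z), (x, z, y), (y, z, x)):
                    if abs(R[a, b]) >= guard:
                        terms.append(abs(partial(a, b, c) / R[a, b]))
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(R[x, y]) < eps * abs(R[x, z]) and abs(R[x, y]) < eps * abs(
                    R[y, z]
                ):
                    sig[x, y] = False
                    break
    return sig & sig.T
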