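"""Independent cross-check implementations used only by the tests."""

import numpy as np


def leslie_growth_rate(L, m_annual, width=5):
    """Intrinsic annual growth rate from the dominant Leslie eigenvalue.

    Builds the birth-flow 5-year Leslie matrix from person-years ``L``
    (radix 1, full grid from birth) and annual maternity rates
    ``m_annual`` aligned to the same grid, then returns ``ln(λ)/width``.
    Entirely separate route from the characteristic-equation root solver.
    """
    L = np.asarray(L, dtype=float)
    m = np.asarray(m_annual, dtype=float)
    k = L.size
    assert m.size == k
    s = L[1:] / L[:-1]  # survival ratios between successive intervals
    m_next = np.append(m[1:], 0.0)
    s_pad = np.append(s, 0.0)
    fert_row = (L[0] / 2.0) * (m + s_pad * m_next)
    A = np.zeros((k, k))
    A[0, :] = fert_row
    A[np.arange(1, k), np.arange(k - 1)] = s
    eig = np.linalg.eigvals(A)
    lam = np.max(eig.real[np.abs(eig.imag) < 1e-9])
    return float(np.log(lam) / width)


def brute_force_ratio_mean(mu_p, sd_p, mu_f, sd_f, n, seed):
    """Direct ratio-of-normals simulation, independent of the package RNG path."""
    rng = np.random.default_rng(seed)
    return float((rng.normal(mu_p, sd_p, n) / rng.normal(mu_f, sd_f, n)).mean())
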