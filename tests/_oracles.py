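"""Independent oracle implementations used only by the tests."""

import numpy as np
from scipy import integrate
from scipy import stats as sps


def bf10_noncentral_t(t: float, n: int, r: float = 0.707) -> float:
    """JZS paired BF10 via the noncentral-t route.

    Independent of the production implementation (which integrates over
    the variance-mixture scale g): here the numerator marginalizes the
    noncentral-t density of the observed statistic over the Cauchy prior
    on the standardized effect size delta, BF10 =
    int nct(t; nu, delta*sqrt(n)) Cauchy(delta; r) ddelta / t(t; nu).
    """
    nu = n - 1

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, nu, delta * np.sqrt(n)) * sps.cauchy.pdf(delta, scale=r)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=400)
    den = sps.t.pdf(t, nu)
    return num / den


def butter_gain(order: int, cutoff_hz: float, fs: float, f_hz: float) -> float:
    """Magnitude response of the zero-phase (forward-backward) Butterworth."""
    # |H(f)|^2 for one pass; filtfilt applies the filter twice
    single = 1.0 / np.sqrt(1.0 + (f_hz / cutoff_hz) ** (2 * order))
    return single**2
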