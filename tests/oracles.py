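"""Brute-force numerical oracles, independent of the package's closed forms.

Everything here integrates densities on a dense grid with the trapezoid
rule; nothing reuses the package's posterior algebra.
"""

import numpy as np
from scipy import stats


def quadrature_choice_probs(
    r: float,
    sigma_p: float,
    sigma_l: float,
    mu1: float,
    mu2: float,
    grid_step: float = 0.01,
    region: float = 90.0,
):
    """(p_orange, p_blue) by trapezoid quadrature of prior x likelihood.

    Each side is integrated on its own grid with exact endpoints so the
    split at the reference is not blurred by floating-point grid drift.
    """
    n_side = int(round(region / grid_step)) + 1

    def side_mass(lo, hi):
        x = np.linspace(lo, hi, n_side)
        prior = 0.5 * (
            stats.norm.pdf(x, mu1, sigma_p) + stats.norm.pdf(x, mu2, sigma_p)
        )
        return np.trapezoid(prior * stats.norm.pdf(x, r, sigma_l), x)

    m_orange = side_mass(-region, 0.0)
    m_blue = side_mass(0.0, region)
    total = m_orange + m_blue
    return m_orange / total, m_blue / total


def quadrature_truncated_mean_distance(
    r: float,
    sigma_p: float,
    sigma_l: float,
    mu1: float,
    mu2: float,
    side: int,
    grid_step: float = 0.01,
    region: float = 90.0,
):
    """E|x| under the posterior restricted to the chosen side (1 = blue)."""
    if side == 1:
        x = np.arange(0.0, region + grid_step / 2, grid_step)
    else:
        x = np.arange(-region, 0.0 + grid_step / 2, grid_step)
    prior = 0.5 * (
        stats.norm.pdf(x, mu1, sigma_p) + stats.norm.pdf(x, mu2, sigma_p)
    )
    post = prior * stats.norm.pdf(x, r, sigma_l)
    z = np.trapezoid(post, x)
    return np.trapezoid(np.abs(x) * post, x) / z


def prior_only_choice_probs(sigma_p: float, mu1: float, mu2: float):
    """(p_orange, p_blue) of the bare mixture prior on the decision region."""
    masses = []
    for lo, hi in ((-90.0, 0.0), (0.0, 90.0)):
        m = 0.5 * (
            stats.norm.cdf(hi, mu1, sigma_p)
            - stats.norm.cdf(lo, mu1, sigma_p)
            + stats.norm.cdf(hi, mu2, sigma_p)
            - stats.norm.cdf(lo, mu2, sigma_p)
        )
        masses.append(m)
    total = sum(masses)
    return masses[0] / total, masses[1] / total
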