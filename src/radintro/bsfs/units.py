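"""Conversion of scaled coalescent estimates to natural units.

N_anc = theta / (4 mu) with theta per site (the per-block estimate divided
by block length), N_urb = nu * N_anc, and the split time in years is
t = T * 2 N_anc * g for generation time g.  The scaled migration rate
M = 4 N_anc m is read directly as migrants per generation, so 1/M is the
expected number of generations between effective migrants.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_MU = 7e-9   # per-site per-generation rate (A. thaliana estimate)
DEFAULT_G = 3.0     # average generation time in years for the species pair


@dataclass(frozen=True)
class NaturalUnits:
    mu: float
    g: float
    N_anc: float
    N_urb: float
    t_years: float
    migrants_per_generation: float
    generations_per_migrant: float | None  # None when M = 0


def to_natural_units(fit_or_params, mu: float = DEFAULT_MU,
                     g: float = DEFAULT_G,
                     block_length: int = 117) -> NaturalUnits:
    """Convert a :class:`FitResult` (or bare :class:`IMParams`)."""
    if mu <= 0 or g <= 0 or block_length <= 0:
        raise ValueError("mu, g and block_length must be positive")
    params = getattr(fit_or_params, "params", fit_or_params)
    theta_site = params.theta_anc / block_length
    n_anc = theta_site / (4.0 * mu)
    n_urb = params.nu * n_anc
    t_years = params.T * 2.0 * n_anc * g
    m = params.M
    return NaturalUnits(
        mu=mu, g=g, N_anc=n_anc, N_urb=n_urb, t_years=t_years,
        migrants_per_generation=m,
        generations_per_migrant=(1.0 / m) if m > 0 else None)
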