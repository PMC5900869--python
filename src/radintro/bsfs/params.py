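"""Parameterisation of the two-population divergence models.

The three models share a common parameter vector:

* ``theta_anc`` -- scaled mutation rate per block, theta = 4 N_anc mu l,
  where N_anc is the effective size of the ancestral population (constrained
  to equal that of the outcrossing species) and l is the block length.
* ``nu`` -- ratio N_urb / N_anc of the selfing species' effective size to
  the ancestral size.
* ``T`` -- split time in units of 2 N_anc generations.
* ``M`` -- scaled migration rate, M = 4 N_anc m migrants per generation,
  active only under the isolation-with-migration (IM) models.
* ``direction`` -- forward-in-time donor -> recipient of migrants:
  ``"none"`` (strict divergence, div2), ``"u_to_r"`` or ``"r_to_u"``.

Time runs backwards in the coalescent: lineages currently in the recipient
population migrate into the donor population at rate M/2 per lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

DIRECTIONS = ("none", "u_to_r", "r_to_u")

MODELS = ("div2", "IM_u_to_r", "IM_r_to_u")

#: direction implied by each model id (div2 has no migration)
MODEL_DIRECTION = {"div2": "none", "IM_u_to_r": "u_to_r", "IM_r_to_u": "r_to_u"}


@dataclass(frozen=True)
class IMParams:
    theta_anc: float
    nu: float
    T: float
    M: float = 0.0
    direction: str = "none"

    def __post_init__(self) -> None:
        if not (self.theta_anc > 0):
            raise ValueError(f"theta_anc must be > 0, got {self.theta_anc}")
        if not (self.nu > 0):
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not (self.T >= 0):
            raise ValueError(f"T must be >= 0, got {self.T}")
        if not (self.M >= 0):
            raise ValueError(f"M must be >= 0, got {self.M}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if (self.M > 0) != (self.direction != "none"):
            raise ValueError("M must be 0 iff direction is 'none'")

    def with_(self, **kwargs) -> "IMParams":
        return replace(self, **kwargs)


def model_params(model: str, theta_anc: float, nu: float, T: float,
                 M: float = 0.0) -> IMParams:
    """Build an :class:`IMParams` for a named model, forcing M = 0 for div2."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    direction = MODEL_DIRECTION[model]
    if direction == "none":
        M = 0.0
    elif M <= 0:
        raise ValueError(f"model {model} requires M > 0")
    return IMParams(theta_anc=theta_anc, nu=nu, T=T, M=M, direction=direction)
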