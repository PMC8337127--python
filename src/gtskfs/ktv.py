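"""Single-pool Kt/V urea kinetics (Daugirdas second-generation formula).

Kt/V — dialyzer clearance K times session time t over urea distribution
volume V — is the standard dialysis-dose index; 1.2 per session is the
commonly cited adequacy floor.  The second-generation estimator computes it
from the post/pre-dialysis urea ratio R, the session duration Thd (hours),
the ultrafiltration volume Uf and the post-dialysis body weight BW (same
mass units):

    Kt/V = -ln(R - 0.008 * Thd) + (4 - 3.5 * R) * Uf / BW

The forward map is strictly decreasing in R, so it can be inverted by
bracketed root finding — used by the synthetic-cohort generator to emit a
urea ratio consistent with a prescribed Kt/V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import DomainError, NoSolutionError

#: 1 ml of ultrafiltrate weighs 1 g.
ML_PER_KG = 1000.0


@dataclass(frozen=True)
class DialysisSession:
    """One dialysis session, as the kinetics formula sees it.

    r_ratio : post/pre-dialysis blood-urea ratio (0 < R <= 1 normally).
    thd : session duration in hours.
    uf : ultrafiltration in the same mass units as ``bw`` (kg).
    bw : post-dialysis body weight (kg).
    """

    r_ratio: float
    thd: float
    uf: float
    bw: float

    def __post_init__(self) -> None:
        if self.thd < 0:
            raise DomainError(f"session duration must be >= 0, got {self.thd}")
        if self.bw <= 0:
            raise DomainError(f"post-dialysis weight must be > 0, got {self.bw}")
        if self.uf < 0:
            raise DomainError(f"ultrafiltration must be >= 0, got {self.uf}")


def daugirdas_ktv(session: DialysisSession) -> float:
    """Single-pool Kt/V of a session via the second-generation formula."""
    r, thd = session.r_ratio, session.thd
    arg = r - 0.008 * thd
    if arg <= 0:
        raise DomainError(
            f"log argument R - 0.008*Thd = {arg:.6g} <= 0 (R={r}, Thd={thd})"
        )
    return -math.log(arg) + (4.0 - 3.5 * r) * session.uf / session.bw


def invert_ktv(
    target_ktv: float,
    thd: float,
    uf: float,
    bw: float,
    tol: float = 1e-12,
) -> float:
    """Urea ratio R whose session Kt/V equals ``target_ktv``.

    Solves on the bracket R in (0.008*thd + eps, 1]; the forward map is
    strictly decreasing in R there, so the root is unique when it exists.
    Raises :class:`NoSolutionError` when the target lies below the minimum
    achievable value (attained at R = 1).
    """
    if target_ktv < 0:
        raise NoSolutionError(f"target Kt/V must be >= 0, got {target_ktv}")

    def f(r: float) -> float:
        return daugirdas_ktv(DialysisSession(r, thd, uf, bw)) - target_ktv

    hi = 1.0
    f_hi = f(hi)
    if f_hi > 0:  # even R=1 gives a larger Kt/V than requested
        raise NoSolutionError(
            f"Kt/V={target_ktv:.6g} below the achievable minimum "
            f"{f_hi + target_ktv:.6g} at R=1 (thd={thd}, uf={uf}, bw={bw})"
        )
    if f_hi == 0:
        return hi

    # walk the lower bracket end toward the log singularity until f > 0
    lo_limit = 0.008 * thd
    lo = max(lo_limit + 1e-9, 1e-12)
    while f(lo) < 0:
        lo = lo_limit + (lo - lo_limit) / 10.0
        if lo - lo_limit < 1e-300:
            raise NoSolutionError(
                f"Kt/V={target_ktv:.6g} not reachable on the bracket"
            )
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))
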