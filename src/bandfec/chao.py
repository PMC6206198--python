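"""Closed-form fecundity estimators from within-season capture frequencies.

The naive age ratio M_j/M_a overstates fecundity whenever juveniles are more
catchable than adults.  The correction estimates the population *available
for capture* per age class with Chao's lower-bound abundance estimator,
N-hat = M + f1^2 / (2 f2), which conditions on the numbers of individuals
captured once (f1) versus twice (f2); vulnerability-adjusted fecundity is the
ratio of the two abundances, and relative vulnerability V-hat follows as
(M_j/M_a) / F-hat.  The three estimators are mutually consistent:
F-hat * V-hat = M_j/M_a identically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import RecaptureSummary

__all__ = [
    "ChaoEstimate",
    "chao_abundance",
    "adjusted_fecundity",
    "naive_fecundity",
    "vulnerability_from_ratio",
]


class ChaoUndefinedError(ZeroDivisionError):
    """Chao's estimator is undefined when no individual was captured twice."""


@dataclass(frozen=True)
class ChaoEstimate:
    """Estimated abundance available for capture, with its ingredients."""

    N_hat: float
    M: int
    f1: int
    f2: int


def chao_abundance(M: int, f1: int, f2: int, bias_corrected: bool = False) -> ChaoEstimate:
    """Chao abundance N-hat = M + f1^2 / (2 f2).

    ``f2 = 0`` is an error ("Chao undefined") unless ``bias_corrected`` is
    set, which switches to the f1(f1-1)/(2(f2+1)) form.
    """
    if min(M, f1, f2) < 0:
        raise ValueError("counts must be non-negative")
    if M != f1 + f2:
        raise ValueError(f"capture-frequency identity violated: M={M} != f1+f2={f1 + f2}")
    if bias_corrected:
        extra = f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        if f2 == 0:
            raise ChaoUndefinedError(
                "Chao undefined: no individuals captured twice (f2 = 0)"
            )
        extra = f1 * f1 / (2.0 * f2)
    return ChaoEstimate(N_hat=M + extra, M=M, f1=f1, f2=f2)


def naive_fecundity(M_j: int, M_a: int) -> float:
    """Uncorrected age ratio at banding, juveniles per adult."""
    if M_a <= 0:
        raise ValueError("no adults banded: naive age ratio undefined")
    return M_j / M_a


def adjusted_fecundity(rs: RecaptureSummary, bias_corrected: bool = False) -> float:
    """Vulnerability-adjusted fecundity: ratio of age-specific Chao abundances."""
    Nj = chao_abundance(rs.M_j, rs.f1_j, rs.f2_j, bias_corrected).N_hat
    Na = chao_abundance(rs.M_a, rs.f1_a, rs.f2_a, bias_corrected).N_hat
    return Nj / Na


def vulnerability_from_ratio(M_j: int, M_a: int, F_hat: float) -> float:
    """Relative vulnerability to capture V-hat = (M_j/M_a) / F-hat."""
    if F_hat <= 0:
        raise ValueError("fecundity estimate must be positive")
    return naive_fecundity(M_j, M_a) / F_hat
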