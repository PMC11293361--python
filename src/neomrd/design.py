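"""Simon two-stage phase-II design evaluation.

A Simon design enrolls ``n1`` patients in stage 1 and stops for futility if
the number of responders is at most ``r1``; otherwise enrollment continues to
``n`` patients in total and the treatment is declared promising if the total
number of responders exceeds ``r``.  All operating characteristics here are
exact binomial computations: the probability of early termination (PET), the
expected sample size EN(p), and the attained type-I error / power by exact
convolution of the two stage-wise binomial counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "SimonDesign",
    "pet",
    "expected_sample_size",
    "attained_alpha",
    "attained_power",
    "search_optimal",
]


@dataclass(frozen=True)
class SimonDesign:
    """A two-stage design with null/alternative response probabilities.

    Rejection of the null (treatment declared active) requires strictly more
    than ``r`` responses among ``n`` patients, after passing the stage-1
    futility bound (more than ``r1`` responses among the first ``n1``).
    """

    n1: int
    r1: int
    n: int
    r: int
    p0: float
    p1: float

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.n1 <= self.n):
            raise ValueError(f"require 0 <= r1 <= n1 <= n, got r1={self.r1}, n1={self.n1}, n={self.n}")
        if not (self.r1 <= self.r <= self.n):
            raise ValueError(f"require r1 <= r <= n, got r1={self.r1}, r={self.r}, n={self.n}")
        if not (0.0 < self.p0 < self.p1 < 1.0):
            raise ValueError(f"require 0 < p0 < p1 < 1, got p0={self.p0}, p1={self.p1}")


def _check_p(p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"response probability must be in (0, 1), got {p}")


def pet(design: SimonDesign, p: float) -> float:
    """Probability of early termination at response probability ``p``.

    The trial stops after stage 1 iff the stage-1 response count is <= r1,
    so PET(p) = B(r1; n1, p), the binomial CDF.
    """
    _check_p(p)
    return float(binom.cdf(design.r1, design.n1, p))


def expected_sample_size(design: SimonDesign, p: float) -> float:
    """Expected accrual EN(p) = n1 + (1 - PET(p)) * (n - n1)."""
    return design.n1 + (1.0 - pet(design, p)) * (design.n - design.n1)


def _reject_prob(n1: int, r1: int, n: int, r: int, p: float) -> float:
    # P(X1 > r1 and X1 + X2 > r) with X1~Bin(n1,p), X2~Bin(n-n1,p)
    x1 = np.arange(r1 + 1, n1 + 1)
    if x1.size == 0:
        return 0.0
    return float(np.sum(binom.pmf(x1, n1, p) * binom.sf(r - x1, n - n1, p)))


def attained_alpha(design: SimonDesign) -> float:
    """Exact rejection probability under the null response rate p0."""
    return _reject_prob(design.n1, design.r1, design.n, design.r, design.p0)


def attained_power(design: SimonDesign) -> float:
    """Exact rejection probability under the alternative response rate p1."""
    return _reject_prob(design.n1, design.r1, design.n, design.r, design.p1)


def search_optimal(
    p0: float,
    p1: float,
    alpha_max: float = 0.05,
    beta_max: float = 0.10,
    n_max: int = 55,
) -> SimonDesign:
    """Exhaustive search for the Simon-optimal design.

    Enumerates all (n1, r1, n, r) with n <= n_max, keeps designs whose exact
    type-I error is <= alpha_max and power >= 1 - beta_max, and returns the
    one minimizing the expected sample size under the null, EN(p0).  Ties are
    broken by smaller n, then smaller n1.

    Raises ``ValueError`` if p0 >= p1 or no feasible design exists.
    """
    if not (0.0 < p0 < p1 < 1.0):
        raise ValueError(f"require 0 < p0 < p1 < 1, got p0={p0}, p1={p1}")
    best: SimonDesign | None = None
    best_key: tuple[float, int, int] | None = None
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            pmf1_0 = binom.pmf(np.arange(n1 + 1), n1, p0)
            pmf1_1 = binom.pmf(np.arange(n1 + 1), n1, p1)
            # sf2[j] = P(X2 > j) for j in -1..n2 (index shifted by 1)
            j = np.arange(-1, n2 + 1)
            sf2_0 = binom.sf(j, n2, p0)
            sf2_1 = binom.sf(j, n2, p1)
            for r1 in range(0, n1):
                pet0 = float(binom.cdf(r1, n1, p0))
                en0 = n1 + (1.0 - pet0) * n2
                if best_key is not None and en0 > best_key[0]:
                    continue  # EN grows with r only through feasibility, prune
                x1 = np.arange(r1 + 1, n1 + 1)
                w0 = pmf1_0[x1]
                w1 = pmf1_1[x1]
                for r in range(r1, n):
                    # clip r - x1 into sf index range [-1, n2]
                    idx = np.clip(r - x1, -1, n2) + 1
                    alpha = float(np.sum(w0 * sf2_0[idx]))
                    if alpha > alpha_max:
                        continue
                    power = float(np.sum(w1 * sf2_1[idx]))
                    if power < 1.0 - beta_max:
                        break  # power decreases as r grows
                    key = (en0, n, n1)
                    if best_key is None or key < best_key:
                        best = SimonDesign(n1=n1, r1=r1, n=n, r=r, p0=p0, p1=p1)
                        best_key = key
                    break  # smallest feasible r minimizes nothing further for this r1
    if best is None:
        raise ValueError(f"no feasible Simon design with n <= {n_max}")
    return best


def summarize(design: SimonDesign) -> dict:
    """Operating characteristics of a design as a plain dict (JSON-ready)."""
    return {
        "n1": design.n1,
        "r1": design.r1,
        "n": design.n,
        "r": design.r,
        "p0": design.p0,
        "p1": design.p1,
        "pet_p0": pet(design, design.p0),
        "en_p0": expected_sample_size(design, design.p0),
        "attained_alpha": attained_alpha(design),
        "attained_power": attained_power(design),
    }
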