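"""Analytic bias theory for the moment estimators.

All of the LD bias algebra runs through three sums of squared marker
correlations, taken over the population LD matrix Sigma*:

    R_CC = sum_{j in C} sum_{l in C} r_jl^2   (among causal markers)
    R_CF = sum_{j in C} sum_{l in F} r_jl^2   (causal x noncausal)
    R_FF = sum_{j in F} sum_{l in F} r_jl^2   (among noncausal markers)

The expectation of the Haseman–Elston estimator of sigma_g^2 is then
approximated by the ratio of expectations

    (M/m) sigma_g^2 (R_CC + R_CF) / (R_CC + 2 R_CF + R_FF),

which is exactly sigma_g^2 when there is no LD, when M = 2m with
R_FF = R_CC (the alternating-causal symmetry), and under exchangeable
correlation.  The exact-repeat structure (d of m causal markers duplicated
r extra times) admits the closed form

    sigma_g^2 (m + r d)^2 / (m (m + r d (2 + r))),

which is strictly below sigma_g^2 for 0 < d < m and r > 0.

For the Dicker-1 estimator only the monotone part of its expectation is
certified here: the inflation diagnostic (R_CC + R_CF)/m is 1 with no LD and
predicts upward bias growing with R_CC and R_CF.

Under relatedness without LD, the HE numerator and denominator no longer
vanish as M grows: E(S_PsiPsi) -> sum_{i<k} phi_ik^2 and
E(S_YPsi) -> sigma_g^2 sum_{i<k} phi_ik^2, so their ratio still targets
sigma_g^2 while the estimator's spread stays bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RSums",
    "r_sums",
    "he_expectation_ratio",
    "repeat_bias",
    "repeat_bias_g",
    "dicker1_inflation_factor",
    "relatedness_limits",
]


@dataclass(frozen=True)
class RSums:
    """Sums of squared correlations over the causal/noncausal index blocks."""

    r_cc: float
    r_cf: float
    r_ff: float
    m: int
    M: int

    def __post_init__(self):
        if self.m < 0 or self.M < self.m:
            raise ValueError("need 0 <= m <= M")


def r_sums(true_ld: np.ndarray, causal_mask: np.ndarray) -> RSums:
    """Exact R sums from a population LD matrix and a causal mask.

    The matrix must be square with unit diagonal; the mask length must match.
    """
    S = np.asarray(true_ld, dtype=float)
    mask = np.asarray(causal_mask, dtype=bool)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("true_ld must be square")
    if mask.size != S.shape[0]:
        raise ValueError("causal_mask length must match the LD matrix size")
    if not np.allclose(np.diagonal(S), 1.0):
        raise ValueError("true_ld must have unit diagonal")
    S2 = S * S
    c = mask
    f = ~mask
    return RSums(
        r_cc=float(S2[np.ix_(c, c)].sum()),
        r_cf=float(S2[np.ix_(c, f)].sum()),
        r_ff=float(S2[np.ix_(f, f)].sum()),
        m=int(c.sum()),
        M=int(mask.size),
    )


def he_expectation_ratio(rs: RSums, sigma_g2: float = 1.0) -> float:
    """Predicted HE expectation (M/m) sigma_g^2 (R_CC+R_CF)/(R_CC+2R_CF+R_FF)."""
    if rs.m == 0:
        raise ValueError("no causal markers")
    denom = rs.r_cc + 2.0 * rs.r_cf + rs.r_ff
    if denom <= 0:
        raise ValueError("denominator R_CC + 2 R_CF + R_FF must be positive")
    return (rs.M / rs.m) * sigma_g2 * (rs.r_cc + rs.r_cf) / denom


def repeat_bias(m: int, d: int, r: int, sigma_g2: float = 1.0) -> float:
    """Closed-form HE expectation under the exact-repeat structure:
    sigma_g^2 (m + r d)^2 / (m (m + r d (2 + r)))."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= d <= m):
        raise ValueError("need 0 <= d <= m")
    if r < 0:
        raise ValueError("r must be >= 0")
    return sigma_g2 * (m + r * d) ** 2 / (m * (m + r * d * (2 + r)))


def repeat_bias_g(g: float, r: int, sigma_g2: float = 1.0) -> float:
    """Repeat bias in the duplicated-fraction parameterization:
    sigma_g^2 (1 + r g)^2 / (1 + 2 r g + r^2 g)."""
    if not (0.0 <= g <= 1.0):
        raise ValueError("g must lie in [0, 1]")
    if r < 0:
        raise ValueError("r must be >= 0")
    return sigma_g2 * (1.0 + r * g) ** 2 / (1.0 + 2.0 * r * g + r * r * g)


def dicker1_inflation_factor(rs: RSums) -> float:
    """Monotone Dicker-1 inflation diagnostic (R_CC + R_CF) / m.

    Equals 1 with no LD; values above 1 predict upward bias of the Dicker-1
    estimator, increasing in R_CC and R_CF.
    """
    if rs.m == 0:
        raise ValueError("no causal markers")
    return (rs.r_cc + rs.r_cf) / rs.m


def relatedness_limits(kinship: np.ndarray, sigma_g2: float = 1.0) -> tuple[float, float]:
    """Large-M limits of the HE sums under relatedness without LD.

    Returns ``(lim E(S_PsiPsi), lim E(S_YPsi)) = (sum_{i<k} phi^2,
    sigma_g^2 sum_{i<k} phi^2)``.  Both are 0 for fully unrelated samples,
    the degenerate regime in which the HE spread grows with M.
    """
    Phi = np.asarray(kinship, dtype=float)
    if Phi.ndim != 2 or Phi.shape[0] != Phi.shape[1]:
        raise ValueError("kinship must be square")
    if not np.allclose(Phi, Phi.T):
        raise ValueError("kinship must be symmetric")
    iu = np.triu_indices(Phi.shape[0], k=1)
    s = float(np.sum(Phi[iu] ** 2))
    return s, sigma_g2 * s
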