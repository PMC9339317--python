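"""SNP-heritability estimators and the matrices they are built from.

Given an n x M matrix of standardized genotypes Gamma, the two fundamental
objects are the genetic relationship matrix (GRM)

    Psi = Gamma Gamma' / M        (n x n)

and the empirical LD matrix

    Sigma = Gamma' Gamma / n      (M x M),

which satisfy the exact trace identity n^2 tr(Sigma^2) = M^2 tr(Psi^2).

The estimators of the genetic variance sigma_g^2 implemented here:

* ``he_regression`` — Haseman–Elston regression of phenotype cross-products
  on GRM off-diagonals: sum_{i<k} y_i y_k Psi_ik / sum_{i<k} Psi_ik^2.
* ``he_matrix_form`` — the approximate matrix form
  (y' Psi y - n) / (tr(Psi' Psi) - n), valid when y is variance-standardized
  and diag(Psi) is close to 1.
* ``dicker1`` — the fixed-SNP-effect moment estimator
  (||Gamma' y||^2 - M y'y) / (n (n+1)), derived for independent markers.
* ``dicker1_sigma`` — its LD-whitened variant using Sigma^{-1} (or a
  pseudoinverse), defined only when Sigma is estimable.
* ``dicker2`` — the trace-moment-corrected estimator using
  mu1 = tr(Sigma)/M and mu2 = tr(Sigma^2)/M - tr(Sigma)^2/(M n).
* ``fit_variance_components`` — ML/REML maximization of the multivariate
  normal log-likelihood with covariance sigma_g^2 Psi + sigma_e^2 I, via a
  one-time eigendecomposition and a 1-D profile over h^2.
* ``gold_standard`` — the oracle that knows the true causal effects beta.

Every estimator reports sigma_g2_hat and the heritability estimate
h2_hat = sigma_g2_hat / sample-variance(y); moment estimates may legally be
negative or exceed 1 and are never truncated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "NonIdentifiableError",
    "StdGenotypeMatrix",
    "GRMatrix",
    "LDMatrix",
    "VarianceEstimate",
    "standardize",
    "standardize_continuous",
    "standardize_data",
    "compute_grm",
    "compute_ld",
    "he_regression",
    "he_matrix_form",
    "dicker1",
    "dicker1_sigma",
    "dicker2",
    "GaussianVarianceModel",
    "mvn_loglik",
    "fit_variance_components",
    "gold_standard",
    "gold_standard_from_trait",
    "clip_unit_interval",
]


class NonIdentifiableError(ValueError):
    """The requested variance component is not identifiable from the data
    (e.g. the GRM is the identity, so genetic and environmental variance
    enter the model only through their sum)."""


@dataclass
class StdGenotypeMatrix:
    """Column-standardized genotypes Gamma with provenance.

    ``kept`` marks the retained (non-monomorphic) input columns; ``freqs``
    are the frequencies actually used for the retained columns.  ``alpha``
    is the frequency-rescaling exponent: the divisor applied to the centered
    counts is ``[2 p (1-p)]^(-alpha/2)``, so the default ``alpha = -1``
    reproduces the usual unit-variance standardization.
    """

    gamma: np.ndarray
    freq_source: str
    alpha: float
    kept: np.ndarray
    freqs: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    @property
    def M(self) -> int:
        return self.gamma.shape[1]


@dataclass
class GRMatrix:
    """Genetic relationship matrix Psi = Gamma Gamma' / M."""

    psi: np.ndarray
    M_used: int


@dataclass
class LDMatrix:
    """Empirical marker LD matrix Sigma = Gamma' Gamma / n."""

    sigma: np.ndarray
    n_used: int


@dataclass
class VarianceEstimate:
    """One estimator's output.

    ``sigma_g2_hat`` is on the variance scale; ``h2_hat`` divides by the
    sample variance (denominator n-1) of the phenotype.  ``diagnostics``
    carries method-specific scalars (S_YPsi/S_PsiPsi for HE, mu1/mu2 for
    Dicker-2, convergence and boundary flags for likelihood fits).
    """

    method: str
    sigma_g2_hat: float
    h2_hat: float
    diagnostics: dict = field(default_factory=dict)


def _sample_var(y: np.ndarray) -> float:
    return float(np.var(y, ddof=1))


def _h2(sigma_g2: float, y: np.ndarray) -> float:
    v = _sample_var(y)
    if v <= 0:
        return float("nan")  # h2 undefined for a constant phenotype
    return sigma_g2 / v


def _as_psi(psi) -> np.ndarray:
    return psi.psi if isinstance(psi, GRMatrix) else np.asarray(psi, dtype=float)


def standardize(
    G: np.ndarray,
    freqs: Optional[np.ndarray] = None,
    alpha: float = -1.0,
    literal_exponent: bool = False,
) -> StdGenotypeMatrix:
    """Standardize allele counts column by column.

    With ``freqs`` omitted, empirical frequencies ``p_hat = mean(G_j)/2``
    are used; monomorphic columns (zero ``2 p (1-p)``) are dropped with a
    warning.  The centered counts are multiplied by
    ``[2 p (1-p)]^(alpha/2)``, so ``alpha = -1`` gives mean-0 variance-1
    columns.  ``literal_exponent`` applies the exponent ``alpha`` directly
    to ``2 p (1-p)`` instead (an alternative published convention).
    """
    G = np.asarray(G)
    if G.ndim != 2:
        raise ValueError("G must be 2-D")
    if freqs is None:
        p = np.asarray(G, dtype=float).mean(axis=0) / 2.0
        source = "empirical"
    else:
        p = np.asarray(freqs, dtype=float)
        if p.size != G.shape[1]:
            raise ValueError("freqs length must equal the marker count")
        source = "true"
    v = 2.0 * p * (1.0 - p)
    kept = v > 0
    if not kept.any():
        raise ValueError("all columns are monomorphic; no usable markers")
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} monomorphic column(s)", stacklevel=2
        )
    vk = v[kept]
    mult = vk**alpha if literal_exponent else vk ** (alpha / 2.0)
    gamma = (np.asarray(G, dtype=float)[:, kept] - 2.0 * p[kept]) * mult
    return StdGenotypeMatrix(
        gamma=gamma, freq_source=source, alpha=alpha, kept=kept, freqs=p[kept]
    )


def standardize_continuous(X: np.ndarray) -> StdGenotypeMatrix:
    """Center and unit-scale continuous (already Gaussian) genotype columns."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.any():
        raise ValueError("all columns are constant; no usable markers")
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} constant column(s)", stacklevel=2)
    return StdGenotypeMatrix(
        gamma=Xc[:, kept] / sd[kept], freq_source="empirical", alpha=-1.0, kept=kept
    )


def standardize_data(data, freqs: Optional[np.ndarray] = None) -> StdGenotypeMatrix:
    """Standardize a :class:`~heritsim.simdata.GenotypeData` by backend."""
    if getattr(data, "backend", None) == "gaussian":
        return standardize_continuous(data.G)
    return standardize(data.G, freqs=freqs)


def compute_grm(std: StdGenotypeMatrix) -> GRMatrix:
    """Psi = Gamma Gamma' / M."""
    if std.n < 2 or std.M < 1:
        raise ValueError("need at least 2 individuals and 1 marker")
    return GRMatrix(psi=(std.gamma @ std.gamma.T) / std.M, M_used=std.M)


def compute_ld(std: StdGenotypeMatrix) -> LDMatrix:
    """Sigma = Gamma' Gamma / n."""
    if std.n < 1 or std.M < 1:
        raise ValueError("empty matrix")
    return LDMatrix(sigma=(std.gamma.T @ std.gamma) / std.n, n_used=std.n)


# ---------------------------------------------------------------------------
# method-of-moments estimators
# ---------------------------------------------------------------------------


def he_regression(y: np.ndarray, psi) -> VarianceEstimate:
    """Haseman–Elston regression estimate of sigma_g^2.

    sigma_g2_hat = S_YPsi / S_PsiPsi with
    S_YPsi = sum_{i<k} y_i y_k Psi_ik and S_PsiPsi = sum_{i<k} Psi_ik^2.
    """
    P = _as_psi(psi)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 individuals")
    d = np.diagonal(P)
    s_ypsi = 0.5 * (y @ P @ y - np.sum(y * y * d))
    s_psipsi = 0.5 * (np.sum(P * P) - np.sum(d * d))
    if s_psipsi == 0:
        raise NonIdentifiableError("GRM is diagonal; no off-diagonal information")
    sg2 = s_ypsi / s_psipsi
    return VarianceEstimate(
        method="HE",
        sigma_g2_hat=float(sg2),
        h2_hat=_h2(sg2, y),
        diagnostics={"S_YPsi": float(s_ypsi), "S_PsiPsi": float(s_psipsi)},
    )


def he_matrix_form(y: np.ndarray, psi, var_rtol: float = 0.2) -> VarianceEstimate:
    """Approximate matrix form (y' Psi y - n) / (tr(Psi' Psi) - n).

    Requires the phenotype to be (approximately) variance-standardized and
    the GRM diagonal to be near 1; both preconditions are checked within
    ``var_rtol``.
    """
    P = _as_psi(psi)
    y = np.asarray(y, dtype=float)
    n = y.size
    vy = _sample_var(y)
    if abs(vy - 1.0) > var_rtol:
        raise ValueError(
            f"phenotype sample variance {vy:.3f} is not ~1; standardize y first"
        )
    mean_diag = float(np.diagonal(P).mean())
    if abs(mean_diag - 1.0) > var_rtol:
        raise ValueError(f"GRM mean diagonal {mean_diag:.3f} is not ~1")
    denom = float(np.sum(P * P)) - n
    if denom == 0:
        raise NonIdentifiableError("tr(Psi'Psi) equals n; GRM is identity-like")
    sg2 = (float(y @ P @ y) - n) / denom
    return VarianceEstimate(
        method="HE_matrix",
        sigma_g2_hat=sg2,
        h2_hat=_h2(sg2, y),
        diagnostics={"denominator": denom},
    )


def dicker1(y: np.ndarray, std: StdGenotypeMatrix) -> VarianceEstimate:
    """Fixed-SNP-effect moment estimator for independent markers:
    (||Gamma' y||^2 - M y'y) / (n (n+1))."""
    y = np.asarray(y, dtype=float)
    n, M = std.n, std.M
    gty = std.gamma.T @ y
    sg2 = (float(gty @ gty) - M * float(y @ y)) / (n * (n + 1))
    return VarianceEstimate(
        method="Dicker1", sigma_g2_hat=sg2, h2_hat=_h2(sg2, y), diagnostics={}
    )


def dicker1_sigma(
    y: np.ndarray,
    std: StdGenotypeMatrix,
    mode: str = "inverse",
    cond_threshold: float = 1e12,
    sigma: Optional[np.ndarray] = None,
) -> VarianceEstimate:
    """LD-whitened Dicker estimator (y' Gamma Sigma^-1 Gamma' y - M y'y) / (n(n+1)).

    ``mode='inverse'`` requires M < n and a numerically invertible Sigma;
    ``mode='pseudoinverse'`` relaxes to rank-deficient Sigma but refuses
    rank(Sigma) = n, where the estimator is undefined.

    ``sigma`` supplies the LD matrix used for whitening; by default the
    empirical Sigma of ``std`` is used.  Note that whitening by the
    empirical Sigma of the *same* data turns Gamma Sigma^-1 Gamma' into n
    times the projection onto the column space of Gamma, which shrinks the
    estimate by roughly (n - M)/(n + 1); the population LD matrix should be
    passed when the unbiased whitened estimator is wanted.
    """
    if mode not in ("inverse", "pseudoinverse"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(y, dtype=float)
    n, M = std.n, std.M
    if sigma is None:
        sigma = compute_ld(std).sigma
    else:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (M, M):
            raise ValueError("sigma shape must be (M, M)")
    gty = std.gamma.T @ y
    if mode == "inverse":
        if M >= n:
            raise ValueError("Sigma is not invertible because M >= n")
        cond = np.linalg.cond(sigma)
        if not np.isfinite(cond) or cond > cond_threshold:
            raise ValueError(f"Sigma condition number {cond:.3g} exceeds threshold")
        quad = float(gty @ np.linalg.solve(sigma, gty))
    else:
        rank = np.linalg.matrix_rank(sigma)
        if rank >= n:
            raise ValueError(
                "rank(Sigma) equals n; the whitened estimator is undefined"
            )
        quad = float(gty @ np.linalg.pinv(sigma, hermitian=True) @ gty)
    sg2 = (quad - M * float(y @ y)) / (n * (n + 1))
    return VarianceEstimate(
        method="Dicker1_sigma",
        sigma_g2_hat=sg2,
        h2_hat=_h2(sg2, y),
        diagnostics={"mode": mode},
    )


def dicker2(y: np.ndarray, std: StdGenotypeMatrix) -> VarianceEstimate:
    """Trace-moment-corrected fixed-SNP-effect estimator.

    sigma_g2_hat = [mu1 ||Gamma' y||^2 - M mu1^2 y'y] / [n (n+1) mu2] with
    mu1 = tr(Sigma)/M and mu2 = tr(Sigma^2)/M - tr(Sigma)^2/(M n).
    The squared-trace term is computed through the smaller Gram matrix, using
    tr(Sigma^2) = ||Gamma Gamma'||_F^2 / n^2.
    """
    y = np.asarray(y, dtype=float)
    n, M = std.n, std.M
    g = std.gamma
    tr_sigma = float(np.sum(g * g)) / n
    if n <= M:
        B = g @ g.T
        tr_sigma2 = float(np.sum(B * B)) / (n * n)
        gty = g.T @ y
        norm_gty2 = float(gty @ gty)
    else:
        B = g.T @ g
        tr_sigma2 = float(np.sum(B * B)) / (n * n)
        gty = g.T @ y
        norm_gty2 = float(gty @ gty)
    mu1 = tr_sigma / M
    mu2 = tr_sigma2 / M - tr_sigma**2 / (M * n)
    # mu2 vanishes (up to rounding) when Sigma is exactly the identity with
    # M = n; compare against the mu1^2 scale of the trace moments
    if mu2 <= 1e-10 * max(mu1 * mu1, 1e-300):
        raise NonIdentifiableError(
            f"mu2 = {mu2:.3g} is not positive; the Dicker-2 estimator is undefined"
        )
    sg2 = (mu1 * norm_gty2 - M * mu1**2 * float(y @ y)) / (n * (n + 1) * mu2)
    return VarianceEstimate(
        method="Dicker2",
        sigma_g2_hat=sg2,
        h2_hat=_h2(sg2, y),
        diagnostics={"mu1": mu1, "mu2": mu2},
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class GaussianVarianceModel:
    """Multivariate-normal likelihood y ~ N(0, sigma_g^2 Psi + sigma_e^2 I).

    A one-time eigendecomposition of Psi makes each likelihood evaluation
    O(n), which is what makes dense (sigma_g^2, sigma_e^2) grids affordable.
    """

    def __init__(self, y: np.ndarray, psi):
        P = _as_psi(psi)
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.size
        if P.shape != (self.n, self.n):
            raise ValueError("GRM shape does not match phenotype length")
        self.eigvals, U = np.linalg.eigh(P)
        self.z = U.T @ self.y
        self.z2 = self.z**2

    def loglik(self, sigma_g2: float, sigma_e2: float) -> float:
        d = sigma_g2 * self.eigvals + sigma_e2
        if np.any(d <= 0):
            raise ValueError("covariance sigma_g2 Psi + sigma_e2 I is not positive definite")
        return float(
            -0.5 * (self.n * math.log(2 * math.pi) + np.sum(np.log(d)) + np.sum(self.z2 / d))
        )

    def loglik_grid(self, sigma_g2s: np.ndarray, sigma_e2s: np.ndarray) -> np.ndarray:
        """Log-likelihood on the outer grid; non-PD cells are NaN.

        Returns an array of shape (len(sigma_g2s), len(sigma_e2s)).
        """
        a = np.asarray(sigma_g2s, dtype=float)[:, None, None]
        b = np.asarray(sigma_e2s, dtype=float)[None, :, None]
        d = a * self.eigvals[None, None, :] + b
        bad = (d <= 0).any(axis=2)
        d = np.where(d <= 0, np.nan, d)
        ll = -0.5 * (
            self.n * math.log(2 * math.pi)
            + np.sum(np.log(d), axis=2)
            + np.sum(self.z2[None, None, :] / d, axis=2)
        )
        ll[bad] = np.nan
        return ll

    @property
    def eigen_spread(self) -> float:
        return float(self.eigvals[-1] - self.eigvals[0])


def mvn_loglik(y: np.ndarray, psi, sigma_g2: float, sigma_e2: float) -> float:
    """Evaluate the MVN log-likelihood at one (sigma_g^2, sigma_e^2) point."""
    return GaussianVarianceModel(y, psi).loglik(sigma_g2, sigma_e2)


def _helmert(n: int) -> np.ndarray:
    """(n-1) x n orthonormal contrast matrix orthogonal to the grand mean."""
    i = np.arange(1, n)
    norm = 1.0 / np.sqrt(i * (i + 1.0))
    H = (np.arange(n)[None, :] < i[:, None]) * norm[:, None]
    H[np.arange(n - 1), i] = -i * norm
    return H


def fit_variance_components(
    y: np.ndarray,
    psi,
    method: str = "ML",
    grid_step: float = 0.001,
    tol: float = 1e-8,
    spread_tol: float = 1e-8,
    boundary_tol: float = 1e-6,
) -> VarianceEstimate:
    """Maximize the MVN log-likelihood over (sigma_g^2, sigma_e^2).

    The total variance is profiled out analytically and the heritability
    ratio h = sigma_g^2 / (sigma_g^2 + sigma_e^2) is optimized on [0, 1] by a
    dense grid followed by local bounded refinement.  ``REML`` projects out a
    grand-mean intercept (Helmert contrasts) before fitting.  Estimates on
    the boundary of [0, 1] are flagged, never silently moved.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=float)
    P = _as_psi(psi)
    if method == "REML":
        H = _helmert(y.size)
        model = GaussianVarianceModel(H @ y, H @ P @ H.T)
    else:
        model = GaussianVarianceModel(y, P)
    if model.eigen_spread <= spread_tol * max(1.0, float(model.eigvals[-1])):
        raise NonIdentifiableError(
            "GRM eigenvalue spread is degenerate (identity-like); "
            "sigma_g2 is not identifiable"
        )
    n, w, z2 = model.n, model.eigvals, model.z2

    def profile_negloglik(h: float) -> float:
        d = h * w + (1.0 - h)
        if np.any(d <= 0):
            return np.inf
        s2 = float(np.mean(z2 / d))
        if s2 <= 0:
            return np.inf
        return 0.5 * (n * math.log(s2) + float(np.sum(np.log(d))))

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    vals = np.array([profile_negloglik(h) for h in grid])
    k = int(np.nanargmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    converged = True
    if hi > lo:
        res = minimize_scalar(
            profile_negloglik, bounds=(lo, hi), method="bounded",
            options={"xatol": tol},
        )
        converged = bool(res.success)
        h_opt = float(res.x) if res.success else float(grid[k])
        if profile_negloglik(float(grid[k])) < res.fun:
            h_opt = float(grid[k])
    else:
        h_opt = float(grid[k])
    d = h_opt * w + (1.0 - h_opt)
    sigma_t2 = float(np.mean(z2 / d))
    sg2 = h_opt * sigma_t2
    se2 = (1.0 - h_opt) * sigma_t2
    boundary = h_opt <= boundary_tol or h_opt >= 1.0 - boundary_tol
    return VarianceEstimate(
        method=method,
        sigma_g2_hat=sg2,
        h2_hat=_h2(sg2, y),
        diagnostics={
            "sigma_e2_hat": se2,
            "h_ratio": h_opt,
            "sigma_t2": sigma_t2,
            "loglik": -profile_negloglik(h_opt) - 0.5 * n * (math.log(2 * math.pi) + 1.0),
            "converged": converged,
            "boundary": boundary,
        },
    )


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def _gold(genetic: np.ndarray, y: np.ndarray) -> VarianceEstimate:
    y = np.asarray(y, dtype=float)
    g = np.asarray(genetic, dtype=float)
    den = float(np.sum((y - y.mean()) ** 2))
    if den == 0:
        raise ValueError("phenotype has zero variance")
    num = float(np.sum((g - g.mean()) ** 2))
    return VarianceEstimate(
        method="gold",
        sigma_g2_hat=float(np.var(g, ddof=1)),
        h2_hat=num / den,
        diagnostics={},
    )


def gold_standard(std_causal: np.ndarray, beta: np.ndarray, y: np.ndarray) -> VarianceEstimate:
    """Oracle estimate: centered sum of squares of Gamma_C beta over that of y."""
    return _gold(np.asarray(std_causal, dtype=float) @ np.asarray(beta, dtype=float), y)


def gold_standard_from_trait(trait) -> VarianceEstimate:
    """Oracle estimate using the genetic values stored in a trait draw."""
    return _gold(trait.genetic_values, trait.y)


def clip_unit_interval(estimate: VarianceEstimate) -> VarianceEstimate:
    """Copy of an estimate with h2_hat clipped to [0, 1] (for plotting only)."""
    return VarianceEstimate(
        method=estimate.method,
        sigma_g2_hat=estimate.sigma_g2_hat,
        h2_hat=float(np.clip(estimate.h2_hat, 0.0, 1.0)),
        diagnostics={**estimate.diagnostics, "clipped": True},
    )
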