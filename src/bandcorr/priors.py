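"""Prior-predictive samplers for 2x2 covariance-matrix priors.

Three ways of putting a prior on the covariance matrix of a bivariate normal
random effect are compared:

* ``uniform_sd`` / ``gamma_sd`` — the *separation strategy*: independent
  priors on each standard deviation plus an independent uniform(-1, 1) prior
  on the correlation.
* ``inverse_wishart`` — the conjugate prior on the whole matrix.  Its draws
  exhibit a built-in dependency between the scale components and the
  correlation, which is the property the diagnostic here quantifies.
* ``flawed_precision`` — a flawed construction that puts gamma priors on the
  *diagonal of the precision matrix* and a shifted-beta prior on an
  off-diagonal coefficient ``rho*``; inverting the resulting precision matrix
  shows the correlation it actually implies is ``-rho*``.

Every sampler returns draws decomposed into (sigma1, sigma2, rho) so the
families can be compared on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import flawed_precision_diagonal, FlawedPrecisionSpec, implied_correlation

__all__ = ["PriorFamily", "PriorDrawSet", "sample_prior", "dependency_diagnostic"]

_KINDS = ("inverse_wishart", "uniform_sd", "gamma_sd", "flawed_precision")

_DEFAULT_HYPERS = {
    # Conventional "vague" conjugate choice: smallest df giving a proper
    # 2x2 inverse-Wishart, identity scale.
    "inverse_wishart": {"df": 3.0, "scale": ((1.0, 0.0), (0.0, 1.0))},
    "uniform_sd": {"lower": 0.0, "upper": 5.0},
    "gamma_sd": {"shape": 1.0, "rate": 1.0},
    # JAGS-style vague gamma on precisions, flat beta on the coefficient.
    "flawed_precision": {
        "omega_shape": 1.001,
        "omega_rate": 0.001,
        "beta_a": 1.0,
        "beta_b": 1.0,
    },
}


@dataclass(frozen=True)
class PriorFamily:
    """A named covariance-prior family with its hyperparameters.

    Gamma hyperparameters follow the shape/rate convention throughout
    (the convention of the MCMC systems these priors are written for).
    """

    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown prior family {self.kind!r}; choose from {_KINDS}")
        hp = dict(_DEFAULT_HYPERS[self.kind])
        unknown = set(self.hyperparameters) - set(hp)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")
        hp.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", hp)
        self._validate(hp)

    def _validate(self, hp: dict) -> None:
        if self.kind == "inverse_wishart":
            scale = np.asarray(hp["scale"], dtype=float)
            if scale.shape != (2, 2) or np.linalg.det(scale) <= 0 or scale[0, 0] <= 0:
                raise ValueError("inverse_wishart scale must be 2x2 positive definite")
            if hp["df"] < 2.0:
                raise ValueError("inverse_wishart df must be >= dimension (2)")
        elif self.kind == "uniform_sd":
            if not hp["lower"] < hp["upper"]:
                raise ValueError("uniform_sd bounds must be ordered")
            if hp["lower"] < 0:
                raise ValueError("uniform_sd lower bound must be >= 0")
        elif self.kind == "gamma_sd":
            if hp["shape"] <= 0 or hp["rate"] <= 0:
                raise ValueError("gamma_sd shape and rate must be positive")
        else:  # flawed_precision
            if hp["omega_shape"] <= 0 or hp["omega_rate"] <= 0:
                raise ValueError("omega gamma shape/rate must be positive")
            if hp["beta_a"] <= 0 or hp["beta_b"] <= 0:
                raise ValueError("beta parameters must be positive")

    @property
    def has_finite_draw_variance(self) -> bool:
        """Inverse-Wishart variances are finite only for df > dim + 3."""
        if self.kind != "inverse_wishart":
            return True
        return self.hyperparameters["df"] > 5.0


@dataclass(frozen=True)
class PriorDrawSet:
    """Monte-Carlo draws of (sigma1, sigma2, rho) from one prior family."""

    sigma1: np.ndarray
    sigma2: np.ndarray
    rho: np.ndarray
    family: PriorFamily
    n_redraws: int = 0  # numerically non-PD inverse-Wishart draws replaced

    def __post_init__(self) -> None:
        if not (len(self.sigma1) == len(self.sigma2) == len(self.rho)):
            raise ValueError("draw columns must have equal length")
        if np.any(self.sigma1 <= 0) or np.any(self.sigma2 <= 0):
            raise ValueError("standard deviations must be positive")
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("correlations must lie in (-1, 1)")

    def __len__(self) -> int:
        return len(self.rho)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sigma1": self.sigma1, "sigma2": self.sigma2, "rho": self.rho}
        )


def _decompose(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s1 = np.sqrt(cov[..., 0, 0])
    s2 = np.sqrt(cov[..., 1, 1])
    return s1, s2, cov[..., 0, 1] / (s1 * s2)


def sample_prior(family: PriorFamily, n_draws: int, seed: int) -> PriorDrawSet:
    """Draw ``n_draws`` (sigma1, sigma2, rho) triples from a prior family.

    For the separation-strategy families the three components are sampled
    independently.  For ``inverse_wishart`` a covariance matrix is drawn and
    decomposed.  For ``flawed_precision`` the flawed precision matrix is built
    from its hyperprior draws and inverted, reporting the covariance
    components the construction *actually* implies.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    hp = family.hyperparameters
    n_redraws = 0

    if family.kind == "uniform_sd":
        sigma1 = rng.uniform(hp["lower"], hp["upper"], n_draws)
        sigma2 = rng.uniform(hp["lower"], hp["upper"], n_draws)
        rho = rng.uniform(-1.0, 1.0, n_draws)
        # uniform(0, b) can emit exact zeros at float resolution; nudge
        sigma1 = np.maximum(sigma1, 1e-300)
        sigma2 = np.maximum(sigma2, 1e-300)
    elif family.kind == "gamma_sd":
        sigma1 = rng.gamma(hp["shape"], 1.0 / hp["rate"], n_draws)
        sigma2 = rng.gamma(hp["shape"], 1.0 / hp["rate"], n_draws)
        rho = rng.uniform(-1.0, 1.0, n_draws)
        sigma1 = np.maximum(sigma1, 1e-300)
        sigma2 = np.maximum(sigma2, 1e-300)
    elif family.kind == "inverse_wishart":
        scale = np.asarray(hp["scale"], dtype=float)
        dist = stats.invwishart(df=hp["df"], scale=scale)
        cov = dist.rvs(size=n_draws, random_state=rng).reshape(n_draws, 2, 2)
        # Guard against numerically degenerate draws (det <= 0 at float
        # precision); redraw them and keep count.
        bad = ~(
            (cov[:, 0, 0] > 0)
            & (cov[:, 1, 1] > 0)
            & (np.linalg.det(cov) > 0)
        )
        while np.any(bad):
            n_bad = int(bad.sum())
            n_redraws += n_bad
            cov[bad] = dist.rvs(size=n_bad, random_state=rng).reshape(n_bad, 2, 2)
            bad = ~(
                (cov[:, 0, 0] > 0)
                & (cov[:, 1, 1] > 0)
                & (np.linalg.det(cov) > 0)
            )
        sigma1, sigma2, rho = _decompose(cov)
    else:  # flawed_precision
        w11 = rng.gamma(hp["omega_shape"], 1.0 / hp["omega_rate"], n_draws)
        w22 = rng.gamma(hp["omega_shape"], 1.0 / hp["omega_rate"], n_draws)
        rho_star = 2.0 * rng.beta(hp["beta_a"], hp["beta_b"], n_draws) - 1.0
        # keep |rho*| < 1 strictly so the precision matrix stays PD
        rho_star = np.clip(rho_star, -1 + 1e-12, 1 - 1e-12)
        off = np.sqrt(w11 * w22) * rho_star
        det = w11 * w22 - off**2
        # analytic 2x2 inverse of the precision matrix
        c11 = w22 / det
        c22 = w11 / det
        c12 = -off / det
        sigma1 = np.sqrt(c11)
        sigma2 = np.sqrt(c22)
        rho = c12 / (sigma1 * sigma2)
    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    return PriorDrawSet(sigma1, sigma2, rho, family=family, n_redraws=n_redraws)


def implied_rho_of_flawed_draw(omega11: float, omega22: float, rho_star: float) -> float:
    """Correlation actually implied by one flawed-precision draw (equals -rho_star)."""
    prec = flawed_precision_diagonal(FlawedPrecisionSpec(omega11, omega22, rho_star))
    return implied_correlation(prec)


def dependency_diagnostic(draws: PriorDrawSet) -> float:
    """Pearson correlation between log(sigma1) and |rho| across prior draws.

    Quantifies whether a prior family couples the scale of the random effects
    to the strength of their correlation: approximately zero for the
    separation-strategy families, bounded away from zero for the
    inverse-Wishart.
    """
    if len(draws) < 1000:
        raise ValueError("diagnostic needs at least 1000 draws")
    x = np.log(draws.sigma1)
    y = np.abs(draws.rho)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("diagnostic undefined for degenerate draws (zero variance)")
    return float(np.corrcoef(x, y)[0, 1])
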