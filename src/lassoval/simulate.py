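"""Synthetic cohort generator for the simulation design.

Twenty standard-normal covariates are drawn from a multivariate normal with
unit variances and eight nonzero pairwise correlations.  The first ten
covariates are dichotomised at fixed percentiles of the standard normal
(theoretical quantiles, so training and external data share the same cut):
X1, X2, X6, X7 at the 50th; X3, X4, X8, X9 at the 30th; X5, X10 at the 20th,
coded 1 when the latent value lies strictly above the threshold.  The outcome
is linear, ``Y = b0 + X'b + eps`` with ``eps ~ N(0, sd)``; with the default
``sd = 1.74`` the irreducible mean squared error is 1.74**2 = 3.0276.

Missingness is missing-completely-at-random: each cell of a listed covariate
column is deleted independently with its per-column probability (defaults:
X2, X7, X12, X17 at 20%; X3, X8, X13, X18 at 50%).  The outcome is never
made missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .data import BINARY, CONTINUOUS, Dataset

N_COV = 20

#: (j, k, r) pairwise correlations of the latent multivariate normal (1-based).
DEFAULT_CORR: list[tuple[int, int, float]] = [
    (1, 5, 0.72), (1, 6, -0.52), (2, 8, 0.74), (4, 12, -0.82),
    (6, 16, -0.34), (10, 20, -0.38), (11, 19, 0.37), (19, 20, 0.65),
]

#: covariate index (1-based) -> dichotomisation percentile
DEFAULT_PERCENTILES: dict[int, float] = {
    1: 50, 2: 50, 6: 50, 7: 50,
    3: 30, 4: 30, 8: 30, 9: 30,
    5: 20, 10: 20,
}

DEFAULT_BETA0 = 1.14
DEFAULT_BETA: list[float] = [
    0.0, 0.0, 0.0, 0.0, 0.0,
    -0.839, 1.131, -1.540, 1.426, 0.854,
    0.0, 0.0, 0.0, 0.0, 0.0,
    0.457, -0.494, -0.738, 1.589, 0.845,
]

#: covariate index (1-based) -> per-cell MCAR probability
DEFAULT_MISS_PROBS: dict[int, float] = {
    2: 0.20, 7: 0.20, 12: 0.20, 17: 0.20,
    3: 0.50, 8: 0.50, 13: 0.50, 18: 0.50,
}

DEFAULT_NOISE_SD = 1.74

#: 1-based indices of covariates with truly nonzero coefficients
RELEVANT_COVARIATES: tuple[int, ...] = (6, 7, 8, 9, 10, 16, 17, 18, 19, 20)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one simulated cohort."""

    n_obs: int = 250
    n_cov: int = N_COV
    corr_entries: list[tuple[int, int, float]] = field(default_factory=lambda: list(DEFAULT_CORR))
    dichotomize_percentiles: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PERCENTILES))
    beta0: float = DEFAULT_BETA0
    beta: list[float] = field(default_factory=lambda: list(DEFAULT_BETA))
    noise_sd: float = DEFAULT_NOISE_SD
    miss_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_MISS_PROBS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.beta) != self.n_cov:
            raise ConfigError(f"beta has length {len(self.beta)}, expected {self.n_cov}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for j, p in self.miss_probs.items():
            if not 1 <= j <= self.n_cov:
                raise ConfigError(f"missingness probability on non-covariate column {j}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"missingness probability {p} outside [0,1]")
        # validates symmetry / positive definiteness as a side effect
        self.correlation_matrix()

    def correlation_matrix(self) -> np.ndarray:
        return build_correlation_matrix(self.corr_entries, self.n_cov)

    def thresholds(self) -> dict[int, float]:
        """1-based covariate index -> latent N(0,1) cut point."""
        return {j: float(stats.norm.ppf(p / 100.0)) for j, p in self.dichotomize_percentiles.items()}

    def var_types(self) -> list[str]:
        types = [BINARY if j in self.dichotomize_percentiles else CONTINUOUS
                 for j in range(1, self.n_cov + 1)]
        return types + [CONTINUOUS]

    def column_names(self) -> list[str]:
        return [f"x{j}" for j in range(1, self.n_cov + 1)] + ["y"]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corr_entries"] = [list(e) for e in self.corr_entries]
        d["dichotomize_percentiles"] = {str(k): v for k, v in self.dichotomize_percentiles.items()}
        d["miss_probs"] = {str(k): v for k, v in self.miss_probs.items()}
        return d


def default_config(n_obs: int = 250, seed: int | None = None, **kwargs) -> SimConfig:
    return SimConfig(n_obs=n_obs, seed=seed, **kwargs)


def build_correlation_matrix(
    corr_entries: list[tuple[int, int, float]], n_cov: int = N_COV
) -> np.ndarray:
    """Assemble the latent correlation matrix from sparse (j, k, r) entries.

    Indices are 1-based.  The matrix must come out positive definite; if it
    does not, the offending smallest eigenvalue is reported.
    """
    R = np.eye(n_cov)
    for j, k, r in corr_entries:
        if not (1 <= j <= n_cov and 1 <= k <= n_cov) or j == k:
            raise ConfigError(f"correlation entry ({j},{k}) out of range")
        if not -1.0 < r < 1.0:
            raise ConfigError(f"correlation value {r} outside (-1, 1)")
        R[j - 1, k - 1] = R[k - 1, j - 1] = r
    eigvals = np.linalg.eigvalsh(R)
    if eigvals[0] <= 0:
        raise ConfigError(
            f"correlation matrix is not positive definite (smallest eigenvalue {eigvals[0]:.6g})"
        )
    return R


def simulate_complete(
    config: SimConfig,
    seed=None,
    return_latent: bool = False,
):
    """Draw one fully observed cohort.

    ``seed`` overrides ``config.seed`` and may be an int, SeedSequence or
    Generator.  With ``return_latent=True`` the pre-dichotomisation latent
    matrix is returned alongside the Dataset (diagnostics only).
    """
    if config.n_obs < 2:
        raise ConfigError("need at least 2 observations")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    R = config.correlation_matrix()
    L = np.linalg.cholesky(R)
    latent = rng.standard_normal((config.n_obs, config.n_cov)) @ L.T

    X = latent.copy()
    for j, cut in config.thresholds().items():
        X[:, j - 1] = (latent[:, j - 1] > cut).astype(float)

    eps = rng.normal(0.0, config.noise_sd, size=config.n_obs) if config.noise_sd > 0 else np.zeros(config.n_obs)
    y = config.beta0 + X @ np.asarray(config.beta, dtype=float) + eps

    values = np.column_stack([X, y])
    ds = Dataset(values, np.ones_like(values, dtype=bool), config.column_names(), config.var_types())
    if return_latent:
        return ds, latent
    return ds


def apply_mcar(dataset: Dataset, miss_probs: dict[int, float], seed=None) -> Dataset:
    """Independently delete cells of the listed covariate columns.

    ``miss_probs`` maps 1-based covariate index to a per-cell Bernoulli
    missingness probability.  Values under the mask are preserved so the truth
    stays available in memory; only the mask changes.
    """
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    for j, p in miss_probs.items():
        if not 1 <= j <= dataset.n_cov:
            raise ConfigError(f"missingness probability on non-covariate column {j}")
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"missingness probability {p} outside [0,1]")
        if p > 0:
            out.mask[:, j - 1] &= rng.random(dataset.n) >= p
    return out
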