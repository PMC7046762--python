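"""Latin-Hypercube Monte Carlo propagation of correction-factor uncertainty.

The dose model is linear in the product of its uncertain correction factors
(FC x DF_shelter for inhalation, FC x Sf for ingestion), so the 95%
uncertainty interval of any dose or dose statistic is the central value
times interval multipliers derived from the simulated factor-product
distribution.  The multipliers are the 2.5th/97.5th percentiles of the
product normalized by the simulated product mean: the reported central
statistic is interpreted as the expectation of the propagated dose
distribution, which the printed dose tables bear out.  Normalization by the
plug-in product of central values is available as an option.

Sampling is stratified (Latin Hypercube): each variable's unit interval is
split into ``n_draws`` equiprobable strata, one uniform draw per stratum,
with stratum order permuted independently per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FactorDistribution:
    """One correction factor's uncertainty distribution.

    kinds:
      ``normal`` — params (mean, sd[, lower]) with optional lower truncation
        by CDF renormalization;
      ``triangular`` — params (low, mode, high);
      ``binomial_proportion`` — params (n, p[, transform]) for Binomial(n,p)/n,
        transform ``complement`` returns 1 - proportion;
      ``point`` — params (value,), degenerate.
    """

    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind == "normal":
            mean, sd = self.params[0], self.params[1]
            if sd <= 0:
                raise ValueError("normal sd must be positive")
        elif self.kind == "triangular":
            low, mode, high = self.params
            if not low < mode < high:
                raise ValueError("triangular requires low < mode < high")
        elif self.kind == "binomial_proportion":
            n, p = self.params[0], self.params[1]
            if not (n >= 1 and 0 < p < 1):
                raise ValueError("binomial_proportion requires n >= 1 and 0 < p < 1")
        elif self.kind == "point":
            if len(self.params) != 1:
                raise ValueError("point takes a single value")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def central(self) -> float:
        """Central (plug-in) value: normal mean, triangular mode, proportion p."""
        if self.kind == "normal":
            return float(self.params[0])
        if self.kind == "triangular":
            return float(self.params[1])
        if self.kind == "binomial_proportion":
            n, p = self.params[0], self.params[1]
            value = float(p)
            if len(self.params) > 2 and self.params[2] == "complement":
                value = 1.0 - value
            return value
        return float(self.params[0])

    def inverse_cdf(self, u):
        """Exact quantile function at probabilities ``u`` in (0,1)."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("probabilities must lie strictly inside (0,1)")
        if self.kind == "point":
            return np.full_like(u, self.params[0])
        if self.kind == "normal":
            mean, sd = self.params[0], self.params[1]
            lower = self.params[2] if len(self.params) > 2 else None
            if lower is None:
                return stats.norm.ppf(u, loc=mean, scale=sd)
            # renormalize the CDF over [lower, inf)
            a = (lower - mean) / sd
            return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)
        if self.kind == "triangular":
            low, mode, high = self.params
            f_mode = (mode - low) / (high - low)
            left = low + np.sqrt(u * (high - low) * (mode - low))
            right = high - np.sqrt((1.0 - u) * (high - low) * (high - mode))
            return np.where(u <= f_mode, left, right)
        if self.kind == "binomial_proportion":
            n, p = int(self.params[0]), float(self.params[1])
            prop = stats.binom.ppf(u, n, p) / n
            if len(self.params) > 2 and self.params[2] == "complement":
                prop = 1.0 - prop
            return prop
        raise AssertionError  # unreachable


# the paper's factor models
FC_DISTRIBUTION = FactorDistribution("normal", (0.62, 0.20, 0.0))
DF_SHELTER_DISTRIBUTION = FactorDistribution("triangular", (0.1, 0.5, 0.95))
SF_TAPWATER_DISTRIBUTION = FactorDistribution("binomial_proportion", (100, 0.3, "complement"))


@dataclass(frozen=True)
class UISpec:
    n_draws: int = 100_000
    quantiles: tuple[float, float] = (0.025, 0.975)
    seed: int = 20110312
    method: str = "lhs"  # or plain_mc

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        lo, hi = self.quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("quantiles must satisfy 0 < low < high < 1")
        if self.method not in ("lhs", "plain_mc"):
            raise ValueError(f"unknown sampling method {self.method!r}")


def lhs_sample(dists: list[FactorDistribution], spec: UISpec) -> np.ndarray:
    """Draw an ``n_draws x k`` sample matrix, stratified per variable.

    With ``method='plain_mc'`` the stratification is dropped and plain
    inverse-transform sampling is used (the convergence cross-check).
    """
    if not dists:
        raise ValueError("need at least one distribution")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_draws
    out = np.empty((n, len(dists)))
    for j, dist in enumerate(dists):
        if spec.method == "lhs":
            u = (rng.permutation(n) + rng.random(n)) / n
        else:
            u = rng.random(n)
        # clip away u==0 that rng.random can in principle return
        np.clip(u, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0), out=u)
        out[:, j] = dist.inverse_cdf(u)
    return out


def product_ui(
    factor_dists: list[FactorDistribution],
    central_product: float,
    spec: UISpec = UISpec(),
    normalize: str = "mean",
) -> tuple[float, float]:
    """95% interval multipliers of the factor product.

    Returns (low, high) such that ``UI(dose) = dose_central * (low, high)``
    for any dose linear in the factor product.  ``normalize='mean'`` (the
    behaviour matching the published dose tables) divides the product
    quantiles by the simulated product mean; ``normalize='central'`` divides
    by ``central_product`` (the plug-in product of central values).
    """
    if central_product <= 0:
        raise ValueError("central product must be positive")
    draws = lhs_sample(factor_dists, spec)
    product = draws.prod(axis=1)
    lo_q, hi_q = np.quantile(product, spec.quantiles)  # type-7 interpolation
    if normalize == "mean":
        denom = float(product.mean())
    elif normalize == "central":
        denom = central_product
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return float(lo_q / denom), float(hi_q / denom)


def inhalation_ui_multipliers(spec: UISpec = UISpec(), normalize: str = "mean",
                              cf=None) -> tuple[float, float]:
    """Interval multipliers for the inhalation pathway (FC x DF_shelter)."""
    if cf is None:
        fc, df = FC_DISTRIBUTION, DF_SHELTER_DISTRIBUTION
        central = 0.62 * 0.5
    else:
        fc = FactorDistribution("normal", (cf.fc_central, cf.fc_sd, 0.0))
        df = FactorDistribution("triangular", cf.df_triangular)
        central = cf.fc_central * cf.df_shelter_central
    return product_ui([fc, df], central, spec, normalize)


def ingestion_ui_multipliers(spec: UISpec = UISpec(), normalize: str = "mean",
                             cf=None) -> tuple[float, float]:
    """Interval multipliers for the tap-water pathway (FC x Sf)."""
    if cf is None:
        fc, sf = FC_DISTRIBUTION, SF_TAPWATER_DISTRIBUTION
        central = 0.62 * 0.7
    else:
        fc = FactorDistribution("normal", (cf.fc_central, cf.fc_sd, 0.0))
        sf = FactorDistribution("binomial_proportion",
                                (*cf.sf_binomial, "complement"))
        central = cf.fc_central * cf.sf_central
    return product_ui([fc, sf], central, spec, normalize)


def combined_ui_multipliers(
    inhal_central: float,
    ing_central: float,
    spec: UISpec = UISpec(),
    normalize: str = "mean",
) -> tuple[float, float]:
    """Interval multipliers for inhalation + ingestion combined.

    FC is the same physiological factor in both pathways, so each replicate
    shares one FC draw: total = inhal * FC*DF + ing * FC*Sf, normalized to
    the central total.
    """
    total_central = inhal_central + ing_central
    if total_central <= 0:
        raise ValueError("central doses must not both be zero")
    draws = lhs_sample(
        [FC_DISTRIBUTION, DF_SHELTER_DISTRIBUTION, SF_TAPWATER_DISTRIBUTION], spec
    )
    fc, df, sf = draws[:, 0], draws[:, 1], draws[:, 2]
    total = inhal_central / 0.31 * fc * df + ing_central / (0.62 * 0.7) * fc * sf
    lo_q, hi_q = np.quantile(total, spec.quantiles)
    denom = float(total.mean()) if normalize == "mean" else total_central
    return float(lo_q / denom), float(hi_q / denom)


def averaged_df_shelter(strata: list[tuple[float, float]]) -> float:
    """Construction-year-averaged sheltering factor.

    ``strata`` are (housing-stock weight, stratum DF) pairs, e.g. by
    building-code era; weights must sum to 1.
    """
    weights = np.array([w for w, _ in strata], dtype=float)
    dfs = np.array([d for _, d in strata], dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative stratum weight")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"stratum weights sum to {weights.sum()}, expected 1")
    return float(weights @ dfs)
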