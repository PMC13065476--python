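"""Fuzzy suitability stage for *Mytilus edulis*.

Each environmental factor is mapped to a [0, 1] physiological-response
score, scores are averaged over time at the factor's native cadence, and
the suitability index is the AHP-weighted sum SI = Σ wᵢ F̄ᵢ, classified
into five bands.

Factor responses (literature fits for *M. edulis*):

* **SST** — CTMI-style thermal growth curve with T_opt = 15.8 °C,
  T_max = 30 °C, shape c = 0.393; equals 1 at T_opt and 0 at/above T_max.
* **CHL** — Michaelis–Menten ingestion saturation, half-saturation
  X_K = 1.06 mg m⁻³.
* **SSS** — quartic fit of the dry-weight/wet-weight ratio against
  salinity; negative values clamped, then min–max standardized over the
  evaluation domain (default [0, 40]).
* **SPM** — quadratic fit of carbon absorption efficiency against
  suspended inorganic sediment; clamped and standardized over [0, 100] g m⁻³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridError, RasterLayer, TimeSeriesStack

#: Saaty random consistency indices by matrix order.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
            8: 1.41, 9: 1.45, 10: 1.49}

#: Consensus factor weights from the expert pairwise comparison.
DEFAULT_WEIGHTS = {"SST": 0.45, "CHL": 0.30, "SSS": 0.16, "SPM": 0.09}

SI_CLASS_NAMES = ["Very low", "Low", "Medium", "High", "Very high"]
SI_CLASS_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


@dataclass(frozen=True)
class SSTResponseParams:
    t_max: float = 30.0
    t_opt: float = 15.8
    c: float = 0.393

    def __post_init__(self):
        if not (self.t_opt < self.t_max and self.c > 0):
            raise ValueError("require t_opt < t_max and c > 0")


@dataclass(frozen=True)
class CHLResponseParams:
    x_k: float = 1.06

    def __post_init__(self):
        if self.x_k <= 0:
            raise ValueError("half-saturation must be positive")


@dataclass(frozen=True)
class PolynomialResponseParams:
    """A fitted polynomial response, clamped and min–max standardized."""

    coefficients: tuple  # descending degree
    domain: tuple = (0.0, 40.0)
    clamp_negative: bool = True

    def __post_init__(self):
        if self.domain[0] >= self.domain[1]:
            raise ValueError("domain lower bound must be below upper bound")
        if not any(c != 0 for c in self.coefficients):
            raise ValueError("at least one coefficient must be nonzero")

    def raw(self, x):
        """Polynomial value before clamping/standardization."""
        return np.polyval(np.asarray(self.coefficients, dtype=float), x)

    def _clamped(self, x):
        y = self.raw(x)
        return np.maximum(y, 0.0) if self.clamp_negative else y

    def extrema(self, n_grid: int = 20001) -> tuple[float, float]:
        """Min and max of the clamped polynomial over the domain.

        Dense grid search refined with the polynomial's critical points
        (roots of the derivative inside the domain).
        """
        lo, hi = self.domain
        xs = np.linspace(lo, hi, n_grid)
        crit = np.roots(np.polyder(np.asarray(self.coefficients, dtype=float)))
        crit = crit[np.isreal(crit)].real
        crit = crit[(crit >= lo) & (crit <= hi)]
        xs = np.concatenate([xs, crit])
        ys = self._clamped(xs)
        return float(ys.min()), float(ys.max())

    def score(self, x):
        """Clamped, min–max-standardized score in [0, 1]; input clipped to domain."""
        x = np.clip(np.asarray(x, dtype=float), *self.domain)
        ymin, ymax = self.extrema()
        if ymax <= ymin:
            raise ValueError("response is constant over the domain; cannot standardize")
        return np.clip((self._clamped(x) - ymin) / (ymax - ymin), 0.0, 1.0)


#: Quartic salinity response (dry-weight/wet-weight ratio fit).
SSS_PARAMS = PolynomialResponseParams(
    coefficients=(-9e-6, 6.91e-4, -2.087e-2, 0.296816, -0.875038),
    domain=(0.0, 40.0),
)

#: Quadratic suspended-sediment response (carbon absorption efficiency fit).
SPM_PARAMS = PolynomialResponseParams(
    coefficients=(-2e-4, -4.2e-3, 0.8273),
    domain=(0.0, 100.0),
)


def sst_score(sst, params: SSTResponseParams = SSTResponseParams()):
    """Thermal suitability in [0, 1]; 1 at T_opt, 0 at and above T_max."""
    t = np.asarray(sst, dtype=float)
    tmax, topt, c = params.t_max, params.t_opt, params.c
    with np.errstate(invalid="ignore"):
        base = np.clip((tmax - t) / (tmax - topt), 0.0, None)
        val = base ** (c * (tmax - topt)) * np.exp(c * (t - topt))
    out = np.where(t >= tmax, 0.0, np.clip(val, 0.0, 1.0))
    out = np.where(np.isnan(t), np.nan, out)
    return out if out.ndim else float(out)


def chl_score(chl, params: CHLResponseParams = CHLResponseParams()):
    """Michaelis–Menten food-saturation score in [0, 1)."""
    x = np.asarray(chl, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("chlorophyll concentrations must be non-negative")
    out = x / (x + params.x_k)
    return out if out.ndim else float(out)


def sss_score(sss, params: PolynomialResponseParams = SSS_PARAMS):
    """Standardized salinity score in [0, 1]."""
    out = params.score(sss)
    return out if out.ndim else float(out)


def spm_score(spm, params: PolynomialResponseParams = SPM_PARAMS):
    """Standardized suspended-sediment score in [0, 1]; non-increasing in SPM."""
    x = np.asarray(spm, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("SPM concentrations must be non-negative")
    out = params.score(x)
    return out if out.ndim else float(out)


def mean_factor_score(stack: TimeSeriesStack, scorer) -> RasterLayer:
    """Score every time slice, then average over time (score-then-average).

    Missing slices are excluded per cell; a cell missing at every time step
    yields a missing mean score.
    """
    scored = np.where(np.isnan(stack.values), np.nan, scorer(stack.values))
    valid = np.isfinite(scored)
    n = valid.sum(axis=0)
    total = np.where(valid, scored, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return RasterLayer(stack.grid, mean, variable=f"{stack.variable}_score", units="1")


@dataclass(frozen=True)
class WeightVector:
    names: tuple
    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.names) != len(w):
            raise ValueError("names and weights length mismatch")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "WeightVector":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.weights))


@dataclass
class AHPResult:
    matrix: np.ndarray
    weights: WeightVector
    lambda_max: float
    ci: float
    cr: float
    ri: float
    consistent: bool = field(init=False)

    def __post_init__(self):
        self.consistent = self.cr < 0.1


def consistent_matrix_from_weights(weights) -> np.ndarray:
    """Reciprocal pairwise matrix a_ij = w_i / w_j (perfectly consistent)."""
    w = np.asarray(list(weights.values()) if isinstance(weights, dict) else weights,
                   dtype=float)
    return w[:, None] / w[None, :]


def ahp_weights(pairwise: np.ndarray, names=("SST", "CHL", "SSS", "SPM"),
                tol: float = 1e-12, max_iter: int = 10000) -> AHPResult:
    """Principal-eigenvector weights and Saaty consistency check.

    Weights are the normalized principal eigenvector found by power
    iteration; CI = (λ_max − n)/(n − 1), CR = CI / RI(n).  CR ≥ 0.1 flags
    inconsistent expert judgments.
    """
    a = np.asarray(pairwise, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 2:
        raise ValueError("pairwise matrix must be square with n >= 2")
    n = a.shape[0]
    if (a <= 0).any():
        raise ValueError("pairwise matrix entries must be positive")
    if not np.allclose(a * a.T, 1.0, rtol=1e-6):
        raise ValueError("matrix is not reciprocal (a_ij * a_ji must equal 1)")
    if len(names) != n:
        raise ValueError("factor names length must match matrix order")

    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = a @ w
        w_new /= w_new.sum()
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    lam = float(np.mean((a @ w) / w))
    ci = (lam - n) / (n - 1)
    ri = SAATY_RI.get(n)
    if ri is None:
        raise ValueError(f"no random consistency index tabulated for n={n}")
    cr = 0.0 if ri == 0 else ci / ri
    cr = max(cr, 0.0)
    return AHPResult(a, WeightVector(tuple(names), tuple(w)), lam, max(ci, 0.0), cr, ri)


def weighted_overlay(factor_means: dict, weights: WeightVector) -> RasterLayer:
    """Cellwise SI = Σ wᵢ F̄ᵢ; missing wherever any factor is missing."""
    if set(factor_means) != set(weights.names):
        raise ValueError(
            f"factor names {sorted(factor_means)} do not match weights {sorted(weights.names)}"
        )
    grids = {f.grid for f in factor_means.values()}
    if len(grids) != 1:
        raise GridError("all factor grids must share one GridSpec")
    grid = grids.pop()
    si = np.zeros(grid.shape)
    for name, w in weights.as_dict().items():
        si = si + w * factor_means[name].values
    return RasterLayer(grid, np.clip(si, 0.0, 1.0), variable="SI", units="1")


def classify_si(si: RasterLayer) -> RasterLayer:
    """Five-band classification: [0,0.2) very low … [0.8,1.0] very high.

    Returns a layer of class indices 0–4 (NaN where SI is missing).
    """
    v = si.values
    finite = np.isfinite(v)
    if finite.any() and ((v[finite] < 0) | (v[finite] > 1)).any():
        raise ValueError("SI values must lie in [0, 1]")
    idx = np.digitize(v, SI_CLASS_EDGES[1:-1], right=False).astype(float)
    idx[finite & (v == 1.0)] = 4  # closed last bin
    idx[~finite] = np.nan
    return si.copy_with(idx, variable="SI_class", units="")
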