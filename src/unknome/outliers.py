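"""Robust elliptical outlier detection for quantitative screen phenotypes.

The hit-calling procedure has three steps.  First, a fixed-effects regression
on the replicate-level measurements yields one effect estimate per gene
(1- or 2-dimensional) together with its sampling variance–covariance, while
removing additive batch effects.  Second, the cloud of per-gene estimates is
modelled as a mixture of a normal "bulk" and a contaminating set of outliers:
a robust location and a robust, consistency-corrected scatter of the bulk are
estimated, and a parametric bootstrap then *deflates* the raw robust scatter
by the component due to per-gene sampling noise, since the spread of the
estimates overstates the spread of the true gene effects.  The outlier region
is the complement of the elliptical contour of the fitted normal that a bulk
gene escapes with probability alpha.  Third, each gene is tested with a
parametric bootstrap against the least-favourable null — its true effect
sitting on the boundary point nearest the estimate — which accounts for the
estimate being noisy; p-values are then Benjamini–Hochberg adjusted within
the screen.

Robust estimators are pluggable.  The default scatter is the pairwise
Gnanadesikan–Kettenring estimator built from median/MAD scales (breakdown
50%, consistency-corrected for the normal); the minimum covariance
determinant is available as ``method="mcd"``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .screens import ScreenTable

logger = logging.getLogger("unknome")

_MAD_CONSISTENCY = 1.4826022185056018  # 1 / Phi^{-1}(3/4)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneEffect:
    """A per-gene phenotype estimate with its sampling covariance."""

    gene_id: str
    estimate: np.ndarray  # shape (d,)
    covariance: np.ndarray  # shape (d, d), symmetric PSD
    n_replicates: int = 1
    transform_applied: str = "identity"
    low_replicate: bool = False

    def __post_init__(self) -> None:
        self.estimate = np.atleast_1d(np.asarray(self.estimate, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        d = self.estimate.shape[0]
        if d not in (1, 2):
            raise ValueError("gene effects must be 1- or 2-dimensional")
        if self.covariance.shape != (d, d):
            raise ValueError("covariance shape does not match estimate dimension")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError(f"covariance for {self.gene_id} is not symmetric")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise ValueError(f"covariance for {self.gene_id} is not positive semidefinite")

    @property
    def d(self) -> int:
        return self.estimate.shape[0]


@dataclass
class BulkModel:
    """Fitted normal bulk: robust center, raw robust scatter of the
    estimates, and the deflated scatter estimating the spread of the true
    gene effects (raw minus deflated is PSD by construction)."""

    center: np.ndarray
    raw_scatter: np.ndarray
    deflated_scatter: np.ndarray

    def __post_init__(self) -> None:
        diff = np.linalg.eigvalsh(self.raw_scatter - self.deflated_scatter)
        if diff.min() < -1e-8 * max(1.0, float(np.abs(self.raw_scatter).max())):
            raise ValueError("deflation must never inflate: raw - deflated must be PSD")


@dataclass
class OutlierRegion:
    """Elliptical null region: a point is an outlier candidate iff its
    Mahalanobis distance from the center exceeds the chi-squared radius
    sqrt(chi2_{1-alpha, d})."""

    center: np.ndarray
    scatter: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.scatter = np.atleast_2d(np.asarray(self.scatter, dtype=float))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        try:
            self._chol = np.linalg.cholesky(self.scatter)
        except np.linalg.LinAlgError as exc:
            raise ValueError("outlier region scatter is singular") from exc

    @property
    def d(self) -> int:
        return self.center.shape[0]

    @property
    def radius(self) -> float:
        return math.sqrt(stats.chi2.ppf(1.0 - self.alpha, df=self.d))

    def mahalanobis(self, x: np.ndarray) -> np.ndarray | float:
        """Mahalanobis distance(s) of point(s) ``x`` from the center."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x) - self.center
        y = np.linalg.solve(self._chol, pts.T)  # whiten
        dist = np.sqrt(np.sum(y * y, axis=0))
        return float(dist[0]) if single else dist

    def contains(self, x: np.ndarray) -> bool:
        return bool(self.mahalanobis(x) <= self.radius)


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    p_value: float
    q_value: float
    outlier: bool
    directions: tuple[str, ...]  # per axis: "above" / "below"
    is_control: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.q_value < self.p_value - 1e-12:
            raise ValueError("BH q-value cannot be smaller than the raw p-value")


@dataclass
class ScreenConfig:
    """Analysis settings for one screen.

    ``transforms`` names the variance-stabilising map per axis (identity,
    log, log1p for counts, logit for proportions); ``alpha`` is the
    outside-probability of the elliptical null region (0.05 or 0.1 in
    typical use; larger values are accepted with a warning);
    ``bootstrap_reps`` is used both for scatter deflation and the per-gene
    tests.  The seed is mandatory — there is no hidden global RNG.
    """

    seed: int
    transforms: str | tuple[str, ...] = "identity"
    alpha: float = 0.05
    bootstrap_reps: int = 1000
    bh_level: float = 0.05
    scatter_method: str = "gk"
    control_genes: tuple[str, ...] = ()
    exclude_controls_from_bulk: bool = True

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be at least 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.alpha > 0.1:
            logger.warning(
                "alpha=%.3g exceeds 0.1; the outlier region will be unusually tight",
                self.alpha,
            )
        if self.scatter_method not in ("gk", "mcd"):
            raise ValueError("scatter_method must be 'gk' or 'mcd'")


@dataclass
class ScreenResult:
    results: list[GeneTestResult]
    bulk: BulkModel
    region: OutlierRegion
    effects: list[GeneEffect]
    config: ScreenConfig


# ---------------------------------------------------------------------------
# step 1: batch-corrected per-gene effects
# ---------------------------------------------------------------------------

def fit_gene_effects(table: ScreenTable, config: ScreenConfig) -> list[GeneEffect]:
    """Estimate per-gene effects and their covariances by fixed-effects OLS.

    The design has one indicator per gene plus additive batch offsets (the
    first batch, in sorted order, is the reference, so estimates are on the
    reference-batch scale).  Residual variance is pooled across genes, which
    also serves as the variance floor for genes with a single replicate;
    such genes are flagged ``low_replicate``.
    """
    df = table.data
    genes = sorted(df["gene"].unique())
    batches = sorted(df["batch"].unique())
    if len(batches) > 1:
        for b in batches:
            batch_genes = df.loc[df["batch"] == b, "gene"].unique()
            if len(batch_genes) < 2:
                raise ValueError(
                    f"batch {b!r} contains only gene {batch_genes[0]!r}: "
                    "its batch effect is unidentifiable"
                )

    Y = table.values_matrix()
    n, d = Y.shape
    gene_idx = pd.Categorical(df["gene"], categories=genes).codes
    G = len(genes)
    X = np.zeros((n, G + len(batches) - 1))
    X[np.arange(n), gene_idx] = 1.0
    for k, b in enumerate(batches[1:]):
        X[(df["batch"] == b).to_numpy(), G + k] = 1.0

    p = X.shape[1]
    if n <= p:
        raise ValueError(
            f"cannot estimate residual variance: {n} observations for {p} parameters"
        )
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p:
        raise ValueError("confounded gene/batch design (rank-deficient); batch effects unidentifiable")

    resid = Y - X @ coef
    sigma = resid.T @ resid / (n - p)  # pooled residual covariance, (d, d)
    xtx_inv = np.linalg.inv(X.T @ X)

    counts = df.groupby("gene").size()
    effects = []
    for j, g in enumerate(genes):
        nrep = int(counts[g])
        effects.append(
            GeneEffect(
                gene_id=g,
                estimate=coef[j],
                covariance=sigma * xtx_inv[j, j],
                n_replicates=nrep,
                low_replicate=nrep < 2,
            )
        )
    return effects


# ---------------------------------------------------------------------------
# step 2a: transform to approximate normality
# ---------------------------------------------------------------------------

_TRANSFORMS: dict[str, tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]] = {
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
    "log": (np.log, lambda x: 1.0 / x),
    "log1p": (np.log1p, lambda x: 1.0 / (1.0 + x)),
    "logit": (lambda x: np.log(x / (1.0 - x)), lambda x: 1.0 / (x * (1.0 - x))),
}


def transform_effects(
    effects: Sequence[GeneEffect], transforms: str | Sequence[str]
) -> list[GeneEffect]:
    """Map estimates elementwise and propagate covariance by the delta
    method (first-order: J Sigma J with J the diagonal Jacobian)."""
    if not effects:
        return []
    d = effects[0].d
    names = (transforms,) * d if isinstance(transforms, str) else tuple(transforms)
    if len(names) != d:
        raise ValueError(f"need one transform per axis ({d}), got {len(names)}")
    for nm in names:
        if nm not in _TRANSFORMS:
            raise ValueError(f"unknown transform {nm!r}; choose from {sorted(_TRANSFORMS)}")
    if all(nm == "identity" for nm in names):
        return list(effects)

    out = []
    for eff in effects:
        est = np.empty(d)
        deriv = np.empty(d)
        for a, nm in enumerate(names):
            f, fprime = _TRANSFORMS[nm]
            x = eff.estimate[a]
            if nm == "log" and x <= 0:
                raise ValueError(f"log transform of non-positive estimate for gene {eff.gene_id}")
            if nm == "log1p" and x <= -1:
                raise ValueError(f"log1p transform of estimate <= -1 for gene {eff.gene_id}")
            if nm == "logit" and not 0 < x < 1:
                raise ValueError(f"logit transform of estimate outside (0,1) for gene {eff.gene_id}")
            est[a] = f(np.asarray(x))
            deriv[a] = fprime(np.asarray(x))
        jac = np.diag(deriv)
        out.append(
            replace(
                eff,
                estimate=est,
                covariance=jac @ eff.covariance @ jac,
                transform_applied="+".join(names),
            )
        )
    return out


# ---------------------------------------------------------------------------
# step 2b: robust bulk, bootstrap deflation, region
# ---------------------------------------------------------------------------

def robust_center(estimates: np.ndarray) -> np.ndarray:
    """Robust location of the per-gene estimates (breakdown 50%).

    Starts from the coordinate-wise median, then takes the mean of the
    points inside the 97.5% Mahalanobis contour of an initial robust
    scatter.  The reweighting removes the small bias the plain median
    retains under asymmetric point-mass contamination; for exactly
    symmetric data the result equals the sample mean of the (symmetric)
    retained set."""
    X = np.atleast_2d(np.asarray(estimates, dtype=float))
    if X.shape[1] > 2 and X.shape[0] in (1, 2):
        X = X.T
    if X.shape[0] < 5:
        raise ValueError("robust center needs at least 5 genes")
    center0 = np.median(X, axis=0)
    d = X.shape[1]
    try:
        L0 = np.linalg.cholesky(_regularized(_gk_scatter(X)))
    except (np.linalg.LinAlgError, ValueError):
        return center0
    y = np.linalg.solve(L0, (X - center0).T)
    q = np.sum(y * y, axis=0)
    keep = q <= stats.chi2.ppf(_REWEIGHT_QUANTILE, df=d)
    if keep.sum() < max(d + 2, 5):
        return center0
    # canonicalise summation order so the result is exactly permutation-invariant
    Xk = X[keep]
    return Xk[np.lexsort(Xk.T)].mean(axis=0)


def _mad_scale(x: np.ndarray) -> float:
    return _MAD_CONSISTENCY * float(np.median(np.abs(x - np.median(x))))


def _gk_scatter(X: np.ndarray) -> np.ndarray:
    """Gnanadesikan–Kettenring pairwise scatter from MAD scales:
    var_i = s(x_i)^2, cov_ij = (s(x_i + x_j)^2 - s(x_i - x_j)^2) / 4,
    projected to the PSD cone.  Consistent at the normal."""
    d = X.shape[1]
    S = np.empty((d, d))
    scales = np.array([_mad_scale(X[:, i]) for i in range(d)])
    for i in range(d):
        S[i, i] = scales[i] ** 2
        for j in range(i + 1, d):
            splus = _mad_scale(X[:, i] + X[:, j])
            sminus = _mad_scale(X[:, i] - X[:, j])
            S[i, j] = S[j, i] = (splus**2 - sminus**2) / 4.0
    w, V = np.linalg.eigh(S)
    if w.min() < 0:
        S = (V * np.clip(w, 0.0, None)) @ V.T
    return S


_REWEIGHT_QUANTILE = 0.975


def _regularized(S: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to a tiny positive floor so Cholesky succeeds."""
    w, V = np.linalg.eigh(S)
    floor = 1e-10 * max(float(w.max()), 1e-30)
    if w.min() >= floor:
        return S
    return (V * np.clip(w, floor, None)) @ V.T


def _reweighted_gk_scatter(X: np.ndarray) -> np.ndarray:
    """One-step reweighted GK scatter.

    The raw GK estimate is robust but inefficient and biased upward under
    heavy point-mass contamination; a single chi-squared reweighting step
    (as in the reweighted MCD) discards points beyond the 97.5% Mahalanobis
    contour of the initial fit and rescales the sample covariance of the
    survivors by the normal truncation-consistency factor."""
    J, d = X.shape
    S0 = _gk_scatter(X)
    if np.any(np.diag(S0) <= 0):
        raise ValueError("degenerate configuration: robust scatter is singular")
    center0 = np.median(X, axis=0)
    L0 = np.linalg.cholesky(_regularized(S0))
    y = np.linalg.solve(L0, (X - center0).T)
    q = np.sum(y * y, axis=0)
    cutoff = stats.chi2.ppf(_REWEIGHT_QUANTILE, df=d)
    keep = q <= cutoff
    if keep.sum() >= max(d + 2, 5):
        retained = _REWEIGHT_QUANTILE
    else:
        # initial fit degenerate: fall back to the half sample with the
        # smallest distances (an MCD-style step) and rescale accordingly
        h = max((J + d + 1) // 2, d + 2)
        keep = np.zeros(J, dtype=bool)
        keep[np.argsort(q, kind="stable")[:h]] = True
        retained = h / J
        cutoff = stats.chi2.ppf(retained, df=d)
    consistency = stats.chi2.cdf(cutoff, df=d + 2) / retained
    Xk = X[keep]
    Xk = Xk[np.lexsort(Xk.T)]  # permutation-invariant summation order
    centered = Xk - Xk.mean(axis=0)
    S = centered.T @ centered / (keep.sum() - 1) / consistency
    return (S + S.T) / 2.0


def robust_scatter(
    estimates: np.ndarray,
    center: np.ndarray | None = None,
    method: str = "gk",
    random_state: int = 0,
) -> np.ndarray:
    """Robust, consistency-corrected scatter of the per-gene estimates.

    ``method="gk"`` (default) is the fast median/MAD pairwise estimator
    with one chi-squared reweighting step; ``method="mcd"`` uses the
    minimum covariance determinant (reweighted, consistency-corrected).
    Both tolerate >=25% contamination.  ``center`` is accepted for
    interface symmetry; both estimators use their own internal robust
    location.
    """
    X = np.atleast_2d(np.asarray(estimates, dtype=float))
    if X.ndim == 2 and X.shape[1] not in (1, 2) and X.shape[0] in (1, 2):
        X = X.T
    J, d = X.shape
    if (d == 1 and J < 5) or (d == 2 and J < 10):
        raise ValueError(f"too few genes (J={J}) for a d={d} robust scatter")
    if np.allclose(X, X[0], atol=0):
        raise ValueError("all points identical: scatter is singular")
    if method == "gk":
        S = _reweighted_gk_scatter(X)
        if np.any(np.diag(S) <= 0) or (d > 1 and np.linalg.det(S) <= 0):
            raise ValueError("degenerate configuration: robust scatter is singular")
        return S
    if method == "mcd":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return MinCovDet(random_state=random_state).fit(X).covariance_
    raise ValueError(f"unknown scatter method {method!r}")


def deflate_scatter(
    raw_scatter: np.ndarray,
    per_gene_covariances: Sequence[np.ndarray] | np.ndarray,
    B: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    method: str = "gk",
) -> np.ndarray:
    """Remove per-gene sampling variance from the raw robust scatter.

    Parametric bootstrap: draw synthetic bulks z_j ~ N(0, raw), add noise
    e_j ~ N(0, Sigma_j), recompute the same robust scatter, and subtract the
    average inflation it exhibits relative to raw.  The result is clipped
    into the PSD interval [0, raw] (never inflates, never goes negative); a
    warning is emitted when clipping is active.
    """
    if B < 100:
        raise ValueError("deflation bootstrap needs B >= 100")
    raw = np.atleast_2d(np.asarray(raw_scatter, dtype=float))
    covs = np.asarray(per_gene_covariances, dtype=float)
    if covs.ndim == 2:  # (J,) of scalars for d=1 handed as (J,1)
        covs = covs[:, :, None]
    J, d, _ = covs.shape
    if np.allclose(covs, 0.0):
        return raw.copy()

    rng = np.random.default_rng(seed)
    L_raw = np.linalg.cholesky(raw + 1e-12 * np.eye(d))
    # per-gene noise factors via eigendecomposition (tolerates PSD-singular)
    wj, Vj = np.linalg.eigh(covs)
    Lj = Vj * np.sqrt(np.clip(wj, 0.0, None))[:, None, :]

    boots = np.empty((B, d, d))
    for b in range(B):
        z = rng.standard_normal((J, d)) @ L_raw.T
        e = np.einsum("jde,je->jd", Lj, rng.standard_normal((J, d)))
        boots[b] = robust_scatter(z + e, method=method)
    inflation = boots.mean(axis=0) - raw
    deflated = raw - inflation

    # clip into [0, raw] in the whitened coordinates of raw
    M = np.linalg.solve(L_raw, np.linalg.solve(L_raw, deflated.T).T)
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    w_clipped = np.clip(w, 0.0, 1.0)
    if np.any(w != w_clipped):
        warnings.warn(
            "deflated scatter clipped to the PSD interval [0, raw]", RuntimeWarning
        )
        logger.warning("deflated scatter clipped to the PSD interval [0, raw]")
    out = L_raw @ (V * w_clipped) @ V.T @ L_raw.T
    return (out + out.T) / 2.0


def outlier_region(
    center: np.ndarray, deflated_scatter: np.ndarray, alpha: float
) -> OutlierRegion:
    """Build the elliptical null region with outside-probability ``alpha``.
    For d=1 the boundary reduces to center +/- z_{1-alpha/2} * sd."""
    return OutlierRegion(center=center, scatter=deflated_scatter, alpha=alpha)


# ---------------------------------------------------------------------------
# step 3: per-gene bootstrap test and BH
# ---------------------------------------------------------------------------

def test_outlier(
    effect: GeneEffect,
    region: OutlierRegion,
    B: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> float:
    """Parametric-bootstrap p-value that a gene lies outside the region.

    The null places the true effect at the least-favourable point of the
    null region — the boundary point nearest the estimate along the
    Mahalanobis ray — and simulates estimates around it with the gene's own
    sampling covariance.  p is the tail probability of a Mahalanobis
    distance at least as extreme as observed; estimates inside the region
    get p = 1 exactly.  Conservative by construction.
    """
    if effect.d != region.d:
        raise ValueError("effect and region dimensions differ")
    w, V = np.linalg.eigh(effect.covariance)
    if w.min() < -1e-8 * max(1.0, float(abs(w).max())):
        raise ValueError(f"covariance for {effect.gene_id} is not PSD")
    dist = region.mahalanobis(effect.estimate)
    r = region.radius
    if dist <= r:
        return 1.0
    # nearest boundary point lies on the ray from the center through the estimate
    null_point = region.center + (effect.estimate - region.center) * (r / dist)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    draws = null_point + rng.standard_normal((B, effect.d)) @ L.T
    t = region.mahalanobis(draws)
    return (1.0 + float(np.sum(t >= dist))) / (B + 1.0)


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, >= p, <= 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def run_screen(table: ScreenTable, config: ScreenConfig) -> ScreenResult:
    """Run the full three-step hit-calling pipeline on one screen.

    Deterministic given ``config.seed``; results are sorted by (q-value,
    gene id).  Control genes are tested and reported but excluded from bulk
    estimation when ``exclude_controls_from_bulk`` is set.
    """
    def _stage(name: str, fn, *args):
        try:
            return fn(*args)
        except ValueError as exc:
            raise ValueError(f"[{name}] {exc}") from exc

    effects = _stage("fit_gene_effects", fit_gene_effects, table, config)
    effects = _stage("transform_effects", transform_effects, effects, config.transforms)

    controls = set(config.control_genes)
    bulk_effects = (
        [e for e in effects if e.gene_id not in controls]
        if config.exclude_controls_from_bulk
        else effects
    )
    X = np.array([e.estimate for e in bulk_effects])
    center = _stage("robust_center", robust_center, X)
    raw = _stage("robust_scatter", robust_scatter, X, center, config.scatter_method)

    ss = np.random.SeedSequence(config.seed)
    seed_deflate, seed_tests = ss.spawn(2)
    covs = np.array([e.covariance for e in bulk_effects])
    deflated = _stage(
        "deflate_scatter",
        deflate_scatter, raw, covs, config.bootstrap_reps, seed_deflate, config.scatter_method,
    )
    bulk = BulkModel(center=center, raw_scatter=raw, deflated_scatter=deflated)
    region = _stage("outlier_region", outlier_region, center, deflated, config.alpha)

    ordered = sorted(effects, key=lambda e: e.gene_id)
    gene_seeds = seed_tests.spawn(len(ordered))
    p_values = [
        test_outlier(e, region, B=config.bootstrap_reps, seed=s)
        for e, s in zip(ordered, gene_seeds)
    ]
    q_values = adjust_bh(p_values)

    results = []
    for e, p, q in zip(ordered, p_values, q_values):
        directions = tuple(
            "above" if e.estimate[a] > center[a] else "below" for a in range(e.d)
        )
        results.append(
            GeneTestResult(
                gene_id=e.gene_id,
                p_value=float(p),
                q_value=float(q),
                outlier=bool(q <= config.bh_level),
                directions=directions,
                is_control=e.gene_id in controls,
            )
        )
    results.sort(key=lambda r: (r.q_value, r.gene_id))
    return ScreenResult(results=results, bulk=bulk, region=region, effects=effects, config=config)


def results_to_frame(result: ScreenResult) -> pd.DataFrame:
    """Tabulate per-gene results with estimates, p/q, flags and directions."""
    eff = {e.gene_id: e for e in result.effects}
    rows = []
    for r in result.results:
        e = eff[r.gene_id]
        row = {"gene": r.gene_id}
        for a in range(e.d):
            row[f"estimate_{a + 1}"] = e.estimate[a]
        row.update(
            p_value=r.p_value,
            q_value=r.q_value,
            outlier=r.outlier,
            direction="|".join(r.directions),
            is_control=r.is_control,
            n_replicates=e.n_replicates,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    result: ScreenResult, tsv_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write the per-gene results TSV and a JSON sidecar describing the
    fitted bulk model and outlier region."""
    results_to_frame(result).to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if sidecar_path is not None:
        sidecar = {
            "center": result.bulk.center.tolist(),
            "raw_scatter": result.bulk.raw_scatter.tolist(),
            "deflated_scatter": result.bulk.deflated_scatter.tolist(),
            "alpha": result.region.alpha,
            "radius": result.region.radius,
            "seed": result.config.seed,
            "bootstrap_reps": result.config.bootstrap_reps,
            "bh_level": result.config.bh_level,
            "scatter_method": result.config.scatter_method,
            "transforms": result.config.transforms
            if isinstance(result.config.transforms, str)
            else list(result.config.transforms),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")
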