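"""Marginal CAMP model: a Cox proportional-hazards fit in which one SNP's
log-hazard effect varies linearly with age.

For marker ``j`` the hazard of individual ``i`` is

    lambda_i(t) = lambda_0(t) * exp( x_ij * beta_j(t) + g_ik * xi_j + z_i @ delta_j ),
    beta_j(t)   = beta_j0 + beta_j1 * (t - t0),

with ``x_ij`` the standardized dosage, ``g_ik`` an optional
leave-one-chromosome-out polygenic offset and ``z_i`` optional covariates.
The marker contributes two partial-likelihood covariates, ``x`` and
``x*(t - t0)``; everything (including ``xi`` and ``delta``) is re-estimated
jointly for every marker.  The (beta0, beta1) covariance block comes from
the corresponding 2x2 block of the inverse observed information of the full
parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _cox
from .exceptions import (
    AllMarkersMonomorphic,
    MonomorphicMarker,
    NoEvents,
    NotConverged,
)

DEFAULT_T0 = 49.0
DEFAULT_MAF_THRESHOLD = 0.0002


@dataclass
class SurvivalCohort:
    """Ages at event or censoring plus optional covariates and LOCO offsets.

    Parameters
    ----------
    ids : array of opaque individual identifiers.
    age : positive ages in years (event age if ``event == 1``, censoring
        age otherwise).
    event : 0/1 indicator; 1 means the event was observed.
    covariates : optional (n, c) numeric matrix ``z_i``.
    covariate_names : optional column labels for ``covariates``.
    loco_offset : optional DataFrame of per-chromosome polygenic predictors
        ``g_ik`` (one column per chromosome, e.g. ``"1"``, ``"2"``...).
    """

    ids: np.ndarray
    age: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    loco_offset: pd.DataFrame | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.age = np.asarray(self.age, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        if self.age.ndim != 1 or self.age.shape != self.event.shape:
            raise ValueError("age and event must be 1-D and equally long")
        if np.any(~np.isfinite(self.age)) or np.any(self.age <= 0):
            raise ValueError("all ages must be positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.n:
                raise ValueError("covariate rows do not match cohort size")

    @property
    def n(self) -> int:
        return self.age.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def loco_for(self, chromosome) -> np.ndarray | None:
        """LOCO predictor column for a marker on ``chromosome`` (or None)."""
        if self.loco_offset is None:
            return None
        key = str(chromosome)
        cols = {str(c): c for c in self.loco_offset.columns}
        if key not in cols:
            from .exceptions import UnknownChromosome

            raise UnknownChromosome(f"no LOCO column for chromosome {chromosome!r}")
        return self.loco_offset[cols[key]].to_numpy(dtype=float)

    def subset(self, mask) -> "SurvivalCohort":
        mask = np.asarray(mask)
        return SurvivalCohort(
            ids=self.ids[mask],
            age=self.age[mask],
            event=self.event[mask],
            covariates=None if self.covariates is None else self.covariates[mask],
            covariate_names=self.covariate_names,
            loco_offset=None if self.loco_offset is None else self.loco_offset.iloc[np.flatnonzero(mask)].reset_index(drop=True),
        )


@dataclass
class GenotypePanel:
    """Marker metadata plus a standardized dosage matrix.

    ``dosages`` holds per-marker standardized values (mean 0, SD 1 over the
    sample); ``maf`` is the minor-allele frequency computed from the raw
    allele counts before standardization.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    dosages: np.ndarray
    sample_ids: np.ndarray
    exclusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["marker_id", "reason"]))

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, marker) -> int:
        idx = np.flatnonzero(self.marker_id == marker)
        if idx.size == 0:
            from .exceptions import UnknownMarker

            raise UnknownMarker(str(marker))
        return int(idx[0])

    def column(self, marker) -> np.ndarray:
        return self.dosages[:, self.index_of(marker)]


@dataclass
class CampFit:
    """Estimates from one marginal CAMP fit.

    ``beta0`` is the log hazard ratio at the reference age ``t0``; ``beta1``
    its change per year of age.  ``var0``, ``var1`` and ``cov01`` are the
    (beta0, beta1) entries of the inverse observed information.
    """

    beta0: float
    beta1: float
    t0: float
    var0: float
    var1: float
    cov01: float
    xi: float | None = None
    delta: np.ndarray | None = None
    log_partial_likelihood: float = float("nan")
    n_events: int = 0
    converged: bool = True
    iterations: int = 0
    monotone_likelihood: bool = False


def standardize_genotypes(
    raw_dosages,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    *,
    marker_id=None,
    chromosome=None,
    position=None,
    effect_allele=None,
    other_allele=None,
    sample_ids=None,
) -> GenotypePanel:
    """Standardize raw allele counts (0/1/2, NaN = missing) into a panel.

    Missing entries are replaced by the marker's observed mean before
    centering and scaling; markers with MAF at or below ``maf_threshold`` or
    with zero variance are dropped and listed in ``panel.exclusions``.

    Raises
    ------
    AllMarkersMonomorphic
        If no marker survives the filters.
    """
    raw = np.array(raw_dosages, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw_dosages must be a 2-D (n individuals x m markers) array")
    n, m = raw.shape

    def _default(arr, maker):
        return np.asarray(arr) if arr is not None else maker()

    marker_id = _default(marker_id, lambda: np.array([f"snp{j + 1}" for j in range(m)]))
    chromosome = _default(chromosome, lambda: np.array(["1"] * m))
    position = _default(position, lambda: np.arange(1, m + 1))
    effect_allele = _default(effect_allele, lambda: np.array(["A"] * m))
    other_allele = _default(other_allele, lambda: np.array(["B"] * m))
    sample_ids = _default(sample_ids, lambda: np.array([f"id{i + 1}" for i in range(n)]))

    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(raw, axis=0)
    filled = np.where(np.isnan(raw), col_mean[None, :], raw)
    freq = col_mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    sd = filled.std(axis=0)

    keep = (sd > 0) & (maf > maf_threshold)
    reasons = np.where(sd <= 0, "zero_variance", np.where(maf <= maf_threshold, "maf_below_threshold", ""))
    excl = pd.DataFrame({"marker_id": marker_id[~keep], "reason": reasons[~keep]})
    if not keep.any():
        raise AllMarkersMonomorphic("no marker passed the variance/MAF filters")

    std = (filled[:, keep] - col_mean[keep][None, :]) / sd[keep][None, :]
    return GenotypePanel(
        marker_id=marker_id[keep],
        chromosome=chromosome[keep],
        position=np.asarray(position)[keep],
        effect_allele=effect_allele[keep],
        other_allele=other_allele[keep],
        maf=maf[keep],
        dosages=std,
        sample_ids=sample_ids,
        exclusions=excl,
    )


def fit_camp_snp(
    cohort: SurvivalCohort,
    x,
    t0: float = DEFAULT_T0,
    ties_method: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    *,
    loco=None,
    fit_slope: bool = True,
) -> CampFit:
    """Fit the marginal CAMP model for one marker.

    Parameters
    ----------
    cohort : the survival data; its covariates enter with coefficients
        ``delta``.
    x : standardized dosage vector for the tested marker.
    t0 : reference age in years at which ``beta0`` is interpreted.
    ties_method : "efron" (default) or "breslow".
    loco : optional per-individual polygenic offset ``g_ik`` with coefficient
        ``xi``; if omitted and the cohort carries a single LOCO column, that
        column is used.
    fit_slope : set False to constrain ``beta1 = 0`` (a plain Cox fit of the
        marker; ``var1`` and ``cov01`` are then NaN).

    Notes
    -----
    Newton-Raphson with analytic gradient and Hessian; step-halving keeps
    the log partial likelihood non-decreasing, and a divergence bound of
    ``|beta| > 50`` flags monotone likelihoods (complete separation) instead
    of silently reporting a huge estimate.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != cohort.age.shape:
        raise ValueError("dosage vector length does not match the cohort")
    if cohort.n_events < 1:
        raise NoEvents("at least one observed event is required")
    if np.ptp(x) == 0:
        raise MonomorphicMarker("tested marker is constant")
    if ties_method not in ("efron", "breslow"):
        raise ValueError("ties_method must be 'efron' or 'breslow'")

    if loco is None and cohort.loco_offset is not None and cohort.loco_offset.shape[1] == 1:
        loco = cohort.loco_offset.iloc[:, 0].to_numpy(dtype=float)
    cols = [x]
    if loco is not None:
        cols.append(np.asarray(loco, dtype=float))
    if cohort.covariates is not None and cohort.covariates.shape[1] > 0:
        cols.extend(cohort.covariates.T)
    statics = np.column_stack(cols)

    data = _cox.prepare(cohort.age, cohort.event, statics, t0,
                        include_tv=fit_slope, ties=ties_method)
    theta, ll, H, converged, iters, monotone = _cox.newton_maximize(
        data, tol=tol, max_iter=max_iter
    )

    cov = _safe_inverse(-H)
    nxt = 2 if fit_slope else 1
    xi = None
    if loco is not None:
        xi = float(theta[nxt])
        nxt += 1
    delta = theta[nxt:].copy() if theta.size > nxt else None

    return CampFit(
        beta0=float(theta[0]),
        beta1=float(theta[1]) if fit_slope else 0.0,
        t0=float(t0),
        var0=float(cov[0, 0]),
        var1=float(cov[1, 1]) if fit_slope else float("nan"),
        cov01=float(cov[0, 1]) if fit_slope else float("nan"),
        xi=xi,
        delta=delta,
        log_partial_likelihood=float(ll),
        n_events=cohort.n_events,
        converged=converged,
        iterations=iters,
        monotone_likelihood=monotone,
    )


def _safe_inverse(info):
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


@dataclass
class SurvivalCurve:
    """Right-continuous step estimate of S(t); starts at 1 before the first
    event age."""

    ages: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.ages, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def survival_curve(fit: CampFit, cohort: SurvivalCohort, x, x_value: float = 0.0,
                   *, loco=None) -> SurvivalCurve:
    """Model-based survival curve for an individual with dosage ``x_value``.

    The Breslow cumulative baseline hazard is accumulated at the event ages
    with the age-varying linear predictor evaluated at each event age;
    covariates and the polygenic offset are taken at zero (the standardized
    reference).
    """
    if not fit.converged:
        raise NotConverged("survival_curve requires a converged fit")
    x = np.asarray(x, dtype=float)

    cols = [x]
    theta = [fit.beta0, fit.beta1]
    if loco is not None:
        cols.append(np.asarray(loco, dtype=float))
        theta.append(fit.xi if fit.xi is not None else 0.0)
    if cohort.covariates is not None and cohort.covariates.shape[1] > 0:
        cols.extend(cohort.covariates.T)
        theta.extend(np.atleast_1d(fit.delta) if fit.delta is not None else np.zeros(cohort.covariates.shape[1]))
    statics = np.column_stack(cols)
    data = _cox.prepare(cohort.age, cohort.event, statics, fit.t0,
                        include_tv=True, ties="breslow")
    ut, dlam0 = _cox.breslow_baseline(np.asarray(theta, dtype=float), data)

    beta_t = fit.beta0 + fit.beta1 * (ut - fit.t0)
    lam = dlam0 * np.exp(x_value * beta_t)
    surv = np.exp(-np.cumsum(lam))
    return SurvivalCurve(ages=ut, survival=surv)
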