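"""Synthetic biobank-like cohorts with known age-varying SNP effects.

Events are drawn from the generative hazard

    lambda_i(t) = lambda_0(t) * exp( sum_j x_ij * (beta_j0 + beta_j1*(t - t0)) )

with a shifted-Weibull baseline lambda_0(t) = (k/b) * ((t - shift)/b)^(k-1).
The default baseline (k = 12, b = 52 years) is steep, concentrating event
ages in the late forties and fifties — the profile of age at natural
menopause, where about nine in ten events fall between 45 and 55.  An
independent assessment age drawn uniformly from ``censor_age_range``
right-censors each individual, mimicking interview-age censoring, and the
standard phenotype window [33, 65] is applied afterwards.

The exponent of the hazard is linear in t, so the cumulative hazard is
integrated piecewise with Simpson's rule on 0.1-year panels and inverted by
bisection to 1e-8 years.  Individuals sharing the same causal-genotype
profile share the same cumulative hazard, which the implementation exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypePanel, SurvivalCohort, standardize_genotypes
from .exceptions import NonFiniteHazard

_PANEL_YEARS = 0.1     # quadrature panel width
_HORIZON = 90.0        # years of hazard integrated past the shift
_ROOT_TOL = 1e-8       # years; bisection tolerance of the inversion
_MANY_PROFILES = 256   # switch point between profile-grouped and chunked inversion


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``causal_effects`` lists (marker index, beta0, beta1) on the log-hazard
    scale, with beta0 the effect at the reference age ``t0``.
    """

    n: int = 1000
    m: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    mafs: list[float] | None = None           # explicit per-marker MAFs
    causal_effects: list[tuple[int, float, float]] = field(default_factory=list)
    t0: float = 49.0
    baseline_shape: float = 12.0              # Weibull k
    baseline_scale: float = 52.0              # Weibull b, years
    age_shift: float = 0.0
    censor_age_range: tuple[float, float] = (40.0, 70.0)
    analysis_window: tuple[float, float] = (33.0, 65.0)
    n_chromosomes: int = 2
    position_spacing: int = 100_000
    maf_threshold: float = 0.0002
    seed: int = 0

    def __post_init__(self):
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        mafs = self.mafs if self.mafs is not None else self.maf_range
        if not all(0 < f <= 0.5 for f in np.atleast_1d(mafs)):
            raise ValueError("MAFs must lie in (0, 0.5]")


def simulate_raw_genotypes(config: SimulationConfig, rng=None):
    """Independent biallelic allele counts ~ Binomial(2, maf).

    Returns (raw n x m matrix, metadata dict with marker_id / chromosome /
    position / sample_ids).  Markers are laid out in contiguous blocks over
    ``n_chromosomes`` chromosomes at ``position_spacing`` bp intervals.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.mafs is not None:
        maf = np.asarray(config.mafs, dtype=float)
        if maf.size != config.m:
            raise ValueError("len(mafs) must equal m")
    else:
        maf = rng.uniform(*config.maf_range, size=config.m)
    raw = rng.binomial(2, maf[None, :], size=(config.n, config.m)).astype(float)

    per_chrom = -(-config.m // config.n_chromosomes)  # ceil
    meta = {
        "marker_id": np.array([f"snp{j + 1}" for j in range(config.m)]),
        "chromosome": np.array([str(1 + j // per_chrom) for j in range(config.m)]),
        "position": np.array([(j % per_chrom + 1) * config.position_spacing
                              for j in range(config.m)]),
        "sample_ids": np.array([f"id{i + 1}" for i in range(config.n)]),
    }
    return raw, meta


def simulate_genotypes(config: SimulationConfig, rng=None) -> GenotypePanel:
    """Standardized panel of independent biallelic dosages."""
    raw, meta = simulate_raw_genotypes(config, rng=rng)
    return standardize_genotypes(raw, maf_threshold=config.maf_threshold, **meta)


def _linear_exponent(panel: GenotypePanel, config: SimulationConfig):
    """Per-individual (A, B) with log hazard ratio A + B*s at age s."""
    A = np.zeros(panel.n)
    B = np.zeros(panel.n)
    for idx, b0, b1 in config.causal_effects:
        x = panel.dosages[:, idx]
        A += x * (b0 - b1 * config.t0)
        B += x * b1
    return A, B


def _panel_integrals(A, B, edges, mids, config):
    """Simpson integrals of lambda0(s)*exp(A + B s) per 0.1-year panel.

    A, B may be scalars or column vectors; returns an array of per-panel
    integrals with the leading shape of A.
    """
    k, b, shift = config.baseline_shape, config.baseline_scale, config.age_shift

    def lam0(s):
        u = np.maximum(s - shift, 0.0) / b
        return (k / b) * u ** (k - 1.0)

    def f(s):
        return lam0(s) * np.exp(A + B * s)

    h = np.diff(edges)
    with np.errstate(over="ignore", invalid="ignore"):
        vals = (f(edges[:-1]) + 4.0 * f(mids) + f(edges[1:])) * (h / 6.0)
    return vals


def simulate_times(panel: GenotypePanel, config: SimulationConfig, rng=None,
                   apply_qc: bool = True) -> SurvivalCohort:
    """Draw event/censoring ages from the generative age-varying hazard.

    For each individual, U ~ Uniform(0,1) and the event age solves
    Lambda_i(T) = -ln U.  Individuals whose cumulative hazard never reaches
    the target within the integration horizon are censored at assessment.
    With ``apply_qc`` (default) the standard phenotype window is applied:
    event ages outside it are dropped, late censoring ages truncated.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = panel.n
    A, B = _linear_exponent(panel, config)

    shift = config.age_shift
    edges = shift + np.arange(0.0, _HORIZON + _PANEL_YEARS, _PANEL_YEARS)
    mids = 0.5 * (edges[:-1] + edges[1:])

    prof, inverse = np.unique(np.column_stack([A, B]), axis=0, return_inverse=True)
    target = -np.log(rng.uniform(size=n))
    T = np.full(n, np.inf)

    if prof.shape[0] <= _MANY_PROFILES:
        cum_by_profile = {}
        for u in range(prof.shape[0]):
            Au, Bu = prof[u]
            vals = _panel_integrals(Au, Bu, edges, mids, config)
            if not np.all(np.isfinite(vals)):
                raise NonFiniteHazard("cumulative hazard overflowed")
            cum_by_profile[u] = np.concatenate([[0.0], np.cumsum(vals)])
        for u in range(prof.shape[0]):
            rows = np.flatnonzero(inverse == u)
            cum = cum_by_profile[u]
            T[rows] = _invert(cum, target[rows], prof[u, 0], prof[u, 1],
                              edges, config)
    else:
        chunk = 2048
        for i0 in range(0, n, chunk):
            i1 = min(i0 + chunk, n)
            Ac, Bc = A[i0:i1, None], B[i0:i1, None]
            vals = _panel_integrals(Ac, Bc, edges, mids, config)
            if not np.all(np.isfinite(vals)):
                raise NonFiniteHazard("cumulative hazard overflowed")
            cum = np.concatenate([np.zeros((i1 - i0, 1)), np.cumsum(vals, axis=1)], axis=1)
            T[i0:i1] = _invert_rows(cum, target[i0:i1], A[i0:i1], B[i0:i1],
                                    edges, config)

    assess = rng.uniform(*config.censor_age_range, size=n)
    event = T <= assess
    age = np.where(event, T, assess)

    cohort = SurvivalCohort(ids=panel.sample_ids.copy(), age=age,
                            event=event.astype(np.int8))
    if apply_qc:
        from .io import apply_phenotype_qc

        cohort, _ = apply_phenotype_qc(cohort, window=config.analysis_window)
    return cohort


def _bisect(lo, hi, c_lo, want, Afun, Bfun, config):
    """Vectorized bisection for Lambda(t) = want inside one panel."""
    for _ in range(max(1, int(np.ceil(np.log2(_PANEL_YEARS / _ROOT_TOL))))):
        mid = 0.5 * (lo + hi)
        m2 = 0.5 * (lo + mid)
        part = _simpson_sub(lo, mid, m2, Afun, Bfun, config)
        left = c_lo + part
        go_right = left < want
        lo = np.where(go_right, mid, lo)
        c_lo = np.where(go_right, left, c_lo)
        hi = np.where(go_right, hi, mid)
    return 0.5 * (lo + hi)


def _simpson_sub(a, b_, mid, A, B, config):
    k, bb, shift = config.baseline_shape, config.baseline_scale, config.age_shift

    def f(s):
        u = np.maximum(s - shift, 0.0) / bb
        return (k / bb) * u ** (k - 1.0) * np.exp(A + B * s)

    return (f(a) + 4.0 * f(mid) + f(b_)) * ((b_ - a) / 6.0)


def _invert(cum, targets, Au, Bu, edges, config):
    """Invert one shared cumulative-hazard grid for several individuals."""
    out = np.full(targets.size, np.inf)
    reach = targets <= cum[-1]
    if not reach.any():
        return out
    t = targets[reach]
    idx = np.searchsorted(cum, t, side="left")
    lo, hi = edges[idx - 1], edges[idx]
    out[reach] = _bisect(lo, hi, cum[idx - 1], t,
                         Au, Bu, config)
    return out


def _invert_rows(cum, targets, A, B, edges, config):
    """Row-wise inversion when each individual has its own grid."""
    out = np.full(targets.size, np.inf)
    reach = targets <= cum[:, -1]
    if not reach.any():
        return out
    rows = np.flatnonzero(reach)
    t = targets[rows]
    idx = (cum[rows] < t[:, None]).sum(axis=1)
    lo, hi = edges[idx - 1], edges[idx]
    c_lo = cum[rows, idx - 1]
    out[rows] = _bisect(lo, hi, c_lo, t, A[rows], B[rows], config)
    return out


#: parameters of the deterministic fixture cohort used across the test suite
D1_CONFIG = SimulationConfig(
    n=200,
    m=10,
    maf_range=(0.1, 0.5),
    causal_effects=[(0, 0.3, -0.02)],
    seed=20230804,
)


def fixture_d1() -> tuple[GenotypePanel, SurvivalCohort]:
    """Deterministic small cohort (n=200, m=10, one causal SNP with
    beta0 = 0.3, beta1 = -0.02 at t0 = 49, seed 20230804)."""
    panel = simulate_genotypes(D1_CONFIG)
    cohort = simulate_times(panel, D1_CONFIG)
    # QC can drop individuals; keep genotype rows aligned with the cohort
    # and re-standardize on the analysis sample (standardization is affine-
    # equivariant, so this equals standardizing the raw subset)
    keep = np.isin(panel.sample_ids, cohort.ids)
    d = panel.dosages[keep]
    panel.dosages = (d - d.mean(axis=0)) / d.std(axis=0)
    panel.sample_ids = panel.sample_ids[keep]
    return panel, cohort
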