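"""Tabular I/O and phenotype QC.

Phenotype tables are TSVs with a header containing ``id``, ``age`` and
``event``; any column named ``chr*`` is treated as a per-chromosome LOCO
predictor and every remaining column as a numeric covariate.  Summary
statistics round-trip losslessly at double precision, with p-values carried
both as floats and as log10 values so genome-wide magnitudes survive
serialization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SurvivalCohort
from .exceptions import IOFailure, MissingColumn, NonNumericAge

DEFAULT_WINDOW = (33.0, 65.0)


def read_phenotypes(path) -> SurvivalCohort:
    """Read a phenotype TSV into a (pre-QC) cohort."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    for col in ("id", "age", "event"):
        if col not in df.columns:
            raise MissingColumn(f"phenotype table lacks required column {col!r}")
    age = pd.to_numeric(df["age"], errors="coerce")
    if age.isna().any():
        raise NonNumericAge("age column contains non-numeric entries")
    event = pd.to_numeric(df["event"], errors="coerce")
    if event.isna().any() or not event.isin((0, 1)).all():
        raise ValueError("event column must contain only 0 and 1")

    loco_cols = [c for c in df.columns if c.lower().startswith("chr")]
    cov_cols = [c for c in df.columns if c not in ("id", "age", "event") and c not in loco_cols]
    loco = None
    if loco_cols:
        loco = df[loco_cols].astype(float)
        loco.columns = [c[3:] for c in loco_cols]
    covs = df[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return SurvivalCohort(
        ids=df["id"].to_numpy(),
        age=age.to_numpy(dtype=float),
        event=event.to_numpy(dtype=np.int8),
        covariates=covs,
        covariate_names=cov_cols or None,
        loco_offset=loco,
    )


def write_phenotypes(cohort: SurvivalCohort, path) -> None:
    df = pd.DataFrame({"id": cohort.ids, "age": cohort.age, "event": cohort.event})
    if cohort.covariates is not None:
        names = cohort.covariate_names or [f"cov{i + 1}" for i in range(cohort.covariates.shape[1])]
        for i, name in enumerate(names):
            df[name] = cohort.covariates[:, i]
    if cohort.loco_offset is not None:
        for c in cohort.loco_offset.columns:
            df[f"chr{c}"] = cohort.loco_offset[c].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def apply_phenotype_qc(cohort: SurvivalCohort, window=DEFAULT_WINDOW):
    """Apply the analysis age window.

    Individuals whose *event* age falls outside ``window`` are excluded;
    censored individuals are always retained, with censoring ages above the
    upper bound truncated to it (they still contribute risk time inside the
    modeled range).  Returns (filtered cohort, exclusion-count report).
    """
    lo, hi = float(window[0]), float(window[1])
    is_event = cohort.event == 1
    early = is_event & (cohort.age < lo)
    late = is_event & (cohort.age > hi)
    keep = ~(early | late)

    out = cohort.subset(keep)
    cens = out.event == 0
    n_trunc = int((cens & (out.age > hi)).sum())
    out.age = np.where(cens, np.minimum(out.age, hi), out.age)
    report = {
        "event_before_window": int(early.sum()),
        "event_after_window": int(late.sum()),
        "censoring_truncated": n_trunc,
        "retained": int(keep.sum()),
    }
    return out, report


def read_loco_tsv(path) -> pd.DataFrame:
    """Read an externally computed LOCO predictor table
    (columns: individual_id, chr1..chrK)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str}, float_precision="round_trip")
    if "individual_id" not in df.columns:
        raise MissingColumn("LOCO table lacks an individual_id column")
    chr_cols = [c for c in df.columns if c.lower().startswith("chr")]
    if not chr_cols:
        raise MissingColumn("LOCO table has no chr* predictor columns")
    out = df.set_index("individual_id")[chr_cols].astype(float)
    out.columns = [c[3:] for c in chr_cols]
    return out


def write_loco_tsv(loco: pd.DataFrame, path) -> None:
    out = loco.copy()
    out.columns = [f"chr{c}" for c in out.columns]
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# --- summary statistics ---------------------------------------------------

_FIXED_COLUMNS = [
    "marker_id", "chromosome", "position", "effect_allele", "other_allele",
    "maf", "beta0", "beta1", "var0", "var1", "cov01", "t0", "t2_star",
    "chi2_max_window", "p_max_window", "log10_p_max_window",
    "chi2_slope", "p_slope", "log10_p_slope", "converged", "monotone_likelihood",
]


def write_sumstats(records: pd.DataFrame, path) -> None:
    """Write per-marker summary statistics, sorted by (chromosome, position).

    Floats are written at full double precision so that read_sumstats
    round-trips losslessly; p-value columns use scientific notation.
    """
    df = records.copy()
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise IOFailure(f"summary statistics lack columns {missing}")
    df = df.sort_values(["chromosome", "position"], kind="stable")
    float_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
    for c in float_cols:
        if c.startswith("p_") or c.startswith("p"):
            df[c] = df[c].map(lambda v: f"{v:.17e}")
        else:
            df[c] = df[c].map(lambda v: f"{v:.17g}")
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:  # pragma: no cover
        raise IOFailure(str(exc)) from exc


def read_sumstats(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str},
                         float_precision="round_trip")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    for col in ("marker_id", "beta0", "beta1"):
        if col not in df.columns:
            raise MissingColumn(f"summary statistics lack column {col!r}")
    return df


def intersect_cohort_panel(cohort: SurvivalCohort, panel):
    """Restrict a cohort and panel to their shared individuals, preserving
    cohort order; returns (cohort, panel, n_dropped_cohort, n_dropped_panel).

    Dosage columns are re-standardized on the retained individuals
    (standardization is affine-equivariant, so this equals standardizing
    the raw subset)."""
    panel_pos = {sid: i for i, sid in enumerate(panel.sample_ids)}
    keep_mask = np.array([sid in panel_pos for sid in cohort.ids])
    sub = cohort.subset(keep_mask)
    rows = np.array([panel_pos[sid] for sid in sub.ids], dtype=np.intp)
    import copy

    new_panel = copy.copy(panel)
    d = panel.dosages[rows]
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic-in-subset columns are caught at fit time
    new_panel.dosages = (d - d.mean(axis=0)) / sd
    new_panel.sample_ids = panel.sample_ids[rows]
    return sub, new_panel, int((~keep_mask).sum()), panel.n - rows.size
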