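"""Per-marker CAMP association scan: fit + all three age tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import agetest
from .core import DEFAULT_T0, GenotypePanel, SurvivalCohort, fit_camp_snp
from .exceptions import DegenerateFit


def scan_markers(
    cohort: SurvivalCohort,
    panel: GenotypePanel,
    t0: float = DEFAULT_T0,
    grid_ages=agetest.GRID_AGES,
    window=agetest.DEFAULT_WINDOW,
    ties_method: str = "efron",
    markers=None,
) -> pd.DataFrame:
    """Fit every marker marginally and evaluate the three significance tests.

    Marker fits are mutually independent, so results do not depend on the
    order or partitioning of markers.  Returns one summary-statistics row
    per marker (see io.write_sumstats for the column contract).
    """
    idx = range(panel.m) if markers is None else [panel.index_of(m) for m in markers]
    rows = []
    for j in idx:
        x = panel.dosages[:, j]
        loco = None
        if cohort.loco_offset is not None:
            loco = cohort.loco_for(panel.chromosome[j])
        fit = fit_camp_snp(cohort, x, t0=t0, ties_method=ties_method, loco=loco)
        mid = str(panel.marker_id[j])

        try:
            ext = agetest.extreme_times(fit)
            t2 = ext.t2
        except DegenerateFit:
            t2 = math.nan
        maxres = agetest.max_evidence_test(fit, window=window, marker_id=mid)
        slres = agetest.slope_test(fit, marker_id=mid)

        row = {
            "marker_id": mid,
            "chromosome": str(panel.chromosome[j]),
            "position": int(panel.position[j]),
            "effect_allele": str(panel.effect_allele[j]),
            "other_allele": str(panel.other_allele[j]),
            "maf": float(panel.maf[j]),
            "beta0": fit.beta0,
            "beta1": fit.beta1,
            "var0": fit.var0,
            "var1": fit.var1,
            "cov01": fit.cov01,
            "t0": fit.t0,
            "t2_star": t2,
            "chi2_max_window": maxres.chi2,
            "p_max_window": maxres.p_value,
            "log10_p_max_window": maxres.log10_p,
            "chi2_slope": slres.chi2,
            "p_slope": slres.p_value,
            "log10_p_slope": slres.log10_p,
            "converged": bool(fit.converged),
            "monotone_likelihood": bool(fit.monotone_likelihood),
        }
        for res in agetest.grid_test(fit, ages=grid_ages, marker_id=mid):
            label = f"{res.age_evaluated:g}"
            row[f"chi2_age_{label}"] = res.chi2
            row[f"p_age_{label}"] = res.p_value
            row[f"log10_p_age_{label}"] = res.log10_p
        rows.append(row)
    return pd.DataFrame(rows)


def classify_scan(discovery: pd.DataFrame, replication: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach slope-evidence classes to a discovery scan, optionally using a
    replication scan (matched on marker_id) for the strong tier."""
    out = discovery.copy()
    rep_p = {}
    rep_sign = {}
    if replication is not None:
        rep = replication.set_index("marker_id")
        rep_p = rep["p_slope"].to_dict()
        rep_sign = np.sign(rep["beta1"]).to_dict()
    classes = []
    for _, row in out.iterrows():
        mid = row["marker_id"]
        rp = rep_p.get(mid)
        concord = (
            rp is not None
            and np.sign(row["beta1"]) == rep_sign.get(mid)
            and np.sign(row["beta1"]) != 0
        )
        # guard against p underflow far beyond genome-wide magnitudes
        p = row["p_slope"] if row["p_slope"] > 0 else 1e-300
        classes.append(agetest.classify_evidence(
            p, replication_slope_p=rp, sign_concordant=bool(concord),
        ))
    out["evidence_class"] = classes
    return out
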