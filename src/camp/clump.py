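"""Greedy p-value-ordered LD clumping of per-marker results.

Defaults follow standard GWAS post-processing of this kind of scan: a
symmetric 1 Mb window around the index SNP, LD threshold r^2 = 0.05, index
p-value threshold 5e-8 and no p-value threshold for the other members of a
clump.  LD is always the squared Pearson correlation of the provided
standardized dosages (no external reference panel), and clumping never
crosses chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypePanel

GENOME_WIDE_P = 5e-8


@dataclass
class Clump:
    """One locus: an index marker plus the correlated markers assigned to it."""

    index_marker: str
    index_p: float
    chromosome: str
    span: tuple[int, int]                  # 1-based bp interval covered
    member_markers: list[str] = field(default_factory=list)  # excludes the index

    @property
    def size(self) -> int:
        return 1 + len(self.member_markers)


def ld_r2(panel: GenotypePanel, marker_a, marker_b) -> float:
    """Squared Pearson correlation of two markers' standardized dosages."""
    a = panel.column(marker_a)
    b = panel.column(marker_b)
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def greedy_clump(
    results: pd.DataFrame,
    panel: GenotypePanel,
    window_kb: float = 1000.0,
    r2_index: float = 0.05,
    p_index: float = GENOME_WIDE_P,
    p_member: float = 1.0,
) -> list[Clump]:
    """Group markers into independent loci, most significant first.

    ``results`` needs columns ``marker_id`` and ``p``.  Markers are visited
    by ascending p (ties broken by chromosome then position); each unassigned
    marker with p < ``p_index`` seeds a clump and absorbs every unassigned
    marker on the same chromosome within ``window_kb`` of it whose r^2 with
    the index is at least ``r2_index`` and whose p is at most ``p_member``.
    Every marker belongs to at most one clump; an empty list is returned if
    no index passes.
    """
    res = results[["marker_id", "p"]].copy()
    meta = pd.DataFrame({
        "marker_id": panel.marker_id,
        "chromosome": [str(c) for c in panel.chromosome],
        "position": panel.position,
        "col": np.arange(panel.m),
    })
    res = res.merge(meta, on="marker_id", how="inner")
    res = res.sort_values(["p", "chromosome", "position"], kind="stable").reset_index(drop=True)

    assigned = np.zeros(len(res), dtype=bool)
    pos = res["position"].to_numpy()
    chrom = res["chromosome"].to_numpy()
    pvals = res["p"].to_numpy()
    cols = res["col"].to_numpy()
    window_bp = window_kb * 1000.0

    X = panel.dosages
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc ** 2).sum(axis=0))

    clumps: list[Clump] = []
    for i in range(len(res)):
        if assigned[i] or not pvals[i] < p_index:
            continue
        assigned[i] = True
        cand = np.flatnonzero(
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
            & (pvals <= p_member)
        )
        members: list[str] = []
        span_lo = span_hi = int(pos[i])
        if cand.size:
            xi = Xc[:, cols[i]]
            r = (Xc[:, cols[cand]].T @ xi) / (norms[cols[cand]] * norms[cols[i]])
            hit = cand[r ** 2 >= r2_index]
            assigned[hit] = True
            members = [str(mid) for mid in res.loc[hit, "marker_id"]]
            if hit.size:
                span_lo = int(min(span_lo, pos[hit].min()))
                span_hi = int(max(span_hi, pos[hit].max()))
        clumps.append(Clump(
            index_marker=str(res.loc[i, "marker_id"]),
            index_p=float(pvals[i]),
            chromosome=str(chrom[i]),
            span=(span_lo, span_hi),
            member_markers=members,
        ))
    return clumps


def clump_table(clumps: list[Clump]) -> pd.DataFrame:
    """Flat report mirroring the essentials of a plink clumped report:
    SNP, CHR, BP interval, P, TOTAL members, SP2-style member list."""
    rows = []
    for cl in clumps:
        rows.append({
            "SNP": cl.index_marker,
            "CHR": cl.chromosome,
            "BP_START": cl.span[0],
            "BP_END": cl.span[1],
            "P": cl.index_p,
            "TOTAL": cl.size - 1,
            "SP2": ",".join(cl.member_markers) if cl.member_markers else "NONE",
        })
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP_START", "BP_END", "P", "TOTAL", "SP2"])
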