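"""Derived deleterious-allele accounting per individual and per group.

Deleterious status comes from externally supplied per-site scores (an amino
acid substitution is deleterious iff its score is <= 0.05, tolerated above);
counting requires polarization, since the unit is the DERIVED deleterious
allele: per individual, total = heterozygous sites + 2 x homozygous-derived
sites. Sites with unknown ancestral allele are excluded and reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vcfio import (GenotypeMatrix, PopulationMap, ANC_UNKNOWN,
                    ANN_DELETERIOUS)

SCORE_THRESHOLD = 0.05


def classify_sites(annotations: pd.DataFrame) -> pd.DataFrame:
    """Classify annotation rows as deleterious/tolerated.

    ``annotations`` has columns (chrom, pos, score) where score is numeric
    in [0, 1] or an explicit deleterious/tolerated label (passed through).
    Score <= 0.05 means deleterious, > 0.05 tolerated.
    """
    out = annotations.copy()
    score = out["score"]
    if score.dtype == object:
        numeric = pd.to_numeric(score, errors="coerce")
    else:
        numeric = score.astype(float)
    cls = np.empty(len(out), dtype=object)
    is_num = numeric.notna().to_numpy()
    vals = numeric.to_numpy(float)
    if np.any(is_num & ((vals < 0) | (vals > 1))):
        raise ValueError("annotation scores must lie in [0, 1]")
    cls[is_num] = np.where(vals[is_num] <= SCORE_THRESHOLD,
                           "deleterious", "tolerated")
    labels = score.astype(str).str.lower()
    lab_ok = labels.isin(["deleterious", "tolerated"]).to_numpy()
    cls[~is_num & lab_ok] = labels[~is_num & lab_ok]
    if np.any(~is_num & ~lab_ok):
        bad = out.loc[~is_num & ~lab_ok, "score"].iloc[0]
        raise ValueError(f"unrecognized annotation value: {bad!r}")
    out["cls"] = cls
    return out


def count_load(gm: GenotypeMatrix, pm: PopulationMap | None = None) -> pd.DataFrame:
    """Per-sample derived deleterious-allele counts.

    Over deleterious-annotated sites with known ancestral allele:
    n_het_del = heterozygous sites, n_hom_del = homozygous-derived sites,
    n_del_total = n_het_del + 2*n_hom_del. The number of deleterious sites
    dropped for unknown polarization is reported once per sample.
    """
    del_mask = gm.annotation == ANN_DELETERIOUS
    if not del_mask.any():
        raise ValueError("no deleterious-annotated sites in matrix")
    known = gm.anc != ANC_UNKNOWN
    usable = np.flatnonzero(del_mask & known)
    n_unpolarized = int((del_mask & ~known).sum())
    if usable.size == 0:
        raise ValueError("no polarizable deleterious sites")
    der = gm.derived_dosage()[:, usable]
    rows = []
    for i, s in enumerate(gm.samples):
        d = der[i]
        het = int((d == 1).sum())
        hom = int((d == 2).sum())
        rows.append((s, pm.assignment.get(s, "") if pm else "",
                     het + 2 * hom, het, hom, n_unpolarized))
    return pd.DataFrame(rows, columns=["sample", "group", "n_del_total",
                                       "n_het_del", "n_hom_del",
                                       "n_unpolarized_del_sites"])


def group_load_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean per-group load counts from a per-sample report."""
    return (report.groupby("group")[["n_del_total", "n_het_del", "n_hom_del"]]
            .mean().reset_index())
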