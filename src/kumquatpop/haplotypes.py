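"""Windowed haplotype divergence and mean-standardized distance comparisons.

Used to trace occasional outcrossing in apomictic samples: the two phased
haplotypes of an apomict are compared within 25-kb windows, each raw
p-distance is standardized by the window's mean pairwise distance over all
cohort haplotypes (so windows of different mutational density become
comparable), and a sample haplotype can be compared against every
haplotype of a reference group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vcfio import GenotypeMatrix, PopulationMap

DEFAULT_WINDOW = 25_000

HAP_COLUMNS = ["chrom", "start", "end", "n_sites", "raw_d"]


def _hap_vector(gm: GenotypeMatrix, hap: tuple[str, int]) -> np.ndarray:
    if gm.hap is None:
        raise ValueError("matrix carries no phased haplotypes")
    sample, which = hap
    if which not in (0, 1):
        raise ValueError("haplotype index must be 0 or 1")
    i = gm.sample_index([sample])[0]
    return gm.hap[i, which].astype(np.int16)


def _window_iter(gm, window_bp):
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        pos0 = gm.pos[idx] - 1
        last = pos0.max()
        start = 0
        while start <= last:
            sel = idx[(pos0 >= start) & (pos0 < start + window_bp)]
            if sel.size:
                yield c, start, start + window_bp, sel
            start += window_bp


def hap_pdist(gm: GenotypeMatrix, hap_a: tuple[str, int], hap_b: tuple[str, int],
              window_bp: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-window p-distance (differing / compared sites) between two phased
    haplotypes. Windows with no jointly non-missing site are missing."""
    va, vb = _hap_vector(gm, hap_a), _hap_vector(gm, hap_b)
    ok = (va >= 0) & (vb >= 0)
    diff = (va != vb) & ok
    rows = []
    for c, start, end, sel in _window_iter(gm, window_bp):
        n = int(ok[sel].sum())
        d = diff[sel].sum() / n if n else np.nan
        rows.append((c, start, end, n, d))
    return pd.DataFrame(rows, columns=HAP_COLUMNS)


def all_pair_mean(gm: GenotypeMatrix, pm: PopulationMap | None = None,
                  samples: list[str] | None = None,
                  window_bp: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Mean pairwise p-distance over all cohort haplotype pairs per window.

    The cohort is ``samples`` if given, else every non-outgroup sample in
    ``pm``, else every sample. This is the standardization background.
    """
    if samples is None:
        if pm is not None:
            samples = [s for s in gm.samples
                       if pm.assignment.get(s) != pm.outgroup_label]
        else:
            samples = list(gm.samples)
    if gm.hap is None:
        raise ValueError("matrix carries no phased haplotypes")
    rows_idx = gm.sample_index(samples)
    H = gm.hap[rows_idx].reshape(len(samples) * 2, gm.n_sites).astype(np.int16)
    valid = H >= 0
    rows = []
    for c, start, end, sel in _window_iter(gm, window_bp):
        Hw = H[:, sel]
        Vw = valid[:, sel]
        # accumulate pairwise diff/compared counts via matrix products
        ones = Vw.astype(np.float64)
        h1 = (Hw == 1) & Vw
        h0 = (Hw == 0) & Vw
        n_cmp = ones @ ones.T
        n_diff = h1.astype(np.float64) @ h0.T.astype(np.float64)
        n_diff = n_diff + n_diff.T
        iu = np.triu_indices(len(H), k=1)
        cmp_u, diff_u = n_cmp[iu], n_diff[iu]
        okp = cmp_u > 0
        mean_d = (diff_u[okp] / cmp_u[okp]).mean() if okp.any() else np.nan
        rows.append((c, start, end, int(sel.size), mean_d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "mean_d"])


def standardize(dists: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Divide each window's raw distance by the window's cohort mean.

    ``dists`` has a raw_d column; ``background`` the matching mean_d column
    from :func:`all_pair_mean`. Windows whose mean is 0 or missing give a
    missing std_d.
    """
    merged = dists.merge(background[["chrom", "start", "end", "mean_d"]],
                         on=["chrom", "start", "end"], how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        std = merged["raw_d"] / merged["mean_d"]
    std[~np.isfinite(std)] = np.nan
    out = dists.copy()
    out["std_d"] = std.to_numpy()
    return out


def hap_vs_group(gm: GenotypeMatrix, pm: PopulationMap, hap: tuple[str, int],
                 group: str, window_bp: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-window mean p-distance from one haplotype to every haplotype of a
    group's samples."""
    names = [s for s in gm.samples if pm.assignment.get(s) == group]
    if not names:
        raise ValueError(f"group {group!r} is empty")
    v = _hap_vector(gm, hap)
    parts = []
    for s in names:
        for w in (0, 1):
            parts.append(hap_pdist(gm, hap, (s, w), window_bp)["raw_d"].to_numpy())
    base = hap_pdist(gm, hap, (names[0], 0), window_bp)
    stack = np.vstack(parts)
    with np.errstate(invalid="ignore"):
        base["raw_d"] = np.nanmean(stack, axis=0)
    return base


def fraction_exceeding(pair_a: pd.DataFrame, pair_b: pd.DataFrame,
                       column: str = "std_d") -> float:
    """Share of windows (both values present) where pair_a's value strictly
    exceeds pair_b's. Ties count as not exceeding."""
    merged = pair_a.merge(pair_b, on=["chrom", "start", "end"],
                          suffixes=("_a", "_b"))
    a = merged[f"{column}_a"].to_numpy(float)
    b = merged[f"{column}_b"].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        return float("nan")
    return float((a[ok] > b[ok]).mean())
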