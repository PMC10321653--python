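"""Windowed diversity/differentiation statistics, heterozygosity, uSFS, ROH.

Windows are 0-based half-open in bp; a site at VCF position p belongs to
window [start, end) iff start <= p-1 < end. All ratio statistics are
ratio-of-sums over the window's sites, so concatenating adjacent windows
recombines exactly. Per-bp statistics (pi, Dxy, het density) are normalized
by window length; a ``per_site`` flag switches to variant-only
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import GenotypeMatrix, PopulationMap, MISSING

log = logging.getLogger("kumquatpop")

DEFAULT_WINDOW = 25_000
DEFAULT_MIN_SITES = 10

WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "value"]


def iter_windows(gm: GenotypeMatrix, window_bp: int):
    """Yield (chrom, start, end, site_index_array) over non-overlapping windows.

    Windows tile each chromosome from 0 up to the last site; empty windows
    are skipped.
    """
    for c in pd.unique(gm.chrom):
        mask = np.flatnonzero(gm.chrom == c)
        pos0 = gm.pos[mask] - 1  # 0-based
        if np.any(np.diff(pos0) < 0):
            raise ValueError(f"positions on {c} are not sorted")
        last = pos0[-1]
        start = 0
        while start <= last:
            end = start + window_bp
            sel = mask[(pos0 >= start) & (pos0 < end)]
            if sel.size:
                yield c, start, end, sel
            start = end


def _group_rows(gm, pm, group):
    names = [s for s in gm.samples if pm.assignment.get(s) == group]
    if not names:
        raise ValueError(f"group {group!r} has no samples in matrix")
    return gm.sample_index(names)


def _allele_counts(gt_rows):
    """Per-site (alt count, total non-missing allele count)."""
    nm = gt_rows != MISSING
    n = 2 * nm.sum(axis=0)
    ac = np.where(nm, gt_rows, 0).sum(axis=0)
    return ac.astype(float), n.astype(float)


def _pi_site(ac, n):
    """Mean pairwise difference per site: 2*ac*(n-ac)/(n*(n-1))."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, 2.0 * ac * (n - ac) / (n * (n - 1.0)), np.nan)


def _windowed(gm, window_bp, site_fn, min_sites, per_site=False):
    rows = []
    for c, start, end, idx in iter_windows(gm, window_bp):
        val, usable = site_fn(idx)
        if usable < min_sites:
            rows.append((c, start, end, usable, np.nan))
            continue
        denom = usable if per_site else (end - start)
        rows.append((c, start, end, usable, val / denom if np.isfinite(val) else np.nan))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def window_pi(gm: GenotypeMatrix, pm: PopulationMap, group: str,
              window_bp: int = DEFAULT_WINDOW, min_sites: int = DEFAULT_MIN_SITES,
              per_site: bool = False) -> pd.DataFrame:
    """Nucleotide diversity per window for one group.

    pi is the mean pairwise difference across available haplotypes
    (unphased genotypes enter via allele counts), summed over sites and
    divided by window bp.
    """
    rows = _group_rows(gm, pm, group)
    ac, n = _allele_counts(gm.gt[rows])
    ps = _pi_site(ac, n)

    def site_fn(idx):
        v = ps[idx]
        ok = np.isfinite(v)
        return np.nansum(v[ok]), int(ok.sum())

    return _windowed(gm, window_bp, site_fn, min_sites, per_site)


def window_dxy(gm: GenotypeMatrix, pm: PopulationMap, group_a: str, group_b: str,
               window_bp: int = DEFAULT_WINDOW, min_sites: int = DEFAULT_MIN_SITES,
               per_site: bool = False) -> pd.DataFrame:
    """Mean between-group pairwise difference per bp: sum(pA·qB + qA·pB)/bp."""
    ra, rb = _group_rows(gm, pm, group_a), _group_rows(gm, pm, group_b)
    aca, na = _allele_counts(gm.gt[ra])
    acb, nb = _allele_counts(gm.gt[rb])
    with np.errstate(invalid="ignore", divide="ignore"):
        pa, pb = aca / na, acb / nb
    dxy = pa * (1 - pb) + (1 - pa) * pb

    def site_fn(idx):
        v = dxy[idx]
        ok = np.isfinite(v)
        return np.nansum(v[ok]), int(ok.sum())

    return _windowed(gm, window_bp, site_fn, min_sites, per_site)


def window_fst(gm: GenotypeMatrix, pm: PopulationMap, group_a: str, group_b: str,
               window_bp: int = DEFAULT_WINDOW,
               min_sites: int = DEFAULT_MIN_SITES) -> pd.DataFrame:
    """Hudson-type ratio-of-sums Fst: 1 - sum(mean within-pi)/sum(dxy)."""
    ra, rb = _group_rows(gm, pm, group_a), _group_rows(gm, pm, group_b)
    aca, na = _allele_counts(gm.gt[ra])
    acb, nb = _allele_counts(gm.gt[rb])
    pia, pib = _pi_site(aca, na), _pi_site(acb, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa, pb = aca / na, acb / nb
    dxy = pa * (1 - pb) + (1 - pa) * pb
    within = 0.5 * (pia + pib)
    ok_all = np.isfinite(within) & np.isfinite(dxy)

    rows = []
    for c, start, end, idx in iter_windows(gm, window_bp):
        ok = idx[ok_all[idx]]
        nd, nw = dxy[ok].sum(), within[ok].sum()
        if ok.size < min_sites or nd == 0:
            rows.append((c, start, end, ok.size, np.nan))
        else:
            rows.append((c, start, end, ok.size, 1.0 - nw / nd))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def genomewide_fst(gm, pm, group_a, group_b) -> float:
    """Genome-wide Hudson Fst (single ratio of sums over all sites)."""
    ra, rb = _group_rows(gm, pm, group_a), _group_rows(gm, pm, group_b)
    aca, na = _allele_counts(gm.gt[ra])
    acb, nb = _allele_counts(gm.gt[rb])
    pia, pib = _pi_site(aca, na), _pi_site(acb, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa, pb = aca / na, acb / nb
    dxy = pa * (1 - pb) + (1 - pa) * pb
    within = 0.5 * (pia + pib)
    ok = np.isfinite(within) & np.isfinite(dxy)
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(1.0 - within[ok].sum() / dxy[ok].sum())


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(gm: GenotypeMatrix, pm: PopulationMap, group: str,
              window_bp: int = 100_000,
              min_sites: int = 1) -> pd.DataFrame:
    """Tajima's D per window from S segregating sites and mean pairwise
    differences, using the fixed haplotype count of the group.

    Sites with missing calls in the group are excluded (the constants
    require a single n). Windows with S = 0 are missing, not 0.
    """
    rows_idx = _group_rows(gm, pm, group)
    sub = gm.gt[rows_idx]
    complete = ~(sub == MISSING).any(axis=0)
    n = 2 * len(rows_idx)
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 haplotypes")
    ac = sub.sum(axis=0).astype(float)
    seg = complete & (ac > 0) & (ac < n)
    ps = _pi_site(ac, np.full(gm.n_sites, float(n)))
    a1, e1, e2 = _tajima_constants(n)

    rows = []
    for c, start, end, idx in iter_windows(gm, window_bp):
        sel = idx[seg[idx]]
        S = sel.size
        if S < max(min_sites, 1):
            rows.append((c, start, end, S, np.nan))
            continue
        pi_sum = ps[sel].sum()
        D = (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        rows.append((c, start, end, S, D))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# Heterozygosity


def heterozygosity(gm: GenotypeMatrix, sample: str) -> float:
    """Observed heterozygous calls / non-missing calls for one sample."""
    i = gm.sample_index([sample])[0]
    g = gm.gt[i]
    nm = g != MISSING
    if not nm.any():
        return float("nan")
    return float((g[nm] == 1).sum() / nm.sum())


def window_het(gm: GenotypeMatrix, sample: str,
               window_bp: int = 100_000) -> pd.DataFrame:
    """Per-window heterozygous-site counts per bp for one sample."""
    i = gm.sample_index([sample])[0]
    het = gm.gt[i] == 1

    def site_fn(idx):
        return float(het[idx].sum()), int((gm.gt[i, idx] != MISSING).sum())

    return _windowed(gm, window_bp, site_fn, min_sites=0)


# ---------------------------------------------------------------------------
# Unfolded site frequency spectrum


def usfs(gm: GenotypeMatrix, pm: PopulationMap, group: str,
         site_set: np.ndarray | None = None, n_bins: int = 10) -> pd.DataFrame:
    """Derived-allele frequencies of one group binned into ``n_bins``
    equal-width clusters over (0, 1].

    Bin k covers (k/n_bins, (k+1)/n_bins]; a frequency exactly on a bin
    edge falls in the lower bin. Sites with unknown ancestral allele or
    zero derived frequency are excluded. Proportions sum to 1.
    """
    rows_idx = _group_rows(gm, pm, group)
    der = gm.derived_dosage()[rows_idx]
    if site_set is not None:
        der = der[:, np.asarray(site_set)]
    nm = np.isfinite(der)
    n = 2 * nm.sum(axis=0)
    dc = np.nansum(der, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, dc / n, np.nan)
    f = f[np.isfinite(f) & (f > 0)]
    if f.size == 0:
        raise ValueError("no polarized segregating-derived sites for uSFS")
    # (k/n, (k+1)/n]: ceil(f*n)-1 with edge values landing in the lower bin
    k = np.ceil(f * n_bins - 1e-9).astype(int) - 1
    k = np.clip(k, 0, n_bins - 1)
    counts = np.bincount(k, minlength=n_bins)
    lo = np.arange(n_bins) / n_bins
    return pd.DataFrame({
        "bin_low": lo, "bin_high": lo + 1.0 / n_bins,
        "count": counts, "proportion": counts / counts.sum(),
    })


# ---------------------------------------------------------------------------
# Runs of homozygosity


@dataclass
class RohParams:
    """PLINK-style ROH scan thresholds.

    window_snps sliding window; a window is homozygous iff it contains at
    most ``max_het_per_window`` heterozygous calls; a SNP is eligible iff
    the fraction of overlapping homozygous windows >= ``hit_threshold``.
    Candidate runs of eligible SNPs are split at inter-SNP gaps >=
    ``max_gap_bp`` and kept iff they have >= ``min_snps`` SNPs, span
    > ``min_length_bp`` and reach >= ``min_density`` SNPs per 100 kb.
    """

    window_snps: int = 50
    max_het_per_window: int = 3
    hit_threshold: float = 0.05
    min_snps: int = 50
    min_length_bp: int = 500_000
    max_gap_bp: int = 100_000
    min_density: float = 10.0  # SNPs per 100 kb

ROH_COLUMNS = ["sample", "chrom", "start", "end", "n_snps", "length_bp"]


def detect_roh(gm: GenotypeMatrix, sample: str,
               params: RohParams | None = None) -> pd.DataFrame:
    """Scan one sample for runs of homozygosity.

    Missing calls are not counted as heterozygous. Output segments are
    per-chromosome, non-overlapping and sorted; start/end are the 1-based
    positions of the first/last SNP in the run.
    """
    par = params or RohParams()
    i = gm.sample_index([sample])[0]
    out = []
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions on {c} are not sorted")
        g = gm.gt[i, idx]
        het = (g == 1).astype(np.int64)
        m = het.size
        w = par.window_snps
        if m >= w:
            csum = np.concatenate([[0], np.cumsum(het)])
            win_het = csum[w:] - csum[:-w]          # windows start at 0..m-w
            win_ok = win_het <= par.max_het_per_window
            # SNP j overlaps windows max(0, j-w+1) .. min(j, m-w)
            ok_csum = np.concatenate([[0], np.cumsum(win_ok.astype(np.int64))])
            j = np.arange(m)
            lo = np.maximum(0, j - w + 1)
            hi = np.minimum(j, m - w)
            n_windows = hi - lo + 1
            n_hom = ok_csum[hi + 1] - ok_csum[lo]
            eligible = n_hom / n_windows >= par.hit_threshold
        else:
            eligible = np.zeros(m, dtype=bool)
        # maximal runs of eligible SNPs, split at large gaps
        runs = _runs(eligible)
        for a, b in runs:  # half-open on SNP index
            for a2, b2 in _split_gaps(pos, a, b, par.max_gap_bp):
                n_snps = b2 - a2
                length = int(pos[b2 - 1] - pos[a2])
                if n_snps < par.min_snps or length <= par.min_length_bp:
                    continue
                if n_snps / max(length, 1) * 100_000 < par.min_density:
                    continue
                out.append((sample, c, int(pos[a2]), int(pos[b2 - 1]),
                            int(n_snps), length))
    return pd.DataFrame(out, columns=ROH_COLUMNS)


def _runs(mask):
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def _split_gaps(pos, a, b, max_gap):
    gaps = np.flatnonzero(np.diff(pos[a:b]) >= max_gap) + a + 1
    bounds = [a, *gaps, b]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def total_roh_length(roh: pd.DataFrame) -> float:
    """Summed ROH length (bp) across segments, as used per-sample."""
    return float(roh["length_bp"].sum())
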