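"""Site-pattern gene-flow statistics and diagnostic-marker dosage.

Patterson's D and its windowed (f_d) and branch-attributed (f-branch)
admixture-fraction relatives are computed from per-group derived-allele
frequencies at polarized biallelic sites; uncertainty comes from a
delete-one block jackknife over contiguous genomic blocks (5 Mb default).

Species-specific markers (SSMs) — sites fixed for different alleles in the
cultivated and reference wild groups, with a monomorphic outgroup as an
incomplete-lineage-sorting guard — give a direct per-individual
introgression dosage: the share of diagnostic alleles carried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import GenotypeMatrix, PopulationMap, MISSING, ANC_UNKNOWN, ANC_ALT

log = logging.getLogger("kumquatpop")

DEFAULT_BLOCK = 5_000_000


class UndefinedStatistic(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Frequency tables


def derived_freq_table(gm: GenotypeMatrix, pm: PopulationMap,
                       groups: list[str]) -> pd.DataFrame:
    """Per-site derived-allele frequency for each named group.

    Sites with unknown ancestral allele are excluded. Columns: chrom, pos,
    one frequency column and one ``n_<group>`` chromosome-count column per
    group; frequencies are NaN where a group has no data.
    """
    keep = gm.anc != ANC_UNKNOWN
    idx = np.flatnonzero(keep)
    der = gm.derived_dosage()
    out = {"chrom": gm.chrom[idx], "pos": gm.pos[idx]}
    for g in groups:
        names = [s for s in gm.samples if pm.assignment.get(s) == g]
        if not names:
            raise ValueError(f"group {g!r} has no samples")
        sub = der[gm.sample_index(names)][:, idx]
        nm = np.isfinite(sub)
        n = 2 * nm.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[g] = np.where(n > 0, np.nansum(sub, axis=0) / n, np.nan)
        out[f"n_{g}"] = n
    return pd.DataFrame(out)


def _patterns(p1, p2, p3, p4):
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _block_ids(chrom, pos, block_bp):
    """Contiguous genomic block index per site."""
    ids = np.empty(len(pos), dtype=np.int64)
    nxt = 0
    for c in pd.unique(chrom):
        m = chrom == c
        ids[m] = nxt + (pos[m] - 1) // block_bp
        nxt = ids[m].max() + 1
    # compact to consecutive ids
    _, ids = np.unique(ids, return_inverse=True)
    return ids


def _jackknife_ratio(num, den, blocks):
    """Delete-one-block jackknife for a ratio-of-sums statistic.

    Returns (estimate, SE, n_blocks). SE is the unweighted delete-one
    formula sqrt((B-1)/B * sum((est_-b - mean)^2)).
    """
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        raise UndefinedStatistic("zero denominator in ratio statistic")
    est = tot_n / tot_d
    B = int(blocks.max()) + 1
    if B < 2:
        raise UndefinedStatistic("need >= 2 blocks for jackknife")
    bn = np.bincount(blocks, weights=num, minlength=B)
    bd = np.bincount(blocks, weights=den, minlength=B)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_n - bn) / (tot_d - bd)
    loo = loo[np.isfinite(loo)]
    if loo.size < 2:
        raise UndefinedStatistic("too few informative jackknife blocks")
    B = loo.size
    se = np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2))
    return est, se, B


@dataclass
class DStatResult:
    D: float
    Z: float
    se: float
    n_blocks: int
    abba_sum: float
    baba_sum: float
    n_sites: int


def d_statistic(ft: pd.DataFrame, p1: str, p2: str, p3: str, out: str,
                block_bp: int = DEFAULT_BLOCK) -> DStatResult:
    """Patterson's D over the whole frequency table with block-jackknife Z.

    D = sum(ABBA - BABA) / sum(ABBA + BABA) with ABBA = (1-p1)p2p3(1-p4)
    and BABA = p1(1-p2)p3(1-p4).
    """
    cols = ft[[p1, p2, p3, out]].to_numpy(float)
    ok = np.isfinite(cols).all(axis=1)
    q1, q2, q3, q4 = cols[ok].T
    abba, baba = _patterns(q1, q2, q3, q4)
    num, den = abba - baba, abba + baba
    blocks = _block_ids(ft["chrom"].to_numpy()[ok], ft["pos"].to_numpy()[ok],
                        block_bp)
    D, se, B = _jackknife_ratio(num, den, blocks)
    z = D / se if se > 0 else np.inf * np.sign(D) if D else 0.0
    return DStatResult(D=float(D), Z=float(z), se=float(se), n_blocks=B,
                       abba_sum=float(abba.sum()), baba_sum=float(baba.sum()),
                       n_sites=int(ok.sum()))


# ---------------------------------------------------------------------------
# Windowed f_d


def fd_windows(ft: pd.DataFrame, p1: str, p2: str, p3: str, out: str,
               window_bp: int = 25_000,
               mask_negative_d: bool = True) -> pd.DataFrame:
    """Windowed f_d admixture fraction.

    Per window f_d = sum(ABBA-BABA) / sum(ABBA_D-BABA_D) where the donor
    row substitutes whichever of P2/P3 has the higher derived frequency at
    each site. With ``mask_negative_d`` windows whose D is negative are
    reported missing (f_d quantifies flow in the positive-D direction);
    without it the signed value is kept, which is the right null-calibration
    scale since truncation at D = 0 biases retained windows upward.
    """
    cols = ft[[p1, p2, p3, out]].to_numpy(float)
    ok = np.isfinite(cols).all(axis=1)
    chrom, pos = ft["chrom"].to_numpy()[ok], ft["pos"].to_numpy()[ok]
    q1, q2, q3, q4 = cols[ok].T
    abba, baba = _patterns(q1, q2, q3, q4)
    pd_ = np.maximum(q2, q3)
    abba_d, baba_d = _patterns(q1, pd_, pd_, q4)
    num, den_d = abba - baba, abba_d - baba_d
    den_abs = abba + baba

    rows = []
    for c in pd.unique(chrom):
        m = np.flatnonzero(chrom == c)
        p0 = pos[m] - 1
        last = p0.max()
        start = 0
        while start <= last:
            sel = m[(p0 >= start) & (p0 < start + window_bp)]
            if sel.size:
                sn, sd = num[sel].sum(), den_d[sel].sum()
                d_w = sn / den_abs[sel].sum() if den_abs[sel].sum() > 0 else np.nan
                if sd == 0 or (mask_negative_d and (not np.isfinite(d_w) or d_w < 0)):
                    fd = np.nan
                else:
                    fd = sn / sd
                rows.append((c, start, start + window_bp, sel.size, fd))
            start += window_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"])


def fd_genomewide(ft, p1, p2, p3, out) -> float:
    """Genome-wide f_d: one ratio of sums over all informative sites."""
    cols = ft[[p1, p2, p3, out]].to_numpy(float)
    ok = np.isfinite(cols).all(axis=1)
    q1, q2, q3, q4 = cols[ok].T
    abba, baba = _patterns(q1, q2, q3, q4)
    pd_ = np.maximum(q2, q3)
    abba_d, baba_d = _patterns(q1, pd_, pd_, q4)
    den = (abba_d - baba_d).sum()
    if den == 0:
        raise UndefinedStatistic("zero f_d denominator")
    return float((abba - baba).sum() / den)


# ---------------------------------------------------------------------------
# f-branch


def _fhat(ft, a, b, c, out, block_bp):
    """f-hat(A,B,C,O) with the homozygous-donor denominator (P2 := P3)."""
    cols = ft[[a, b, c, out]].to_numpy(float)
    ok = np.isfinite(cols).all(axis=1)
    q1, q2, q3, q4 = cols[ok].T
    abba, baba = _patterns(q1, q2, q3, q4)
    abba_hd, baba_hd = _patterns(q1, q3, q3, q4)
    num, den = abba - baba, abba_hd - baba_hd
    blocks = _block_ids(ft["chrom"].to_numpy()[ok], ft["pos"].to_numpy()[ok],
                        block_bp)
    return _jackknife_ratio(num, den, blocks)


def _parse_tree(newick: str):
    """Parse a rooted newick group tree into (clade -> tip set, children)."""
    from io import StringIO
    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    return tree


def f_branch(ft: pd.DataFrame, tree_newick: str, out: str,
             block_bp: int = DEFAULT_BLOCK,
             alpha: float = 0.001) -> pd.DataFrame:
    """f-branch matrix: excess allele sharing assigned to tree branches.

    For each branch b of the rooted group tree (internal or terminal,
    excluding the root) and each candidate donor group C not descended
    from b:

        f_b(C) = median over A in descendants(sister(b)) of
                 [ min over B in descendants(b) of f-hat(A, B, C, O) ]

    with f-hat's denominator the homozygous-donor substitution (P2 := P3).
    Negative estimates are floored at 0. Each cell carries a block-jackknife
    Z and a significance flag at p < ``alpha`` (two-sided normal).
    """
    from scipy.stats import norm

    tree = _parse_tree(tree_newick)
    root = tree.root
    tips = [t.name for t in tree.get_terminals()]
    if len(tips) < 3:
        raise ValueError("f-branch needs >= 3 groups in the tree")

    def desc(clade):
        return [t.name for t in clade.get_terminals()]

    # enumerate branches: every clade except the root
    branches = []
    for clade in tree.find_clades():
        if clade is root:
            continue
        parent = tree.get_path(clade)
        parent = parent[-2] if len(parent) > 1 else root
        sisters = [ch for ch in parent.clades if ch is not clade]
        if not sisters:
            continue
        sister_desc = [n for s in sisters for n in desc(s)]
        branches.append((clade, desc(clade), sister_desc))

    rows = []
    crit = norm.ppf(1 - alpha / 2)
    for clade, db, ds in branches:
        label = ",".join(sorted(db))
        for cand in tips:
            if cand in db:
                rows.append((label, cand, np.nan, np.nan, False))
                continue
            med_vals, med_ses = [], []
            for a in ds:
                if a == cand:
                    continue
                vals = [(v, se) for bb in db if bb != cand
                        for v, se, _ in [_fhat(ft, a, bb, cand, out, block_bp)]]
                if not vals:
                    continue
                v, se = min(vals, key=lambda t: t[0])
                med_vals.append(v)
                med_ses.append(se)
            if not med_vals:
                rows.append((label, cand, np.nan, np.nan, False))
                continue
            order = np.argsort(med_vals)
            mid = order[(len(order) - 1) // 2]
            fb, se = med_vals[mid], med_ses[mid]
            z = fb / se if se > 0 else 0.0
            rows.append((label, cand, max(fb, 0.0), z, bool(z > crit)))
    return pd.DataFrame(rows, columns=["branch", "donor", "f_b", "Z", "significant"])


# ---------------------------------------------------------------------------
# Species-specific markers and dosage


@dataclass
class SsmSet:
    """Diagnostic sites: cultivated-fixed allele differing from the wild
    reference group, with a monomorphic outgroup."""

    site_idx: np.ndarray       # indices into the source matrix
    chrom: np.ndarray
    pos: np.ndarray
    diag_allele: np.ndarray    # 0 = REF diagnostic, 1 = ALT diagnostic
    polarity: np.ndarray       # True where the diagnostic allele is derived

    def __len__(self):
        return len(self.site_idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos,
            "diag_allele": np.where(self.diag_allele == 1, "alt", "ref"),
            "polarity": np.where(self.polarity, "derived", "ancestral"),
        })


def identify_ssms(gm: GenotypeMatrix, pm: PopulationMap,
                  group_cul: str | list[str], group_wild_ref: str,
                  miss_tol: float = 0.0) -> SsmSet:
    """Find species-specific markers between cultivated and wild-reference
    groups.

    A site qualifies iff all non-missing cultivated calls are homozygous for
    one allele, all non-missing wild-reference calls homozygous for the
    other, per-group missingness <= miss_tol, and the outgroup is
    non-missing and monomorphic.
    """
    culs = [group_cul] if isinstance(group_cul, str) else list(group_cul)
    cul_names = [s for s in gm.samples for g in culs if pm.assignment.get(s) == g]
    wild_names = [s for s in gm.samples if pm.assignment.get(s) == group_wild_ref]
    og_names = [s for s in gm.samples
                if pm.assignment.get(s) == pm.outgroup_label]
    if set(cul_names) & set(wild_names):
        raise ValueError("defining groups overlap")
    if len(cul_names) < 2 or len(wild_names) < 2:
        raise ValueError("both defining groups need >= 2 samples")
    if not og_names:
        raise ValueError("outgroup required for SSM identification")

    def fixed_allele(rows):
        sub = gm.gt[rows]
        nm = sub != MISSING
        n_nm = nm.sum(axis=0)
        miss = 1 - n_nm / len(rows)
        hom0 = np.where(nm, sub == 0, True).all(axis=0)
        hom2 = np.where(nm, sub == 2, True).all(axis=0)
        allele = np.where(hom2, 1, np.where(hom0, 0, -9))
        okm = (n_nm > 0) & (miss <= miss_tol + 1e-12)
        return np.where(okm, allele, -9)

    a_cul = fixed_allele(gm.sample_index(cul_names))
    a_wild = fixed_allele(gm.sample_index(wild_names))
    og = gm.gt[gm.sample_index(og_names)]
    og_nm = og != MISSING
    og_mono = (og_nm.sum(axis=0) == len(og_names)) & (
        np.ptp(og, axis=0) == 0) & ~(og == 1).any(axis=0)

    is_ssm = (a_cul >= 0) & (a_wild >= 0) & (a_cul != a_wild) & og_mono
    idx = np.flatnonzero(is_ssm)
    diag = a_cul[idx].astype(np.int8)
    polarity = ((diag == 1) & (gm.anc[idx] == 0)) | ((diag == 0) & (gm.anc[idx] == ANC_ALT))
    return SsmSet(site_idx=idx, chrom=gm.chrom[idx], pos=gm.pos[idx],
                  diag_allele=diag, polarity=polarity)


def introgression_dosage(gm: GenotypeMatrix, ssm: SsmSet,
                         samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample diagnostic-allele dosage over genotyped SSMs.

    proportion = (diagnostic-allele dosage summed over genotyped SSMs)
               / (2 x genotyped SSMs); n_het / n_hom count SSM sites where
    the sample carries one / two diagnostic alleles. Samples with zero
    genotyped SSMs are skipped with a warning.
    """
    samples = samples or gm.samples
    rows = []
    for s in samples:
        i = gm.sample_index([s])[0]
        g = gm.gt[i, ssm.site_idx]
        nm = g != MISSING
        n_gt = int(nm.sum())
        if n_gt == 0:
            log.warning("sample %s has no genotyped SSMs; skipped", s)
            continue
        dose = np.where(ssm.diag_allele == 1, g, 2 - g)[nm]
        n_het = int((dose == 1).sum())
        n_hom = int((dose == 2).sum())
        rows.append((s, (n_het + 2 * n_hom) / (2 * n_gt), n_het, n_hom, n_gt))
    return pd.DataFrame(rows, columns=["sample", "proportion", "n_het_sites",
                                       "n_hom_sites", "n_genotyped"])
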