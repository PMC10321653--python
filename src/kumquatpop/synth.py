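"""Synthetic cohorts and climate tables with a known truth channel.

The cohort generator emulates the statistical structure of a kumquat-like
resequencing panel: five ingroup groups (cultivated apomictic/sexual, wild
apomictic, two wild sexual subpopulations) plus a diverged outgroup, with

* group allele frequencies drifted around a shared ancestral frequency
  under the Balding-Nichols model (Beta(p(1-F)/F, (1-p)(1-F)/F)),
* phased haplotypes drawn per chromosome copy,
* introgression planted as contiguous donor-haplotype tracts of known
  per-sample total fraction,
* apomictic groups given elevated heterozygosity by drawing their two
  haplotypes from two independently drifted source pools,
* a subset of sites annotated deleterious, with per-sample heterozygous /
  homozygous derived counts recorded exactly, and
* an outgroup fixed for the ancestral allele at a configurable fraction of
  sites (the remainder fixed derived, emulating outgroup-specific
  substitutions).

Everything is deterministic under (config, seed). Group sizes default to the
study panel: 12 + 7 cultivated, 24 + 11 + 17 wild, 15 outgroup accessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .vcfio import (GenotypeMatrix, PopulationMap, ANC_REF, ANN_DELETERIOUS,
                    ANN_TOLERATED)

GROUPS = ("CULAPO", "CULSEX", "WILDAPO", "WILDSEX1", "WILDSEX2")
OUTGROUP = "OUTGROUP"


class SynthConfigError(ValueError):
    """Unsatisfiable generator configuration."""


@dataclass
class CohortConfig:
    """Ground-truth cohort parameters.

    ``introgression`` maps target group -> (donor group, fraction); the
    fraction is the share of the target's total haplotype content copied
    from freshly drawn donor haplotypes, matched to within one tract.
    ``apomict_groups`` get haplotypes from two diverged source pools.
    """

    group_sizes: dict = field(default_factory=lambda: {
        "CULAPO": 12, "CULSEX": 7, "WILDAPO": 24,
        "WILDSEX1": 11, "WILDSEX2": 17, OUTGROUP: 15})
    drift: dict = field(default_factory=lambda: {
        "CULAPO": 0.05, "CULSEX": 0.05, "WILDAPO": 0.02,
        "WILDSEX1": 0.13, "WILDSEX2": 0.13})
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 5_000_000, "chr2": 5_000_000})
    n_sites: int = 5000
    freq_min: float = 0.02
    introgression: dict = field(default_factory=dict)
    tract_bp: int = 250_000
    deleterious_fraction: float = 0.02
    diagnostic_fraction: float = 0.05
    cultivated_groups: tuple = ("CULAPO", "CULSEX")
    apomict_groups: tuple = ("CULAPO", "WILDAPO")
    apomict_pool_drift: float = 0.08
    outgroup_concordance: float = 1.0

    def validate(self):
        genome = sum(self.chrom_lengths.values())
        for tgt, (donor, frac) in self.introgression.items():
            if not 0.0 <= frac <= 1.0:
                raise SynthConfigError(f"introgression fraction {frac} not in [0,1]")
            if frac > 0 and self.tract_bp > 2 * genome:
                raise SynthConfigError("tract length exceeds genome; fraction unreachable")
            if tgt not in self.group_sizes or donor not in self.group_sizes:
                raise SynthConfigError(f"unknown group in introgression spec: {tgt}->{donor}")


@dataclass
class CohortTruth:
    """Planted ground truth emitted alongside the genotypes."""

    group_of: dict
    introgression_fraction: dict          # sample -> realized fraction
    tract_map: dict                       # sample -> [(chrom, start, end, hap, donor)]
    deleterious_sites: np.ndarray         # site indices
    het_del: dict                         # sample -> het deleterious site count
    hom_del: dict                         # sample -> hom-derived deleterious site count
    diagnostic_sites: np.ndarray | None = None  # planted species-diagnostic sites
    seed: int | None = None

    def to_json(self, path):
        d = {
            "group_of": self.group_of,
            "introgression_fraction": self.introgression_fraction,
            "tract_map": {s: [list(t) for t in v] for s, v in self.tract_map.items()},
            "deleterious_sites": [int(i) for i in self.deleterious_sites],
            "het_del": self.het_del, "hom_del": self.hom_del,
            "diagnostic_sites": (None if self.diagnostic_sites is None
                                 else [int(i) for i in self.diagnostic_sites]),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _ancestral_freqs(rng, n, lo, hi):
    # density proportional to 1/p on [lo, hi] (neutral-like spectrum)
    u = rng.random(n)
    return lo * (hi / lo) ** u


def _bn_freqs(rng, p, F):
    """Balding-Nichols drifted frequencies around ancestral p."""
    if F <= 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def simulate_cohort(cfg: CohortConfig | None = None, seed: int = 0):
    """Generate (GenotypeMatrix, PopulationMap, CohortTruth).

    Deterministic under (cfg, seed).
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    chroms = list(cfg.chrom_lengths)
    genome = sum(cfg.chrom_lengths.values())
    # allocate site counts per chromosome proportional to length
    per = np.array([cfg.chrom_lengths[c] for c in chroms], float)
    counts = np.floor(cfg.n_sites * per / per.sum()).astype(int)
    counts[0] += cfg.n_sites - counts.sum()
    chrom_arr, pos_arr = [], []
    for c, k in zip(chroms, counts):
        p = np.sort(rng.choice(cfg.chrom_lengths[c], size=k, replace=False)) + 1
        chrom_arr.append(np.full(k, c, dtype=object))
        pos_arr.append(p.astype(np.int64))
    chrom_arr = np.concatenate(chrom_arr)
    pos_arr = np.concatenate(pos_arr)
    S = cfg.n_sites

    p_anc = _ancestral_freqs(rng, S, cfg.freq_min, 1 - cfg.freq_min)

    samples, group_of = [], {}
    for g in GROUPS + (OUTGROUP,):
        for i in range(cfg.group_sizes.get(g, 0)):
            name = f"{g}_{i:02d}"
            samples.append(name)
            group_of[name] = g
    n = len(samples)

    hap = np.zeros((n, 2, S), dtype=np.int8)
    group_freq = {}
    for g in GROUPS:
        if g in cfg.apomict_groups:
            # two diverged source pools around a common drifted frequency
            base = _bn_freqs(rng, p_anc, cfg.drift.get(g, 0.05))
            group_freq[g] = (
                _bn_freqs(rng, base, cfg.apomict_pool_drift),
                _bn_freqs(rng, base, cfg.apomict_pool_drift),
            )
        else:
            f = _bn_freqs(rng, p_anc, cfg.drift.get(g, 0.05))
            group_freq[g] = (f, f)

    og_discordant = np.zeros(S, dtype=bool)
    if cfg.outgroup_concordance < 1.0:
        og_discordant = rng.random(S) >= cfg.outgroup_concordance

    # species-diagnostic sites: fixed derived in cultivated groups, fixed
    # ancestral in wild groups (a fixed species difference); the outgroup
    # stays ancestral, so these are recoverable as SSMs and introgressed
    # tracts carry the cultivated allele at exactly the planted rate
    n_diag = int(round(cfg.diagnostic_fraction * S))
    diag_pool = np.flatnonzero(~og_discordant)
    diag_sites = np.sort(rng.choice(diag_pool, size=min(n_diag, diag_pool.size),
                                    replace=False))
    for g in GROUPS:
        fa0, fb0 = group_freq[g]
        tgt = 1.0 if g in cfg.cultivated_groups else 0.0
        fa = fa0.copy()
        fb = fa if fb0 is fa0 else fb0.copy()
        fa[diag_sites] = tgt
        fb[diag_sites] = tgt
        group_freq[g] = (fa, fb)

    for i, s in enumerate(samples):
        g = group_of[s]
        if g == OUTGROUP:
            hap[i, :, :] = 0
            hap[i, :, og_discordant] = 1
        else:
            fa, fb = group_freq[g]
            hap[i, 0] = rng.random(S) < fa
            hap[i, 1] = rng.random(S) < fb

    # --- plant introgression tracts ------------------------------------
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += cfg.chrom_lengths[c]
    tract_map = {s: [] for s in samples}
    frac_real = {s: 0.0 for s in samples}
    for tgt_group, (donor, frac) in cfg.introgression.items():
        if frac <= 0:
            continue
        donor_fa, donor_fb = group_freq[donor]
        for i, s in enumerate(samples):
            if group_of[s] != tgt_group:
                continue
            target_bp = frac * 2 * genome
            placed = 0.0
            copies = [(h, c) for h in (0, 1) for c in chroms]
            rng.shuffle(copies)
            occupied = {hc: [] for hc in copies}
            guard = 0
            while placed < target_bp - 1 and guard < 10000:
                guard += 1
                h, c = copies[rng.integers(len(copies))]
                L = cfg.chrom_lengths[c]
                tl = min(cfg.tract_bp, L, int(target_bp - placed) + 1)
                start = int(rng.integers(0, max(L - tl, 1)))
                end = start + tl
                if any(not (end <= a or start >= b) for a, b in occupied[(h, c)]):
                    continue
                occupied[(h, c)].append((start, end))
                in_tract = ((chrom_arr == c) & (pos_arr - 1 >= start)
                            & (pos_arr - 1 < end))
                dfreq = donor_fa if h == 0 else donor_fb
                hap[i, h, in_tract] = rng.random(in_tract.sum()) < dfreq[in_tract]
                tract_map[s].append((c, start, end, h, donor))
                placed += tl
            frac_real[s] = placed / (2 * genome)

    gt = hap.sum(axis=1).astype(np.int8)

    # --- deleterious annotation + exact truth counts --------------------
    eligible = np.flatnonzero(~og_discordant & ~np.isin(np.arange(S), diag_sites))
    n_del = int(round(cfg.deleterious_fraction * S))
    del_sites = np.sort(rng.choice(eligible, size=min(n_del, eligible.size),
                                   replace=False))
    annotation = np.full(S, ANN_TOLERATED, dtype=np.int8)
    annotation[del_sites] = ANN_DELETERIOUS
    het_del = {s: int(((gt[i, del_sites] == 1)).sum()) for i, s in enumerate(samples)}
    hom_del = {s: int(((gt[i, del_sites] == 2)).sum()) for i, s in enumerate(samples)}

    anc = np.full(S, ANC_REF, dtype=np.int8)  # truth: REF is ancestral everywhere
    gm = GenotypeMatrix(
        samples=samples, chrom=chrom_arr, pos=pos_arr,
        ref=np.full(S, "A", dtype=object), alt=np.full(S, "T", dtype=object),
        gt=gt, hap=hap, anc=anc,
        qd=np.full(S, 25.0), qual=np.full(S, 100.0), mq=np.full(S, 60.0),
        annotation=annotation,
    )
    pm = PopulationMap({s: group_of[s] for s in samples}, OUTGROUP)
    truth = CohortTruth(group_of=group_of, introgression_fraction=frac_real,
                        tract_map=tract_map, deleterious_sites=del_sites,
                        het_del=het_del, hom_del=hom_del,
                        diagnostic_sites=diag_sites, seed=seed)
    return gm, pm, truth


# ---------------------------------------------------------------------------
# Climate occurrence tables

BIOCLIM_VARS = [f"bio{i}" for i in range(1, 20)]


DEFAULT_MEAN_SHIFT = 3.1908
"""Centre separation (Mahalanobis units) whose closed-form directional
overlap at the 95% niche region equals the ~58% reported for the real
wild/cultivated ranges: P(ncx2(19, d^2) <= chi2_19(0.95)) = 0.58."""


def bioclim_covariance(d: int = 19, pc1: float = 0.475, pc2: float = 0.206,
                       sep_inflation: float = 0.0):
    """Two-factor covariance emulating the strong inter-correlation of the
    19 bioclimatic variables.

    Built so the leading principal components of the POOLED two-label panel
    carry ``pc1`` and ``pc2`` of the total variance (the shares reported
    for the real 396-record panel), the rest being isotropic noise.
    ``sep_inflation`` is the between-centre variance contribution
    p(1-p)*shift^2 added along the dominant factor by the label separation
    (0 when both labels share one centre). Per-variable within-label
    variances are 1.
    """
    c = sep_inflation
    v1 = pc1 * d / ((1 + c) - pc1 * c)
    v2 = pc2 * (d + c * v1)
    psi = (d - v1 - v2) / (d - 2)
    a2 = max((v1 - psi) / d, 0.0)
    b2 = max((v2 - psi) / d, 0.0)
    psi = 1.0 - a2 - b2
    s1 = np.ones(d)
    s2 = np.where(np.arange(d) % 2 == 0, 1.0, -1.0)
    return (a2 * np.outer(s1, s1) + b2 * np.outer(s2, s2)
            + psi * np.eye(d))


def simulate_occurrences(n_wild: int = 244, n_cult: int = 152,
                         mean_shift: float = DEFAULT_MEAN_SHIFT,
                         cov_scale: float = 1.0,
                         seed: int = 0):
    """Two 19-dimensional Gaussian climate clouds with tunable separation.

    Returns a DataFrame with a ``label`` column (wild|cultivated) and the 19
    bioclimatic variables. Both labels share the correlated
    :func:`bioclim_covariance`; ``mean_shift`` is the Mahalanobis distance
    between the cloud centres, applied along the dominant climate factor, so
    the true-distribution directional overlap has the closed form
    P(ncx2(19, shift^2) <= chi2_19(alpha)). ``cov_scale`` scales both
    covariances. Defaults emulate the herbarium panel: 244 wild and 152
    cultivated records.
    """
    import pandas as pd

    if n_wild < 2 or n_cult < 2:
        raise SynthConfigError("need at least 2 records per label")
    if cov_scale <= 0:
        raise SynthConfigError("covariance scale must be positive")
    rng = np.random.default_rng(seed)
    d = 19
    p_cult = n_cult / (n_wild + n_cult)
    cov = bioclim_covariance(
        d, sep_inflation=p_cult * (1 - p_cult) * mean_shift ** 2) * cov_scale
    w, V = np.linalg.eigh(cov)
    sqrt_cov = (V * np.sqrt(w)) @ V.T
    u = np.ones(d) / np.sqrt(d)
    mu_w = np.zeros(d)
    mu_c = mean_shift * (sqrt_cov @ u)
    xw = rng.multivariate_normal(mu_w, cov, size=n_wild)
    xc = rng.multivariate_normal(mu_c, cov, size=n_cult)
    df = pd.DataFrame(np.vstack([xw, xc]), columns=BIOCLIM_VARS)
    df.insert(0, "label", ["wild"] * n_wild + ["cultivated"] * n_cult)
    return df
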