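"""Forward Wright-Fisher simulation of selfing vs outcrossing under a
bottleneck demography, with a standard-neutral-model control.

The model: a diploid population of N individuals evolves in discrete
generations on a 1-Mb sequence with per-bp mutation rate mu and crossover
rate r. After a burn-in of 10N generations the population contracts to
0.25N (bottleneck), and later splits into two 0.1N subpopulations, one
reproducing by selfing (selfing rate 1) and one by obligate outcrossing
(selfing rate 0). New mutations inside a synthetic exon mask are
deleterious with probability ``p_deleterious``; their selection coefficient
is drawn from a gamma distribution of |s| and they are fully recessive
(h = 0). Fitness is multiplicative across homozygous-derived sites and acts
as viability selection on offspring. The SNM arm is a constant-N,
randomly mating, neutral-only control.

Haplotypes are stored as a dense 0/1 matrix over segregating mutations
(columns carry position and selection coefficient); fixed and lost columns
are recycled, with fixed deleterious sites accumulated into every
individual's homozygous count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

log = logging.getLogger("kumquatpop")


class SimulationCollapse(RuntimeError):
    """All proposed offspring were inviable for too many attempts."""


@dataclass
class SimConfig:
    """Forward-simulation parameters (defaults follow the study demography).

    Times are generations; ``bottleneck_start_bp``/``split_bp`` are counted
    backwards from the present. The simulated timeline is::

        burn_in gens at N  ->  (bottleneck_start_bp - split_bp) gens at
        bottleneck_frac*N  ->  split_bp gens as two split_frac*N subpops
        (selfing arm, outcrossing arm)

    ``burn_in`` defaults to 10*N. The SNM arm runs the same total number of
    generations at constant N with neutral mutations only.
    """

    N: int = 1000
    burn_in: int | None = None
    bottleneck_frac: float = 0.25
    split_frac: float = 0.1
    bottleneck_start_bp: int = 10_000
    split_bp: int = 2_000
    L: int = 1_000_000
    mu: float = 2.2e-8
    r: float = 1.0e-7
    selfing_rate_selfing_arm: float = 1.0
    selfing_rate_outcrossing_arm: float = 0.0
    deleterious: bool = True
    p_deleterious: float = 1.0
    dfe_shape: float = 0.186
    dfe_mean_s: float = 0.01
    h: float = 0.0
    exon_fraction: float = 0.3
    exon_mean_bp: float = 250.0
    n_sample: int = 20
    replicates: int = 10
    max_retries: int = 3
    snm_generations: int | None = None  # default: same total as the main arms

    def __post_init__(self):
        if not (0 <= self.bottleneck_frac and 0 <= self.split_frac):
            raise ValueError("population size fractions must be non-negative")
        for sr in (self.selfing_rate_selfing_arm, self.selfing_rate_outcrossing_arm):
            if not 0 <= sr <= 1:
                raise ValueError("selfing rate must lie in [0, 1]")
        if not 0 <= self.h <= 1:
            raise ValueError("dominance must lie in [0, 1]")
        if self.split_bp >= self.bottleneck_start_bp:
            raise ValueError("schedule times must decrease toward the present")
        if min(self.mu, self.r, self.L) < 0:
            raise ValueError("rates and lengths must be non-negative")

    @property
    def burn_in_gens(self) -> int:
        return self.burn_in if self.burn_in is not None else 10 * self.N

    @property
    def total_gens(self) -> int:
        return self.burn_in_gens + self.bottleneck_start_bp - self.split_bp + self.split_bp

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                k, _, v = line.partition("=")
                k = k.strip()
                v = v.strip()
                fld = cls.__dataclass_fields__.get(k)
                if fld is None:
                    raise ValueError(f"unknown simulation parameter {k!r}")
                if fld.type in ("int", "int | None"):
                    kv[k] = int(float(v))
                elif fld.type == "bool":
                    kv[k] = v.lower() in ("1", "true", "yes")
                else:
                    kv[k] = float(v)
        return cls(**kv)


def make_exon_mask(cfg: SimConfig, rng) -> np.ndarray:
    """Synthetic exon intervals [(start, end)) covering ~exon_fraction of L,
    with exponentially distributed exon lengths around exon_mean_bp."""
    target = cfg.exon_fraction * cfg.L
    ivs = []
    covered, cursor = 0.0, 0.0
    mean_gap = cfg.exon_mean_bp * (1 - cfg.exon_fraction) / max(cfg.exon_fraction, 1e-9)
    while covered < target and cursor < cfg.L:
        gap = rng.exponential(mean_gap)
        length = max(1.0, rng.exponential(cfg.exon_mean_bp))
        start = cursor + gap
        end = min(start + length, cfg.L)
        if start >= cfg.L:
            break
        ivs.append((start, end))
        covered += end - start
        cursor = end
    return np.array(ivs) if ivs else np.zeros((0, 2))


def _in_exon(positions, mask):
    if mask.size == 0:
        return np.zeros(len(positions), dtype=bool)
    starts, ends = mask[:, 0], mask[:, 1]
    k = np.searchsorted(starts, positions, side="right") - 1
    ok = k >= 0
    res = np.zeros(len(positions), dtype=bool)
    res[ok] = positions[ok] < ends[k[ok]]
    return res


class _Pop:
    """Dense-matrix Wright-Fisher population (internal)."""

    def __init__(self, n_dip, cfg: SimConfig, rng, exon_mask, neutral_only=False):
        self.cfg = cfg
        self.rng = rng
        self.exon_mask = exon_mask
        self.neutral_only = neutral_only
        self.H = np.zeros((2 * n_dip, 64), dtype=np.int8)
        self.positions = np.zeros(64)
        self.sel = np.zeros(64)
        self.S = 0
        self.fixed_neutral = 0
        self.fixed_del = 0
        self.rL = cfg.r * cfg.L
        self.muL = cfg.mu * cfg.L

    @property
    def n_dip(self):
        return self.H.shape[0] // 2

    # -- gamete formation ------------------------------------------------
    def _gametes(self, par, H, positions):
        k = len(par)
        S = H.shape[1]
        rng = self.rng
        c = rng.integers(0, 2, k)
        rows_a = 2 * par + c
        rows_b = 2 * par + 1 - c
        gam = H[rows_a]  # fancy indexing copies
        if S == 0 or self.rL == 0:
            return gam
        ncx = rng.poisson(self.rL, k)
        one = np.flatnonzero(ncx == 1)
        if one.size:
            xs = rng.uniform(0, self.cfg.L, one.size)
            mask = positions[None, :] >= xs[:, None]
            gam[one] = np.where(mask, H[rows_b[one]], gam[one])
        multi = np.flatnonzero(ncx >= 2)
        for i in multi:
            xs = np.sort(rng.uniform(0, self.cfg.L, ncx[i]))
            cnt = np.searchsorted(xs, positions, side="right")
            src_b = (cnt % 2) == 1
            gam[i] = np.where(src_b, H[rows_b[i]], gam[i])
        return gam

    # -- one generation --------------------------------------------------
    def step(self, next_n, selfing_rate):
        cfg, rng = self.cfg, self.rng
        n_par = self.n_dip
        S = self.S
        H = self.H[:, :S]
        positions = self.positions[:S]
        sel_on = (not self.neutral_only) and cfg.deleterious
        del_cols = np.flatnonzero(self.sel[:S] < 0) if sel_on else np.empty(0, np.intp)
        log1ps = np.log1p(np.maximum(self.sel[:S][del_cols], -1.0)) if del_cols.size else None

        acc1, acc2 = [], []
        need = next_n
        attempts = 0
        while need > 0:
            attempts += 1
            if attempts > 200:
                raise SimulationCollapse("population fitness collapsed")
            k = max(16, int(need * 1.2) + 4)
            p1 = rng.integers(0, n_par, k)
            if selfing_rate >= 1.0:
                p2 = p1
            else:
                p2 = rng.integers(0, n_par, k)
                if selfing_rate <= 0.0:
                    clash = p2 == p1
                    while clash.any() and n_par > 1:
                        p2[clash] = rng.integers(0, n_par, clash.sum())
                        clash = p2 == p1
                else:
                    selfed = rng.random(k) < selfing_rate
                    p2[selfed] = p1[selfed]
            gam = self._gametes(np.concatenate([p1, p2]), H, positions)
            g1, g2 = gam[:k], gam[k:]
            if del_cols.size:
                hom = (g1[:, del_cols] + g2[:, del_cols]) == 2
                logw = hom @ log1ps
                if cfg.h > 0:
                    het = (g1[:, del_cols] + g2[:, del_cols]) == 1
                    logw = logw + het @ np.log1p(cfg.h * np.maximum(
                        self.sel[:S][del_cols], -1.0))
                ok = np.log(rng.random(k)) < logw
            else:
                ok = np.ones(k, dtype=bool)
            ia = np.flatnonzero(ok)[:need]
            acc1.append(g1[ia])
            acc2.append(g2[ia])
            need -= ia.size

        # new mutations
        n_new = rng.poisson(self.muL * 2 * next_n)
        new_H = np.zeros((2 * next_n, S + n_new), dtype=np.int8)
        new_H[0::2, :S] = np.vstack(acc1) if len(acc1) > 1 else acc1[0]
        new_H[1::2, :S] = np.vstack(acc2) if len(acc2) > 1 else acc2[0]
        if n_new:
            pos_new = rng.uniform(0, cfg.L, n_new)
            carriers = rng.integers(0, 2 * next_n, n_new)
            s_new = np.zeros(n_new)
            if sel_on:
                exonic = _in_exon(pos_new, self.exon_mask)
                deleterious = exonic & (rng.random(n_new) < cfg.p_deleterious)
                nd = int(deleterious.sum())
                if nd:
                    s_new[deleterious] = -rng.gamma(
                        cfg.dfe_shape, cfg.dfe_mean_s / cfg.dfe_shape, nd)
            new_H[carriers, S + np.arange(n_new)] = 1
            positions = np.concatenate([positions, pos_new])
            sel_arr = np.concatenate([self.sel[:S], s_new])
        else:
            sel_arr = self.sel[:S].copy()

        # drop fixed and lost columns
        counts = np.count_nonzero(new_H, axis=0)
        fixed = counts == 2 * next_n
        keep = (counts > 0) & ~fixed
        if fixed.any():
            self.fixed_del += int((sel_arr[fixed] < 0).sum())
            self.fixed_neutral += int((sel_arr[fixed] == 0).sum())
        self.H = new_H[:, keep]
        self.positions = positions[keep]
        self.sel = sel_arr[keep]
        self.S = self.H.shape[1]

    def spawn_subpop(self, n_dip, selfing_rate):
        """Found a subpopulation: one reproduction step into a new deme."""
        child = _Pop.__new__(_Pop)
        child.cfg = self.cfg
        child.rng = self.rng
        child.exon_mask = self.exon_mask
        child.neutral_only = self.neutral_only
        child.H = self.H
        child.positions = self.positions
        child.sel = self.sel
        child.S = self.S
        child.fixed_neutral = self.fixed_neutral
        child.fixed_del = self.fixed_del
        child.rL = self.rL
        child.muL = self.muL
        child.step(n_dip, selfing_rate)
        return child

    # -- summaries -------------------------------------------------------
    def sample_summary(self, n_sample):
        cfg, rng = self.cfg, self.rng
        n = min(n_sample, self.n_dip)
        idx = rng.choice(self.n_dip, size=n, replace=False)
        hap_rows = np.empty(2 * n, dtype=np.intp)
        hap_rows[0::2] = 2 * idx
        hap_rows[1::2] = 2 * idx + 1
        Hs = self.H[hap_rows, : self.S]
        m = 2 * n
        ac = Hs.sum(axis=0, dtype=np.int64)
        seg = (ac > 0) & (ac < m)
        pi = float((2.0 * ac[seg] * (m - ac[seg]) / (m * (m - 1.0))).sum() / cfg.L)
        geno = Hs[0::2] + Hs[1::2]
        het = float((geno == 1).sum(axis=1).mean() / cfg.L)
        del_cols = self.sel[: self.S] < 0
        het_del = float((geno[:, del_cols] == 1).sum(axis=1).mean())
        hom_del = float((geno[:, del_cols] == 2).sum(axis=1).mean()) + self.fixed_del
        return pi, het, het_del, hom_del


ARM_SELFING, ARM_OUTCROSSING, ARM_SNM = "selfing", "outcrossing", "SNM"


@dataclass
class SimResult:
    table: pd.DataFrame          # replicate, arm, pi, het, n_het_del, n_hom_del
    config: SimConfig
    seed: int
    failed_replicates: list = field(default_factory=list)

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def metadata(self) -> dict:
        return {"config": asdict(self.config), "seed": self.seed,
                "failed_replicates": self.failed_replicates}


def _one_replicate(cfg: SimConfig, seed_seq):
    rng = np.random.default_rng(seed_seq)
    exon_mask = make_exon_mask(cfg, rng)
    n_bot = max(1, round(cfg.bottleneck_frac * cfg.N))
    n_sub = max(1, round(cfg.split_frac * cfg.N))
    bottleneck_dur = cfg.bottleneck_start_bp - cfg.split_bp

    pop = _Pop(cfg.N, cfg, rng, exon_mask)
    for _ in range(cfg.burn_in_gens):
        pop.step(cfg.N, 0.0)
    for _ in range(bottleneck_dur):
        pop.step(n_bot, 0.0)
    self_pop = pop.spawn_subpop(n_sub, cfg.selfing_rate_selfing_arm)
    out_pop = pop.spawn_subpop(n_sub, cfg.selfing_rate_outcrossing_arm)
    for _ in range(cfg.split_bp - 1):
        self_pop.step(n_sub, cfg.selfing_rate_selfing_arm)
        out_pop.step(n_sub, cfg.selfing_rate_outcrossing_arm)

    snm = _Pop(cfg.N, cfg, rng, exon_mask, neutral_only=True)
    snm_gens = (cfg.snm_generations if cfg.snm_generations is not None
                else cfg.total_gens)
    for _ in range(snm_gens):
        snm.step(cfg.N, 0.0)

    rows = []
    for arm, p in ((ARM_SELFING, self_pop), (ARM_OUTCROSSING, out_pop),
                   (ARM_SNM, snm)):
        pi, het, hd, homd = p.sample_summary(cfg.n_sample)
        rows.append((arm, pi, het, hd, homd))
    return rows


def run_sim(cfg: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Run ``cfg.replicates`` forward simulations of the three arms.

    Deterministic under (cfg, seed); a replicate whose population collapses
    is retried with a fresh derived seed up to ``cfg.max_retries`` times and
    recorded in ``failed_replicates``.
    """
    cfg = cfg or SimConfig()
    rows = []
    failed = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(cfg.replicates)
    for rep, ss in enumerate(streams):
        attempt = 0
        while True:
            try:
                arm_rows = _one_replicate(cfg, ss if attempt == 0 else ss.spawn(1)[0])
                break
            except SimulationCollapse:
                attempt += 1
                failed.append((rep, attempt))
                if attempt > cfg.max_retries:
                    raise
        for arm, pi, het, hd, homd in arm_rows:
            rows.append((rep, arm, pi, het, hd, homd))
    table = pd.DataFrame(rows, columns=["replicate", "arm", "pi", "het",
                                        "n_het_del", "n_hom_del"])
    return SimResult(table=table, config=cfg, seed=seed, failed_replicates=failed)


def compare_arms(res: SimResult) -> pd.DataFrame:
    """Paired replicate comparisons of diversity between arms.

    Reports mean pi per arm and Wilcoxon signed-rank p-values for
    selfing-vs-outcrossing and outcrossing-vs-SNM (replicates share their
    ancestral history, hence paired).
    """
    from scipy.stats import wilcoxon

    t = res.table.pivot(index="replicate", columns="arm", values="pi")
    if len(t) < 5:
        raise ValueError("need >= 5 replicates for arm comparison")
    out = []
    for a, b in ((ARM_SELFING, ARM_OUTCROSSING), (ARM_OUTCROSSING, ARM_SNM)):
        d = t[a] - t[b]
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(wilcoxon(t[a], t[b]).pvalue)
        out.append((a, b, float(t[a].mean()), float(t[b].mean()),
                    float(d.mean()), p))
    return pd.DataFrame(out, columns=["arm_a", "arm_b", "mean_pi_a",
                                      "mean_pi_b", "mean_diff", "p_value"])
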