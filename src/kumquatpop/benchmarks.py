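"""Study-condition evaluation runs shared by the test suite and the
reproduction script.

Each function regenerates its inputs from the synthetic-cohort generator
(or the forward simulator) under the study conditions, executes the method
under test and returns the measured quantities. All randomness derives
from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .fwdsim import (SimConfig, compare_arms, run_sim, ARM_OUTCROSSING,
                     ARM_SELFING, ARM_SNM)
from .introgression import (d_statistic, derived_freq_table, fd_windows,
                            identify_ssms, introgression_dosage)
from .load import count_load
from .niche import niche_overlap, pca_variance
from .popstats import genomewide_fst, usfs
from .vcfio import polarize


def _seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------------------
# Introgression statistics under the no-flow null


def dstat_null_calibration(n_cohorts: int = 50, seed: int = 0,
                           n_sites: int = 20_000, block_bp: int = 500_000,
                           fd_window_bp: int = 100_000):
    """D-statistic Z scores and signed windowed f_d means over no-flow
    cohorts (star-like drift, no planted tracts).

    Sites are dense enough (~200 per window) for the per-window ratio to be
    stable, mirroring the real panel's variant density.
    """
    zs, fd_means = [], []
    drift = {g: 0.05 for g in synth.GROUPS}
    for s in _seeds(seed, n_cohorts):
        cfg = synth.CohortConfig(n_sites=n_sites, drift=drift,
                                 apomict_groups=())
        gm, pm, _ = synth.simulate_cohort(cfg, seed=s)
        gm = polarize(gm, pm)
        ft = derived_freq_table(gm, pm, ["WILDSEX1", "WILDSEX2", "CULAPO",
                                         "OUTGROUP"])
        r = d_statistic(ft, "WILDSEX1", "WILDSEX2", "CULAPO", "OUTGROUP",
                        block_bp=block_bp)
        zs.append(r.Z)
        fd = fd_windows(ft, "WILDSEX1", "WILDSEX2", "CULAPO", "OUTGROUP",
                        window_bp=fd_window_bp, mask_negative_d=False)
        fd_means.append(np.nanmean(fd["value"]))
    zs = np.array(zs)
    return {
        "z_scores": zs,
        "frac_abs_z_below_3": float((np.abs(zs) < 3).mean()),
        "fd_signed_window_mean": float(np.mean(fd_means)),
    }


def introgression_recovery(n_seeds: int = 20, seed: int = 0,
                           fraction: float = 0.25):
    """Recover a planted per-sample introgression fraction by SSM dosage."""
    ests = []
    for s in _seeds(seed, n_seeds):
        cfg = synth.CohortConfig(
            introgression={"WILDAPO": ("CULAPO", fraction)})
        gm, pm, truth = synth.simulate_cohort(cfg, seed=s)
        ssm = identify_ssms(gm, pm, ["CULAPO", "CULSEX"], "WILDSEX1")
        res = introgression_dosage(gm, ssm, pm.samples_of("WILDAPO"))
        ests.append(res["proportion"].mean())
    ests = np.array(ests)
    return {
        "planted_fraction": fraction,
        "mean_estimate": float(ests.mean()),
        "mean_abs_error": float(np.abs(ests - fraction).mean()),
    }


def load_recovery(seed: int = 0):
    """Planted heterozygous/homozygous deleterious counts vs the report."""
    gm, pm, truth = synth.simulate_cohort(seed=seed)
    rep = count_load(gm, pm).set_index("sample")
    mismatch = sum(
        int(rep.loc[s, "n_het_del"] != truth.het_del[s])
        + int(rep.loc[s, "n_hom_del"] != truth.hom_del[s])
        for s in gm.samples)
    return {"n_samples": gm.n_samples, "count_mismatches": mismatch}


# ---------------------------------------------------------------------------
# Forward-simulation closed forms and the selfing/outcrossing contrast


def fwdsim_neutral_pi(replicates: int = 20, seed: int = 0):
    """Constant-N neutral equilibrium diversity vs 4*N*mu (the SNM arm)."""
    cfg = SimConfig(N=100, burn_in=5, bottleneck_start_bp=20, split_bp=10,
                    L=100_000, mu=2e-6, r=1e-5, deleterious=False,
                    snm_generations=1000, replicates=replicates, n_sample=20)
    res = run_sim(cfg, seed=seed)
    snm = res.table[res.table["arm"] == ARM_SNM]["pi"]
    expected = 4 * cfg.N * cfg.mu
    return {"mean_pi": float(snm.mean()), "expected_pi": expected,
            "rel_error": float(abs(snm.mean() - expected) / expected),
            "replicates": replicates}


def fwdsim_selfing_ratio(replicates: int = 25, seed: int = 0):
    """Neutral constant-size selfing vs outcrossing diversity ratio (~0.5)."""
    cfg = SimConfig(N=100, burn_in=1000, bottleneck_frac=1.0, split_frac=1.0,
                    bottleneck_start_bp=620, split_bp=600, L=100_000,
                    mu=2e-6, r=1e-5, deleterious=False, snm_generations=1,
                    replicates=replicates)
    res = run_sim(cfg, seed=seed)
    t = res.table.pivot(index="replicate", columns="arm", values="pi")
    return {"ratio": float(t[ARM_SELFING].mean() / t[ARM_OUTCROSSING].mean()),
            "replicates": replicates}


def fwdsim_ordering(replicates: int = 30, seed: int = 0):
    """Scaled-down bottleneck-and-split contrast: diversity ordering
    selfing < outcrossing < SNM with rank tests.

    N = 500 with every schedule time halved relative to the N = 1000
    demography (burn-in 10N, bottleneck and split durations scale with N);
    the SNM control runs 10N generations at constant N.
    """
    cfg = SimConfig(N=500, burn_in=5000, bottleneck_start_bp=5000,
                    split_bp=1000, snm_generations=5000,
                    replicates=replicates)
    res = run_sim(cfg, seed=seed)
    comp = compare_arms(res).set_index(["arm_a", "arm_b"])
    t = res.table.pivot(index="replicate", columns="arm", values="pi")
    return {
        "mean_pi_selfing": float(t[ARM_SELFING].mean()),
        "mean_pi_outcrossing": float(t[ARM_OUTCROSSING].mean()),
        "mean_pi_snm": float(t[ARM_SNM].mean()),
        "p_selfing_vs_outcrossing": float(
            comp.loc[(ARM_SELFING, ARM_OUTCROSSING), "p_value"]),
        "p_outcrossing_vs_snm": float(
            comp.loc[(ARM_OUTCROSSING, ARM_SNM), "p_value"]),
        "replicates": replicates,
    }


# ---------------------------------------------------------------------------
# uSFS neutrality


def usfs_neutral_gof(seed: int = 0, n_diploids: int = 10,
                     min_sites: int = 5000):
    """Chi-square goodness of fit of the 10-bin uSFS against the neutral
    1/i expectation, on coalescent-simulated genotypes (20 haplotypes)."""
    import msprime
    from scipy.stats import chisquare

    from .vcfio import GenotypeMatrix, PopulationMap, ANC_REF

    n_hap = 2 * n_diploids
    rng = np.random.default_rng(seed)
    pop_size = 1e4
    reps = msprime.sim_ancestry(samples=n_diploids, population_size=pop_size,
                                num_replicates=8 * min_sites,
                                random_seed=max(seed, 1))
    # one segregating site per independent genealogy: accept a tree with
    # probability proportional to its total branch length (a site falls on
    # long trees more often), then place the mutation on a branch drawn
    # proportional to branch length — the exact infinite-sites site
    # distribution, independent across sites, so the binned counts are a
    # true multinomial sample and the chi-square test is calibrated
    exp_total = 4 * pop_size * np.sum(1.0 / np.arange(1, n_hap))
    cap = 3.0 * exp_total
    cols = []
    for ts in reps:
        tree = ts.first()
        if rng.random() >= tree.total_branch_length / cap:
            continue
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        lens = np.array([tree.branch_length(u) for u in nodes])
        u = nodes[rng.choice(len(nodes), p=lens / lens.sum())]
        col = np.zeros(n_hap, dtype=np.int8)
        col[list(tree.samples(u))] = 1
        cols.append(col)
        if len(cols) >= min_sites:
            break
    H = np.stack(cols, axis=1)
    gt = (H[0::2] + H[1::2]).astype(np.int8)
    S = gt.shape[1]
    gm = GenotypeMatrix(
        samples=[f"d{i}" for i in range(n_diploids)],
        chrom=np.full(S, "chr1", dtype=object), pos=np.arange(1, S + 1),
        ref=np.full(S, "A", dtype=object), alt=np.full(S, "T", dtype=object),
        gt=gt, anc=np.full(S, ANC_REF, dtype=np.int8))
    pm = PopulationMap({s: "G" for s in gm.samples})
    spec = usfs(gm, pm, "G")
    counts = spec["count"].to_numpy()
    # neutral expectation: P(i derived copies) ~ 1/i, i = 1..n-1; bin k of
    # 10 collects i in {2k+1, 2k+2} (i = n never occurs in a sample tree)
    probs = np.array([1 / (2 * k + 1) + (1 / (2 * k + 2) if 2 * k + 2 < n_hap
                                         else 0.0) for k in range(10)])
    probs /= probs.sum()
    stat, p = chisquare(counts, counts.sum() * probs)
    return {"n_sites": int(counts.sum()), "chi2": float(stat),
            "p_value": float(p)}


# ---------------------------------------------------------------------------
# Niche overlap on the emulated occurrence panel


def niche_panel(seed: int = 0, draws: int = 100_000):
    """PCA and plug-in + Bayesian overlap on the emulated 244/152 panel."""
    tbl = synth.simulate_occurrences(seed=seed)
    _, pct = pca_variance(tbl)
    plug = niche_overlap(tbl, "wild", "cultivated", estimator="plugin",
                         draws=draws, seed=seed)
    bay = niche_overlap(tbl, "wild", "cultivated", estimator="bayesian",
                        draws=50_000, posterior_draws=500, seed=seed + 1)
    return {
        "pc1_pct": float(pct[0]), "pc2_pct": float(pct[1]),
        "overlap_wild_in_cultivated": plug.a_in_b,
        "overlap_cultivated_in_wild": plug.b_in_a,
        "overlap_bayes_wild_in_cultivated": bay.a_in_b,
        "overlap_bayes_cultivated_in_wild": bay.b_in_a,
    }


def cohort_headline_stats(seed: int = 0):
    """Genome-wide differentiation and dosage numbers from one
    study-condition cohort with the planted 25% introgression."""
    cfg = synth.CohortConfig(introgression={"WILDAPO": ("CULAPO", 0.25)})
    gm, pm, truth = synth.simulate_cohort(cfg, seed=seed)
    gm = polarize(gm, pm)
    ssm = identify_ssms(gm, pm, ["CULAPO", "CULSEX"], "WILDSEX1")
    dos = introgression_dosage(gm, ssm, pm.samples_of("WILDAPO"))
    return {
        "fst_wildsex1_wildsex2": genomewide_fst(gm, pm, "WILDSEX1", "WILDSEX2"),
        "fst_wildsex1_wildapo": genomewide_fst(gm, pm, "WILDSEX1", "WILDAPO"),
        "n_ssms": len(ssm),
        "mean_wildapo_introgression": float(dos["proportion"].mean()),
    }
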