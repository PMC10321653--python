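"""Variant I/O and the polarized genotype matrix.

Every downstream statistic consumes a :class:`GenotypeMatrix`: diploid
genotypes over biallelic SNPs coded as the count of ALT alleles (0/1/2, -1
for missing), optionally phased, together with per-site quality fields and
an ancestral-allele assignment inferred from an outgroup.

Coordinates are 1-based at the VCF boundary (``pos``) and 0-based half-open
everywhere windows are formed (a site at VCF position p lies in window
[start, end) iff start <= p-1 < end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("kumquatpop")

# annotation codes
ANN_NONE, ANN_DELETERIOUS, ANN_TOLERATED = 0, 1, 2
# ancestral-allele codes
ANC_UNKNOWN, ANC_REF, ANC_ALT = -1, 0, 1
MISSING = -1


class VcfIOError(RuntimeError):
    """Unreadable or malformed variant input."""


class PolarizationError(RuntimeError):
    """Ancestral-allele inference requested without usable outgroup."""


@dataclass
class PopulationMap:
    """Sample -> group assignment with a designated outgroup label."""

    assignment: dict[str, str]
    outgroup_label: str = "OUTGROUP"

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    @classmethod
    def from_tsv(cls, path, outgroup_label: str = "OUTGROUP") -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["group"])), outgroup_label)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, g in self.assignment.items():
                fh.write(f"{s}\t{g}\n")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes of ``samples`` over ordered biallelic sites.

    Attributes
    ----------
    gt : int8 array, shape (n_samples, n_sites)
        ALT-allele dosage per call, ``-1`` = missing. Half-missing diploid
        calls (``./1``) are treated as missing.
    hap : int8 array, shape (n_samples, 2, n_sites) or None
        Phased haplotypes where available; ``-1`` where unphased/missing.
        At every phased non-missing call ``hap.sum(axis=1) == gt``.
    anc : int8 array, (n_sites,)
        ``0`` REF ancestral, ``1`` ALT ancestral, ``-1`` unknown.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    hap: np.ndarray | None = None
    anc: np.ndarray | None = None
    qd: np.ndarray | None = None
    qual: np.ndarray | None = None
    mq: np.ndarray | None = None
    depth: np.ndarray | None = None
    annotation: np.ndarray | None = None

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), len(self.pos)):
            raise ValueError("genotype dimensions must be |samples| x |sites|")
        if self.anc is None:
            self.anc = np.full(self.n_sites, ANC_UNKNOWN, dtype=np.int8)
        if self.annotation is None:
            self.annotation = np.zeros(self.n_sites, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"sample {e} not in matrix") from None

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        pick = lambda a: None if a is None else a[..., idx] if a.ndim > 1 else a[idx]
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx], pos=self.pos[idx],
            ref=self.ref[idx], alt=self.alt[idx],
            gt=self.gt[:, idx],
            hap=None if self.hap is None else self.hap[:, :, idx],
            anc=self.anc[idx],
            qd=pick(self.qd), qual=pick(self.qual), mq=pick(self.mq),
            depth=None if self.depth is None else self.depth[:, idx],
            annotation=self.annotation[idx],
        )

    def derived_dosage(self) -> np.ndarray:
        """Derived-allele dosage view: float array, NaN where the genotype is
        missing or the ancestral allele is unknown."""
        d = self.gt.astype(float)
        d[self.gt == MISSING] = np.nan
        flip = self.anc == ANC_ALT
        d[:, flip] = 2.0 - d[:, flip]
        d[:, self.anc == ANC_UNKNOWN] = np.nan
        return d


# ---------------------------------------------------------------------------
# VCF reading / writing


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file.

    Multiallelic records, indels and non-SNPs are skipped; phased pipes are
    preserved in ``hap``; missing calls stay missing.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:
        raise VcfIOError(f"cannot read VCF {path}: {e}") from e
    samples = list(vcf.samples)
    n = len(samples)
    chrom, pos, ref, alt = [], [], [], []
    qd, qual, mq = [], [], []
    gts, haps, depths = [], [], []
    it = vcf(region) if region else vcf
    for v in it:
        if len(v.ALT) != 1:
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        qd.append(_info_float(v, "QD"))
        mq.append(_info_float(v, "MQ"))
        g = np.array(v.genotypes, dtype=object)  # rows: [a, b, phased]
        a = np.array([row[0] for row in g], dtype=np.int16)
        b = np.array([row[1] for row in g], dtype=np.int16)
        ph = np.array([bool(row[2]) for row in g])
        code = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        gts.append(code)
        h = np.full((n, 2), MISSING, dtype=np.int8)
        ok = ph & (a >= 0) & (b >= 0)
        h[ok, 0] = a[ok]
        h[ok, 1] = b[ok]
        haps.append(h)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            depths.append(np.full(n, -1, dtype=np.int32))
        else:
            depths.append(np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
    vcf.close()
    if not pos:
        log.warning("no biallelic SNPs found in %s", path)
        return GenotypeMatrix(samples=samples,
                              chrom=np.array([], dtype=object),
                              pos=np.array([], dtype=np.int64),
                              ref=np.array([], dtype=object),
                              alt=np.array([], dtype=object),
                              gt=np.zeros((n, 0), dtype=np.int8),
                              hap=np.zeros((n, 2, 0), dtype=np.int8))
    gt = np.stack(gts, axis=1)
    hap = np.stack(haps, axis=2)
    depth = np.stack(depths, axis=1)
    if np.all(depth < 0):
        depth = None
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object), pos=np.array(pos),
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        gt=gt, hap=hap,
        qd=np.array(qd), qual=np.array(qual), mq=np.array(mq),
        depth=depth,
    )


def _info_float(v, key):
    x = v.INFO.get(key)
    return float(x) if x is not None else np.nan


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        fmt = "GT:DP" if gm.depth is not None else "GT"
        for j in range(gm.n_sites):
            info = []
            if gm.qd is not None and np.isfinite(gm.qd[j]):
                info.append(f"QD={gm.qd[j]:g}")
            if gm.mq is not None and np.isfinite(gm.mq[j]):
                info.append(f"MQ={gm.mq[j]:g}")
            qual = "." if gm.qual is None or not np.isfinite(gm.qual[j]) else f"{gm.qual[j]:g}"
            cells = []
            for i in range(gm.n_samples):
                g = gm.gt[i, j]
                if g == MISSING:
                    s = "./."
                elif gm.hap is not None and gm.hap[i, 0, j] >= 0:
                    s = f"{gm.hap[i, 0, j]}|{gm.hap[i, 1, j]}"
                else:
                    s = {0: "0/0", 1: "0/1", 2: "1/1"}[int(g)]
                if gm.depth is not None:
                    d = gm.depth[i, j]
                    s += ":" + (str(int(d)) if d >= 0 else ".")
                cells.append(s)
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t"
                     f"{qual}\tPASS\t{';'.join(info) or '.'}\t{fmt}\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterConfig:
    """Site/call retention thresholds.

    All inequalities are strict, matching the upstream pipeline convention:
    keep sites with QD > 2, QUAL > 40, MQ > 30; keep calls with
    min_depth < depth < max_depth; keep sites with missing-call fraction
    strictly below ``max_missing``.
    """

    min_qd: float = 2.0
    min_qual: float = 40.0
    min_mq: float = 30.0
    min_depth: float = 2
    max_depth: float = 100
    max_missing: float = 0.2

    def __post_init__(self):
        for name in ("min_qd", "min_qual", "min_mq", "min_depth",
                     "max_depth", "max_missing"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not np.isfinite(v):
                raise ValueError(f"filter threshold {name} must be numeric, got {v!r}")

    @classmethod
    def from_file(cls, path) -> "FilterConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                k, _, v = line.partition("=")
                try:
                    kv[k.strip()] = float(v.strip())
                except ValueError:
                    raise ValueError(f"non-numeric filter threshold: {line!r}")
        return cls(**kv)


def filter_sites(gm: GenotypeMatrix, thresholds: FilterConfig | None = None) -> GenotypeMatrix:
    """Apply site-quality, call-depth and missingness filters.

    Sites failing QD/QUAL/MQ are dropped; calls outside the open depth
    interval are set missing; sites with >= max_missing missing calls are
    then dropped. Site order is preserved. Absent quality fields pass.
    """
    thr = thresholds or FilterConfig()
    passing = lambda a, t: (np.ones(gm.n_sites, bool) if a is None
                            else ~(np.nan_to_num(a, nan=t + 1) <= t))
    keep = passing(gm.qd, thr.min_qd) & passing(gm.qual, thr.min_qual) & passing(gm.mq, thr.min_mq)

    gt = gm.gt.copy()
    hap = None if gm.hap is None else gm.hap.copy()
    if gm.depth is not None:
        bad = (gm.depth >= 0) & ((gm.depth <= thr.min_depth) | (gm.depth >= thr.max_depth))
        gt[bad] = MISSING
        if hap is not None:
            hap[np.repeat(bad[:, None, :], 2, axis=1)] = MISSING
    miss_rate = (gt == MISSING).mean(axis=0)
    keep &= miss_rate < thr.max_missing
    out = replace(gm, gt=gt, hap=hap)
    return out.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Polarization


def polarize(gm: GenotypeMatrix, pm: PopulationMap) -> GenotypeMatrix:
    """Assign per-site ancestral alleles from outgroup genotypes.

    A site is polarized iff at least one outgroup call is non-missing and
    every non-missing outgroup call is homozygous for the same allele; that
    allele becomes ancestral. Polymorphic or fully-missing outgroups give
    ``anc = unknown``. Genotype codes are never altered.
    """
    og = [s for s in gm.samples if pm.assignment.get(s) == pm.outgroup_label]
    if not og:
        raise PolarizationError("no outgroup samples present in matrix")
    sub = gm.gt[gm.sample_index(og)]  # (n_og, S)
    nonmiss = sub != MISSING
    n_nm = nonmiss.sum(axis=0)
    any_het = ((sub == 1) & nonmiss).any(axis=0)
    all_ref = np.where(nonmiss, sub == 0, True).all(axis=0)
    all_alt = np.where(nonmiss, sub == 2, True).all(axis=0)
    anc = np.full(gm.n_sites, ANC_UNKNOWN, dtype=np.int8)
    anc[(n_nm > 0) & ~any_het & all_ref] = ANC_REF
    anc[(n_nm > 0) & ~any_het & all_alt] = ANC_ALT
    return replace(gm, anc=anc)


# ---------------------------------------------------------------------------
# Annotations


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a per-site annotation TSV (chrom, pos, score-or-label)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "score"], comment="#",
                     dtype={"chrom": str})
    return df


def attach_annotations(gm: GenotypeMatrix, classes: pd.DataFrame) -> GenotypeMatrix:
    """Set per-site annotation codes from a classified table.

    ``classes`` must have columns chrom, pos, cls with cls in
    {deleterious, tolerated}. Sites absent from the table stay unannotated.
    """
    code = {"deleterious": ANN_DELETERIOUS, "tolerated": ANN_TOLERATED}
    lut = {(c, p): code[k] for c, p, k in
           zip(classes["chrom"], classes["pos"], classes["cls"])}
    ann = np.array([lut.get((c, p), ANN_NONE)
                    for c, p in zip(gm.chrom, gm.pos)], dtype=np.int8)
    return replace(gm, annotation=ann)
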