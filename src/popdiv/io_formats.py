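"""Genotype container, VCF I/O, the site-level hard filters, and the
shared/unique SNP partition.

Coordinates: VCF is 1-based inclusive on disk; ``GenotypeMatrix.pos``
keeps the 1-based VCF positions, while all window arithmetic elsewhere in
the package is 0-based half-open.  BED input stays 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SiteFilterSpec",
    "read_vcf",
    "write_vcf",
    "read_pop_map",
    "write_pop_map",
    "filter_sites",
    "snp_partition",
    "read_bed",
]

MISSING = -1  # genotype code for a missing diploid call


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (ALT-dosage 0/1/2, -1 missing) by sample x site.

    ``genotypes`` has shape (n_samples, n_sites).  ``chrom``/``pos`` give
    each site's contig and 1-based position, strictly increasing within a
    contig.  ``pop_labels`` assigns each sample to a population.  Optional
    per-site ``depth`` and ``rms_mq`` annotations feed the hard filters.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    rms_mq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if len(self.pop_labels) != len(self.sample_ids):
            raise ValueError("pop_labels and sample_ids lengths differ")
        if self.genotypes.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != "
                f"({len(self.sample_ids)}, {len(self.pos)})"
            )
        if len(self.chrom) != len(self.pos):
            raise ValueError("chrom and pos lengths differ")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or -1 (missing)")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.pop_labels))

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.pop_labels) if p == pop])
        if idx.size == 0:
            raise KeyError(f"no samples in population {pop!r}")
        return idx

    def take_sites(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return replace(
            self,
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            genotypes=self.genotypes[:, keep],
            depth=None if self.depth is None else self.depth[keep],
            rms_mq=None if self.rms_mq is None else self.rms_mq[keep],
        )

    def allele_counts(self, sample_idx=None):
        """(derived_count, called_copies) per site over a sample subset."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = g != MISSING
        derived = np.where(called, g, 0).sum(axis=0)
        return derived.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class SiteFilterSpec:
    """Hard site filters; each threshold is individually disable-able
    (set to None).  Defaults: depth in [5, 100], RMS mapping quality >= 20,
    pooled minor-allele frequency >= 0.05, missingness <= 0.1.
    """

    min_depth: float | None = 5
    max_depth: float | None = 100
    min_rms_mq: float | None = 20
    min_maf: float | None = 0.05
    max_missing: float | None = 0.1

    def __post_init__(self) -> None:
        if self.min_maf is not None and not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.max_missing is not None and not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must lie in [0, 1]")
        if (
            self.min_depth is not None
            and self.max_depth is not None
            and self.min_depth > self.max_depth
        ):
            raise ValueError("min_depth > max_depth")


def read_pop_map(path) -> dict[str, str]:
    """Read a two-column TSV: sample_id <TAB> population."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def write_pop_map(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(gm.sample_ids, gm.pop_labels):
            fh.write(f"{s}\t{p}\n")


def read_vcf(path, pop_map) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    ``pop_map`` is a path to a sample->population TSV or a dict.
    Multiallelic and indel records are skipped (counted in the log);
    half-missing calls count as missing.  DP and MQ INFO fields, when
    present on every record, populate the depth / RMS-MQ annotations.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pop_map]
    if missing_samples:
        raise KeyError(
            f"samples absent from population map: {missing_samples}"
        )

    chroms, poss, gts, depths, mqs = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        # gts012: 0/1/2 dosage, 3 = unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        depths.append(rec.INFO.get("DP"))
        mqs.append(rec.INFO.get("MQ"))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    n_sites = len(poss)
    gm = GenotypeMatrix(
        sample_ids=samples,
        pop_labels=[pop_map[s] for s in samples],
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        genotypes=(
            np.stack(gts, axis=1) if n_sites else
            np.zeros((len(samples), 0), dtype=np.int8)
        ),
        depth=(
            np.array([np.nan if d is None else d for d in depths], float)
            if n_sites and any(d is not None for d in depths) else None
        ),
        rms_mq=(
            np.array([np.nan if m is None else m for m in mqs], float)
            if n_sites and any(m is not None for m in mqs) else None
        ),
    )
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a VCF v4.2 with placeholder REF=A / ALT=T alleles.

    Depth and RMS-MQ annotations, when present, are emitted as DP / MQ
    INFO fields so a round-trip preserves them.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=popdiv\n')
        for c in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            info = []
            if gm.depth is not None and np.isfinite(gm.depth[j]):
                info.append(f"DP={int(round(gm.depth[j]))}")
            if gm.rms_mq is not None and np.isfinite(gm.rms_mq[j]):
                info.append(f"MQ={gm.rms_mq[j]:g}")
            fields = [
                str(gm.chrom[j]),
                str(int(gm.pos[j])),
                ".",
                "A",
                "T",
                ".",
                "PASS",
                ";".join(info) if info else ".",
                "GT",
            ] + [_GT_STR[int(g)] for g in gm.genotypes[:, j]]
            fh.write("\t".join(fields) + "\n")


def filter_sites(gm: GenotypeMatrix, spec: SiteFilterSpec = SiteFilterSpec()) -> GenotypeMatrix:
    """Apply the hard site filters; a site must satisfy every enabled one.

    MAF is pooled over all samples' non-missing allele copies; missingness
    is the fraction of samples with a missing genotype.  Depth / MQ
    filters require the corresponding annotation.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    if spec.min_depth is not None or spec.max_depth is not None:
        if gm.depth is None:
            raise ValueError("depth filter enabled but no depth annotation")
        if spec.min_depth is not None:
            keep &= gm.depth >= spec.min_depth
        if spec.max_depth is not None:
            keep &= gm.depth <= spec.max_depth
    if spec.min_rms_mq is not None:
        if gm.rms_mq is None:
            raise ValueError("MQ filter enabled but no RMS-MQ annotation")
        keep &= gm.rms_mq >= spec.min_rms_mq
    if spec.min_maf is not None:
        derived, copies = gm.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(copies > 0, derived / np.maximum(copies, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        keep &= (maf >= spec.min_maf) & (copies > 0)
    if spec.max_missing is not None:
        miss = (gm.genotypes == MISSING).mean(axis=0)
        keep &= miss <= spec.max_missing
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_sites: removed %d of %d sites", n_removed, gm.n_sites)
    return gm.take_sites(keep)


def snp_partition(gm: GenotypeMatrix) -> dict[str, int]:
    """Count sites polymorphic in both populations vs private to one.

    A site is "present" in a population iff it is polymorphic within that
    population's samples (both alleles observed there).  Returns
    ``{"shared": ., "unique_<pop>": ., "absent": .}``; the counts sum to
    the total number of sites.
    """
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("snp_partition needs >= 2 populations")
    present = {}
    for pop in pops:
        derived, copies = gm.allele_counts(gm.sample_indices(pop))
        present[pop] = (derived > 0) & (derived < copies)
    stack = np.stack([present[p] for p in pops])
    n_present = stack.sum(axis=0)
    out = {"shared": int((n_present >= 2).sum())}
    for i, pop in enumerate(pops):
        out[f"unique_{pop}"] = int((stack[i] & (n_present == 1)).sum())
    out["absent"] = int((n_present == 0).sum())
    return out


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (0-based half-open) as (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from e
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            out.append((parts[0], start, end, name))
    return out
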