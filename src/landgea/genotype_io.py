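"""Genotype matrix I/O, filtering, imputation, and candidate annotation.

Genotypes are stored as alternate-allele counts (0, 1, 2) per diploid
individual and bi-allelic SNP, with ``MISSING = -1`` as the sentinel.
Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

_LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele count matrix.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, one per row of ``calls``.
    loci : pandas.DataFrame
        One row per locus with columns ``chrom`` (str), ``pos`` (1-based int),
        ``ref`` and ``alt`` (single bases). Sorted by (chrom, pos), no
        duplicate coordinates.
    calls : numpy.ndarray
        ``(n_samples, n_loci)`` int8 array with values in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, 2, MISSING}")
        self.loci = self.loci.reset_index(drop=True)
        if (self.loci["pos"] < 1).any():
            raise ValueError("locus positions must be >= 1 (1-based)")
        key = self.loci[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) locus coordinates")
        if not key.equals(key.sort_values(["chrom", "pos"]).reset_index(drop=True)):
            raise ValueError("loci must be sorted by (chrom, pos)")

    # -- summaries -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def allele_frequency(self) -> np.ndarray:
        """ALT allele frequency per locus over non-missing calls."""
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per locus (non-missing calls)."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def het_rate(self) -> np.ndarray:
        """Fraction of heterozygous calls per locus among non-missing."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        het = (self.calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def sample_callrate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def missing_fraction(self) -> float:
        return float((self.calls == MISSING).mean())

    # -- slicing ---------------------------------------------------------
    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.loci.copy(), self.calls[idx]
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.samples), self.loci.iloc[idx], self.calls[:, idx]
        )


@dataclass(frozen=True)
class VariantFilterSpec:
    """Variant/sample filter thresholds.

    All three thresholds are exclusive in the sense used by TASSEL-style
    filtering: loci with MAF <= ``max_maf_excl`` or heterozygote rate
    >= ``max_het_rate_excl`` are removed, as are samples with genotyping
    rate <= ``min_sample_callrate_excl``.
    """

    max_maf_excl: float = 0.05
    max_het_rate_excl: float = 0.50
    min_sample_callrate_excl: float = 0.80

    def __post_init__(self) -> None:
        for name in ("max_maf_excl", "max_het_rate_excl", "min_sample_callrate_excl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only bi-allelic SNP records are retained; multi-allelic or non-SNP
    records are skipped with a logged count. Diploid GT is mapped
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; any missing allele -> MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(g)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        columns=_LOCUS_COLUMNS,
    )
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    return GenotypeMatrix(samples, loci.iloc[order], calls[:, order])


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.loci["chrom"]):
            max_pos = int(G.loci.loc[G.loci["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, locus in enumerate(G.loci.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(g)] for g in G.calls[:, j])
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

def filter_variants(
    G: GenotypeMatrix, spec: VariantFilterSpec | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply sample-callrate, MAF, and heterozygosity filters in that order.

    Order matters: per-locus statistics are recomputed on the retained
    samples. Returns the filtered matrix and a report of counts removed at
    each step.
    """
    spec = spec or VariantFilterSpec()
    if G.n_samples < 2:
        raise ValueError("filter_variants requires at least 2 samples")

    keep_samples = np.flatnonzero(G.sample_callrate() > spec.min_sample_callrate_excl)
    if keep_samples.size == 0:
        raise ValueError("all samples removed by the genotyping-rate filter")
    n_samples_removed = G.n_samples - keep_samples.size
    G = G.take_samples(keep_samples)

    maf = G.maf()
    keep_maf = np.flatnonzero(~np.isnan(maf) & (maf > spec.max_maf_excl))
    n_maf_removed = G.n_loci - keep_maf.size
    G = G.take_loci(keep_maf)

    het = G.het_rate()
    keep_het = np.flatnonzero(het < spec.max_het_rate_excl)
    n_het_removed = G.n_loci - keep_het.size
    G = G.take_loci(keep_het)

    report = {
        "samples_removed": int(n_samples_removed),
        "loci_removed_maf": int(n_maf_removed),
        "loci_removed_het": int(n_het_removed),
        "samples_retained": G.n_samples,
        "loci_retained": G.n_loci,
    }
    return G, report


def impute_modal(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace MISSING calls with the modal genotype of each locus.

    Ties between genotype classes break toward the smaller allele count
    (0 over 1 over 2), which favours the major allele after MAF filtering.
    """
    calls = G.calls.copy()
    obs = calls != MISSING
    counts = np.stack([np.where(obs, calls == g, False).sum(axis=0) for g in (0, 1, 2)])
    empty = counts.sum(axis=0) == 0
    if empty.any():
        j = int(np.flatnonzero(empty)[0])
        locus = G.loci.iloc[j]
        raise ValueError(
            f"locus {locus['chrom']}:{locus['pos']} has no non-missing calls"
        )
    mode = counts.argmax(axis=0).astype(np.int8)  # argmax breaks ties low
    miss_rows, miss_cols = np.nonzero(~obs)
    calls[miss_rows, miss_cols] = mode[miss_cols]
    return GenotypeMatrix(list(G.samples), G.loci.copy(), calls)


# ---------------------------------------------------------------------------
# Candidate-gene annotation
# ---------------------------------------------------------------------------

def annotate_candidates(
    loci: list[tuple[str, int]], gff_path: str, margin: int = 1000
) -> pd.DataFrame:
    """Report genes within ``margin`` bp of each candidate locus.

    A gene is reported when the locus falls inside
    ``[gene.start - margin, gene.end + margin]`` (1-based inclusive).
    The relation is ``within_gene`` when the locus is inside the gene body,
    otherwise ``upstream_1kb``/``downstream_1kb`` resolved with the
    annotated strand ('-' strand flips the sense).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    genes = [
        (f.seqid, f.start, f.end, f.strand, f.id)
        for f in db.features_of_type("gene")
    ]
    gene_chroms = {g[0] for g in genes}
    records = []
    unmatched = set()
    for chrom, pos in loci:
        if chrom not in gene_chroms:
            unmatched.add(chrom)
            continue
        for gchrom, start, end, strand, gid in genes:
            if gchrom != chrom or not (start - margin <= pos <= end + margin):
                continue
            if start <= pos <= end:
                relation = "within_gene"
            elif pos < start:
                relation = "upstream_1kb" if strand != "-" else "downstream_1kb"
            else:
                relation = "downstream_1kb" if strand != "-" else "upstream_1kb"
            records.append((chrom, pos, gid, relation))
    if unmatched:
        logger.warning(
            "annotate_candidates: no gene features on chromosome(s) %s",
            ", ".join(sorted(unmatched)),
        )
    return pd.DataFrame(records, columns=["chrom", "pos", "gene_id", "relation"])
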