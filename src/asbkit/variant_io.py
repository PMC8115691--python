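"""Reading, filtering and grouping of heterozygous SNV calls.

The pipeline starts downstream of variant calling: the input is one VCF per
ChIP-seq dataset with genotype (``GT``) and per-allele read depth (``AD``)
for a single sample.  Eligibility for allele-specific binding (ASB) analysis
requires a call to be a biallelic heterozygous SNV with at least
``min_allele_reads`` reads supporting *each* allele, listed in a whitelist of
known common SNPs (to exclude de novo point mutations, whose allelic ratios
reflect clonal composition rather than copy number or binding), and located
on a chromosome retaining at least ``min_snvs_per_chrom`` eligible calls.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_GENOTYPES = ("het", "hom_ref", "hom_alt", "other")

#: default per-allele read-depth cutoff
MIN_ALLELE_READS = 5
#: default minimum eligible SNVs for a chromosome to enter BAD calling
MIN_SNVS_PER_CHROM = 100


@dataclass(frozen=True)
class SnvCall:
    """One biallelic SNV observation in one dataset.

    ``pos`` is 1-based, as in VCF.  ``c_ref``/``c_alt`` are the read counts
    supporting the reference and alternative allele.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    c_ref: int
    c_alt: int
    genotype: str = "het"
    snp_id: str | None = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("alleles must be single nucleotides")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.c_ref < 0 or self.c_alt < 0:
            raise ValueError("read counts must be non-negative")
        if self.genotype not in _GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def coverage(self) -> int:
        return self.c_ref + self.c_alt

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class DatasetMeta:
    """Provenance of one dataset: which TF was assayed in which cell type,
    and the series/lab identifier used to pool datasets for BAD calling."""

    dataset_id: str
    tf_name: str
    cell_type: str
    series_id: str


@dataclass
class FilterReport:
    """Per-rule bookkeeping of dropped records; ``kept + dropped == n_input``."""

    n_input: int = 0
    n_kept: int = 0
    non_biallelic: int = 0
    non_het: int = 0
    low_coverage: int = 0
    not_in_whitelist: int = 0
    small_chromosome: int = 0

    @property
    def n_dropped(self) -> int:
        return (self.non_biallelic + self.non_het + self.low_coverage
                + self.not_in_whitelist + self.small_chromosome)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _genotype_of(gt: tuple | None) -> str:
    alleles = [a for a in (gt or ()) if a is not None]
    if len(alleles) != 2:
        return "other"
    if sorted(alleles) == [0, 1]:
        return "het"
    if alleles == [0, 0]:
        return "hom_ref"
    if alleles == [1, 1]:
        return "hom_alt"
    return "other"


def read_snv_calls(vcf_source: str | Path, dataset_id: str) -> list[SnvCall]:
    """Read biallelic SNV records with allelic depths from a one-sample VCF.

    Multiallelic records, indels and records without a usable ``AD`` field
    are skipped (counted in the log).  Positions stay 1-based.
    """
    path = str(vcf_source)
    skipped = Counter()
    calls: list[SnvCall] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        sample = samples[0]
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt == "*":
                skipped["indel"] += 1
                continue
            data = rec.samples[sample]
            ad = data.get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                skipped["missing_depth"] += 1
                continue
            calls.append(SnvCall(
                chrom=rec.chrom, pos=rec.pos, ref_allele=ref, alt_allele=alt,
                c_ref=int(ad[0]), c_alt=int(ad[1]),
                genotype=_genotype_of(data.get("GT")),
                snp_id=None if rec.id in (None, ".") else rec.id,
                dataset_id=dataset_id,
            ))
    if skipped:
        logger.warning("%s: skipped records: %s", path, dict(skipped))
    return calls


def _in_whitelist(call: SnvCall, whitelist: frozenset) -> bool:
    # membership by SNP id when present, by site key otherwise, so that
    # id-less (e.g. synthetic) VCFs remain filterable
    if call.snp_id is not None and call.snp_id in whitelist:
        return True
    return call.site_key in whitelist


def filter_calls(
    calls: Sequence[SnvCall],
    whitelist: Iterable | None = None,
    min_allele_reads: int = MIN_ALLELE_READS,
    min_snvs_per_chrom: int = MIN_SNVS_PER_CHROM,
) -> tuple[list[SnvCall], FilterReport]:
    """Apply the ASB eligibility rules and report per-rule drop counts.

    Rules, in order of attribution for a record failing several: biallelic
    SNV, heterozygous genotype, ``>= min_allele_reads`` reads on both
    alleles, whitelist membership (skipped when ``whitelist`` is empty or
    None), and finally the per-chromosome census rule.
    """
    wl = frozenset(whitelist or ())
    if not wl:
        logger.info("empty whitelist: the whitelist rule is disabled")
    report = FilterReport(n_input=len(calls))
    survivors: list[SnvCall] = []
    for call in calls:
        if len(call.ref_allele) != 1 or len(call.alt_allele) != 1:
            report.non_biallelic += 1
        elif call.genotype != "het":
            report.non_het += 1
        elif call.c_ref < min_allele_reads or call.c_alt < min_allele_reads:
            report.low_coverage += 1
        elif wl and not _in_whitelist(call, wl):
            report.not_in_whitelist += 1
        else:
            survivors.append(call)

    census = Counter(c.chrom for c in survivors)
    kept = [c for c in survivors if census[c.chrom] >= min_snvs_per_chrom]
    report.small_chromosome = len(survivors) - len(kept)
    report.n_kept = len(kept)
    return kept, report


def read_metadata(source: str | Path) -> list[DatasetMeta]:
    """Read the dataset metadata TSV (dataset_id, tf_name, cell_type, series_id)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"dataset_id", "tf_name", "cell_type", "series_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if df["dataset_id"].duplicated().any():
        dup = df.loc[df["dataset_id"].duplicated(), "dataset_id"].iloc[0]
        raise ValueError(f"duplicate dataset_id in metadata: {dup}")
    for i, row in df.iterrows():
        if row.isna().any():
            raise ValueError(f"metadata row {i + 2}: missing value")
    return [DatasetMeta(r.dataset_id, r.tf_name, r.cell_type, r.series_id)
            for r in df.itertuples()]


def write_metadata(meta: Sequence[DatasetMeta], sink: str | Path) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(sink, sep="\t", index=False)


def group_for_bad(
    calls_by_dataset: Mapping[str, Sequence[SnvCall]],
    meta: Sequence[DatasetMeta],
) -> dict[tuple[str, str], list[SnvCall]]:
    """Pool datasets of one biological sample for BAD estimation.

    Datasets sharing (cell type, series id) are merged; the same SNP seen in
    several datasets of a group contributes one observation per dataset
    (recurrent calls are treated as independent read-count measurements of
    the same underlying allelic dosage).
    """
    by_id = {m.dataset_id: m for m in meta}
    groups: dict[tuple[str, str], list[SnvCall]] = defaultdict(list)
    for dataset_id, calls in calls_by_dataset.items():
        if dataset_id not in by_id:
            raise KeyError(f"dataset {dataset_id!r} missing from metadata")
        m = by_id[dataset_id]
        groups[(m.cell_type, m.series_id)].extend(calls)
    for key in groups:
        groups[key].sort(key=lambda c: (c.chrom, c.pos))
    return dict(groups)


def calls_to_frame(calls: Sequence[SnvCall]) -> pd.DataFrame:
    cols = ["chrom", "pos", "ref_allele", "alt_allele", "c_ref", "c_alt",
            "genotype", "snp_id", "dataset_id"]
    return pd.DataFrame([{k: getattr(c, k) for k in cols} for c in calls],
                        columns=cols)


def frame_to_calls(df: pd.DataFrame) -> list[SnvCall]:
    out = []
    for r in df.itertuples():
        snp_id = None if pd.isna(r.snp_id) else str(r.snp_id)
        out.append(SnvCall(str(r.chrom), int(r.pos), str(r.ref_allele),
                           str(r.alt_allele), int(r.c_ref), int(r.c_alt),
                           str(r.genotype), snp_id, str(r.dataset_id)))
    return out


def write_badmap_bed(badmap, sink: str | Path) -> None:
    """Write a BAD map as BED (0-based half-open) with auxiliary columns.

    Columns: chrom, start, end, assigned BAD, SNV count, then one
    log-likelihood column per grid BAD.  Excluded intervals follow with BAD
    "." and the exclusion reason.  Floats carry 6 decimals, making the
    round trip lossless at that precision.
    """
    grid = badmap.grid
    with open(sink, "w") as fh:
        fh.write("#grid=" + ",".join(f"{v:.6f}" for v in grid.values) + "\n")
        header = ["#chrom", "start", "end", "bad", "snv_count"]
        header += [f"L_{v:g}" for v in grid.values]
        fh.write("\t".join(header) + "\n")
        for seg in badmap.segments:
            row = [seg.chrom, str(seg.start), str(seg.end),
                   f"{seg.assigned_bad:.6f}", str(seg.snv_count)]
            row += [f"{ll:.6f}" for ll in seg.log_likelihood]
            fh.write("\t".join(row) + "\n")
        for ex in badmap.excluded:
            fh.write(f"{ex.chrom}\t{ex.start}\t{ex.end}\t.\t0\t{ex.reason}\n")


def read_badmap_bed(source: str | Path):
    """Read a BAD map written by :func:`write_badmap_bed`.

    Overlapping segments raise; the BadMap constructor enforces this.
    """
    import numpy as np

    from .bad_caller import BadGrid, BadMap, BadSegment, ExcludedInterval

    grid = None
    segments, excluded = [], []
    with open(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#grid="):
                grid = BadGrid(tuple(float(v)
                               for v in line[len("#grid="):].split(",")))
                continue
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if f[3] == ".":
                excluded.append(ExcludedInterval(chrom, start, end, f[5]))
                continue
            if grid is None:
                raise ValueError("BAD-map BED lacks the #grid header line")
            ll = np.array([float(v) for v in f[5:5 + len(grid.values)]])
            from .bad_caller import assign_bad
            seg = BadSegment(chrom=chrom, start=start, end=end,
                             snv_count=int(f[4]), log_likelihood=ll)
            assign_bad(seg, grid)
            seg.assigned_bad = float(f[3])
            segments.append(seg)
    if grid is None:
        raise ValueError("BAD-map BED lacks the #grid header line")
    return BadMap(segments, excluded, grid)


def read_whitelist(source: str | Path) -> frozenset:
    """Read a whitelist: one SNP id per line, or ``chrom pos ref alt`` rows."""
    entries = set()
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) >= 4:
                entries.add((parts[0], int(parts[1]), parts[2], parts[3]))
            else:
                entries.add(parts[0])
    return frozenset(entries)
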