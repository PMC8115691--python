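"""Fully labelled synthetic inputs for every pipeline stage.

The generator emulates the data model of allele-specific ChIP-seq variant
calls: a genome partitioned into segments of constant background allelic
dosage (BAD), heterozygous SNVs scattered over it, and per-dataset allelic
read counts whose reference fraction is set by the BAD, the (randomly
phased) haplotype, a global reference-mapping bias, and — for a planted
subset — a true allele-specific binding effect.  Allelic draws are
beta-binomial with a small intra-class correlation so that downstream model
fits are exercised off-model, as with real data.

Everything is driven by one :class:`SimConfig` and a seed; identical seeds
give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bad_caller import DEFAULT_BAD_GRID
from .motif_annot import Pwm, reverse_complement, write_pwm
from .variant_io import DatasetMeta

_NUCS = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a desk-scale caricature of a moderately aneuploid
    cell line panel: a 20 Mb genome over two chromosomes, piecewise BAD in
    {1, 2, 3}, one SNV per 10 kb, mean total coverage 40 with mild
    beta-binomial overdispersion (rho = 0.02), no mapping bias unless asked
    for, 5% of SNVs carrying a +1 log2 ASB effect, and a 2 TF x 2 cell type
    x 2 datasets-per-group design.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 10_000_000, "chr2": 10_000_000})
    segment_plan: dict | None = None  # chrom -> list of (length, bad)
    snv_density: float = 1e-4         # SNVs per bp
    mean_coverage: float = 40.0
    coverage_dispersion: float = 0.3  # NB dispersion of total coverage
    overdispersion: float = 0.02      # beta-binomial intra-class correlation
    bias_factor: float = 1.0          # multiplies the ref-allele odds
    asb_fraction: float = 0.05
    asb_effect: float = 1.0           # log2 odds shift for planted ASBs
    n_tfs: int = 2
    n_cell_types: int = 2
    datasets_per_group: int = 2
    gap_fraction: float = 0.0         # fraction of segment junctions made SNV-free


def _default_segment_plan(config: SimConfig, rng: np.random.Generator) -> dict:
    plan = {}
    bads = [1.0, 2.0, 3.0]
    for chrom, length in config.chrom_lengths.items():
        n_seg = max(1, length // 5_000_000)
        edges = np.linspace(0, length, n_seg + 1).astype(int)
        plan[chrom] = [(int(b - a), float(rng.choice(bads)))
                       for a, b in zip(edges[:-1], edges[1:])]
    return plan


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[tuple], pd.DataFrame]:
    """Piecewise-constant BAD truth plus SNV positions.

    Returns ``(truth, snvs)``: truth intervals (chrom, start, end, bad) in
    0-based half-open coordinates, and a table of SNV sites (chrom, pos,
    ref, alt, snp_id, true bad) with Poisson-spaced 1-based positions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    plan = config.segment_plan or _default_segment_plan(config, rng)
    if not any(plan.values()):
        raise ValueError("segment plan has no segments")
    grid = set(np.round(DEFAULT_BAD_GRID, 6))
    truth: list[tuple] = []
    rows = []
    snp_counter = 1
    for chrom in plan:
        offset = 0
        for length, bad in plan[chrom]:
            if round(float(bad), 6) not in grid:
                raise ValueError(f"BAD {bad} not on the default grid")
            start, end = offset, offset + int(length)
            truth.append((chrom, start, end, float(bad)))
            n_snvs = rng.poisson(config.snv_density * length)
            positions = np.sort(rng.integers(start + 1, end + 1, size=n_snvs))
            margin = int(0.05 * length)
            if config.gap_fraction > 0 and rng.random() < config.gap_fraction:
                # carve an SNV-free band at the segment end (deletion mimic)
                positions = positions[positions <= end - margin]
            for pos in np.unique(positions):
                ref, alt = rng.choice(list(_NUCS), size=2, replace=False)
                rows.append({"chrom": chrom, "pos": int(pos), "ref_allele": ref,
                             "alt_allele": alt, "snp_id": f"rs{snp_counter}",
                             "bad": float(bad)})
                snp_counter += 1
            offset = end
    snvs = pd.DataFrame(rows, columns=["chrom", "pos", "ref_allele",
                                       "alt_allele", "snp_id", "bad"])
    return truth, snvs


def make_metadata(config: SimConfig) -> list[DatasetMeta]:
    """The dataset design: every TF assayed in every cell type, with
    ``datasets_per_group`` replicate datasets per (TF, cell type)."""
    meta = []
    for ct in range(config.n_cell_types):
        cell_type = f"cell{ct + 1}"
        series = f"series{ct + 1}"   # one series per biological sample
        for tf in range(config.n_tfs):
            for rep in range(config.datasets_per_group):
                meta.append(DatasetMeta(
                    dataset_id=f"ds_{cell_type}_TF{tf + 1}_r{rep + 1}",
                    tf_name=f"TF{tf + 1}", cell_type=cell_type,
                    series_id=series))
    return meta


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Beta-binomial draws with mean n*p and intra-class correlation rho."""
    if rho <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    a = np.maximum(p * conc, 1e-6)
    b = np.maximum((1.0 - p) * conc, 1e-6)
    return rng.binomial(n, rng.beta(a, b))


def simulate_counts(truth: Sequence[tuple], snvs: pd.DataFrame,
                    config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-dataset allelic read counts plus the ground-truth label table.

    The haplotype phasing (which allele sits on the amplified haplotype) is
    drawn once per SNV per cell type, mimicking one cell line per series;
    planted ASB effects are per (SNV, TF) and shift the log-odds of the
    reference allele by ±``asb_effect``.  Reference-mapping bias multiplies
    the reference odds in every dataset.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    meta = make_metadata(config)
    n_snv = len(snvs)
    bads = snvs["bad"].to_numpy()

    cell_types = sorted({m.cell_type for m in meta})
    tfs = sorted({m.tf_name for m in meta})
    # per-cell-type phasing: True = reference allele on the major haplotype
    phase = {ct: rng.random(n_snv) < 0.5 for ct in cell_types}
    # planted ASB assignments per TF
    is_asb = {tf: rng.random(n_snv) < config.asb_fraction for tf in tfs}
    prefers_ref = {tf: rng.random(n_snv) < 0.5 for tf in tfs}

    label_rows = []
    for tf in tfs:
        for i in range(n_snv):
            label_rows.append({
                "chrom": snvs["chrom"].iat[i], "pos": int(snvs["pos"].iat[i]),
                "snp_id": snvs["snp_id"].iat[i], "tf_name": tf,
                "bad": float(bads[i]), "is_asb": bool(is_asb[tf][i]),
                "preferred_allele": ("ref" if prefers_ref[tf][i] else "alt")
                                    if is_asb[tf][i] else "",
                "effect": config.asb_effect if is_asb[tf][i] else 0.0,
            })
    labels = pd.DataFrame(label_rows)

    datasets: dict[str, pd.DataFrame] = {}
    for m in meta:
        major_is_ref = phase[m.cell_type]
        p_major = bads / (bads + 1.0)
        p_ref = np.where(major_is_ref, p_major, 1.0 - p_major)
        logodds = np.log(p_ref) - np.log1p(-p_ref)
        logodds += np.log(config.bias_factor)
        asb = is_asb[m.tf_name]
        sign = np.where(prefers_ref[m.tf_name], 1.0, -1.0)
        logodds += np.where(asb, sign * config.asb_effect * np.log(2.0), 0.0)
        p_ref_eff = 1.0 / (1.0 + np.exp(-logodds))

        disp = config.coverage_dispersion
        r = 1.0 / disp
        totals = rng.negative_binomial(
            r, r / (r + config.mean_coverage), size=n_snv) + 1
        c_ref = _beta_binomial(rng, totals, p_ref_eff, config.overdispersion)
        df = snvs[["chrom", "pos", "ref_allele", "alt_allele", "snp_id"]].copy()
        df["c_ref"] = c_ref
        df["c_alt"] = totals - c_ref
        df["dataset_id"] = m.dataset_id
        datasets[m.dataset_id] = df
    return datasets, labels


def write_vcf(df: pd.DataFrame, path: str | Path, sample: str = "sample",
              contigs: dict | None = None) -> None:
    """Write per-dataset calls as an uncompressed single-sample VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for r in df.itertuples():
            gt = getattr(r, "genotype", "het")
            gt_code = {"het": "0/1", "hom_ref": "0/0", "hom_alt": "1/1"}.get(gt, "./.")
            snp_id = r.snp_id if isinstance(r.snp_id, str) else "."
            fh.write(f"{r.chrom}\t{r.pos}\t{snp_id}\t{r.ref_allele}\t"
                     f"{r.alt_allele}\t.\tPASS\t.\tGT:AD\t"
                     f"{gt_code}:{r.c_ref},{r.c_alt}\n")


def write_truth_bed(truth: Sequence[tuple], path: str | Path) -> None:
    """Ground-truth BAD intervals as BED with BAD in the score column."""
    with open(path, "w") as fh:
        for chrom, start, end, bad in truth:
            fh.write(f"{chrom}\t{start}\t{end}\tbad\t{bad:.6f}\n")


def read_truth_bed(path: str | Path) -> list[tuple]:
    truth = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            truth.append((f[0], int(f[1]), int(f[2]), float(f[4])))
    return truth


# ---------------------------------------------------------------------------
# motif cases


def _random_pwm(rng: np.random.Generator, length: int = 8,
                strength: float = 2.0, name: str = "SYN_MOTIF") -> Pwm:
    """A synthetic log-odds PWM with one strong consensus letter per column."""
    consensus = rng.integers(0, 4, size=length)
    matrix = rng.normal(-strength, 0.3, size=(length, 4))
    matrix[np.arange(length), consensus] = strength + rng.normal(0, 0.2, length)
    return Pwm(name=name, matrix=matrix)


def _consensus(pwm: Pwm) -> str:
    return "".join(_NUCS[i] for i in pwm.matrix.argmax(axis=1))


def simulate_motif_cases(config: SimConfig | None = None,
                         n_per_class: int = 10,
                         motif_length: int = 8,
                         flank: int = 12,
                         rng: np.random.Generator | None = None
                         ) -> tuple[Pwm, pd.DataFrame]:
    """Planted motif/ASB scenarios with expected concordance labels.

    Three constructions: *driver* cases place the SNV inside a consensus
    match so that one allele weakens the site, with the ASB preferring the
    strong-motif allele (expected ``concordant``) or the weak one (expected
    ``discordant``); *scrambled* cases have no motif match (``no_hit``).
    """
    rng = np.random.default_rng(0 if config is None else config.seed + 2) if rng is None else rng
    pwm = _random_pwm(rng, motif_length)
    consensus = _consensus(pwm)
    rows = []
    for label in ("concordant", "discordant", "no_hit"):
        for i in range(n_per_class):
            offset_in_motif = int(rng.integers(0, motif_length))
            left = "".join(rng.choice(list(_NUCS), flank))
            right = "".join(rng.choice(list(_NUCS), flank))
            ref = consensus[offset_in_motif]
            alt = rng.choice([c for c in _NUCS if c != ref])
            if label == "no_hit":
                core = "".join(rng.choice(list(_NUCS), motif_length))
                # re-scramble until no strong match on either strand/allele
                while _max_consensus_identity(core, consensus) > 0.5:
                    core = "".join(rng.choice(list(_NUCS), motif_length))
                ref = core[offset_in_motif]
                alt = rng.choice([c for c in _NUCS if c != ref])
            else:
                core = consensus
            context = left + core + right
            snv_offset = flank + offset_in_motif
            # reference allele carries the consensus -> stronger ref motif;
            # concordant cases prefer ref (smaller ref FDR), discordant alt
            if label == "concordant":
                fdr_ref, fdr_alt = 1e-4, 0.8
            elif label == "discordant":
                fdr_ref, fdr_alt = 0.8, 1e-4
            else:
                fdr_ref, fdr_alt = 1e-4, 0.8
            rows.append({"case_id": f"{label}_{i}", "context": context,
                         "snv_offset": snv_offset, "ref_allele": ref,
                         "alt_allele": alt, "fdr_ref": fdr_ref,
                         "fdr_alt": fdr_alt, "expected_class": label})
    return pwm, pd.DataFrame(rows)


def _max_consensus_identity(seq: str, consensus: str) -> float:
    fwd = np.mean([a == b for a, b in zip(seq, consensus)])
    rev = np.mean([a == b for a, b in zip(reverse_complement(seq), consensus)])
    return float(max(fwd, rev))


# ---------------------------------------------------------------------------
# bundle writer


def simulate_bundle(config: SimConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic input bundle; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth, snvs = simulate_genome(config, rng)
    datasets, labels = simulate_counts(truth, snvs, config, rng)
    meta = make_metadata(config)

    manifest = {"vcfs": {}, "outdir": str(outdir)}
    for ds_id, df in datasets.items():
        path = outdir / f"{ds_id}.vcf"
        write_vcf(df, path, sample=ds_id, contigs=config.chrom_lengths)
        manifest["vcfs"][ds_id] = str(path)

    write_truth_bed(truth, outdir / "truth_bad.bed")
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    pd.DataFrame([asdict_meta(m) for m in meta]).to_csv(
        outdir / "metadata.tsv", sep="\t", index=False)
    snvs["snp_id"].to_csv(outdir / "whitelist.txt", index=False, header=False)

    pwm, cases = simulate_motif_cases(config, rng=np.random.default_rng(config.seed + 2))
    write_pwm(pwm, outdir / f"{pwm.name}.pwm")
    cases.to_csv(outdir / "motif_cases.tsv", sep="\t", index=False)

    manifest.update(truth_bed=str(outdir / "truth_bad.bed"),
                    labels=str(outdir / "labels.tsv"),
                    metadata=str(outdir / "metadata.tsv"),
                    whitelist=str(outdir / "whitelist.txt"),
                    pwm=str(outdir / f"{pwm.name}.pwm"),
                    motif_cases=str(outdir / "motif_cases.tsv"))
    return manifest


def asdict_meta(m: DatasetMeta) -> dict:
    return {"dataset_id": m.dataset_id, "tf_name": m.tf_name,
            "cell_type": m.cell_type, "series_id": m.series_id}
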