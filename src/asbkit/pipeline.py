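"""End-to-end orchestration: filter -> badmap -> fit -> call -> aggregate
-> annotate-motifs -> evaluate, with a YAML config, per-stage outputs and
mtime-based resumption.

Every stage reads only prior-stage outputs from the output directory, so a
rerun with unchanged inputs skips everything (unless forced).  Floating
point columns are written at 6 significant digits, making repeated runs
byte-identical.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import aggregation, asb_model, bad_caller, motif_annot, synthetic, variant_io

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

_DEFAULTS = {
    "seed": 0,
    "out_dir": "asbkit_out",
    "inputs": {
        "vcf_dir": None,
        "metadata": None,
        "whitelist": None,
        "truth_bed": None,
        "pwm": None,
        "motif_cases": None,
    },
    "simulate": None,   # SimConfig fields; None = no simulation stage
    "filter": {"min_allele_reads": 5, "min_snvs_per_chrom": 100},
    "badmap": {"gap_bp": 1_000_000, "penalty": 10.0,
               "grid": "1,4/3,3/2,2,5/2,3,4,5,6"},
    "fit": {"max_m": 200, "min_obs": 50},
    "aggregate": {"fdr": 0.05, "min_coverage": 20},
    "motifs": {"pval_thr": 0.0005, "fc_thr": 2.0},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} at '{path or '/'}'")
    for key, dv in defaults.items():
        uv = user.get(key)
        if isinstance(dv, dict) and uv is not None:
            if not isinstance(uv, dict):
                raise ConfigError(f"'{path}{key}' must be a mapping")
            out[key] = _merge(dv, uv, f"{path}{key}.")
        elif key in user:
            out[key] = uv
        else:
            # deep-copied so that stages mutating the config (e.g. simulate
            # pointing inputs at the bundle) never touch the defaults
            out[key] = copy.deepcopy(dv)
    return out


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    if "simulate" in user and user["simulate"] is not None:
        sim = user["simulate"]
        valid = set(synthetic.SimConfig.__dataclass_fields__)
        unknown = set(sim) - valid
        if unknown:
            raise ConfigError(f"unknown simulate key(s) {sorted(unknown)}")
    cfg = _merge(_DEFAULTS, {k: v for k, v in user.items() if k != "simulate"} | {})
    cfg["simulate"] = user.get("simulate")
    return cfg


class Pipeline:
    """Stage runner bound to one resolved configuration."""

    def __init__(self, config: dict, force: bool = False) -> None:
        self.cfg = config
        self.force = force
        self.out = Path(config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, str] = {}
        with open(self.out / "config.resolved.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)

    # -- helpers -----------------------------------------------------------

    def _fresh(self, outputs: list[Path], inputs: list[Path]) -> bool:
        if self.force or not outputs:
            return False
        if not all(p.exists() for p in outputs):
            return False
        newest_in = max((p.stat().st_mtime for p in inputs if p.exists()),
                        default=0.0)
        oldest_out = min(p.stat().st_mtime for p in outputs)
        return oldest_out >= newest_in

    def _run_stage(self, name: str, fn, inputs: list[Path],
                   outputs: list[Path]) -> bool:
        """Returns True if the stage ran, False if skipped."""
        if self._fresh(outputs, inputs):
            logger.info("stage=%s skipped (outputs up to date)", name)
            for p in outputs:
                self.manifest[p.name] = str(p)
            return False
        t0 = time.monotonic()
        try:
            fn()
        except Exception as exc:
            for p in outputs:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        for p in outputs:
            self.manifest[p.name] = str(p)
        logger.info("stage=%s wall=%.2fs outputs=%d", name,
                    time.monotonic() - t0, len(outputs))
        return True

    def _write(self, df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)

    def _inputs(self, key: str, required: bool = True) -> Path | None:
        val = self.cfg["inputs"].get(key)
        if val is None:
            if required:
                raise ConfigError(f"inputs.{key} is required for this stage")
            return None
        p = Path(val)
        if not p.exists():
            raise ConfigError(f"inputs.{key}: no such file or directory: {p}")
        return p

    def _metadata(self):
        return variant_io.read_metadata(self._inputs("metadata"))

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        sim_cfg = self.cfg.get("simulate")
        if sim_cfg is None:
            sim_cfg = {}
        sim_cfg = dict(sim_cfg)
        sim_cfg.setdefault("seed", self.cfg["seed"])
        config = synthetic.SimConfig(**sim_cfg)
        sim_dir = self.out / "sim"
        stamp = sim_dir / "metadata.tsv"

        def run():
            manifest = synthetic.simulate_bundle(config, sim_dir)
            inputs = self.cfg["inputs"]
            inputs["vcf_dir"] = str(sim_dir)
            inputs["metadata"] = manifest["metadata"]
            inputs["whitelist"] = manifest["whitelist"]
            inputs["truth_bed"] = manifest["truth_bed"]
            inputs["pwm"] = manifest["pwm"]
            inputs["motif_cases"] = manifest["motif_cases"]

        self._run_stage("simulate", run, [], [stamp])
        # point inputs at the bundle even when the stage was skipped
        inputs = self.cfg["inputs"]
        inputs.setdefault("vcf_dir", str(sim_dir))
        for key, fname in [("vcf_dir", ""), ("metadata", "metadata.tsv"),
                           ("whitelist", "whitelist.txt"),
                           ("truth_bed", "truth_bad.bed"),
                           ("motif_cases", "motif_cases.tsv")]:
            if inputs.get(key) is None:
                inputs[key] = str(sim_dir / fname)
        if inputs.get("pwm") is None:
            pwms = sorted(sim_dir.glob("*.pwm"))
            inputs["pwm"] = str(pwms[0]) if pwms else None

    def filter(self) -> None:
        meta = self._metadata()
        vcf_dir = self._inputs("vcf_dir")
        wl_path = self._inputs("whitelist", required=False)
        whitelist = variant_io.read_whitelist(wl_path) if wl_path else frozenset()
        fcfg = self.cfg["filter"]
        out_calls = self.out / "filtered_calls.tsv"
        out_report = self.out / "filter_report.tsv"

        def run():
            frames, reports = [], []
            for m in meta:
                vcf = vcf_dir / f"{m.dataset_id}.vcf"
                if not vcf.exists():
                    raise FileNotFoundError(f"no VCF for dataset {m.dataset_id}")
                calls = variant_io.read_snv_calls(vcf, m.dataset_id)
                kept, report = variant_io.filter_calls(
                    calls, whitelist,
                    min_allele_reads=fcfg["min_allele_reads"],
                    min_snvs_per_chrom=fcfg["min_snvs_per_chrom"])
                frames.append(variant_io.calls_to_frame(kept))
                reports.append(report.to_frame().assign(dataset_id=m.dataset_id))
            self._write(pd.concat(frames, ignore_index=True), out_calls)
            self._write(pd.concat(reports, ignore_index=True), out_report)

        vcf_inputs = [vcf_dir / f"{m.dataset_id}.vcf" for m in meta]
        self._run_stage("filter", run, vcf_inputs, [out_calls, out_report])

    def _load_filtered(self) -> dict[str, list]:
        df = pd.read_csv(self.out / "filtered_calls.tsv", sep="\t")
        calls = variant_io.frame_to_calls(df)
        by_ds: dict[str, list] = {}
        for c in calls:
            by_ds.setdefault(c.dataset_id, []).append(c)
        return by_ds

    def badmap(self) -> None:
        meta = self._metadata()
        bcfg = self.cfg["badmap"]
        grid = bad_caller.BadGrid.from_string(str(bcfg["grid"]))
        out_files = [self.out / "badmaps.done"]

        def run():
            by_ds = self._load_filtered()
            groups = variant_io.group_for_bad(by_ds, meta)
            for (cell_type, series), calls in sorted(groups.items()):
                caller = bad_caller.BadCaller.from_calls(
                    calls, grid=grid, gap_bp=int(bcfg["gap_bp"]),
                    changepoint_penalty=float(bcfg["penalty"]))
                badmap = caller.fit()
                path = self.out / f"badmap.{cell_type}.{series}.bed"
                variant_io.write_badmap_bed(badmap, path)
            (self.out / "badmaps.done").write_text(
                "\n".join(f"{ct}\t{se}" for ct, se in sorted(groups)) + "\n")

        self._run_stage("badmap", run, [self.out / "filtered_calls.tsv"],
                        out_files)

    def _group_badmaps(self, meta) -> dict[str, "bad_caller.BadMap"]:
        maps: dict[tuple, bad_caller.BadMap] = {}
        by_ds = {}
        for m in meta:
            key = (m.cell_type, m.series_id)
            if key not in maps:
                path = self.out / f"badmap.{m.cell_type}.{m.series_id}.bed"
                if path.exists():
                    maps[key] = variant_io.read_badmap_bed(path)
                else:
                    maps[key] = None
            by_ds[m.dataset_id] = maps[key]
        return by_ds

    def fit(self) -> None:
        meta = self._metadata()
        fcfg = self.cfg["fit"]
        out_fits = self.out / "fits.tsv"

        def run():
            by_ds = self._load_filtered()
            maps = self._group_badmaps(meta)
            cells: dict = {}
            for ds_id, calls in by_ds.items():
                for key, counts in asb_model.collect_cells(
                        calls, maps[ds_id]).items():
                    cells.setdefault(key, []).extend(counts)
            table = asb_model.FitTable.fit_all(
                cells, max_m=int(fcfg["max_m"]), min_obs=int(fcfg["min_obs"]))
            self._write(table.to_frame(), out_fits)

        self._run_stage("fit", run,
                        [self.out / "filtered_calls.tsv",
                         self.out / "badmaps.done"], [out_fits])

    def call(self) -> None:
        meta = self._metadata()
        out_scores = self.out / "asb_scores.tsv"

        def run():
            by_ds = self._load_filtered()
            maps = self._group_badmaps(meta)
            fits = asb_model.FitTable.from_frame(
                pd.read_csv(self.out / "fits.tsv", sep="\t"))
            frames = [asb_model.score_calls(calls, maps[ds_id], fits)
                      for ds_id, calls in sorted(by_ds.items())]
            self._write(pd.concat(frames, ignore_index=True), out_scores)

        self._run_stage("call", run,
                        [self.out / "filtered_calls.tsv", self.out / "fits.tsv"],
                        [out_scores])

    def aggregate(self) -> None:
        meta = self._metadata()
        acfg = self.cfg["aggregate"]
        outs = [self.out / "asb_tf.tsv", self.out / "asb_cell_type.tsv"]

        def run():
            scores = pd.read_csv(self.out / "asb_scores.tsv", sep="\t")
            for level, path in zip(("tf", "cell_type"), outs):
                table = aggregation.aggregate(
                    scores, meta, level=level, fdr_level=float(acfg["fdr"]),
                    min_total_coverage=int(acfg["min_coverage"]))
                self._write(table, path)

        self._run_stage("aggregate", run, [self.out / "asb_scores.tsv"], outs)

    def annotate_motifs(self) -> None:
        mcfg = self.cfg["motifs"]
        pwm_path = self._inputs("pwm")
        cases_path = self._inputs("motif_cases")
        out_annot = self.out / "motif_annotation.tsv"

        def run():
            pwm = motif_annot.read_pwm(pwm_path)
            cases = pd.read_csv(cases_path, sep="\t")
            rows = []
            for r in cases.itertuples():
                ann = motif_annot.annotate_snp(
                    pwm, r.context, int(r.snv_offset), r.ref_allele,
                    r.alt_allele, float(r.fdr_ref), float(r.fdr_alt),
                    hit_pvalue=float(mcfg["pval_thr"]),
                    fc_threshold=float(mcfg["fc_thr"]))
                ann["case_id"] = getattr(r, "case_id", r.Index)
                rows.append(ann)
            self._write(pd.DataFrame(rows), out_annot)

        self._run_stage("annotate-motifs", run, [pwm_path, cases_path],
                        [out_annot])

    def evaluate(self) -> None:
        meta = self._metadata()
        truth_path = self._inputs("truth_bed")
        out_metrics = self.out / "badmap_metrics.tsv"

        def run():
            truth = synthetic.read_truth_bed(truth_path)
            by_ds = self._load_filtered()
            maps = self._group_badmaps(meta)
            groups = variant_io.group_for_bad(by_ds, meta)
            rows = []
            for (cell_type, series), calls in sorted(groups.items()):
                badmap = maps[[m.dataset_id for m in meta
                               if (m.cell_type, m.series_id) == (cell_type, series)][0]]
                metrics = bad_caller.evaluate_map(badmap, truth, calls)
                row = {"cell_type": cell_type, "series_id": series,
                       "n_snvs": metrics["n_snvs"],
                       "kendall_tau_b": metrics["kendall_tau_b"],
                       "accuracy": metrics["accuracy"]}
                for bad, m in metrics["per_bad"].items():
                    row[f"auroc_bad_{bad:g}"] = m["auroc"]
                    row[f"auprc_bad_{bad:g}"] = m["auprc"]
                rows.append(row)
            self._write(pd.DataFrame(rows), out_metrics)

        self._run_stage("evaluate", run,
                        [self.out / "badmaps.done", truth_path], [out_metrics])

    # -- entry point -------------------------------------------------------

    def run(self) -> dict:
        """Run every configured stage in order; returns the file manifest."""
        if self.cfg.get("simulate") is not None:
            self.simulate()
        self.filter()
        self.badmap()
        self.fit()
        self.call()
        self.aggregate()
        if (self.cfg["inputs"].get("pwm")
                and self.cfg["inputs"].get("motif_cases")
                and Path(self.cfg["inputs"]["pwm"]).exists()):
            self.annotate_motifs()
        if (self.cfg["inputs"].get("truth_bed")
                and Path(self.cfg["inputs"]["truth_bed"]).exists()):
            self.evaluate()
        return dict(self.manifest)


def run_pipeline(config: dict | str | Path, force: bool = False) -> dict:
    """Load/validate the config, run all stages, return the manifest."""
    cfg = load_config(config)
    return Pipeline(cfg, force=force).run()
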