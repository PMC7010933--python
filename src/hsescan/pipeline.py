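"""End-to-end orchestration: extract -> scan -> classify -> respond ->
stats -> enrich, with a reproducible run manifest.

Each stage writes plain TSV/FASTA/BED outputs into the run directory;
the manifest records the configuration, input checksums, package
version, and per-stage status.  Identical configuration and inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

import hsescan
from hsescan import (
    architecture_stats,
    gene_classifier,
    genome_io,
    go_enrichment,
    hse_scanner,
    response_analysis,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genome: Optional[str] = None
    gff3: Optional[str] = None
    de_table: Optional[str] = None
    term_map: Optional[str] = None
    out_dir: str = "hsescan_run"
    promoter_length: int = 2000
    min_subunits: int = 3
    max_subunits: int = 8
    maximality: str = "longest-first"
    fc_min: float = 2.0
    alpha: float = 0.05
    q_cut: float = 0.01
    direction: str = "both"
    seed: int = 0

    def __post_init__(self):
        if self.promoter_length < 15:
            raise ValueError("promoter_length must be >= 15")
        for name in ("fc_min", "alpha", "q_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage for which inputs are configured.

    Returns the manifest dict (also written to ``manifest.json``).  On
    a stage failure, partial outputs are kept, a ``FAILED`` marker file
    names the stage, and :class:`StageError` is raised.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "hsescan",
        "version": hsescan.__version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": {},
    }
    for key in ("genome", "gff3", "de_table", "term_map"):
        path = getattr(cfg, key)
        if path:
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input {key!r} missing: {path}")
            manifest["inputs"][key] = _sha256(path)

    state: dict = {}

    def stage(name, fn):
        logger.info("[%s] starting", name)
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:
            manifest["stages"][name] = f"failed: {exc}"
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            _write_manifest(out, manifest)
            raise StageError(name, exc) from exc

    def do_extract():
        if not (cfg.genome and cfg.gff3):
            raise ValueError("extract requires --genome and --gff3")
        genes = genome_io.load_gene_models(cfg.gff3)
        genome = genome_io.load_genome(cfg.genome)
        promoters = genome_io.extract_promoters(
            genes, genome, promoter_length=cfg.promoter_length
        )
        genome_io.write_promoters_fasta(promoters, out / "promoters.fa")
        genome_io.write_promoters_bed(promoters, out / "promoters.bed")
        state["genes"] = genes
        state["promoters"] = promoters

    def do_scan():
        matches = hse_scanner.scan_promoters(
            state["promoters"],
            min_subunits=cfg.min_subunits,
            max_subunits=cfg.max_subunits,
            maximality=cfg.maximality,
        )
        hse_scanner.write_matches_tsv(matches, out / "hse.tsv")
        state["matches"] = matches

    def do_classify():
        records = gene_classifier.classify_genes(state["matches"], state["genes"])
        frame = gene_classifier.records_to_frame(records)
        frame.to_csv(out / "gene_classes.tsv", sep="\t", index=False)
        gene_classifier.summarize_classes(records).to_csv(
            out / "class_summary.tsv", sep="\t"
        )
        state["records"] = records
        state["gene_frame"] = frame

    def do_respond():
        de = pd.read_csv(cfg.de_table, sep="\t")
        responsive = response_analysis.call_responsive(
            de, fc_min=cfg.fc_min, alpha=cfg.alpha, direction=cfg.direction
        )
        mfh = response_analysis.compute_mfh(de, responsive, direction=cfg.direction)
        pd.DataFrame(sorted(responsive), columns=["gene_id", "organ"]).to_csv(
            out / "responsive.tsv", sep="\t", index=False
        )
        mfh.to_csv(out / "mfh.tsv", sep="\t", index=False)
        state["responsive"] = responsive
        state["mfh"] = mfh
        state["organs"] = sorted(mfh["organ"].unique())

    def do_stats():
        frame = state["gene_frame"]
        single = frame[frame["gene_class"].isin(["TTG", "TGG", "TVG"])].copy()
        lines = []
        results_rows = []
        for organ in state["organs"]:
            resp_set = {g for g, o in state["responsive"] if o == organ}
            single["responsive"] = single["gene_id"].isin(resp_set)
            counts = {
                cls: (int(grp["responsive"].sum()), len(grp))
                for cls, grp in single.groupby("gene_class")
                if len(grp) > 0
            }
            if len(counts) >= 2:
                res = architecture_stats.response_proportion_test(counts)
                lines.append(
                    f"[{organ}] chi-squared class x response: "
                    f"X2={res.statistic:.3f} df={res.df} p={res.p:.3g}"
                )
                results_rows.append(
                    {"organ": organ, "test": "chisq", "statistic": res.statistic,
                     "df": res.df, "p": res.p}
                )
            mfh = state["mfh"]
            organ_mfh = mfh[mfh["organ"] == organ]
            merged = single.merge(organ_mfh, on="gene_id", how="inner")
            merged = merged.rename(columns={"distance_to_atg": "position"})
            if len(merged) >= 10 and merged["gene_class"].nunique() >= 2:
                try:
                    anc = architecture_stats.ancova_magnitude(
                        merged, factor="gene_class"
                    )
                    lines.append(
                        f"[{organ}] ANCOVA mfh ~ class + position: "
                        f"class F={anc.factor_F:.3f} p={anc.factor_p:.3g}; "
                        f"position slope={anc.covariate_coefficient:.3g} "
                        f"p={anc.covariate_p:.3g}"
                    )
                    results_rows.append(
                        {"organ": organ, "test": "ancova_class",
                         "statistic": anc.factor_F, "p": anc.factor_p}
                    )
                    r, p = architecture_stats.position_magnitude_correlation(merged)
                    lines.append(
                        f"[{organ}] position-magnitude correlation: r={r:.3f} p={p:.3g}"
                    )
                    results_rows.append(
                        {"organ": organ, "test": "position_corr",
                         "statistic": r, "p": p}
                    )
                except ValueError as exc:
                    lines.append(f"[{organ}] ANCOVA skipped: {exc}")
        (out / "stats_report.txt").write_text("\n".join(lines) + "\n")
        pd.DataFrame(results_rows).to_csv(out / "stats.tsv", sep="\t", index=False)

    def do_enrich():
        term_map = go_enrichment.read_term_map(cfg.term_map)
        universe = set().union(*term_map.values())
        frame = state["gene_frame"]
        single = frame[frame["gene_class"].isin(["TTG", "TGG", "TVG"])]
        all_results = []
        for organ in state.get("organs", []):
            resp_set = {g for g, o in state["responsive"] if o == organ}
            for cls, grp in single.groupby("gene_class"):
                for flag, sub in (
                    ("responsive", grp[grp["gene_id"].isin(resp_set)]),
                    ("nonresponsive", grp[~grp["gene_id"].isin(resp_set)]),
                ):
                    study = set(sub["gene_id"]) & universe
                    if not study:
                        continue
                    res = go_enrichment.enrich(
                        study, universe, term_map, q_cut=cfg.q_cut
                    )
                    df = go_enrichment.results_to_frame(res)
                    df.insert(0, "gene_set", f"{organ}:{cls}:{flag}")
                    all_results.append(df)
        if all_results:
            pd.concat(all_results, ignore_index=True).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )

    stage("extract", do_extract)
    stage("scan", do_scan)
    stage("classify", do_classify)
    if cfg.de_table:
        stage("respond", do_respond)
        stage("stats", do_stats)
        if cfg.term_map:
            stage("enrich", do_enrich)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
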