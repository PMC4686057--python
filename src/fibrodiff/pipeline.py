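"""End-to-end orchestration of the four-contrast fibroblast analysis.

Given a normalized matrix and sample groups, the pipeline runs rank-product
differential expression on every contrast, summarizes UP/DOWN/TOTAL counts,
builds the differential correlation network on a user panel, detects
ascorbic-acid reversion genes, computes contrast overlaps and (optionally)
gene-set enrichment. Every intermediate is written as TSV so any stage can be
re-run and inspected independently; a machine-readable index and a manifest
copy land next to the outputs. A one-command synthetic run exercises the whole
chain against planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffnet import build_group_network
from .errors import FibrodiffError, PipelineError
from .io_formats import (
    read_expression_matrix,
    read_gene_list,
    read_probe_annotation,
    write_de_table,
    write_expression_matrix,
    write_gene_list,
    write_group_map,
    write_network,
)
from .rankprod import call_significant, collapse_probesets, estimate_pfp
from .setops import ContrastResult, contrast_overlap, reversion_genes, summarize_counts
from .simdata import ModuleSpec, SimConfig, simulate_expression_study, truth_table
from .study import Contrast

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS = ("P-C", "P_AA-P", "P_AA-C_AA", "C_AA-C")


@dataclass
class RunManifest:
    """Everything needed to reproduce one pipeline run."""

    matrix: str
    groups: str
    out_dir: str
    annotation: str | None = None
    panel: str | None = None
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    fdr: float = 0.05
    r_min: float = 0.8
    p_max: float = 0.005
    n_permutations: int = 1000
    seed: int = 0
    pool_treated: bool = False
    dialect: str = "tsv"
    version: str = __version__

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("manifest", f"unknown manifest keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["contrasts"] = list(d["contrasts"])
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except FibrodiffError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise PipelineError(name, str(exc)) from exc

    return wrap


def run_analysis(manifest: RunManifest) -> dict:
    """Run every stage; returns the output index (also written as index.json)."""
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    index: dict[str, str] = {}
    try:
        for p in (manifest.matrix, manifest.groups, manifest.annotation, manifest.panel):
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"input file not found: {p}")
        manifest.to_yaml(out_dir / "manifest.yaml")
        index["manifest"] = "manifest.yaml"
        log.info("thresholds: fdr=%s r_min=%s p_max=%s; permutations=%s seed=%s",
                 manifest.fdr, manifest.r_min, manifest.p_max,
                 manifest.n_permutations, manifest.seed)

        study = _stage("load")(
            read_expression_matrix, manifest.matrix, manifest.groups,
            dialect=manifest.dialect,
        )
        annotation = (
            _stage("load")(read_probe_annotation, manifest.annotation)
            if manifest.annotation
            else {g: g for g in study.genes}
        )

        results: dict[str, ContrastResult] = {}
        for i, ctext in enumerate(manifest.contrasts):
            contrast = Contrast.parse(ctext)
            table = _stage(f"de:{ctext}")(
                estimate_pfp, study, contrast,
                n_permutations=manifest.n_permutations,
                seed=manifest.seed + i,
            )
            fname = f"de_{ctext.replace('-', '_vs_')}.tsv"
            write_de_table(table, out_dir / fname)
            index[f"de:{ctext}"] = fname
            up, down = call_significant(table, manifest.fdr)
            gup, gdown, total = collapse_probesets(up, down, annotation)
            log.info("contrast %s: %d up, %d down, %d total unique genes",
                     ctext, len(gup), len(gdown), total)
            for direction, df in (("up", gup), ("down", gdown)):
                fname = f"genes_{ctext.replace('-', '_vs_')}_{direction}.tsv"
                write_gene_list(df, out_dir / fname)
                index[f"genes:{ctext}:{direction}"] = fname
            results[ctext] = ContrastResult(ctext, gup, gdown)

        counts = summarize_counts(list(results.values()))
        counts.to_csv(out_dir / "counts.tsv", sep="\t", lineterminator="\n")
        index["counts"] = "counts.tsv"

        if manifest.panel:
            panel = _stage("network")(read_gene_list, manifest.panel)
            net = _stage("network")(
                build_group_network, study, panel, "P", "C",
                r_min=manifest.r_min, p_max=manifest.p_max,
                pool_patient=("P_AA",) if manifest.pool_treated else (),
                pool_control=("C_AA",) if manifest.pool_treated else (),
            )
            net.to_frame().to_csv(out_dir / "network_edges.tsv", sep="\t",
                                  index=False, float_format="%.4f", lineterminator="\n")
            write_network(net, out_dir / "network.sif", "sif")
            write_network(net, out_dir / "network.graphml", "graphml")
            index.update({"network_edges": "network_edges.tsv",
                          "network_sif": "network.sif",
                          "network_graphml": "network.graphml"})
            log.info("network: %s", net.class_counts())

        pc, paap = manifest.contrasts[0], manifest.contrasts[1]
        if pc in results and paap in results:
            rev = _stage("reversion")(reversion_genes, results[pc], results[paap])
            rev.to_csv(out_dir / "reversion.tsv", sep="\t", index=False,
                       float_format="%.4f", lineterminator="\n")
            index["reversion"] = "reversion.tsv"
            log.info("reversion genes: %d", len(rev))

        overlaps = []
        names = list(manifest.contrasts)
        for a, b in ((0, 2), (1, 3)):
            if a < len(names) and b < len(names):
                common, ua, ub = contrast_overlap(results[names[a]], results[names[b]])
                overlaps.append({"contrast_a": names[a], "contrast_b": names[b],
                                 "common": len(common), "unique_a": len(ua),
                                 "unique_b": len(ub)})
        pd.DataFrame(overlaps).to_csv(out_dir / "overlaps.tsv", sep="\t",
                                      index=False, lineterminator="\n")
        index["overlaps"] = "overlaps.tsv"

        with open(out_dir / "index.json", "w", encoding="utf-8") as fh:
            json.dump(index, fh, indent=2)
        return index
    finally:
        log.removeHandler(handler)
        handler.close()


def default_synthetic_config(seed: int, n_genes: int = 2000) -> SimConfig:
    """The study-design defaults at a desk-friendly gene count, with one
    patient-arm correlation module so the network stage has planted structure."""
    return SimConfig(
        n_genes=n_genes,
        module_specs=[ModuleSpec(n_genes=10, r=0.95, group_signs={"P": 1, "P_AA": 1})],
        seed=seed,
    )


def run_synthetic(
    seed: int,
    out_dir,
    n_genes: int = 2000,
    n_permutations: int = 200,
) -> dict:
    """Simulate a study, write it to disk, run the full pipeline against it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = default_synthetic_config(seed, n_genes)
    study, truth = simulate_expression_study(config)
    write_expression_matrix(study, out_dir / "matrix.tsv")
    write_group_map(study.groups, out_dir / "groups.tsv")
    truth_table(truth).to_csv(out_dir / "truth.tsv", sep="\t", index=False,
                              lineterminator="\n")
    module_genes = sorted(
        {g for edges in truth.module_edges.values() for pair in edges for g in pair}
    )
    with open(out_dir / "panel.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(module_genes) + "\n")
    manifest = RunManifest(
        matrix=str(out_dir / "matrix.tsv"),
        groups=str(out_dir / "groups.tsv"),
        out_dir=str(out_dir / "results"),
        panel=str(out_dir / "panel.txt"),
        n_permutations=n_permutations,
        seed=seed,
        pool_treated=True,
    )
    return run_analysis(manifest)
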