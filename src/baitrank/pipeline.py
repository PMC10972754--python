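"""End-to-end orchestration: simulate/load -> TPM -> PCC -> clusters -> rank.

One run consumes a plain-text (YAML) config and an output directory and
writes every stage product as TSV plus a JSON run manifest that records the
resolved config, input checksums and per-stage row counts — enough to re-run
the identical pipeline.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .clusters import call_clusters, load_external_clusters
from .errors import InputError, PipelineError
from .expression import bait_pcc, compute_tpm, tissue_mean_tpm
from .io import (
    load_count_matrix,
    load_gff3,
    write_clusters,
    write_count_matrix,
    write_gff3,
    write_pcc,
    write_tpm,
    write_truth,
)
from .models import BgcStatus, CandidateScore
from .scoring import ScoringConfig, composite_score, rank_candidates, report_score
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": False,
    "sim": {},  # SimConfig field overrides when simulate is true
    "inputs": {  # paths, required when simulate is false
        "annotation": None,
        "counts": None,
        "lengths": None,
        "samples": None,
    },
    "bait": None,  # defaults to the simulated truth bait
    "clusters": None,  # external cluster-call TSV; None -> internal caller
    "coexpression": {"log1p": False, "tissue_means": False},
    "cluster_call": {"max_gap_bp": 20_000, "min_classes": 2},
    "scoring": {
        "pcc_lo": 0.8,
        "pcc_hi": 0.9,
        "tpm_lo": 1000.0,
        "tpm_hi": 3000.0,
        "bgc_char_bonus": 1.0,
        "bgc_other_bonus": 0.5,
        "abundance_tissue": "primordia",
        "top_n": 68,
        "class_whitelist": None,
        "whitelist_before_topn": True,
    },
    "report_top_n": 40,
    "seed": 1,
}

RANKED_COLUMNS = [
    "rank",
    "gene_id",
    "enzyme_class",
    "pcc",
    "primordium_tpm",
    "bgc_status",
    "c_coexpr",
    "c_abund",
    "c_bgc",
    "composite",
    "score",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"config {path} must be a mapping")
    return data


def resolve_config(user: Optional[dict]) -> dict:
    """Deep-merge a user config over the defaults."""

    def merge(base: dict, over: dict) -> dict:
        out = dict(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                out[k] = merge(base[k], v)
            else:
                out[k] = v
        return out

    return merge(DEFAULT_CONFIG, user or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    outdir: Path
    ranked_all: pd.DataFrame
    candidates: pd.DataFrame
    manifest: dict
    truth: Optional[object] = None


def _scores_frame(scores: list[CandidateScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append(
            {
                "rank": s.rank,
                "gene_id": s.gene_id,
                "enzyme_class": s.enzyme_class or "none",
                "pcc": s.pcc,
                "primordium_tpm": s.primordium_tpm,
                "bgc_status": s.bgc_status.value,
                "c_coexpr": s.c_coexpr,
                "c_abund": s.c_abund,
                "c_bgc": s.c_bgc,
                "composite": s.composite,
                "score": report_score(s.composite),
            }
        )
    return pd.DataFrame(rows, columns=RANKED_COLUMNS)


def run_pipeline(config: Optional[dict], outdir: str | Path) -> RunResult:
    """Execute the full prioritization run; returns tables and the manifest.

    Raises :class:`PipelineError` naming the failing stage; warnings
    (zero-variance genes, all-zero samples) never abort the run.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("baitrank")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "inputs"
    try:
        truth = None
        if cfg["simulate"]:
            sim_overrides = dict(cfg["sim"])
            sim_overrides.setdefault("seed", cfg["seed"])
            for key in ("planted_cluster_sizes", "low_tissue_frac",
                        "intergenic_gap_bp", "gene_length_bp"):
                if key in sim_overrides:
                    sim_overrides[key] = tuple(sim_overrides[key])
            sim_cfg = SimConfig(**sim_overrides)
            genes, truth, cm = simulate_dataset(sim_cfg)
            write_gff3(genes, outdir / "genes.gff3")
            write_count_matrix(
                cm, outdir / "counts.tsv", outdir / "lengths.tsv", outdir / "samples.tsv"
            )
            write_truth(truth, outdir / "truth.json")
            input_paths = {
                "annotation": outdir / "genes.gff3",
                "counts": outdir / "counts.tsv",
                "lengths": outdir / "lengths.tsv",
                "samples": outdir / "samples.tsv",
            }
            # round-trip through the written files: one loading path for both modes
            genes = load_gff3(input_paths["annotation"])
            cm = load_count_matrix(
                input_paths["counts"], input_paths["lengths"], input_paths["samples"]
            )
        else:
            for key in ("annotation", "counts", "lengths", "samples"):
                if not cfg["inputs"].get(key):
                    raise InputError(f"config inputs.{key} is required when simulate is false")
            input_paths = {k: Path(v) for k, v in cfg["inputs"].items()}
            genes = load_gff3(input_paths["annotation"])
            cm = load_count_matrix(
                input_paths["counts"], input_paths["lengths"], input_paths["samples"]
            )

        bait = cfg["bait"] or (truth.bait_id if truth is not None else None)
        if not bait:
            raise InputError("no bait gene: set 'bait' in the config")

        annotated = {g.gene_id: g for g in genes}
        missing = [gid for gid in cm.gene_ids if gid not in annotated]
        if missing:
            raise InputError(
                f"{len(missing)} count-matrix gene(s) absent from annotation, "
                f"first: {missing[0]}"
            )
        log.info("inputs: %d genes, %d samples", len(cm.gene_ids), len(cm.sample_ids))

        stage = "normalize"
        tm = compute_tpm(cm)
        write_tpm(tm, outdir / "tpm.tsv")

        stage = "coexpression"
        coex = bait_pcc(
            tm,
            bait,
            log1p=cfg["coexpression"]["log1p"],
            tissue_means=cfg["coexpression"]["tissue_means"],
        )
        write_pcc(coex, outdir / "pcc.tsv")

        stage = "clusters"
        if cfg["clusters"]:
            cluster_source = f"external:{cfg['clusters']}"
            clusters = load_external_clusters(cfg["clusters"], genes)
        else:
            cluster_source = "internal"
            clusters = call_clusters(
                genes,
                max_gap_bp=cfg["cluster_call"]["max_gap_bp"],
                min_classes=cfg["cluster_call"]["min_classes"],
            )
        write_clusters(clusters, genes, outdir / "clusters.tsv")
        log.info("clusters: %d called (%s)", len(clusters), cluster_source)

        stage = "scoring"
        sc_dict = dict(cfg["scoring"])
        if sc_dict.get("class_whitelist"):
            sc_dict["class_whitelist"] = frozenset(sc_dict["class_whitelist"])
        else:
            sc_dict["class_whitelist"] = None
        scfg = ScoringConfig(**sc_dict)
        abund = tissue_mean_tpm(tm, scfg.abundance_tissue)
        membership: dict[str, BgcStatus] = {}
        for c in clusters:
            for mid in c.member_ids:
                prev = membership.get(mid)
                if c.contains_characterized:
                    membership[mid] = BgcStatus.IN_CHARACTERIZED_CLUSTER
                elif prev is not BgcStatus.IN_CHARACTERIZED_CLUSTER:
                    membership[mid] = BgcStatus.IN_OTHER_CLUSTER
        scores = []
        for gid in cm.gene_ids:
            pcc = coex.pcc[gid] if bool(coex.defined[gid]) else None
            scores.append(
                composite_score(
                    gid,
                    pcc,
                    float(abund[gid]),
                    membership.get(gid, BgcStatus.UNCLUSTERED),
                    scfg,
                    enzyme_class=annotated[gid].enzyme_class,
                )
            )
        full_cfg = dataclasses.replace(scfg, top_n=None, class_whitelist=None)
        ranked_all = _scores_frame(rank_candidates(scores, full_cfg))
        candidates = _scores_frame(rank_candidates(scores, scfg))
        report = ranked_all.head(int(cfg["report_top_n"]))
        log.info("scoring: %d genes scored, %d candidates emitted",
                 len(ranked_all), len(candidates))

        stage = "report"
        ranked_all.to_csv(outdir / "ranked_all.tsv", sep="\t", index=False, na_rep="NA")
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False, na_rep="NA")
        report.to_csv(outdir / "report_table.tsv", sep="\t", index=False, na_rep="NA")

        manifest = {
            "tool": "baitrank",
            "version": __version__,
            "seed": cfg["seed"],
            "bait": bait,
            "cluster_source": cluster_source,
            "config": _jsonable(cfg),
            "inputs": {
                k: {"path": p.name, "sha256": _sha256(p)} for k, p in input_paths.items()
            },
            "stages": {
                "genes": len(cm.gene_ids),
                "samples": len(cm.sample_ids),
                "clusters": len(clusters),
                "scored": len(ranked_all),
                "candidates": len(candidates),
            },
            "outputs": {
                name: _sha256(outdir / name)
                for name in (
                    "tpm.tsv",
                    "pcc.tsv",
                    "clusters.tsv",
                    "ranked_all.tsv",
                    "candidates.tsv",
                    "report_table.tsv",
                )
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return RunResult(
            outdir=outdir,
            ranked_all=ranked_all,
            candidates=candidates,
            manifest=manifest,
            truth=truth,
        )
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
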