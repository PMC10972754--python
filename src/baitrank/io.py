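"""Readers/writers for the plain-text interchange formats.

GFF3 carries the gene annotation (``enzyme_class`` and ``characterized``
attributes); counts, gene lengths, sample->tissue metadata, cluster calls and
ranked candidates travel as TSV; the simulation ground truth is a JSON
sidecar manifest.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd

from .errors import InputError
from .expression import CountMatrix, TpmMatrix, CoexpressionResult
from .models import ClusterCall, GeneModel
from .simulate import SimConfig, SyntheticTruth

GFF_SOURCE = "baitrank"


# ---------------------------------------------------------------- annotation

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    path = Path(path)
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.scaffold, g.start, g.gene_id)):
        attrs = (
            f"ID={g.gene_id};"
            f"enzyme_class={g.enzyme_class if g.enzyme_class else 'none'};"
            f"characterized={'true' if g.characterized else 'false'}"
        )
        lines.append(
            "\t".join(
                [
                    g.scaffold,
                    GFF_SOURCE,
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    attrs,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def load_gff3(path: str | Path) -> list[GeneModel]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise InputError(f"malformed GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.all_features(featuretype="gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        enzyme_class = feat.attributes.get("enzyme_class", ["none"])[0]
        characterized = feat.attributes.get("characterized", ["false"])[0].lower()
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
                enzyme_class=None if enzyme_class == "none" else enzyme_class,
                characterized=characterized == "true",
            )
        )
    return genes


# -------------------------------------------------------------- count matrix

def write_count_matrix(cm: CountMatrix, counts_path, lengths_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.lengths.astype(int).to_frame("length").to_csv(
        lengths_path, sep="\t", index_label="gene_id"
    )
    cm.sample_tissue.to_frame("tissue").to_csv(
        samples_path, sep="\t", index_label="sample"
    )


def load_count_matrix(counts_path, lengths_path, samples_path) -> CountMatrix:
    for p in (counts_path, lengths_path, samples_path):
        if not Path(p).exists():
            raise InputError(f"input file not found: {p}")
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length"]
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")["tissue"]
    return CountMatrix(counts=counts, lengths=lengths, sample_tissue=samples)


def write_tpm(tm: TpmMatrix, path) -> None:
    tm.tpm.to_csv(path, sep="\t", index_label="gene_id")


def write_pcc(res: CoexpressionResult, path) -> None:
    df = pd.DataFrame(
        {"pcc": res.pcc, "defined": res.defined.map({True: "true", False: "false"})}
    )
    df.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


# ------------------------------------------------------------------ clusters

def write_clusters(clusters: Sequence[ClusterCall], genes: Sequence[GeneModel], path) -> None:
    """One row per (cluster, member): cluster_id, scaffold, span, member_id,
    enzyme_class, characterized."""
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for c in clusters:
        for mid in c.member_ids:
            g = by_id.get(mid)
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "scaffold": c.scaffold,
                    "span_start": c.span_start,
                    "span_end": c.span_end,
                    "member_id": mid,
                    "enzyme_class": (g.enzyme_class or "none") if g else "none",
                    "characterized": "true" if (g and g.characterized) else "false",
                }
            )
    cols = [
        "cluster_id",
        "scaffold",
        "span_start",
        "span_end",
        "member_id",
        "enzyme_class",
        "characterized",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- truth

def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "bait_id": truth.bait_id,
        "pathway_ids": truth.pathway_ids,
        "decoy_ids": truth.decoy_ids,
        "planted_cluster_members": truth.planted_cluster_members,
        "characterized_ids": truth.characterized_ids,
        "config": dataclasses.asdict(truth.config_echo),
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    cfg_dict = payload["config"]
    for key in ("planted_cluster_sizes", "low_tissue_frac", "intergenic_gap_bp", "gene_length_bp"):
        cfg_dict[key] = tuple(cfg_dict[key])
    return SyntheticTruth(
        bait_id=payload["bait_id"],
        pathway_ids=payload["pathway_ids"],
        decoy_ids=payload["decoy_ids"],
        planted_cluster_members=payload["planted_cluster_members"],
        characterized_ids=payload["characterized_ids"],
        config_echo=SimConfig(**cfg_dict),
        seed=payload["seed"],
    )
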