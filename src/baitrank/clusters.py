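"""Proximity-based putative BGC calling.

A transparent stand-in for full plant cluster-mining tools: signature-class
genes on a scaffold are chained while the intergenic gap between consecutive
signature genes stays within ``max_gap_bp``; a chain with at least two
signature genes spanning at least ``min_classes`` distinct enzyme classes
becomes a cluster, and every gene inside the chain's span (signature or not)
is a member.  Externally produced cluster calls can be ingested instead via
:func:`load_external_clusters`.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, UnknownGeneError
from .models import (
    DEFAULT_SIGNATURE_CLASSES,
    BgcStatus,
    ClusterCall,
    GeneModel,
    check_unique_ids,
)


def call_clusters(
    genes: Sequence[GeneModel],
    max_gap_bp: int = 20_000,
    min_classes: int = 2,
    signature_classes: Iterable[str] = DEFAULT_SIGNATURE_CLASSES,
) -> list[ClusterCall]:
    """Call putative gene clusters by chaining nearby signature genes.

    Per scaffold, signature genes sorted by start are chained while
    ``next.start - prev.end - 1 <= max_gap_bp`` (overlapping genes count as
    gap 0). Chains with >= 2 signature genes covering >= ``min_classes``
    distinct classes become clusters; the span runs from the first to the
    last signature gene, and all genes lying within it are members.
    ``contains_characterized`` is true iff any member is characterized.
    """
    if max_gap_bp <= 0:
        raise InputError("max_gap_bp must be positive")
    if min_classes < 2:
        raise InputError("min_classes must be >= 2")
    check_unique_ids(genes)
    sig_set = set(signature_classes)

    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    clusters: list[ClusterCall] = []
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.end))
        sig = [g for g in ordered if g.enzyme_class in sig_set]
        if len(sig) < 2:
            continue
        chains: list[list[GeneModel]] = [[sig[0]]]
        for prev, nxt in zip(sig, sig[1:]):
            gap = max(0, nxt.start - prev.end - 1)
            if gap <= max_gap_bp:
                chains[-1].append(nxt)
            else:
                chains.append([nxt])
        for chain in chains:
            classes = {g.enzyme_class for g in chain}
            if len(chain) < 2 or len(classes) < min_classes:
                continue
            span_start = min(g.start for g in chain)
            span_end = max(g.end for g in chain)
            members = [
                g for g in ordered if g.start >= span_start and g.end <= span_end
            ]
            clusters.append(
                ClusterCall(
                    cluster_id=f"bgc_{len(clusters) + 1:04d}",
                    scaffold=scaffold,
                    member_ids=[g.gene_id for g in members],
                    span_start=span_start,
                    span_end=span_end,
                    n_signature_classes=len(classes),
                    contains_characterized=any(g.characterized for g in members),
                )
            )
    return clusters


def load_external_clusters(
    path: str | Path, genes: Sequence[GeneModel]
) -> list[ClusterCall]:
    """Load cluster calls from a TSV with columns ``cluster_id`` and ``member_id``.

    Extra columns (e.g. the ones this package writes) are ignored; spans,
    signature-class counts and the characterized flag are recomputed from the
    gene annotation.  An empty file yields an empty list; a member id absent
    from the annotation raises :class:`UnknownGeneError` naming the id.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cluster file not found: {path}")
    text = path.read_text()
    if not text.strip():
        return []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cluster_id", "member_id"):
        if col not in df.columns:
            raise InputError(f"cluster file {path}: missing column {col!r}")
    by_id = {g.gene_id: g for g in genes}
    clusters: list[ClusterCall] = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        members: list[GeneModel] = []
        for mid in grp["member_id"]:
            if mid not in by_id:
                raise UnknownGeneError(
                    f"cluster {cid}: member gene {mid!r} absent from annotation"
                )
            members.append(by_id[mid])
        scaffolds = {g.scaffold for g in members}
        if len(scaffolds) != 1:
            raise InputError(f"cluster {cid}: members span multiple scaffolds {sorted(scaffolds)}")
        members.sort(key=lambda g: (g.start, g.end))
        clusters.append(
            ClusterCall(
                cluster_id=str(cid),
                scaffold=members[0].scaffold,
                member_ids=[g.gene_id for g in members],
                span_start=min(g.start for g in members),
                span_end=max(g.end for g in members),
                n_signature_classes=len(
                    {g.enzyme_class for g in members if g.enzyme_class is not None}
                ),
                contains_characterized=any(g.characterized for g in members),
            )
        )
    return clusters


def gene_bgc_status(gene_id: str, clusters: Sequence[ClusterCall]) -> BgcStatus:
    """Cluster-membership status of one gene; multi-membership takes the best.

    A gene in any cluster containing a characterized pathway gene is
    ``IN_CHARACTERIZED_CLUSTER``; otherwise membership in any cluster gives
    ``IN_OTHER_CLUSTER``; a gene in no cluster (or absent) is ``UNCLUSTERED``.
    """
    in_any = False
    for c in clusters:
        if gene_id in c.member_ids:
            if c.contains_characterized:
                return BgcStatus.IN_CHARACTERIZED_CLUSTER
            in_any = True
    return BgcStatus.IN_OTHER_CLUSTER if in_any else BgcStatus.UNCLUSTERED
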