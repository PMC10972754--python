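"""Independent oracles and instance generators used across the test suite."""
from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from baitrank.expression import TpmMatrix
from baitrank.models import GeneModel


def pearson_sigma_formula(x, y) -> float:
    """Pearson r via the raw sum formula, in pure Python floats."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def make_tpm(rows: dict[str, list[float]], tissue_of=None) -> TpmMatrix:
    """TpmMatrix from per-gene vectors (columns s1..sn, one tissue by default)."""
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i+1}" for i in range(df.shape[1])]
    tissues = tissue_of or {c: "t1" for c in df.columns}
    return TpmMatrix(tpm=df, sample_tissue=pd.Series(tissues))


def brute_force_clusters(genes, max_gap_bp, min_classes, signature_classes):
    """Cluster oracle: explicit pairwise gap graph + connected components.

    Signature genes become nodes; an edge joins genes adjacent in start order
    whose intergenic gap is within ``max_gap_bp``. Components with >= 2 genes
    and >= ``min_classes`` distinct classes are clusters; membership is a
    brute-force span-containment scan over all genes. Returns a set of
    frozensets of member ids with flags, for order-free comparison.
    """
    sig_set = set(signature_classes)
    out = set()
    for scaffold in sorted({g.scaffold for g in genes}):
        sg = sorted(
            (g for g in genes if g.scaffold == scaffold), key=lambda g: (g.start, g.end)
        )
        sig = [g for g in sg if g.enzyme_class in sig_set]
        G = nx.Graph()
        G.add_nodes_from(g.gene_id for g in sig)
        for a, b in zip(sig, sig[1:]):
            if max(0, b.start - a.end - 1) <= max_gap_bp:
                G.add_edge(a.gene_id, b.gene_id)
        by_id = {g.gene_id: g for g in sig}
        for comp in nx.connected_components(G):
            comp_genes = [by_id[i] for i in comp]
            classes = {g.enzyme_class for g in comp_genes}
            if len(comp_genes) < 2 or len(classes) < min_classes:
                continue
            lo = min(g.start for g in comp_genes)
            hi = max(g.end for g in comp_genes)
            members = frozenset(
                g.gene_id for g in sg if g.start >= lo and g.end <= hi
            )
            chara = any(
                g.characterized for g in sg if g.gene_id in members
            )
            out.add((scaffold, members, len(classes), chara))
    return out


def random_scaffold_instance(rng: np.random.Generator, max_genes: int = 25):
    """Random single-scaffold annotation with mixed classes, gaps and overlaps."""
    n = int(rng.integers(2, max_genes + 1))
    classes = ["CYP", "glycosyltransferase", "SDR-reductase", None, None]
    genes = []
    pos = 1
    prev_end = 0
    for i in range(n):
        gap = int(rng.integers(-800, 30_001))  # negative -> overlapping genes
        start = max(prev_end + 1 + gap, pos)
        length = int(rng.integers(500, 4000))
        end = start + length - 1
        genes.append(
            GeneModel(
                gene_id=f"r{i:03d}",
                scaffold="scfA",
                start=start,
                end=end,
                enzyme_class=classes[int(rng.integers(0, len(classes)))],
                characterized=bool(rng.random() < 0.1),
            )
        )
        prev_end = end
        pos = start + 1  # keep start order strictly increasing
    return genes
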