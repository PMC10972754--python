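"""Synthetic genome + multi-tissue RNA-seq simulator with a planted pathway.

The generator emulates the data a bait-gene prioritization run consumes: a
gene annotation on a handful of scaffolds and a negative-binomial count
matrix over several tissues with replicates, in which a planted pathway
module (bait included) is

* tightly coexpressed — all pathway genes share one latent tissue profile
  with a strong spike in "primordia",
* abundant in primordia — the spike sits at ``primordium_mean_tpm``,
* partially genome-clustered — pathway genes are laid out in compact blocks
  that a proximity cluster caller will recover, seeded with characterized
  genes.

Two decoy kinds break the evidence channels apart: coexpression decoys share
the latent profile but sit far from any cluster; clustered decoys sit inside
a planted block but express like background.  Ground truth goes into a
sidecar manifest and is never encoded in gene identifiers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .expression import CountMatrix
from .models import DEFAULT_SIGNATURE_CLASSES, GeneModel

PRIMORDIA = "primordia"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a 2,000-gene genome over 10 scaffolds, 8 tissues x 3
    replicates, a 12-gene pathway planted in two 6-gene clusters, plus 4
    coexpressed-but-unclustered and 4 clustered-but-uncorrelated decoys.
    """

    n_scaffolds: int = 10
    n_genes: int = 2000
    n_tissues: int = 8
    replicates_per_tissue: int = 3
    n_pathway_genes: int = 12  # bait included
    n_decoy_coexpr: int = 4
    n_decoy_clustered: int = 4
    planted_cluster_sizes: tuple[int, ...] = (6, 6)  # pathway genes per cluster
    n_characterized: int = 4  # bait included; all placed inside planted clusters
    primordium_mean_tpm: float = 6000.0
    low_tissue_frac: tuple[float, float] = (0.01, 0.10)
    pathway_scale_logsd: float = 0.3  # gene-specific lognormal amplitude
    background_tpm_logmean: float = 5.0
    background_tpm_logsd: float = 1.5
    nb_dispersion: float = 0.03  # NB variance = m + phi * m^2
    cluster_gap_bp: int = 5000
    intergenic_gap_bp: tuple[int, int] = (25_000, 80_000)
    gene_length_bp: tuple[int, int] = (1000, 5000)
    library_size: int = 5_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        positive = {
            "n_scaffolds": self.n_scaffolds,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "replicates_per_tissue": self.replicates_per_tissue,
            "n_pathway_genes": self.n_pathway_genes,
            "cluster_gap_bp": self.cluster_gap_bp,
            "library_size": self.library_size,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive (got {v})")
        if self.n_pathway_genes < 2:
            raise ConfigError("n_pathway_genes must be >= 2 (bait included)")
        if self.n_tissues < 2:
            raise ConfigError("need >= 2 tissues (primordia plus at least one other)")
        if self.n_decoy_coexpr < 0 or self.n_decoy_clustered < 0:
            raise ConfigError("decoy counts must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        n_special = self.n_pathway_genes + self.n_decoy_coexpr + self.n_decoy_clustered
        if n_special > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} cannot hold {n_special} pathway+decoy genes"
            )
        if any(k < 2 for k in self.planted_cluster_sizes):
            raise ConfigError("each planted cluster needs >= 2 pathway genes")
        n_clustered = sum(self.planted_cluster_sizes)
        if n_clustered > self.n_pathway_genes:
            raise ConfigError(
                "planted_cluster_sizes exceed n_pathway_genes "
                f"({n_clustered} > {self.n_pathway_genes})"
            )
        if len(self.planted_cluster_sizes) > self.n_scaffolds:
            raise ConfigError("more planted clusters than scaffolds")
        if not 1 <= self.n_characterized <= n_clustered:
            raise ConfigError(
                "n_characterized must be in [1, sum(planted_cluster_sizes)] "
                "(characterized genes live inside planted clusters)"
            )
        if not (0 < self.low_tissue_frac[0] <= self.low_tissue_frac[1] < 1):
            raise ConfigError("low_tissue_frac must satisfy 0 < lo <= hi < 1")
        if self.intergenic_gap_bp[0] > self.intergenic_gap_bp[1] or self.intergenic_gap_bp[0] < 1:
            raise ConfigError("invalid intergenic_gap_bp range")
        if self.gene_length_bp[0] > self.gene_length_bp[1] or self.gene_length_bp[0] < 1:
            raise ConfigError("invalid gene_length_bp range")

    def tissue_names(self) -> list[str]:
        return [PRIMORDIA] + [f"tissue_{i:02d}" for i in range(2, self.n_tissues + 1)]

    def sample_names(self) -> list[str]:
        return [
            f"{t}_r{r}"
            for t in self.tissue_names()
            for r in range(1, self.replicates_per_tissue + 1)
        ]


@dataclass
class SyntheticTruth:
    """Ground-truth manifest for one simulated dataset."""

    bait_id: str
    pathway_ids: list[str]
    decoy_ids: dict[str, list[str]]  # keys: "coexpressed", "clustered"
    planted_cluster_members: dict[str, list[str]]
    characterized_ids: list[str]
    config_echo: SimConfig
    seed: int

    def __post_init__(self) -> None:
        if self.bait_id not in self.pathway_ids:
            raise InputError("bait_id must be one of pathway_ids")
        if not set(self.characterized_ids) <= set(self.pathway_ids):
            raise InputError("characterized_ids must be a subset of pathway_ids")


def _stage_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """One root seed; fixed-order children per stage (layout, counts)."""
    layout_ss, counts_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(layout_ss), np.random.default_rng(counts_ss)


def generate_genome(config: SimConfig) -> tuple[list[GeneModel], SyntheticTruth]:
    """Lay out the synthetic annotation and ground truth.

    Genes are placed left to right per scaffold with intergenic gaps drawn
    from ``intergenic_gap_bp``, except inside planted cluster blocks where
    gaps stay within ``cluster_gap_bp``.  Each planted block holds its share
    of pathway genes interleaved with clustered decoys; every block carries
    at least two distinct signature enzyme classes and at least one
    characterized gene.  Deterministic for a fixed ``config.seed``.
    """
    rng, _ = _stage_rngs(config.seed)
    catalogue = list(DEFAULT_SIGNATURE_CLASSES)

    # genes per scaffold
    base, extra = divmod(config.n_genes, config.n_scaffolds)
    scaffold_sizes = [base + (1 if i < extra else 0) for i in range(config.n_scaffolds)]
    if min(scaffold_sizes) < 1:
        raise ConfigError("more scaffolds than genes")

    n_clusters = len(config.planted_cluster_sizes)
    # round-robin split of clustered decoys over planted blocks
    decoys_per_cluster = [
        config.n_decoy_clustered // n_clusters
        + (1 if c < config.n_decoy_clustered % n_clusters else 0)
        for c in range(n_clusters)
    ]
    block_sizes = [
        k + d for k, d in zip(config.planted_cluster_sizes, decoys_per_cluster)
    ]

    # one block per distinct scaffold, at a random slot offset
    scaffold_order = [int(s) for s in rng.permutation(config.n_scaffolds)]
    block_slots: dict[int, tuple[int, int]] = {}  # scaffold -> (start_slot, size)
    scaffold_for_cluster: list[int] = []
    for bsize in block_sizes:
        placed = False
        for s in scaffold_order:
            if scaffold_sizes[s] >= bsize and s not in block_slots:
                offset = int(rng.integers(0, scaffold_sizes[s] - bsize + 1))
                block_slots[s] = (offset, bsize)
                scaffold_for_cluster.append(s)
                placed = True
                break
        if not placed:
            raise ConfigError(
                f"planted cluster of {bsize} genes does not fit on any free scaffold"
            )

    # role grid: per scaffold, slot -> role tag
    BG, PATH_C, DEC_C, PATH_U, DEC_X = "bg", "pathC", "decC", "pathU", "decX"
    roles: list[list[str]] = [[BG] * n for n in scaffold_sizes]
    block_of_slot: dict[tuple[int, int], int] = {}
    for c, s in enumerate(scaffold_for_cluster):
        offset, bsize = block_slots[s]
        k = config.planted_cluster_sizes[c]
        tags = [PATH_C] * k + [DEC_C] * decoys_per_cluster[c]
        tags = list(rng.permutation(tags))
        for j, tag in enumerate(tags):
            roles[s][offset + j] = tag
            block_of_slot[(s, offset + j)] = c

    # isolated specials: unclustered pathway genes + coexpression decoys
    n_path_unclustered = config.n_pathway_genes - sum(config.planted_cluster_sizes)
    free = [
        (s, j)
        for s in range(config.n_scaffolds)
        for j in range(scaffold_sizes[s])
        if roles[s][j] == BG
    ]
    need = n_path_unclustered + config.n_decoy_coexpr
    if need > len(free):
        raise ConfigError("not enough free gene slots for unclustered pathway/decoy genes")
    pick = rng.choice(len(free), size=need, replace=False)
    for i, p in enumerate(pick):
        s, j = free[int(p)]
        roles[s][j] = PATH_U if i < n_path_unclustered else DEC_X

    # coordinates, ids, classes
    genes: list[GeneModel] = []
    pathway_ids: list[str] = []
    coexpr_decoy_ids: list[str] = []
    clustered_decoy_ids: list[str] = []
    cluster_members: dict[str, list[str]] = {
        f"cluster_{c + 1}": [] for c in range(n_clusters)
    }
    path_in_cluster: dict[int, list[str]] = {c: [] for c in range(n_clusters)}
    gid = 0
    for s in range(config.n_scaffolds):
        scaffold = f"scf{s + 1:02d}"
        pos = 1
        for j in range(scaffold_sizes[s]):
            role = roles[s][j]
            in_block = (s, j) in block_of_slot
            prev_in_same_block = (s, j - 1) in block_of_slot and in_block and (
                block_of_slot[(s, j - 1)] == block_of_slot[(s, j)]
            )
            if j > 0:
                if prev_in_same_block:
                    gap = int(rng.integers(200, config.cluster_gap_bp + 1))
                else:
                    gap = int(
                        rng.integers(
                            config.intergenic_gap_bp[0],
                            config.intergenic_gap_bp[1] + 1,
                        )
                    )
                pos += gap
            length = int(
                rng.integers(config.gene_length_bp[0], config.gene_length_bp[1] + 1)
            )
            gid += 1
            gene_id = f"g{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"

            if role == PATH_C:
                c = block_of_slot[(s, j)]
                # cycle the catalogue so every block carries >= 2 classes
                enzyme_class = catalogue[len(path_in_cluster[c]) % len(catalogue)]
                pathway_ids.append(gene_id)
                path_in_cluster[c].append(gene_id)
                cluster_members[f"cluster_{c + 1}"].append(gene_id)
            elif role == DEC_C:
                c = block_of_slot[(s, j)]
                choice = int(rng.integers(0, len(catalogue) + 1))
                enzyme_class = None if choice == len(catalogue) else catalogue[choice]
                clustered_decoy_ids.append(gene_id)
                cluster_members[f"cluster_{c + 1}"].append(gene_id)
            elif role == PATH_U:
                enzyme_class = catalogue[int(rng.integers(0, len(catalogue)))]
                pathway_ids.append(gene_id)
            elif role == DEC_X:
                enzyme_class = catalogue[int(rng.integers(0, len(catalogue)))]
                coexpr_decoy_ids.append(gene_id)
            else:  # background: sparse signature classes, mostly unlabelled
                if rng.random() < 0.2:
                    enzyme_class = catalogue[int(rng.integers(0, len(catalogue)))]
                else:
                    enzyme_class = None
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    scaffold=scaffold,
                    start=pos,
                    end=pos + length - 1,
                    strand=strand,
                    enzyme_class=enzyme_class,
                    characterized=False,  # flags set below
                )
            )
            pos += length

    # bait: first pathway gene of cluster 1; characterized genes round-robin
    bait_id = path_in_cluster[0][0]
    characterized: list[str] = []
    c = 0
    offsets = [0] * n_clusters
    while len(characterized) < config.n_characterized:
        members = path_in_cluster[c % n_clusters]
        i = offsets[c % n_clusters]
        if i < len(members):
            characterized.append(members[i])
            offsets[c % n_clusters] += 1
        c += 1
    char_set = set(characterized)
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            scaffold=g.scaffold,
            start=g.start,
            end=g.end,
            strand=g.strand,
            enzyme_class=g.enzyme_class,
            characterized=g.gene_id in char_set,
        )
        for g in genes
    ]

    truth = SyntheticTruth(
        bait_id=bait_id,
        pathway_ids=pathway_ids,
        decoy_ids={"coexpressed": coexpr_decoy_ids, "clustered": clustered_decoy_ids},
        planted_cluster_members=cluster_members,
        characterized_ids=characterized,
        config_echo=config,
        seed=config.seed,
    )
    return genes, truth


def generate_counts(
    config: SimConfig, genes: list[GeneModel], truth: SyntheticTruth
) -> CountMatrix:
    """Draw the negative-binomial count matrix for a generated genome.

    Target TPM is built per tissue — pathway genes and coexpression decoys
    share one latent profile (primordia at ``primordium_mean_tpm``, other
    tissues at 1–10% of it) scaled by a gene-specific lognormal factor;
    background and clustered decoys draw independent lognormal tissue means.
    Each tissue column is renormalized to 1e6 so recomputed TPM tracks the
    target, then counts[g, s] ~ NB(mean ∝ TPM x length, dispersion phi) with
    equal library sizes. Deterministic for a fixed ``config.seed``.
    """
    if len(genes) != config.n_genes:
        raise InputError(
            f"gene list ({len(genes)}) does not match config n_genes ({config.n_genes})"
        )
    gene_ids = [g.gene_id for g in genes]
    id_set = set(gene_ids)
    for gid in truth.pathway_ids:
        if gid not in id_set:
            raise InputError(f"truth pathway gene {gid} absent from gene list")
    if truth.config_echo != config:
        raise InputError("truth was generated under a different config")

    _, rng = _stage_rngs(config.seed)
    n_genes = config.n_genes
    tissues = config.tissue_names()
    lengths = np.array([g.length for g in genes], dtype=float)

    # latent tissue profile shared by the coexpressed module
    frac = rng.uniform(*config.low_tissue_frac, size=config.n_tissues - 1)
    profile = np.concatenate([[1.0], frac]) * config.primordium_mean_tpm

    idx = {gid: i for i, gid in enumerate(gene_ids)}
    module_rows = [idx[g] for g in truth.pathway_ids] + [
        idx[g] for g in truth.decoy_ids["coexpressed"]
    ]
    module_mask = np.zeros(n_genes, dtype=bool)
    module_mask[module_rows] = True

    # gene-specific lognormal amplitude, mean 1
    sd = config.pathway_scale_logsd
    factors = rng.lognormal(-0.5 * sd * sd, sd, size=n_genes)

    target = np.empty((n_genes, config.n_tissues))
    bg = rng.lognormal(
        config.background_tpm_logmean,
        config.background_tpm_logsd,
        size=(n_genes, config.n_tissues),
    )
    target[:] = bg
    target[module_mask] = factors[module_mask][:, None] * profile[None, :]

    # per-tissue renormalization keeps recomputed TPM on the target scale
    target *= 1e6 / target.sum(axis=0, keepdims=True)

    phi = config.nb_dispersion
    r = 1.0 / phi
    counts = np.empty(
        (n_genes, config.n_tissues * config.replicates_per_tissue), dtype=np.int64
    )
    col = 0
    for t in range(config.n_tissues):
        w = target[:, t] * lengths
        mean = w / w.sum() * config.library_size
        p = r / (r + mean)
        for _rep in range(config.replicates_per_tissue):
            counts[:, col] = rng.negative_binomial(r, p)
            col += 1

    sample_ids = config.sample_names()
    sample_tissue = pd.Series(
        [s.rsplit("_r", 1)[0] for s in sample_ids], index=sample_ids, name="tissue"
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        lengths=pd.Series(lengths, index=gene_ids, name="length"),
        sample_tissue=sample_tissue,
    )


def simulate_dataset(config: SimConfig) -> tuple[list[GeneModel], SyntheticTruth, CountMatrix]:
    """Convenience wrapper: genome layout plus counts in one call."""
    genes, truth = generate_genome(config)
    cm = generate_counts(config, genes, truth)
    return genes, truth, cm
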