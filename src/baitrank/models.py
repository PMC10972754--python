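"""Core domain types shared across modules.

A :class:`GeneModel` is one annotated gene on the genome; a
:class:`ClusterCall` is one putative biosynthetic gene cluster (BGC); a
:class:`CandidateScore` carries the three evidence sub-scores and the
composite used for ranking.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InputError

#: Enzyme classes treated as cluster "signature" genes: families plausibly
#: encoding triterpene-saponin pathway steps. Configurable everywhere it is
#: consumed; this tuple is only the shared default catalogue.
DEFAULT_SIGNATURE_CLASSES: tuple[str, ...] = (
    "oxidosqualene-cyclase",
    "CYP",
    "glycosyltransferase",
    "PKSIII",
    "BAHD-acyltransferase",
    "SDR-reductase",
    "CCL",
)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: 1-based inclusive coordinates plus evidence labels."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    enzyme_class: Optional[str] = None  # None == no enzyme-class assignment
    characterized: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"gene {self.gene_id}: invalid coordinates "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def intergenic_gap(a: GeneModel, b: GeneModel) -> int:
    """Gap in bp between two gene bodies; overlapping/abutting genes have gap 0."""
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end - 1)


@dataclass
class ClusterCall:
    """One putative BGC: member genes, genomic span and evidence flags."""

    cluster_id: str
    scaffold: str
    member_ids: list[str]
    span_start: int
    span_end: int
    n_signature_classes: int
    contains_characterized: bool


class BgcStatus(enum.Enum):
    """Cluster-membership status of a single gene, the BGC evidence channel."""

    IN_CHARACTERIZED_CLUSTER = "in_characterized_cluster"
    IN_OTHER_CLUSTER = "in_other_cluster"
    UNCLUSTERED = "unclustered"


@dataclass
class CandidateScore:
    """Evidence sub-scores and composite for one candidate gene.

    ``composite`` is the exact (unrounded) sum of the three sub-scores;
    rounding to two decimals happens only at report time.
    """

    gene_id: str
    c_coexpr: float
    c_abund: float
    c_bgc: float
    composite: float
    pcc: Optional[float]  # None == undefined (zero-variance gene)
    primordium_tpm: float
    bgc_status: BgcStatus
    enzyme_class: Optional[str] = None
    rank: Optional[int] = None

    def sort_key(self) -> tuple:
        """Descending composite, then PCC, then abundance; gene id breaks ties."""
        pcc = self.pcc if self.pcc is not None and not math.isnan(self.pcc) else -2.0
        return (-self.composite, -pcc, -self.primordium_tpm, self.gene_id)


def check_unique_ids(genes: Sequence[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise InputError(f"duplicate gene id: {g.gene_id}")
        seen.add(g.gene_id)
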