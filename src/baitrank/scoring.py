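"""Multi-evidence candidate scoring and ranking.

Three evidence channels are mapped to sub-scores in [0, 1] and summed to a
composite with maximum 3.0:

* coexpression — piecewise-linear ramp on the bait-gene PCC: 0 at or below
  ``pcc_lo`` (0.8), 1 at or above ``pcc_hi`` (0.9), linear between;
* abundance — the same ramp shape on primordium-tissue TPM between
  ``tpm_lo`` (1,000) and ``tpm_hi`` (3,000);
* cluster membership — 1 for genes in a putative BGC containing a
  characterized pathway gene, 0.5 for genes in any other putative BGC,
  0 otherwise.

Candidates are ranked by descending composite (ties: PCC, then primordium
TPM, then gene id); an optional enzyme-class whitelist narrows the list
before or after the top-N cut.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .errors import ConfigError, InputError
from .models import BgcStatus, CandidateScore


@dataclass
class ScoringConfig:
    """Scoring constants; defaults are the published prioritization values."""

    pcc_lo: float = 0.8
    pcc_hi: float = 0.9
    tpm_lo: float = 1000.0
    tpm_hi: float = 3000.0
    bgc_char_bonus: float = 1.0
    bgc_other_bonus: float = 0.5
    abundance_tissue: str = "primordia"
    top_n: Optional[int] = 68
    class_whitelist: Optional[frozenset[str]] = None
    whitelist_before_topn: bool = True

    def __post_init__(self) -> None:
        if not self.pcc_lo < self.pcc_hi:
            raise ConfigError("pcc_lo must be < pcc_hi")
        if not self.tpm_lo < self.tpm_hi:
            raise ConfigError("tpm_lo must be < tpm_hi")
        for b in (self.bgc_char_bonus, self.bgc_other_bonus):
            if not 0.0 <= b <= 1.0:
                raise ConfigError("BGC bonuses must lie in [0, 1]")
        if self.top_n is not None and self.top_n < 1:
            raise ConfigError("top_n must be positive")
        if self.class_whitelist is not None:
            self.class_whitelist = frozenset(self.class_whitelist)


def _ramp(x: float, lo: float, hi: float) -> float:
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    return (x - lo) / (hi - lo)


def coexpr_subscore(pcc: Optional[float], cfg: ScoringConfig) -> float:
    """Coexpression sub-score; undefined PCC (None/NaN) maps to 0."""
    if pcc is None or (isinstance(pcc, float) and math.isnan(pcc)):
        return 0.0
    if not -1.0 <= pcc <= 1.0:
        raise InputError(f"PCC {pcc} outside [-1, 1]")
    return _ramp(pcc, cfg.pcc_lo, cfg.pcc_hi)


def abundance_subscore(tpm: float, cfg: ScoringConfig) -> float:
    """Abundance sub-score from the gene's mean TPM in the abundance tissue."""
    if tpm < 0:
        raise InputError(f"negative TPM {tpm}")
    return _ramp(tpm, cfg.tpm_lo, cfg.tpm_hi)


def bgc_subscore(status: BgcStatus, cfg: ScoringConfig) -> float:
    """Cluster-membership sub-score: characterized cluster > other cluster > none."""
    if status is BgcStatus.IN_CHARACTERIZED_CLUSTER:
        return cfg.bgc_char_bonus
    if status is BgcStatus.IN_OTHER_CLUSTER:
        return cfg.bgc_other_bonus
    return 0.0


def composite_score(
    gene_id: str,
    pcc: Optional[float],
    primordium_tpm: float,
    bgc_status: BgcStatus,
    cfg: ScoringConfig,
    enzyme_class: Optional[str] = None,
) -> CandidateScore:
    """Sum the three sub-scores into the composite (max 3.0), echoing evidence."""
    c_coexpr = coexpr_subscore(pcc, cfg)
    c_abund = abundance_subscore(primordium_tpm, cfg)
    c_bgc = bgc_subscore(bgc_status, cfg)
    pcc_val = None
    if pcc is not None and not (isinstance(pcc, float) and math.isnan(pcc)):
        pcc_val = float(pcc)
    return CandidateScore(
        gene_id=gene_id,
        c_coexpr=c_coexpr,
        c_abund=c_abund,
        c_bgc=c_bgc,
        composite=c_coexpr + c_abund + c_bgc,
        pcc=pcc_val,
        primordium_tpm=float(primordium_tpm),
        bgc_status=bgc_status,
        enzyme_class=enzyme_class,
    )


def rank_candidates(
    scores: Sequence[CandidateScore], cfg: ScoringConfig
) -> list[CandidateScore]:
    """Sort, optionally class-filter, rank 1..n, and truncate to ``top_n``.

    Sorting is by descending composite with ties broken by descending PCC,
    then descending primordium TPM, then ascending gene id. When a class
    whitelist is set it is applied before (default) or after the top-N cut,
    per ``whitelist_before_topn``; ranks are reassigned 1..n on the emitted
    list either way.
    """
    ordered = sorted(scores, key=lambda s: s.sort_key())

    def _filter(rows: list[CandidateScore]) -> list[CandidateScore]:
        if cfg.class_whitelist is None:
            return rows
        return [s for s in rows if s.enzyme_class in cfg.class_whitelist]

    if cfg.whitelist_before_topn:
        ordered = _filter(ordered)
        if cfg.top_n is not None:
            ordered = ordered[: cfg.top_n]
    else:
        if cfg.top_n is not None:
            ordered = ordered[: cfg.top_n]
        ordered = _filter(ordered)

    # emit copies so callers can rank the same scores under several configs
    return [replace(s, rank=i) for i, s in enumerate(ordered, start=1)]


def report_score(composite: float) -> float:
    """Report-time rounding of the composite to 2 decimals (machine output
    keeps full precision)."""
    return round(composite, 2)
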