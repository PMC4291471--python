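"""Gene/position filtering and normalized footprint count (NFC) pooling.

Raw ribosome profiles are unreliable for most genes (low coverage), so
estimation uses only genes whose footprint-count (FC) profile passes a
per-gene statistic threshold (default: median FC > 1). Within kept genes
the first and last 20 codons are trimmed (5' ramp and terminal effects),
positions with FC below 1 are dropped, and the surviving counts are
divided by the gene's average FC, yielding NFC values that are comparable
across genes with different mRNA levels and initiation rates. NFC values
are then pooled per codon type into the per-codon NFC distributions the
EMG model is fitted to.

Order of operations is fixed: gene filter (on the untrimmed profile) ->
trim -> position filter -> normalize. The normalization denominator is,
by default, the mean over exactly those trimmed positions that pass the
position filter (so each gene's contributing NFC values average to 1);
``denominator="all_trimmed"`` selects the mean over all trimmed positions
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genetic_code import SENSE_CODONS, STOP_CODONS, iter_codons
from .io_formats import GeneProfile, ORFRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "CodonNFCTable",
    "filter_genes",
    "trim_profile",
    "normalize_profile",
    "build_nfc_table",
]


@dataclass(frozen=True)
class FilterConfig:
    """Gene/position filter settings.

    trim_start / trim_end: codons removed from each profile end (default 20).
    gene_stat: per-gene statistic ("median" or "mean") compared against
        gene_threshold (strict >) on the untrimmed profile.
    codon_min_fc: positions with FC below this are excluded (default 1.0).
    denominator: "passing" (mean over surviving positions, default) or
        "all_trimmed" (mean over every trimmed position).
    """

    trim_start: int = 20
    trim_end: int = 20
    gene_stat: str = "median"
    gene_threshold: float = 1.0
    codon_min_fc: float = 1.0
    min_len_after_trim: int = 1
    denominator: str = "passing"

    def __post_init__(self) -> None:
        if self.trim_start < 0 or self.trim_end < 0:
            raise ValueError("trim lengths must be non-negative")
        if self.gene_threshold < 0 or self.codon_min_fc < 0:
            raise ValueError("thresholds must be non-negative")
        if self.gene_stat not in ("median", "mean"):
            raise ValueError("gene_stat must be 'median' or 'mean'")
        if self.denominator not in ("passing", "all_trimmed"):
            raise ValueError("denominator must be 'passing' or 'all_trimmed'")
        if self.min_len_after_trim < 1:
            raise ValueError("min_len_after_trim must be >= 1")


@dataclass
class FilterReport:
    """Per-gene filtering bookkeeping: (gene_id, statistic, kept, reason)."""

    entries: list[tuple[str, float, bool, str]] = field(default_factory=list)

    def add(self, gene_id: str, statistic: float, kept: bool, reason: str) -> None:
        self.entries.append((gene_id, statistic, kept, reason))

    @property
    def n_kept(self) -> int:
        return sum(1 for e in self.entries if e[2])

    @property
    def n_dropped(self) -> int:
        return len(self.entries) - self.n_kept

    def to_rows(self) -> list[tuple[str, float, bool, str]]:
        return list(self.entries)


@dataclass
class CodonNFCTable:
    """Pooled NFC samples per sense codon, plus contribution provenance."""

    samples: dict[str, list[float]]
    n_genes: int = 0
    n_positions: int = 0
    genes_per_codon: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for codon in self.samples:
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} may not appear in an NFC table")

    def arrays(self) -> dict[str, np.ndarray]:
        return {c: np.asarray(v, dtype=float) for c, v in self.samples.items()}


def _gene_statistic(counts: np.ndarray, cfg: FilterConfig) -> float:
    return float(np.median(counts) if cfg.gene_stat == "median" else np.mean(counts))


def filter_genes(
    profiles: Sequence[GeneProfile], cfg: FilterConfig
) -> tuple[list[GeneProfile], FilterReport]:
    """Keep genes whose untrimmed-profile statistic strictly exceeds the threshold."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    kept: list[GeneProfile] = []
    report = FilterReport()
    for p in profiles:
        stat = _gene_statistic(p.counts, cfg)
        ok = stat > cfg.gene_threshold
        if ok:
            kept.append(p)
        report.add(
            p.gene_id,
            stat,
            ok,
            "kept" if ok else f"{cfg.gene_stat} {stat:g} <= {cfg.gene_threshold:g}",
        )
    if not kept:
        logger.warning("gene filter kept 0 of %d genes", len(profiles))
    return kept, report


def trim_profile(p: GeneProfile, cfg: FilterConfig) -> GeneProfile | None:
    """Drop the first/last trim codons; None when too few codons remain."""
    if p.n_codons < cfg.trim_start + cfg.trim_end + cfg.min_len_after_trim:
        return None
    stop = p.n_codons - cfg.trim_end
    return GeneProfile(p.gene_id, p.counts[cfg.trim_start : stop])


def normalize_profile(
    p: GeneProfile, cfg: FilterConfig
) -> list[tuple[int, float]]:
    """NFC values for a trimmed profile: (position-within-profile, count/mean).

    Positions with count below ``codon_min_fc`` are excluded from the
    output; the denominator is the mean over passing positions (default)
    or over all positions of the given profile (``denominator="all_trimmed"``).
    Returns [] when no position passes.
    """
    counts = p.counts
    passing = np.nonzero(counts >= cfg.codon_min_fc)[0]
    if passing.size == 0:
        return []
    denom_counts = counts[passing] if cfg.denominator == "passing" else counts
    denom = float(np.mean(denom_counts))
    if denom <= 0:
        return []
    return [(int(i), float(counts[i] / denom)) for i in passing]


def build_nfc_table(
    profiles: Sequence[GeneProfile],
    orfs: Iterable[ORFRecord],
    cfg: FilterConfig,
) -> tuple[CodonNFCTable, FilterReport]:
    """Run the full preprocessing chain and pool NFC samples per codon type.

    Genes missing from the FASTA, or whose profile length disagrees with
    their ORF's codon count, are skipped with a warning. Stop-codon
    positions never contribute samples.
    """
    orf_map: dict[str, ORFRecord] = {}
    for orf in orfs:
        orf_map[orf.gene_id] = orf
    kept, report = filter_genes(profiles, cfg)

    samples: dict[str, list[float]] = {c: [] for c in SENSE_CODONS}
    genes_per_codon: dict[str, set[str]] = {c: set() for c in SENSE_CODONS}
    n_genes = 0
    n_positions = 0
    for p in kept:
        orf = orf_map.get(p.gene_id)
        if orf is None:
            logger.warning("gene %s has a profile but no ORF sequence; skipped", p.gene_id)
            report.add(p.gene_id, float("nan"), False, "no matching ORF")
            continue
        codons = iter_codons(orf.sequence)
        if len(codons) != p.n_codons:
            logger.warning(
                "gene %s: profile has %d codons but ORF has %d; skipped",
                p.gene_id, p.n_codons, len(codons),
            )
            report.add(p.gene_id, float("nan"), False, "profile/ORF length mismatch")
            continue
        trimmed = trim_profile(p, cfg)
        if trimmed is None:
            report.add(p.gene_id, float("nan"), False, "too short after trimming")
            continue
        pairs = normalize_profile(trimmed, cfg)
        if not pairs:
            report.add(p.gene_id, float("nan"), False, "no position passed codon_min_fc")
            continue
        contributed = False
        for local_pos, nfc in pairs:
            codon = codons[local_pos + cfg.trim_start]
            if codon in STOP_CODONS:
                continue
            samples[codon].append(nfc)
            genes_per_codon[codon].add(p.gene_id)
            n_positions += 1
            contributed = True
        if contributed:
            n_genes += 1
    table = CodonNFCTable(
        samples=samples,
        n_genes=n_genes,
        n_positions=n_positions,
        genes_per_codon={c: len(g) for c, g in genes_per_codon.items()},
    )
    return table, report
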