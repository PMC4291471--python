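"""The MTDR index: typical decoding rates and their geometric mean per ORF.

The fitted mu of a codon's EMG is its typical decoding time; the typical
decoding rate is 1/mu (the only dimensionally consistent reading of the
time-to-rate conversion). A gene's MTDR is the geometric mean of its
codons' rates, computed as exp(mean of log rates). Whole input ORFs are
scored (no end trimming by default — trimming is an estimation-side
artifact filter); the terminal stop codon is never scored.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .emg_model import EMGFit
from .genetic_code import STOP_CODONS
from .io_formats import ORFRecord

logger = logging.getLogger(__name__)

__all__ = ["RateEntry", "DecodingRateTable", "MTDRScore", "rates_from_times",
           "compute_mtdr", "score_batch"]


@dataclass(frozen=True)
class RateEntry:
    """One codon's fitted decoding time and derived rate."""

    codon: str
    mu: float
    sigma: float
    lam: float
    n_samples: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"{self.codon}: typical decoding time must be positive")

    @property
    def rate(self) -> float:
        return 1.0 / self.mu


@dataclass
class DecodingRateTable:
    """Per-codon typical decoding times/rates (<= 61 sense codons)."""

    entries: dict[str, RateEntry]
    metadata: dict = field(default_factory=dict)

    def rate(self, codon: str) -> float | None:
        e = self.entries.get(codon)
        return None if e is None else e.rate

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MTDRScore:
    """One ORF's MTDR plus bookkeeping of scored and skipped codons."""

    gene_id: str
    mtdr: float
    n_used: int
    n_skipped: int
    skipped_codons: Counter = field(default_factory=Counter)
    note: str = ""


def rates_from_times(fits: Mapping[str, EMGFit], metadata: dict | None = None) -> DecodingRateTable:
    """Build the rate table from per-codon EMG fits.

    Unfit codons (not converged) and atypical fits (mu <= 0, for which a
    decoding rate is undefined) are excluded; raises if nothing remains.
    """
    entries: dict[str, RateEntry] = {}
    for codon, fit in fits.items():
        if fit.params is None or not fit.converged:
            continue
        if fit.params.mu <= 0:
            logger.warning("codon %s: atypical fit (mu=%.4g <= 0); excluded",
                           codon, fit.params.mu)
            continue
        entries[codon] = RateEntry(
            codon=codon,
            mu=fit.params.mu,
            sigma=fit.params.sigma,
            lam=fit.params.lam,
            n_samples=fit.n,
            converged=fit.converged,
        )
    if not entries:
        raise ValueError("no converged fits with positive typical decoding time")
    return DecodingRateTable(entries=entries, metadata=dict(metadata or {}))


def _scorable_codons(orf: ORFRecord, trim_ends: int = 0) -> list[str]:
    codons = orf.codons()
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if trim_ends:
        codons = codons[trim_ends : len(codons) - trim_ends]
    return codons


def compute_mtdr(
    orf: ORFRecord,
    table: DecodingRateTable,
    policy: str = "skip",
    trim_ends: int = 0,
) -> MTDRScore:
    """Geometric mean of the ORF's codon decoding rates.

    ``policy="skip"``: codons without a rate (unfit, or internal stops)
    are excluded and counted in ``n_skipped``; ``policy="strict"`` raises
    on any such codon. Raises when no codon is scorable.
    """
    if policy not in ("skip", "strict"):
        raise ValueError("policy must be 'skip' or 'strict'")
    log_rates: list[float] = []
    skipped: Counter = Counter()
    for codon in _scorable_codons(orf, trim_ends):
        if codon in STOP_CODONS:
            if policy == "strict":
                raise ValueError(f"{orf.gene_id}: internal stop codon {codon}")
            logger.warning("%s: internal stop codon %s skipped", orf.gene_id, codon)
            skipped[codon] += 1
            continue
        rate = table.rate(codon)
        if rate is None:
            if policy == "strict":
                raise ValueError(f"{orf.gene_id}: codon {codon} missing from rate table")
            skipped[codon] += 1
            continue
        log_rates.append(math.log(rate))
    if not log_rates:
        raise ValueError(f"{orf.gene_id}: no scorable codon has a decoding rate")
    return MTDRScore(
        gene_id=orf.gene_id,
        mtdr=float(np.exp(np.mean(log_rates))),
        n_used=len(log_rates),
        n_skipped=int(sum(skipped.values())),
        skipped_codons=skipped,
    )


def score_batch(
    orfs: Sequence[ORFRecord],
    table: DecodingRateTable,
    policy: str = "skip",
    trim_ends: int = 0,
) -> list[MTDRScore]:
    """Score every ORF, preserving order; under the skip policy an
    unscorable ORF yields an NA row (mtdr = NaN) with the reason noted."""
    scores: list[MTDRScore] = []
    for orf in orfs:
        try:
            scores.append(compute_mtdr(orf, table, policy=policy, trim_ends=trim_ends))
        except ValueError as exc:
            if policy == "strict":
                raise
            scores.append(
                MTDRScore(
                    gene_id=orf.gene_id,
                    mtdr=float("nan"),
                    n_used=0,
                    n_skipped=max(orf.n_codons - 1, 0),
                    note=str(exc),
                )
            )
    return scores
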