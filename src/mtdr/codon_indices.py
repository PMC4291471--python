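"""Codon-usage-bias comparison indexes: CAI, tAI, and their
decoding-time transforms (DTCAI / DTtAI).

CAI (Sharp & Li): each codon's weight is its count in a highly expressed
reference set divided by the count of the most used synonym; an ORF's
CAI is the geometric mean of its codons' weights, conventionally
excluding the single-codon families (ATG, TGG).

tAI (dos Reis et al.): each codon's absolute adaptiveness is
W_c = sum over recognizing anticodons of (1 - s) * tGCN, where tGCN is
the genomic tRNA copy number of the anticodon and s the wobble-pairing
penalty; weights are W / max(W), zero weights are replaced by the
geometric mean of the non-zero weights, and an ORF's tAI is the
geometric mean over its sense codons.

DTCAI / DTtAI are decoding-TIME proxies derived from the weights by the
monotone transform 1/w (or -log w with ``log_scale=True``); only their
ranks are ever compared with fitted decoding times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_code import (
    CODON_TO_AA,
    SENSE_CODONS,
    SINGLE_CODON_FAMILY,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    revcomp,
)
from .io_formats import ORFRecord

__all__ = [
    "CAIWeights",
    "TAIWeights",
    "DOS_REIS_S",
    "cai_weights",
    "cai",
    "tai_weights",
    "tai",
    "decoding_time_transform",
]

#: Default wobble-pairing penalties (dos Reis et al. s-values). Keys name
#: the anticodon(34):codon(3) pair; Watson-Crick pairs have penalty 0.
DOS_REIS_S: dict[str, float] = {
    "G:T": 0.41,     # anticodon G34 reading codon-3rd U
    "I:C": 0.28,     # inosine (genomically A34) reading C
    "I:A": 0.9999,   # inosine reading A
    "T:G": 0.68,     # U34 reading G
    "L:A": 0.89,     # lysidine-modified C34 (tRNA gene CAT) reading ATA
}


@dataclass(frozen=True)
class CAIWeights:
    """Relative-adaptiveness weights per sense codon, in (0, 1]."""

    w: Mapping[str, float]
    reference_size: int


@dataclass(frozen=True)
class TAIWeights:
    """Normalized tAI weights per sense codon, in (0, 1]."""

    w: Mapping[str, float]
    tgcn: Mapping[str, float]
    s: Mapping[str, float]


def _codon_counts(orfs: Iterable[ORFRecord]) -> dict[str, int]:
    counts = {c: 0 for c in SENSE_CODONS}
    for orf in orfs:
        for codon in orf.codons():
            if codon in counts:
                counts[codon] += 1
    return counts


def cai_weights(reference_orfs: Sequence[ORFRecord], pseudo: float = 0.5) -> CAIWeights:
    """Sharp-Li weights from a highly expressed reference set.

    w_c = (count_c + pseudo) / max over synonyms of (count + pseudo);
    the pseudo-count keeps unobserved codons strictly positive.
    """
    if not reference_orfs:
        raise ValueError("reference set must be non-empty")
    counts = _codon_counts(reference_orfs)
    w: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        fam_max = max(counts[c] + pseudo for c in codons)
        if fam_max <= 0:
            # family never observed and pseudo=0: fall back to uniform weights
            for c in codons:
                w[c] = 1.0
            continue
        for c in codons:
            w[c] = (counts[c] + pseudo) / fam_max
    return CAIWeights(w=w, reference_size=len(reference_orfs))


def _geometric_mean(values: Sequence[float]) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _index_codons(orf: ORFRecord, exclude: frozenset[str]) -> list[str]:
    codons = orf.codons()
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return [c for c in codons if c in CODON_TO_AA and c not in exclude]


def cai(orf: ORFRecord, weights: CAIWeights, exclude_single_codon_families: bool = True) -> float:
    """Geometric mean of the ORF's codon weights; in (0, 1]."""
    exclude = SINGLE_CODON_FAMILY if exclude_single_codon_families else frozenset()
    codons = _index_codons(orf, exclude)
    if not codons:
        raise ValueError(f"{orf.gene_id}: no scorable codons for CAI")
    return _geometric_mean([weights.w[c] for c in codons])


def _recognizers(codon: str, s: Mapping[str, float]) -> list[tuple[str, float]]:
    """(anticodon, penalty) pairs able to read the codon, wobble included."""
    if codon == "ATG":  # Met: read only by CAT; no wobble from the Ile box
        return [(revcomp(codon), 0.0)]
    stem, third = codon[:2], codon[2]
    pairs = [(revcomp(codon), 0.0)]
    if third == "T":
        pairs.append((revcomp(stem + "C"), s["G:T"]))
    elif third == "C":
        pairs.append((revcomp(stem + "T"), s["I:C"]))
    elif third == "A":
        pairs.append((revcomp(stem + "T"), s["I:A"]))
    else:  # G
        pairs.append((revcomp(stem + "A"), s["T:G"]))
    if codon == "ATA":  # bacterial lysidine tRNA (gene anticodon CAT)
        pairs.append(("CAT", s["L:A"]))
    return pairs


def tai_weights(
    tgcn: Mapping[str, float],
    s: Mapping[str, float] | None = None,
) -> TAIWeights:
    """tAI weights from tRNA gene copy numbers per anticodon.

    Anticodons are written 5'->3' (wobble base first); anticodons absent
    from ``tgcn`` contribute copy number 0.
    """
    s_values = dict(DOS_REIS_S)
    s_values.update(s or {})
    if not any(v > 0 for v in tgcn.values()):
        raise ValueError("all tRNA gene copy numbers are zero")
    absolute: dict[str, float] = {}
    for codon in SENSE_CODONS:
        absolute[codon] = sum(
            (1.0 - penalty) * float(tgcn.get(anticodon, 0.0))
            for anticodon, penalty in _recognizers(codon, s_values)
        )
    w_max = max(absolute.values())
    if w_max <= 0:
        raise ValueError("no sense codon is recognized by any supplied tRNA")
    w = {c: v / w_max for c, v in absolute.items()}
    nonzero = [v for v in w.values() if v > 0]
    fill = _geometric_mean(nonzero)  # dos Reis convention for unrecognized codons
    w = {c: (v if v > 0 else fill) for c, v in w.items()}
    return TAIWeights(w=w, tgcn=dict(tgcn), s=s_values)


def tai(orf: ORFRecord, weights: TAIWeights) -> float:
    """Geometric mean of tAI weights over all sense codons of the ORF."""
    codons = _index_codons(orf, frozenset())
    if not codons:
        raise ValueError(f"{orf.gene_id}: no scorable codons for tAI")
    return _geometric_mean([weights.w[c] for c in codons])


def decoding_time_transform(
    weights: CAIWeights | TAIWeights | Mapping[str, float],
    log_scale: bool = False,
) -> dict[str, float]:
    """Per-codon decoding-time proxy from adaptiveness weights.

    DT_c = 1/w_c by default (-log w_c with ``log_scale=True``); either
    way the transform is strictly decreasing in the weight, so only the
    ranking is meaningful.
    """
    w = weights.w if isinstance(weights, (CAIWeights, TAIWeights)) else weights
    if any(v <= 0 for v in w.values()):
        raise ValueError("weights must be strictly positive")
    if log_scale:
        return {c: -math.log(v) for c, v in w.items()}
    return {c: 1.0 / v for c, v in w.items()}
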