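"""File formats: ORF FASTA, codon-resolution profile TSV, expression TSV,
and the decoding-rate / MTDR-score result tables.

Profile dialect: a header line ``gene_id<TAB>counts`` followed by one row
per gene, where ``counts`` is a comma-separated list of non-negative
decimal numbers, one per codon position. Counts are reals (upstream
pipelines often emit multi-mapping-weighted coverage). Result tables are
TSV with ``#``-prefixed metadata lines and values printed at 12
significant digits, so write-then-read round-trips to 1e-9 relative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .genetic_code import STOP_CODONS, iter_codons

logger = logging.getLogger(__name__)

__all__ = [
    "ORFRecord",
    "GeneProfile",
    "read_fasta",
    "read_profiles",
    "read_expression_table",
    "write_decoding_table",
    "read_decoding_table",
    "write_mtdr_scores",
    "read_mtdr_scores",
]

_VALID_NT = frozenset("ACGT")


@dataclass(frozen=True)
class ORFRecord:
    """One open reading frame: gene id and its in-frame nucleotide sequence."""

    gene_id: str
    sequence: str

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list[str]:
        return iter_codons(self.sequence)


@dataclass
class GeneProfile:
    """One gene's ribosome footprint counts, one value per codon position."""

    gene_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError(f"{self.gene_id}: counts must be a non-empty 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.gene_id}: negative footprint count")

    @property
    def n_codons(self) -> int:
        return int(self.counts.size)


def _validate_orf(gene_id: str, seq: str, strict: bool) -> ORFRecord | None:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"{gene_id}: non-ACGTU character(s) {sorted(bad)}")
    if len(seq) % 3 != 0:
        msg = f"{gene_id}: length {len(seq)} is not a multiple of 3"
        if strict:
            raise ValueError(msg)
        logger.warning("%s; record skipped", msg)
        return None
    if strict:
        # internal (non-terminal) stop codons invalidate the ORF
        for i, codon in enumerate(iter_codons(seq)[:-1]):
            if codon in STOP_CODONS:
                raise ValueError(f"{gene_id}: internal stop codon {codon} at codon {i + 1}")
    return ORFRecord(gene_id=gene_id, sequence=seq)


def read_fasta(path: str | Path, strict: bool = False) -> list[ORFRecord]:
    """Read ORFs from FASTA. gene_id is the first whitespace token of the
    header; sequences are upper-cased with U mapped to T. Records whose
    length is not a multiple of 3 are skipped with a warning (strict=False)
    or raise (strict=True); non-nucleotide characters always raise."""
    records: list[ORFRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        orf = _validate_orf(rec.id, str(rec.seq), strict)
        if orf is not None:
            records.append(orf)
    return records


def read_profiles(path: str | Path, nt_input: bool = False) -> list[GeneProfile]:
    """Read the profile TSV. With ``nt_input=True`` counts are per
    nucleotide and non-overlapping triplets are summed into codon counts
    (trailing remainder positions are rejected)."""
    profiles: list[GeneProfile] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = ""
        for raw in fh:  # skip metadata/blank lines before the header
            stripped = raw.rstrip("\n")
            if stripped and not stripped.startswith("#"):
                header = stripped
                break
        if header.split("\t")[:2] != ["gene_id", "counts"]:
            raise ValueError(f"{path}: expected header 'gene_id\\tcounts', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene_id, counts_str = fields
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if not counts_str:
                raise ValueError(f"{path}:{lineno}: empty counts field")
            try:
                counts = np.array([float(t) for t in counts_str.split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric count") from exc
            if np.any(counts < 0):
                raise ValueError(f"{path}:{lineno}: negative count for {gene_id}")
            if nt_input:
                if counts.size % 3 != 0:
                    raise ValueError(
                        f"{path}:{lineno}: nucleotide profile length {counts.size} "
                        "is not a multiple of 3"
                    )
                counts = counts.reshape(-1, 3).sum(axis=1)
            profiles.append(GeneProfile(gene_id=gene_id, counts=counts))
    return profiles


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV ``gene_id<TAB>value``; non-positive or non-numeric
    values are dropped (count logged). A header row is optional."""
    table: dict[str, float] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene_id, raw = fields[0], fields[1]
            if lineno == 1 and gene_id.lower() in ("gene_id", "gene", "id"):
                continue
            try:
                value = float(raw)
            except ValueError:
                dropped += 1
                continue
            if not math.isfinite(value) or value <= 0:
                dropped += 1
                continue
            table[gene_id] = value
    if dropped:
        logger.info("%s: dropped %d rows with non-positive/non-numeric values", path, dropped)
    return table


def _fmt(x: float) -> str:
    if isinstance(x, bool):
        return "1" if x else "0"
    return f"{x:.12g}"


def _write_table(
    path: str | Path,
    header: Sequence[str],
    rows: Iterable[Sequence],
    metadata: dict | None,
) -> None:
    with open(path, "w") as fh:
        for key, value in sorted((metadata or {}).items()):
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) if isinstance(v, (int, float)) else str(v) for v in row))
            fh.write("\n")


def write_decoding_table(table, path: str | Path, metadata: dict | None = None) -> None:
    """Write a DecodingRateTable as TSV (codon, mu, sigma, lambda, rate,
    n_samples, converged, mean_pause); mean_pause is 1/lambda, reported to
    remove any rate-vs-scale ambiguity in lambda."""
    rows = []
    for codon in sorted(table.entries):
        e = table.entries[codon]
        rows.append(
            (codon, e.mu, e.sigma, e.lam, e.rate, e.n_samples,
             1 if e.converged else 0, 1.0 / e.lam)
        )
    meta = dict(table.metadata or {})
    meta.update(metadata or {})
    _write_table(
        path,
        ("codon", "mu", "sigma", "lambda", "rate", "n_samples", "converged", "mean_pause"),
        rows,
        meta,
    )


def read_decoding_table(path: str | Path):
    """Read a decoding-rate table written by :func:`write_decoding_table`."""
    from .mtdr_index import DecodingRateTable, RateEntry

    entries: dict[str, RateEntry] = {}
    metadata: dict[str, str] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:5] != ["codon", "mu", "sigma", "lambda", "rate"]:
                    raise ValueError(f"{path}: unexpected decoding-table header {header!r}")
                continue
            rec = dict(zip(header, fields))
            entries[rec["codon"]] = RateEntry(
                codon=rec["codon"],
                mu=float(rec["mu"]),
                sigma=float(rec["sigma"]),
                lam=float(rec["lambda"]),
                n_samples=int(rec["n_samples"]),
                converged=rec.get("converged", "1") == "1",
            )
    if header is None:
        raise ValueError(f"{path}: empty decoding table")
    return DecodingRateTable(entries=entries, metadata=metadata)


def write_mtdr_scores(scores, path: str | Path, metadata: dict | None = None) -> None:
    """Write MTDR scores as TSV (gene_id, mtdr, n_codons_used, n_codons_skipped, note)."""
    rows = [
        (s.gene_id,
         "NA" if s.mtdr is None or not math.isfinite(s.mtdr) else _fmt(s.mtdr),
         s.n_used, s.n_skipped, s.note or "")
        for s in scores
    ]
    _write_table(
        path,
        ("gene_id", "mtdr", "n_codons_used", "n_codons_skipped", "note"),
        rows,
        metadata,
    )


def read_mtdr_scores(path: str | Path):
    """Read a score table written by :func:`write_mtdr_scores`."""
    from .mtdr_index import MTDRScore

    scores: list[MTDRScore] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rec = dict(zip(header, fields))
            mtdr = float("nan") if rec["mtdr"] == "NA" else float(rec["mtdr"])
            scores.append(
                MTDRScore(
                    gene_id=rec["gene_id"],
                    mtdr=mtdr,
                    n_used=int(rec["n_codons_used"]),
                    n_skipped=int(rec["n_codons_skipped"]),
                    note=rec.get("note", ""),
                )
            )
    if header is None:
        raise ValueError(f"{path}: empty score table")
    return scores
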