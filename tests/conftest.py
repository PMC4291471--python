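import numpy as np
import pytest

from mtdr.emg_model import EMGParams
from mtdr.io_formats import GeneProfile, ORFRecord


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "orfs.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records.items():
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_profiles_tsv(tmp_path):
    def _write(rows: list[tuple[str, str]], name: str = "profiles.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("gene_id\tcounts\n")
            for gene_id, counts in rows:
                fh.write(f"{gene_id}\t{counts}\n")
        return path

    return _write


def emg_draws(rng: np.random.Generator, p: EMGParams, n: int) -> np.ndarray:
    """Independent EMG sampler used as the test oracle (normal + exponential)."""
    return rng.normal(p.mu, p.sigma, n) + rng.exponential(1.0 / p.lam, n)


@pytest.fixture
def orf():
    def _orf(seq: str, gene_id: str = "g1") -> ORFRecord:
        return ORFRecord(gene_id=gene_id, sequence=seq)

    return _orf


@pytest.fixture
def profile():
    def _profile(counts, gene_id: str = "g1") -> GeneProfile:
        return GeneProfile(gene_id=gene_id, counts=np.asarray(counts, dtype=float))

    return _profile
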