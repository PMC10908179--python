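import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from foldscan.genome_io import GenomicInterval, ReferenceWindow


def make_window(seq: str, chrom: str = "chrT", start: int = 0) -> ReferenceWindow:
    iv = GenomicInterval(chrom, start, start + len(seq))
    return ReferenceWindow(iv, seq, (iv,))


def random_seq(seed: int, length: int, n_frac: float = 0.0) -> str:
    rng = np.random.default_rng(seed)
    seq = ["ACGT"[i] for i in rng.integers(0, 4, length)]
    if n_frac > 0:
        k = max(1, int(length * n_frac))
        for pos in rng.integers(0, length, k):
            seq[pos] = "N"
    return "".join(seq)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Write a small FASTA (with .fai) and return (path, sequences)."""

    def _write(seqs: dict[str, str], name: str = "ref.fa"):
        import pyfaidx

        path = tmp_path / name
        with open(path, "w") as fh:
            for cname, seq in seqs.items():
                fh.write(f">{cname}\n{seq}\n")
        pyfaidx.Faidx(str(path))
        return path

    return _write
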