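import numpy as np
import pytest

from asc import CountTable, Hyperparameters


@pytest.fixture
def hyper() -> Hyperparameters:
    """Hyperparameters at the scale of a deep tag-profiling experiment."""
    return Hyperparameters(alpha=2.0, tau=0.122)


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        gene_id=np.array(["g1", "g2", "g3", "g4", "g5"], dtype=object),
        x1=np.array([10, 5, 0, 200, 0]),
        x2=np.array([1, 5, 2, 50, 0]),
        N1=1_000_000,
        N2=1_000_000,
    )


@pytest.fixture
def write_tsv(tmp_path):
    """Write lines to a temp TSV file and return its path."""

    def _write(lines, name="counts.tsv"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
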