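import numpy as np
import pytest

from causnet.dataset import ExpressionDataset, write_expression


def make_dataset(values: np.ndarray, signed: bool = False) -> ExpressionDataset:
    """Wrap a raw (G, C, T, R) array in a dataset with auto-generated labels."""
    G, C, T, R = values.shape
    return ExpressionDataset(
        gene_ids=tuple(f"g{i}" for i in range(G)),
        condition_ids=tuple(f"c{i}" for i in range(C)),
        time_labels=tuple(f"T{i + 1}" for i in range(T)),
        values=values,
        signed=signed,
    )


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """2 genes x 1 condition x 3 times x 3 replicates, small positive values."""
    rng = np.random.default_rng(42)
    return make_dataset(rng.uniform(0.5, 2.0, size=(2, 1, 3, 3)))


@pytest.fixture
def tiny_tsv(tmp_path, tiny_dataset):
    path = tmp_path / "expr.tsv"
    write_expression(tiny_dataset, path)
    return path
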