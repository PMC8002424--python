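import numpy as np
import pytest

from mieqsar.descriptors import DescriptorMatrix
from mieqsar.synthetic import GeneratorSpec, generate_descriptor_dataset


@pytest.fixture
def toy_csv(tmp_path):
    """Small compound CSV with one unparseable SMILES row."""
    path = tmp_path / "compounds.csv"
    path.write_text(
        "id,cas,smiles,label\n"
        "b1,100-41-4,c1ccccc1CC,1\n"
        "b2,64-17-5,CCO,0\n"
        "b3,,not_a_smiles,1\n"
        "b4,123-03-5,[Cl-].CCCCCCCCCCCCCCCC[n+]1ccccc1,1\n"
    )
    return path


def matrix_from_array(values, ids=None, names=None, mask=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = ids or [f"s{i + 1:03d}" for i in range(n)]
    names = names or [f"D{j + 1:03d}" for j in range(m)]
    mask = mask if mask is not None else np.zeros_like(values, dtype=bool)
    return DescriptorMatrix(ids, names, values, mask)


@pytest.fixture
def separable_dataset():
    """Perfectly separable two-class descriptor set (no noise, no overlap)."""
    spec = GeneratorSpec(n_pos=30, n_neg=30, n_descriptors=5, n_informative=1,
                         class_separation=10.0, overlap_fraction=0.0,
                         label_noise=0.0, seed=7)
    matrix, labels, truth = generate_descriptor_dataset(spec)
    return matrix, labels, truth
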