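import numpy as np
import pytest

from recessmap.genotype_io import GenotypePanel, Marker
from recessmap.synthetic_data import generate_ccdc189_fixture


def make_panel(rows, positions, chromosome="1", samples=None, alleles=("A", "G")):
    """Build a small panel from genotype rows (list of lists) and positions."""
    rows = np.asarray(rows, dtype=np.int8)
    if rows.ndim == 1:
        rows = rows[None, :]
    n_samples, n_markers = rows.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    markers = [
        Marker(
            id=f"m{k + 1}", chromosome=chromosome, position=int(p),
            allele_a=alleles[0], allele_b=alleles[1],
        )
        for k, p in enumerate(positions)
    ]
    return GenotypePanel(markers=markers, samples=samples, genotypes=rows)


@pytest.fixture(scope="session")
def ccdc_fixture():
    return generate_ccdc189_fixture(seed=0)
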