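import numpy as np
import pandas as pd
import pytest

from dermeval.dataio import CountMatrix, HomologyMap, unique_filter
from dermeval.diffexpr import de_contrast
from dermeval.synthdata import (SynthConfig, generate_counts,
                                generate_homology)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_genes=800,
        strains=("B6", "CD1", "MOLF"),
        shared_module_size=100,
        strain_module_size=10,
        interaction_module_size=20,
        strain_response_scale=(1.5, 1.0, 0.6),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A compact synthetic study shared across test modules."""
    return generate_counts(small_config)


@pytest.fixture(scope="session")
def small_hmap(small_config) -> HomologyMap:
    raw = generate_homology(small_config.n_genes, 0, seed=1)
    return HomologyMap(*unique_filter(raw.table))


@pytest.fixture(scope="session")
def small_de(small_study):
    """DE results for two groups of the small study."""
    cm, _ = small_study
    return {
        "B6_M": de_contrast(cm, "B6", "M"),
        "MOLF_M": de_contrast(cm, "MOLF", "M"),
    }


def toy_count_matrix(counts: np.ndarray, genes=None, samples=None,
                     treatments=None, strains=None, sexes=None
                     ) -> CountMatrix:
    """Hand-built CountMatrix for arithmetic-level tests."""
    counts = np.asarray(counts)
    g, s = counts.shape
    genes = genes or [f"Gene{i + 1}" for i in range(g)]
    samples = samples or [f"s{j + 1}" for j in range(s)]
    treatments = treatments or ["CTL" if j < s // 2 else "IMQ"
                                for j in range(s)]
    design = pd.DataFrame({
        "strain": strains or ["B6"] * s,
        "sex": sexes or ["M"] * s,
        "treatment": treatments,
        "replicate": [str(j + 1) for j in range(s)],
    }, index=pd.Index(samples, name="sample_id"))
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                            columns=samples),
        design=design,
    )
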