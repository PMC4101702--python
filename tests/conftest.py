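import numpy as np
import pytest

from pana.compression import CompressionParams, Profile, ProfileSet, build_plm
from pana.simulate import SimulationDesign, simulate


@pytest.fixture(scope="session")
def small_design():
    """A reduced factorial design: 2 sizes x 7 SEPs x 3 fractions."""
    return SimulationDesign(
        gene_counts=(10, 60),
        inner_correlations=(0.0, 0.5, 0.8),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate(small_design)


@pytest.fixture(scope="session")
def small_profile_set(small_dataset):
    params = CompressionParams(alpha=0.05, n_boot=30, seed=11)
    return build_plm(small_dataset.matrix, small_dataset.annotation, params)


def make_profile_set(rows: np.ndarray, pathway_ids=None) -> ProfileSet:
    """Wrap raw score rows as a ProfileSet (one profile per row).

    Each row becomes component 1 of its own pathway unless explicit
    pathway ids are given; gene ids/loadings are left empty (they play no
    role in rule inference).
    """
    rows = np.asarray(rows, dtype=float)
    k, m = rows.shape
    if pathway_ids is None:
        pathway_ids = [f"P{i}" for i in range(k)]
    comp_counter: dict[str, int] = {}
    profiles = []
    for i, pid in enumerate(pathway_ids):
        comp_counter[pid] = comp_counter.get(pid, 0) + 1
        profiles.append(Profile(pid, comp_counter[pid], rows[i],
                                [], np.empty(0), float("nan")))
    return ProfileSet(profiles, [f"s{j}" for j in range(m)])
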