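import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mqtlseq.io_formats import ROLE_NAMES, AlleleCountTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

ROLES = {r: r for r in ROLE_NAMES}


@pytest.fixture
def roles():
    return dict(ROLES)


def make_count_table(
    pos,
    bulk_early,
    bulk_late,
    depth=30,
    chrom="Ca4",
    mean_bq=35.0,
    parent_early=0.0,
    parent_late=1.0,
):
    """Build a deterministic AlleleCountTable from per-SNP bulk alt fractions.

    ``bulk_early``/``bulk_late`` are alt-read fractions; depths are exact
    (no sampling) so expected indices are exact.
    """
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.size

    def cols(frac):
        frac = np.broadcast_to(np.asarray(frac, dtype=float), (n,))
        alt = np.rint(frac * depth).astype(int)
        return depth - alt, alt

    data = {
        "chrom": chrom,
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "mean_bq": np.broadcast_to(np.asarray(mean_bq, dtype=float), (n,)).copy(),
    }
    for name, frac in (
        ("parent_early", parent_early),
        ("parent_late", parent_late),
        ("bulk_early", bulk_early),
        ("bulk_late", bulk_late),
    ):
        r, a = cols(frac)
        data[name + "_ref"] = r
        data[name + "_alt"] = a
    return AlleleCountTable(pd.DataFrame(data), list(ROLES))


@pytest.fixture
def small_table():
    return make_count_table(
        pos=[1_000, 2_000, 3_000, 4_000],
        bulk_early=[0.0, 0.5, 1.0, 0.9],
        bulk_late=[1.0, 0.5, 0.0, 0.1],
    )


@pytest.fixture(scope="session")
def genome_annotation():
    from mqtlseq.synthetic_data import generate_gene_models

    return generate_gene_models(seed=2)
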