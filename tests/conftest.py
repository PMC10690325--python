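import pandas as pd
import pytest

from genagephen.age_framework import AgeFramework
from genagephen.synthdata import SimulationConfig, simulate_dataset

SMALL_GENES_PER_BRANCH = {
    "br0": 900, "br1": 300, "br2": 300, "br3": 700,
    "br4": 300, "br5": 300, "br6": 200,
}


@pytest.fixture(scope="session")
def framework() -> AgeFramework:
    return AgeFramework()


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    """A modest synthetic bundle on disk, with filter-stress extras so the
    ingest filters have material."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=11, genes_per_branch=SMALL_GENES_PER_BRANCH,
                              filter_stress=True)
    simulate_dataset(config, out)
    return out


def make_profiles(rows):
    """Profile frame from (gene_id, systems, branch[, reproductive_class,
    chromosome]) tuples."""
    recs = []
    for row in rows:
        gene_id, systems = row[0], frozenset(row[1])
        branch = row[2] if len(row) > 2 else "br0"
        cls = row[3] if len(row) > 3 else "none"
        chrom = row[4] if len(row) > 4 else "1"
        recs.append({
            "gene_id": gene_id, "systems": systems, "m": len(systems),
            "reproductive_class": cls,
            "is_reproductive": cls != "none" or "OP7" in systems,
            "branch": branch, "chromosome": chrom, "start": 1000, "end": 2000,
        })
    return pd.DataFrame(recs)
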