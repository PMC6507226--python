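import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dmrscan as ds
from dmrscan.synth import SimulationDesign, simulate

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """Small planted-DMR study reused across tests: 120 kb over two
    chromosomes, 10 genes, 4 planted DMRs (2 hyper / 2 hypo), 20x."""
    design = SimulationDesign(genome_length_bp=120_000, n_chromosomes=2,
                              n_genes=10, n_planted_dmrs=4,
                              coverage_mean=20.0, rng_seed=7)
    return simulate(design)


@pytest.fixture(scope="session")
def detected(bundle):
    windows, dmrs = ds.detect_dmrs(bundle.methylome)
    return windows, dmrs


@pytest.fixture(scope="session")
def called_sites(bundle):
    conv = ds.estimate_conversion(bundle.spikein)
    called = ds.call_methylated_sites(bundle.methylome, conv.failure_rate)
    return {g: ds.group_called_sites(called, bundle.methylome.group_of, g)
            for g in ("treatment", "control")}


@pytest.fixture()
def toy_genome():
    return ds.GenomeStore({"chrA": "ACGTACGTAACCGGTTACGT",
                           "chrB": "TTTTCTTTTGAAAACAAAA"})


def make_methylome(site_tables, chrom_sizes=None):
    """Two-sample one-per-group methylome from raw per-sample frames."""
    samples = list(site_tables)
    group_of = {s: ("treatment" if s.startswith("t") else "control")
                for s in samples}
    return ds.MethylomeSet(samples=samples, group_of=group_of,
                           tables=site_tables, chrom_sizes=chrom_sizes)


def site_frame(chrom, positions, meth, unmeth, strand="+", context="CHH"):
    n = len(positions)
    return pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "strand": strand, "meth_count": np.asarray(meth, dtype=np.int64),
        "unmeth_count": np.asarray(unmeth, dtype=np.int64),
        "context": [context] * n if isinstance(context, str) else context,
    })
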