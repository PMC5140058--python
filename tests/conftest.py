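import numpy as np
import pytest

from ibcpipe.clonal import CCFRecord
from ibcpipe.synthdata import SimulationConfig, TruthBundle, expected_vaf, simulate_cohort, write_fixture


@pytest.fixture(scope="session")
def small_bundle() -> TruthBundle:
    return simulate_cohort(SimulationConfig(n_patients=2, seed=42))


@pytest.fixture(scope="session")
def fixture_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    manifest = write_fixture(small_bundle, d)
    return d, manifest


def make_planted_records(ccf_pairs, n_per_cluster, depth=400, purity=0.8, seed=7,
                         chrom="chr1"):
    """Planted clonal clusters as CCFRecord maps, plus true labels.

    ``ccf_pairs``: list of (pre CCF, post CCF) per cluster; diploid loci,
    multiplicity 1, Poisson depth, binomial alt reads.
    """
    rng = np.random.default_rng(seed)
    records, labels = {}, {}
    pos = 0
    for ci, pair in enumerate(ccf_pairs):
        for _ in range(n_per_cluster):
            pos += 1
            key = (chrom, pos, "C", "T")
            labels[key] = ci
            per_sample = {}
            for sample, ccf in zip(("pre", "post"), pair):
                dp = max(int(rng.poisson(depth)), 1)
                alt = int(rng.binomial(dp, expected_vaf(purity, 2, 1, ccf)))
                vaf = alt / dp
                nmut = vaf * (purity * 2 + 2 * (1 - purity)) / purity
                per_sample[sample] = CCFRecord(
                    key, sample, 1, nmut, min(nmut, 1.0), alt, dp, 2, 1, purity)
            records[key] = per_sample
    return records, labels


def partition_labels(clusters, keys):
    """Flatten retained+excluded clusters into a key->cluster-id map."""
    lab = {}
    for c in clusters:
        for k in c.members:
            lab[k] = c.cluster_id
    return [lab[k] for k in keys]
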