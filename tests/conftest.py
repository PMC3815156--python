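import os

import pytest

from txlandscape import esnv, simulate


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort: 4 groups x 8 samples, 150 genes, 10 planted DE."""
    return simulate.SimulationConfig(seed=11, n_genes=150, n_de_genes=10, n_as_genes=8)


@pytest.fixture(scope="session")
def cohort(small_config):
    counts, truth = simulate.generate_cohort_counts(small_config)
    return counts, truth


@pytest.fixture(scope="session")
def groups(small_config):
    return simulate.sample_groups(small_config)


@pytest.fixture(scope="session")
def pileup_dir(tmp_path_factory):
    """One synthetic dual-pileup cohort (3 samples/group, 12 true variants)."""
    cfg = simulate.SimulationConfig(seed=3, n_per_group=3, n_variants=12)
    d = tmp_path_factory.mktemp("pileups")
    truth = simulate.generate_pileup_pair(cfg, d)
    return cfg, d, truth


@pytest.fixture(scope="session")
def pileup_refs(pileup_dir):
    _, d, _ = pileup_dir
    transcripts = esnv.read_refflat(os.path.join(d, "genes.refflat"))
    genome = esnv.read_genome(os.path.join(d, "genome.fa"))
    known = esnv.load_known_sites(os.path.join(d, "known_sites.vcf"))
    return transcripts, genome, known


def run_esnv_cohort(cfg, d, truth):
    """Full per-sample chain + cohort database for a synthetic pileup dir."""
    transcripts = esnv.read_refflat(os.path.join(d, "genes.refflat"))
    genome = esnv.read_genome(os.path.join(d, "genome.fa"))
    known = esnv.load_known_sites(os.path.join(d, "known_sites.vcf"))
    db = esnv.CohortVariantDB(simulate.sample_groups(cfg).to_dict())
    for s in simulate.sample_names(cfg):
        bwa = os.path.join(d, f"{s}.bwa.pileup")
        if not os.path.exists(bwa):
            continue
        db.add_calls(
            esnv.call_sample(
                bwa,
                os.path.join(d, f"{s}.tophat.pileup"),
                sample=s,
                transcripts=transcripts,
                genome=genome,
                known=known,
            )
        )
    return db
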