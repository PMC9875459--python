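import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyhap import synthetic
from polyhap.alignment import progressive_msa
from polyhap.haplotyping import call_haplotypes
from polyhap.io_core import load_sugar_traits

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def traits():
    return load_sugar_traits()


@pytest.fixture(scope="session")
def small_study():
    """An error-free small simulated study shared across tests:
    template -> planted haplotypes -> assignment -> clones -> called -> MSA."""
    template = synthetic.make_template(
        11, exon_lengths=(60, 90, 60), intron_lengths=(80, 80)
    )
    haps, truth = synthetic.plant_haplotypes(
        template, n_hap=8, n_snp=16, n_indel=2, seed=12, large_insertion=None
    )
    assignment = synthetic.assign_to_accessions(
        truth.hap_ids, n_acc=8, ploidy=4, shared_fraction=0.4, seed=13
    )
    clones = synthetic.simulate_clones(
        assignment, truth.hap_seqs, clones_per_acc=10, error_rate=0.0,
        dropout=0.0, seed=14,
    )
    called, table = call_haplotypes(clones, min_support=2)
    ref_id = next(h.hap_id for h in called if h.seq == template.seq)
    aln = progressive_msa([(h.hap_id, h.seq) for h in called])
    return {
        "template": template,
        "truth": truth,
        "assignment": assignment,
        "clones": clones,
        "called": called,
        "table": table,
        "ref_id": ref_id,
        "aln": aln,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
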