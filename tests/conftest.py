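import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "covbias",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("covbias")

from covbias import CoverageProfile, ExperimentMeta, GeneModel, ProfileSet


def make_profile_set(matrix_by_gene, labs=None, read_length=5):
    """Build a ProfileSet from {gene_id: {experiment_id: values}}.

    Gene intervals are laid out consecutively on one chromosome; lab
    assignment defaults to one lab per experiment.
    """
    gene_ids = list(matrix_by_gene)
    exp_ids = sorted({e for g in matrix_by_gene.values() for e in g})
    labs = labs or {e: e for e in exp_ids}
    genes = []
    pos = 0
    for gid in gene_ids:
        length = len(next(iter(matrix_by_gene[gid].values())))
        genes.append(GeneModel(gid, "chr1", pos, pos + length, "+"))
        pos += length + 10
    experiments = [
        ExperimentMeta(e, labs[e], read_length=read_length) for e in exp_ids
    ]
    profiles = {
        (gid, eid): CoverageProfile(gid, eid, np.asarray(vals))
        for gid, by_exp in matrix_by_gene.items()
        for eid, vals in by_exp.items()
    }
    return ProfileSet(profiles, genes, experiments)


@pytest.fixture
def profile_set_factory():
    return make_profile_set
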