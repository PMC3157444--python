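import pytest

from mycnet import SimulationConfig, generate_study

# compact study with strong planted effects: fast to generate, and powered
# so that planted features are recovered essentially surely
SMALL_STUDY_KW = dict(
    n_genes=60, n_mirnas=15, n_replicates_per_group=3,
    mrna_effect_log2=4.0, mrna_noise_sd=0.15,
    mirna_effect_dct=-4.0, ct_noise_sd=0.2,
    n_motif_genes=4, n_mirna_target_genes=3, n_overlap_genes=2,
    promoter_len_upstream=400, first_exon_len=100, utr_len=150,
    n_genesets=6, geneset_size=10,
)

# the full-size end-to-end study conditions (200 genes, 40 miRNAs,
# 12-gene motif arm, 9-gene miRNA arm, 4-gene overlap)
E2E_STUDY_KW = dict(
    mrna_effect_log2=4.0, mrna_noise_sd=0.15,
    mirna_effect_dct=-4.0, ct_noise_sd=0.2, n_replicates_per_group=3,
)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SimulationConfig(seed=7, **SMALL_STUDY_KW))
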