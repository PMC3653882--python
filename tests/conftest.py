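import pytest

from tagdge import (
    SimConfig,
    build_index,
    filter_tags,
    generate_transcriptome,
    generate_truth,
    simulate_tag_library,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale design: 50 genes, two 20k-tag libraries, all noise classes on."""
    return SimConfig(
        n_genes=50,
        length_range=(150, 600),
        depth_per_library=20_000,
        de_fraction=0.2,
        log2fc_magnitude=2.0,
        error_rate=0.01,
        n_rate=0.01,
        singleton_rate=0.02,
        antisense_fraction=0.3,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(config, transcripts, truth, index) for the small design."""
    transcripts = generate_transcriptome(small_config)
    truth = generate_truth(small_config)
    index = build_index(transcripts)
    return small_config, transcripts, truth, index


@pytest.fixture(scope="session")
def small_libraries(small_world):
    """Raw and clean libraries for both conditions of the small design."""
    cfg, transcripts, truth, index = small_world
    out = []
    for lib in range(cfg.n_libraries):
        raw = simulate_tag_library(transcripts, truth, lib, cfg)
        clean, ledger = filter_tags(raw)
        out.append((raw, clean, ledger))
    return out
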