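import pytest

from raid import (
    ArcLayout,
    SimConfig,
    build_transcript_index,
    generate_cell_index,
    generate_panel,
    simulate_ground_truth,
    simulate_reference,
    write_fastq_pair,
)


@pytest.fixture(scope="session")
def layout():
    return ArcLayout()


@pytest.fixture(scope="session")
def panel(layout):
    return generate_panel(
        ("pFAK", "pRPS6", "NOTCH1", "JAG1", "KLK6", "TGM1"), layout.ab_barcode_len, seed=11
    )


def make_library(tmp_path, config, layout=None, panel_seed=11):
    """Simulate ground truth and render it to FASTQ under ``tmp_path``.

    Returns everything downstream stages need, so each test can build a
    library at its own scale.
    """
    layout = layout or ArcLayout()
    truth = simulate_ground_truth(config)
    lib_panel = generate_panel(config.antibodies, layout.ab_barcode_len, panel_seed)
    cell_index = generate_cell_index(list(truth.cells.index), seed=config.seed)
    reference = simulate_reference(truth.genes, config.reference_len, config.seed)
    output = write_fastq_pair(truth, layout, lib_panel, cell_index, reference, config, tmp_path)
    index = build_transcript_index(reference, 21)
    return {
        "truth": truth,
        "layout": layout,
        "panel": lib_panel,
        "cell_index": cell_index,
        "reference": reference,
        "index": index,
        "output": output,
    }


@pytest.fixture()
def tiny_library(tmp_path):
    """~2.5k-read library: 5 cells per group, 20 genes, error-free."""
    config = SimConfig(
        n_cells_per_group=5,
        n_genes=20,
        n_stem_genes=5,
        n_diff_genes=5,
        n_integrin_substrates=2,
        mrna_mean=3.0,
        arc_mean=20.0,
        error_rate=0.0,
        seed=7,
    )
    lib = make_library(tmp_path, config)
    lib["config"] = config
    return lib
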