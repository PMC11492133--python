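import numpy as np
import pytest

import tfcrkit as tk


def make_tfbs(chrom, midpoint, tf_name="TFX", family="FAMX", width=15):
    """A TFBS whose interval midpoint lands exactly at ``midpoint``."""
    start = midpoint - width // 2
    return tk.TFBSRecord(
        interval=tk.GenomicInterval(chrom, start, start + width),
        tf_name=tf_name,
        tf_family=family,
        scan_score=10.0,
    )


def make_tfcr(tfcr_id, chrom, start, end, peak_pos=None, tc=1.0, stage="s"):
    return tk.TFCR(
        tfcr_id=tfcr_id,
        stage=stage,
        interval=tk.GenomicInterval(chrom, start, end),
        peak_pos=peak_pos if peak_pos is not None else (start + end) // 2,
        tc=tc,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default single-stage synthetic bundle (the study conditions)."""
    out = tmp_path_factory.mktemp("bundle")
    config = tk.SyntheticConfig(seed=1, n_genes=500)
    paths, truth = tk.generate_bundle(config, str(out))
    return config, paths, truth


@pytest.fixture(scope="session")
def called_bundle(bundle):
    """The default bundle run through the caller and linker."""
    _, paths, truth = bundle
    fam = tk.read_family_map(paths.family_map)
    tfbs = tk.read_fimo_tfbs(paths.tfbs, fam)
    tracks = tk.kde_density(tfbs)
    tfcrs = tk.call_tfcrs(tracks, tfbs, stage="stage")
    genes = tk.read_gene_tss(paths.genes, format="bed")
    return {"tfbs": tfbs, "tfcrs": tfcrs, "genes": genes, "paths": paths, "truth": truth}


@pytest.fixture(scope="session")
def panel(tmp_path_factory):
    """Default 5-stage synthetic panel with a planted activation stage."""
    out = tmp_path_factory.mktemp("panel")
    config = tk.SyntheticConfig(seed=1, n_genes=400)
    stage_paths, truth = tk.generate_stage_panel(config, str(out))
    return config, stage_paths, truth


@pytest.fixture(scope="session")
def panel_run(panel, tmp_path_factory):
    """Full pipeline report over the default panel."""
    _, stage_paths, truth = panel
    first = stage_paths[truth.stage_names[0]]
    stages = [
        tk.StageInputs(
            name=s,
            tfbs=p.tfbs,
            atac=p.atac,
            expression=p.expression,
            tads=p.tads,
        )
        for s, p in stage_paths.items()
    ]
    config = tk.RunConfig(
        stages=stages,
        genes=first.genes,
        family_map=first.family_map,
        pstf_list=first.pstf_list,
        output_dir=str(tmp_path_factory.mktemp("panel_run")),
        seed=11,
    )
    report = tk.run_panel(config)
    return config, report, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
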