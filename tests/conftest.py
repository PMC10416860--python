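import numpy as np
import pytest

from octdme.phantom import PhantomSpec, default_phantom_spec, generate_phantom

# desk-scale pipeline geometry: 128 px phantoms, pixel pitch scaled so the
# retina fills the same fraction of the frame as 192 px at 11.7 um/px
PIPE_SIZE = 128
PIPE_UM = 11.7 * 192.0 / PIPE_SIZE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_benign_spec(seed: int = 0) -> PhantomSpec:
    return default_phantom_spec(PIPE_SIZE, PIPE_SIZE, um_per_px=PIPE_UM, seed=seed)


def make_severe_spec(seed: int = 0) -> PhantomSpec:
    """Central DRIL, five sub-OPL HRFs and one 500x350 um cystoid."""
    base = default_phantom_spec(PIPE_SIZE, PIPE_SIZE, um_per_px=PIPE_UM, seed=seed)
    opl_top, _ = base.opl_band_rows()
    a = round(500.0 / PIPE_UM / 2)  # ~14 px
    b = round(350.0 / PIPE_UM / 2)  # ~10 px
    hrf_rows = opl_top + 12
    return default_phantom_spec(
        PIPE_SIZE,
        PIPE_SIZE,
        um_per_px=PIPE_UM,
        seed=seed,
        dril_region=(base.fovea_col - 12, base.fovea_col + 20),
        hrf_list=((hrf_rows, 14, 2), (hrf_rows + 6, 30, 2), (hrf_rows, 100, 2), (hrf_rows + 8, 114, 2), (hrf_rows + 16, 20, 2)),
        cystoid_list=((opl_top + 22, 64, a, b),),
    )


@pytest.fixture(scope="session")
def pipeline_setup(tmp_path_factory):
    """Train the five desk-scale models once per session and expose a
    PipelineConfig pointing at the saved checkpoints."""
    from octdme.classification import ClassifierConfig, save_classifier
    from octdme.pipeline import PipelineConfig
    from octdme.segmentation import UNetConfig, save_model
    from octdme.workflows import (
        train_centrality_classifier_on_phantoms,
        train_dril_classifier_on_phantoms,
        train_segmenter_on_phantoms,
    )

    root = tmp_path_factory.mktemp("models")
    dril, _, _, _ = train_dril_classifier_on_phantoms(
        n_train=60, n_test=0, config=ClassifierConfig(input_size=PIPE_SIZE, epochs=20, seed=0), seed=0
    )
    save_classifier(dril, root / "dril.npz")
    cent, _, _ = train_centrality_classifier_on_phantoms(
        n_train=50, n_test=0, config=ClassifierConfig(input_size=PIPE_SIZE, epochs=20, seed=0), seed=0,
        phantom_size=PIPE_SIZE,
    )
    save_classifier(cent, root / "centrality.npz")
    for target, epochs in (("hrf", 30), ("opl", 12), ("cystoid", 20)):
        cfg = UNetConfig(input_size=PIPE_SIZE, epochs=epochs, seed=0)
        model, _, _ = train_segmenter_on_phantoms(target, n_train=16, n_test=0, config=cfg, seed=0)
        save_model(model, root / f"{target}.npz")
    return PipelineConfig(
        um_per_px=PIPE_UM,
        dril_model=str(root / "dril.npz"),
        centrality_model=str(root / "centrality.npz"),
        hrf_model=str(root / "hrf.npz"),
        opl_model=str(root / "opl.npz"),
        cystoid_model=str(root / "cystoid.npz"),
        out_dir=str(root / "reports"),
    )
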