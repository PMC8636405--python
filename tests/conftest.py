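import numpy as np
import pytest

from cliffpix.curation import CompoundRecord, canonicalize_smiles


def make_compound(cid: str, smiles: str, pki: float) -> CompoundRecord:
    canon = canonicalize_smiles(smiles)
    assert canon is not None, f"fixture SMILES {smiles!r} must parse"
    return CompoundRecord(cid, canon[0], pki, canon[1])


@pytest.fixture(scope="session")
def toy_series():
    """A small analog series around toluene-like cores for MMP tests."""
    return [
        make_compound("m1", "Cc1ccccc1", 6.0),  # toluene
        make_compound("m2", "CCc1ccccc1", 6.5),  # ethylbenzene
        make_compound("m3", "CCCc1ccccc1", 8.4),  # propylbenzene
        make_compound("m4", "OCc1ccccc1", 7.1),  # benzyl alcohol
    ]


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """One reduced-profile benchmark run shared by the acceptance tests.

    Training the image classifier dominates the suite's runtime, so the
    learning and attribution properties are checked against the same
    two-trial run.
    """
    from cliffpix.pipeline import reduced_run_config, run_pipeline

    config = reduced_run_config(
        synthetic_seed=11,
        base_seed=7,
        out_dir=str(tmp_path_factory.mktemp("benchmark_run")),
        explain_layers=(),  # attribution tests drive gradcam directly
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small planted-signal model for fast network/attribution tests.

    Images are 24x72 with three 24-pixel panels; class 1 images carry a
    dark block in the middle (substituent) panel.  A short training run
    separates the classes, giving the attribution tests a model whose
    discriminative feature is known by construction.
    """
    from cliffpix.classifier import CNNClassifier, ModelConfig

    rng = np.random.default_rng(5)
    n = 48
    images = np.ones((n, 24, 72, 3), dtype=np.float32)
    labels = rng.integers(0, 2, size=n)
    labels[:2] = [0, 1]  # both classes present
    for img, lab in zip(images, labels):
        noise = rng.random((24, 72, 3), dtype=np.float32) * 0.1
        img -= noise
        if lab == 1:
            img[8:16, 32:40, :] = 0.0  # dark feature in the middle panel
    cfg = ModelConfig(
        input_shape=(24, 72, 3), epochs=8, batch_size=8, seed=3, dropout_rate=0.1
    )
    model = CNNClassifier(cfg)
    history = model.fit(images, labels)
    return model, images, labels, history
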