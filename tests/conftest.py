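import numpy as np
import pytest

import herdface as hf


@pytest.fixture(scope="session")
def synth_spec():
    """Small image world: 3 mates + 1 non-mate, 128 px canvases."""
    return hf.SynthSpec(n_mates=3, n_nonmates=1, dimension=64, sigma=0.05, seed=42)


@pytest.fixture(scope="session")
def identities(synth_spec):
    return hf.make_identities(synth_spec)


@pytest.fixture(scope="session")
def rendered_face(identities, synth_spec):
    """One upright rendered face with exact ground truth."""
    return hf.render_face(identities[0], 0.0, synth_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_encoder():
    return hf.ToyEncoder(dimension=64)


def chip_from_render(frame, box, lm, chip_side=112):
    sq = hf.squarify(box, frame.width, frame.height)
    return hf.align_chip(frame, sq, lm, chip_side)


@pytest.fixture(scope="session")
def embedding_gallery(identities):
    """Gallery of synthetic embeddings: every mate enrolled with 10 records."""
    rng = np.random.default_rng(7)
    gallery = hf.Gallery()
    for ident in identities:
        if ident.is_mate:
            hf.enroll(
                gallery,
                ident.identity_id,
                [hf.sample_embedding(ident, rng) for _ in range(15)],
                hf.EnrollmentConfig(nim_target=10),
            )
    return gallery
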