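import numpy as np
import pytest

import sacssl as S


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A small generated dataset with patient-level splits, shared per session."""
    out = tmp_path_factory.mktemp("synth")
    spec = S.SyntheticSpec(
        n_classes=3, k_true=3, images_per_subclass=12, image_size=32,
        noise_sd=0.08, n_patients=12, seed=11,
    )
    manifest = S.generate_dataset(spec, out)
    manifest = S.split_by_patient(manifest, 0.2, 0.2, seed=11)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def random_multiview_batch(rng, bu, n_classes, dim):
    """Random unit embeddings plus view-paired soft pseudo-labels."""
    z = rng.normal(size=(2 * bu, dim))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    logits = rng.normal(scale=2.0, size=(bu, n_classes))
    q = np.exp(logits)
    q /= q.sum(axis=1, keepdims=True)
    q_tilde = np.vstack([q, q])
    return z, q_tilde
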