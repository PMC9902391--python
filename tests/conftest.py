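import numpy as np
import pytest

from dicascade.extractor import DetectedObject


def as_object(mask: np.ndarray) -> DetectedObject:
    """Wrap a bare boolean mask as a DetectedObject at origin."""
    rr, cc = np.nonzero(mask)
    return DetectedObject(mask_crop=np.asarray(mask, dtype=bool),
                          bbox=(0, 0, mask.shape[0], mask.shape[1]),
                          centroid=(float(rr.mean()), float(cc.mean())),
                          object_id=1)


@pytest.fixture(scope="session")
def tiny_tile_corpus():
    """Small seeded tile corpus shared by CNN and pipeline tests."""
    from dicascade.synthetic import make_tile_dataset

    tiles, labels = make_tile_dataset(150, 5.0, seed=90, entangled_fraction=0.0)
    return tiles, labels


@pytest.fixture(scope="session")
def tiny_models(tiny_tile_corpus):
    """A quickly trained cascade (small corpus, few epochs) for tests that
    need real TrainedModel objects rather than good classifiers."""
    from dicascade.cnn import (TrainingConfig, build_architecture,
                               mine_stage2_training_set, train_stage)

    tiles, labels = tiny_tile_corpus
    cfg1 = TrainingConfig(lr=0.01, epochs=5, batch_size=16,
                          dic_oversample=3, seed=90)
    m1 = train_stage(build_architecture(1), tiles, labels, cfg1)
    pool = mine_stage2_training_set(m1, tiles, labels, batch_size=64,
                                    min_negatives=30)
    cfg2 = TrainingConfig(lr=0.01, epochs=3, batch_size=16,
                          dic_oversample=2, seed=91)
    m2 = train_stage(build_architecture(2), tiles, labels, cfg2, indices=pool)
    return m1, m2
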