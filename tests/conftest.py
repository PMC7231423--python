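import numpy as np
import pytest

import szdetect as sz


@pytest.fixture(scope="session")
def stft_config():
    return sz.StftConfig()


@pytest.fixture(scope="session")
def long_record():
    """3600 s record with one 40 s seizure at [300, 340]."""
    return sz.generate_record(
        sz.SynthConfig(duration_s=3600.0,
                       seizure_intervals=[sz.SeizureInterval(300.0, 340.0)],
                       seed=11)
    )


@pytest.fixture(scope="session")
def image_bank_400():
    """Balanced 400-image synthetic dataset built through the full pipeline.

    Each image comes from its own 180 s record (one sliding window);
    positives carry a 120 s seizure burst, negatives are background only.
    """
    records = []
    for k in range(400):
        seizures = [sz.SeizureInterval(30.0, 150.0)] if k % 2 else []
        records.append(
            sz.generate_record(
                sz.SynthConfig(duration_s=180.0, seizure_intervals=seizures,
                               seed=1000 + k)
            )
        )
    dataset = sz.build_dataset(records)
    assert len(dataset) == 400 and dataset.class_balance == 0.5
    return dataset


@pytest.fixture(scope="session")
def small_image_bank(image_bank_400):
    """A balanced 80-image subset for fast model tests."""
    idx = np.arange(80)
    return sz.ImageDataset(images=image_bank_400.images[idx],
                           labels=image_bank_400.labels[idx],
                           manifest=image_bank_400.manifest.iloc[idx]
                           .reset_index(drop=True))
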