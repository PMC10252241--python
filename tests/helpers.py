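import numpy as np

from kneeoa.data import GradedImageSet, ImageRecord


def make_tiny_set(counts: dict[int, int], split: str = "train", size: int = 8,
                  seed: int = 0) -> GradedImageSet:
    """Grade-labelled random tiny images for bookkeeping-level tests."""
    rng = np.random.default_rng(seed)
    records = [
        ImageRecord(image=rng.random((size, size)), grade=grade, split=split)
        for grade, n in counts.items()
        for _ in range(n)
    ]
    return GradedImageSet(records)
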