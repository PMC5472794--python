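"""Shared fixtures: one fully processed synthetic nucleus reused across tests."""

from dataclasses import dataclass

import numpy as np
import pytest

from nanofoci import imaging
from nanofoci.synthetic import make_nucleus_image


@dataclass
class ProcessedNucleus:
    stack: object
    truth: object
    nucleus: object
    labels: np.ndarray
    foci: object  # DataFrame


def _process(seed: int, **kwargs) -> ProcessedNucleus:
    stack, truth = make_nucleus_image(seed=seed, **kwargs)
    nucleus = imaging.segment_nucleus(stack, "dapi", 1000.0, min_volume_um3=20.0)
    labels = imaging.detect_foci(stack, "gamma", nucleus)
    labels = imaging.separate_touching(
        labels, stack.channel("gamma"), stack.voxel_size_nm
    )
    foci = imaging.foci_table(labels, stack, "gamma", nucleus)
    return ProcessedNucleus(stack, truth, nucleus, labels, foci)


@pytest.fixture(scope="session")
def default_nucleus() -> ProcessedNucleus:
    """Default synthetic nucleus (5 clusters x 4 foci), fully segmented."""
    return _process(seed=1)


@pytest.fixture(scope="session")
def sparse_nucleus() -> ProcessedNucleus:
    """Well-separated single foci (no clustering), noiseless channels."""
    return _process(seed=3, n_clusters=5, foci_per_cluster=1, noise_sigma=0.0)
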