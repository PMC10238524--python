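import numpy as np
import pytest

import mvmar as m

BENCH_SEED = 1  # fixed acquisition seed for all simulation-backed checks


@pytest.fixture(scope="session")
def geom_small() -> m.ScanGeometry:
    """Fast unit-test geometry."""
    return m.ScanGeometry((96, 96), 1.0, 90)


@pytest.fixture(scope="session")
def geom_default() -> m.ScanGeometry:
    """The study geometry: 256x256 slice at 1 mm, 180 angles."""
    return m.ScanGeometry((256, 256), 1.0, 180)


@pytest.fixture(scope="session")
def dental_pair(geom_default) -> m.ScanPair:
    """Multi-metal dental phantom acquisition at the default study conditions."""
    return m.simulate_scan_pair(m.dental_phantom(), m.default_kv_spectrum(),
                                m.default_mv_spectrum(), geom_default, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def dental_noiseless(geom_default) -> m.ScanPair:
    """Same phantom without counting noise: deterministic artifact content."""
    return m.simulate_scan_pair(m.dental_phantom(), m.default_kv_spectrum(),
                                m.default_mv_spectrum(), geom_default,
                                seed=BENCH_SEED, noiseless=True)


@pytest.fixture(scope="session")
def dental_metal(dental_pair) -> m.MetalMask:
    return m.segment_metal(dental_pair.kv_image)


@pytest.fixture(scope="session")
def dental_masks(dental_pair, dental_metal) -> m.TissueMasks:
    return m.blockwise_segment(dental_pair.mv_image, metal_hint=dental_metal)


@pytest.fixture(scope="session")
def rod_noiseless(geom_default) -> m.ScanPair:
    """Rod phantom, noise-free: deterministic single-metal artifact content."""
    return m.simulate_scan_pair(m.rod_phantom(), m.default_kv_spectrum(),
                                m.default_mv_spectrum(), geom_default,
                                seed=BENCH_SEED, noiseless=True)


@pytest.fixture(scope="session")
def dental_methods(geom_default, dental_pair, dental_metal) -> dict:
    """All four method images for the dental benchmark plus diagnostics."""
    roi = m.dental_rois()["inter_metal"]
    result = m.iterate_mar(dental_pair.kv_image, dental_pair.mv_image, geom_default,
                           m.MarConfig(), metal=dental_metal,
                           truth=dental_pair.ground_truth_kv, roi=roi)
    return {
        "original": dental_pair.kv_image,
        "limar": m.limar(dental_pair.kv_image, dental_metal, geom_default),
        "nmar": m.nmar(dental_pair.kv_image, dental_metal, geom_default),
        "proposed": result.corrected,
        "result": result,
        "roi": roi,
    }
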