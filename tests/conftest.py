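import numpy as np
import pytest

import panobreast as pb


@pytest.fixture(scope="session")
def phantom8():
    """Coarse default phantom (8 mm voxels) for fast geometric checks."""
    spec = pb.PhantomSpec(voxel_spacing=8.0)
    return spec, pb.build_phantom(spec)


@pytest.fixture(scope="session")
def phantom6():
    """Medium-resolution phantom (6 mm) for rotation-recovery checks."""
    spec = pb.PhantomSpec(voxel_spacing=6.0)
    return spec, pb.build_phantom(spec)


@pytest.fixture(scope="session")
def coil8(phantom8):
    """8-channel sub-array with sensitivities, covariance and noisy data."""
    spec, ph = phantom8
    layout = pb.build_coil_layout(spec, n_modules=4, coils_per_module=2)
    sens = pb.loop_sensitivity(layout, ph.signal)
    cov = pb.make_noise_cov(layout.channel_count, 5e-4, 0.065)
    mc, noise = pb.simulate_multicoil(ph.signal, sens, cov, seed=11)
    return {"layout": layout, "sens": sens, "cov": cov, "mc": mc, "noise": noise}


@pytest.fixture(scope="session")
def coil28(phantom8):
    """Full 28-channel conformal array on the coarse phantom."""
    spec, ph = phantom8
    layout = pb.build_coil_layout(spec)
    sens = pb.loop_sensitivity(layout, ph.signal)
    cov = pb.make_noise_cov(layout.channel_count, 5e-4, 0.065)
    return {"layout": layout, "sens": sens, "cov": cov}


@pytest.fixture(scope="session")
def coronal_slice(phantom8, coil28):
    """Coronal slice through the fullest breast section: sensitivities,
    object support and breast-ROI masks."""
    _, ph = phantom8
    roi = ph.breast_roi.data
    ap = int(np.argmax(roi.sum(axis=(0, 2))))
    return {
        "sens": coil28["sens"][:, :, ap, :],
        "support": ph.signal.data[:, ap, :] > 0,
        "roi": roi[:, ap, :].astype(bool),
        "signal": ph.signal.data[:, ap, :],
        "cov": coil28["cov"],
    }
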