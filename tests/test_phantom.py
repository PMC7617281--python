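"""Numerical phantom generation and the k-space forward model."""

import numpy as np
import pytest

from ssfse_t2.dictionary import simulate_signals
from ssfse_t2.epg import slice_integrated_batch
from ssfse_t2.phantom import (
    TISSUES,
    QuantitativePhantom,
    _quantize_pairs,
    default_noise_sigma,
    forward_acquire,
    get_train_profiles,
    make_fetal_phantom,
)
from ssfse_t2.sequences import SequenceParams, echo_index_for_te


def _uniform_phantom(size, t1, t2, pd=1.0):
    shape = (size, size)
    return QuantitativePhantom(
        t1_map=np.full(shape, t1),
        t2_map=np.full(shape, t2),
        pd_map=np.full(shape, pd),
        label_map=np.ones(shape, dtype=np.int16),
        seed=0,
    )


def test_phantom_contains_all_tissues(phantom256):
    assert set(np.unique(phantom256.label_map)) == set(TISSUES.values())


def test_phantom_tissue_means(phantom256):
    """Scaled tissue means land on the configured targets (up to the 3% field)."""
    wm = phantom256.t2_map[phantom256.label_map == TISSUES["fetal_wm"]]
    gm = phantom256.t2_map[
        np.isin(phantom256.label_map, [TISSUES["fetal_cortical_gm"], TISSUES["fetal_deep_gm"]])
    ]
    assert wm.mean() == pytest.approx(216.0, rel=0.03)
    assert gm.mean() == pytest.approx(129.0, rel=0.03)
    body = phantom256.t2_map[phantom256.label_map == TISSUES["maternal_body"]]
    fluid = phantom256.t2_map[phantom256.label_map == TISSUES["amniotic_fluid"]]
    assert np.all(body == 80.0) and np.all(fluid == 2000.0)
    t1_fluid = phantom256.t1_map[phantom256.label_map == TISSUES["amniotic_fluid"]]
    assert np.all(t1_fluid == 2800.0)


def test_phantom_determinism(phantom256):
    again = make_fetal_phantom(size=256, seed=1)
    assert np.array_equal(again.t2_map, phantom256.t2_map)
    assert np.array_equal(again.label_map, phantom256.label_map)
    other = make_fetal_phantom(size=256, seed=2)
    assert not np.array_equal(other.label_map, phantom256.label_map)


def test_phantom_size_validation():
    with pytest.raises(ValueError):
        make_fetal_phantom(size=32)


def test_uniform_phantom_full_scan_reconstructs_centre_echo_signal():
    """A single-T2 object reconstructs uniformly at the centre-echo value."""
    size = 64
    ph = _uniform_phantom(size, 1500.0, 150.0)
    seq = SequenceParams(te=195.2, esp=6.1, halfscan=1.0, tse_factor=64, matrix=64, sense=1.0)
    acq = forward_acquire(ph, seq, noise_sigma=0.0)
    q1, q2 = _quantize_pairs(np.array([1500.0]), np.array([150.0]))
    expected = simulate_signals([seq], q1, q2)[0, 0]
    assert acq.image.std() / acq.image.mean() < 5e-3
    assert acq.image.mean() == pytest.approx(expected, rel=1e-12)


def test_forward_model_matches_kspace_filter_oracle():
    """With uniform T2, the model equals row-wise echo filtering of FFT(pd)."""
    size = 64
    rng = np.random.default_rng(0)
    pd = rng.uniform(0.5, 1.0, (size, size))
    ph = QuantitativePhantom(
        t1_map=np.full((size, size), 1500.0),
        t2_map=np.full((size, size), 150.0),
        pd_map=pd,
        label_map=np.ones((size, size), dtype=np.int16),
        seed=0,
    )
    seq = SequenceParams(te=195.2, esp=6.1, halfscan=1.0, tse_factor=64, matrix=64, sense=1.0)
    acq = forward_acquire(ph, seq, noise_sigma=0.0)
    q1, q2 = _quantize_pairs(np.array([1500.0]), np.array([150.0]))
    train = slice_integrated_batch(get_train_profiles(seq), q1, q2, seq.esp, seq.tse_factor)[0]
    idx = echo_index_for_te(seq)
    filt = np.zeros(size)
    for e in range(1, seq.tse_factor + 1):
        filt[(size // 2 + e - idx) % size] = train[e - 1]
    k = np.fft.fftshift(np.fft.fft2(pd, norm="ortho")) * filt[:, None]
    expected = np.abs(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))
    assert np.max(np.abs(acq.image - expected)) < 1e-12


def test_partial_fourier_ringing_strongest_at_short_te():
    """Edge ringing is pronounced at halfscan 0.587 and mild at 0.966.

    Uses a long-T2 object (negligible decay modulation) with a sharp
    edge across phase encode; the artifact is measured as the maximum
    deviation near the edge from the fully sampled reconstruction.
    """
    size = 128
    ph = _uniform_phantom(size, 2800.0, 2000.0)
    ph.pd_map[: size // 2, :] = 0.4  # sharp edge across the phase-encode axis

    def recon(halfscan):
        n_full = 128
        index = int(round((halfscan - 0.5) * n_full))
        seq = SequenceParams(
            te=index * 6.1, esp=6.1, halfscan=halfscan,
            tse_factor=min(n_full, n_full // 2 + index), matrix=128, sense=1.0,
        )
        return forward_acquire(ph, seq, noise_sigma=0.0).image

    reference = recon(1.0)

    def ringing(halfscan):
        dev = np.abs(recon(halfscan) - reference)
        return dev[size // 2 - 10 : size // 2 + 10, :].max()

    r_short, r_long = ringing(0.587), ringing(0.966)
    assert r_short > 5.0 * r_long


def test_unacquired_lines_are_exactly_zero(phantom256):
    seq = SequenceParams.from_te_preset(80)
    acq = forward_acquire(phantom256, seq, noise_sigma=0.0)
    row_energy = np.abs(acq.kspace).sum(axis=1)
    nonzero = np.flatnonzero(row_energy)
    # 82 acquired lines, truncated side below the centre
    assert nonzero.size == seq.tse_factor
    index_c = echo_index_for_te(seq)
    assert nonzero[0] == 256 // 2 + 1 - index_c


def test_acquisition_determinism(phantom256):
    seq = SequenceParams.from_te_preset(180)
    a = forward_acquire(phantom256, seq, noise_sigma=0.001, seed=9)
    b = forward_acquire(phantom256, seq, noise_sigma=0.001, seed=9)
    assert np.array_equal(a.image, b.image)
    c = forward_acquire(phantom256, seq, noise_sigma=0.001, seed=10)
    assert not np.array_equal(a.image, c.image)


def test_default_noise_level_sets_wm_snr(phantom256):
    sigma = default_noise_sigma(phantom256, snr=30.0)
    seq = SequenceParams.from_te_preset(80)
    acq = forward_acquire(phantom256, seq, noise_sigma=0.0)
    wm = phantom256.tissue_mask("fetal_wm", erode=2)
    assert acq.image[wm].mean() / sigma == pytest.approx(30.0, rel=0.05)
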