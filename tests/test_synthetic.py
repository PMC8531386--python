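"""The surrogate-EEG study generator and two-way table generator."""

import numpy as np
import pytest
from scipy.signal import periodogram

from graphrely import (
    BandDefinition,
    CouplingSpec,
    StudyDesign,
    VarianceComponents,
    default_bands,
    default_coupling,
    epoch_signal,
    generate_recording,
    generate_study,
    generate_two_way_table,
    wpli,
)
from graphrely.connectivity import ConfigurationError
from graphrely.synthetic import _latent, draw_strengths


@pytest.fixture
def pair_spec(alpha_band):
    return CouplingSpec(band=alpha_band, edges=((0, 1, 1.0, np.pi / 3),),
                        noise_sd=0.0)


def test_recording_determinism(tiny_design, pair_spec):
    a = generate_recording(tiny_design, pair_spec, 0.7, seed=42)
    b = generate_recording(tiny_design, pair_spec, 0.7, seed=42)
    np.testing.assert_array_equal(a.samples, b.samples)
    c = generate_recording(tiny_design, pair_spec, 0.7, seed=43)
    assert not np.array_equal(a.samples, c.samples)


def test_zero_coupling_gives_independent_noise(tiny_design, alpha_band):
    spec = CouplingSpec(band=alpha_band, edges=((0, 1, 0.0, np.pi / 3),),
                        noise_sd=1.0)
    rec = generate_recording(tiny_design, spec, 1.0, seed=1)
    r = np.corrcoef(rec.samples)[0, 1]
    assert abs(r) < 0.05


def test_noiseless_lagged_pair_gives_wpli_one(tiny_design, alpha_band, pair_spec):
    rec = generate_recording(tiny_design, pair_spec, 1.0, seed=2)
    stack = wpli(epoch_signal(rec, 8, 4, None), alpha_band)
    assert stack.matrices[:, 0, 1].mean() > 0.999


def test_wpli_monotone_in_coupling_strength(tiny_design, alpha_band):
    """Mean downstream wPLI is strictly larger at strength 0.8 than 0.2,
    in expectation over seeds, at a fixed noise level."""
    means = {}
    for strength in (0.2, 0.8):
        spec = CouplingSpec(band=alpha_band, edges=((0, 1, 1.0, np.pi / 3),),
                            noise_sd=1.0)
        vals = []
        for seed in range(20):
            rec = generate_recording(tiny_design, spec, strength, seed=300 + seed)
            vals.append(wpli(epoch_signal(rec, 8, 4, None),
                             alpha_band).matrices[:, 0, 1].mean())
        means[strength] = np.mean(vals)
    assert means[0.8] > means[0.2]


def test_spectral_content_concentrated_in_band():
    """At least 80% of the noiseless latent's variance lies inside the
    requested band edges (periodogram assessment), for every default band."""
    for band in default_bands():
        s = _latent(band, 256 * 60, 256.0, "filtered_noise",
                    np.random.default_rng(1))
        f, p = periodogram(s, fs=256.0)
        inband = p[(f >= band.low) & (f <= band.high)].sum() / p.sum()
        assert inband >= 0.80, band.name


def test_study_layout_and_determinism():
    design = StudyDesign(n_participants=15, duration=4.0, n_channels=4)
    band = BandDefinition("alpha1", 8.0, 10.5)
    spec = CouplingSpec(band=band, edges=((0, 1, 0.8, np.pi / 4),
                                          (2, 3, 0.6, np.pi / 3)))
    recs = generate_study(design, spec, seed=11)
    assert len(recs) == 15 * 2 * 2
    keys = {r.key for r in recs}
    assert len(keys) == 60
    recs2 = generate_study(design, spec, seed=11)
    for a, b in zip(recs, recs2):
        np.testing.assert_array_equal(a.samples, b.samples)


def test_perfect_consistency_zero_noise_identical_sessions(alpha_band):
    design = StudyDesign(n_participants=3, duration=4.0, n_channels=3)
    spec = CouplingSpec(band=alpha_band, edges=((0, 1, 0.9, np.pi / 4),
                                                (1, 2, 0.7, np.pi / 3)),
                        noise_sd=0.0, session_consistency=1.0,
                        condition_shift=0.0)
    recs = {r.key: r for r in generate_study(design, spec, seed=3)}
    for pid in design.participant_ids:
        for cond in design.conditions:
            np.testing.assert_array_equal(
                recs[(pid, "S1", cond)].samples,
                recs[(pid, "S2", cond)].samples,
            )


def test_zero_consistency_decorrelates_sessions():
    design = StudyDesign(n_participants=500, duration=4.0, n_channels=2)
    s0 = draw_strengths(design, session_consistency=0.0, condition_shift=0.0,
                        seed=4)
    r0 = np.corrcoef(s0[:, 0, 0], s0[:, 1, 0])[0, 1]
    assert abs(r0) < 0.1
    s1 = draw_strengths(design, session_consistency=1.0, condition_shift=0.0,
                        seed=4)
    np.testing.assert_array_equal(s1[:, 0, 0], s1[:, 1, 0])


def test_condition_shift_moves_post_strengths():
    design = StudyDesign(n_participants=200, duration=4.0, n_channels=2)
    s = draw_strengths(design, session_consistency=0.8, condition_shift=0.1,
                       seed=5)
    diff = s[:, :, 1] - s[:, :, 0]
    assert 0.05 < diff.mean() < 0.1 + 1e-9  # clipping can only shrink it


def test_default_coupling_covers_all_channels_per_band():
    specs = default_coupling(n_channels=19)
    assert len(specs) == 5
    for spec in specs:
        touched = {i for e in spec.edges for i in e[:2]}
        assert touched == set(range(19))


# ---------------------------------------------------------------------------
# two-way tables


def test_two_way_table_known_components():
    """Grand mean converges to mu and the empirical variance decomposition
    recovers the specified components within Monte-Carlo error."""
    vc = VarianceComponents(mu=50.0, var_subject=4.0, var_session=1.0,
                            var_error=0.25)
    tab = generate_two_way_table(4000, 10, vc, seed=6)
    # grand-mean SE is dominated by the k=10 session draws: ~0.32
    assert tab.values.mean() == pytest.approx(50.0, abs=1.0)
    subj_var = np.var(tab.values.mean(axis=1), ddof=1) - vc.var_error / 10
    assert subj_var == pytest.approx(4.0, rel=0.15)
    err_var = np.var(tab.values - tab.values.mean(axis=1, keepdims=True)
                     - tab.values.mean(axis=0, keepdims=True)
                     + tab.values.mean())
    assert err_var == pytest.approx(0.25, rel=0.15)


def test_two_way_table_determinism_and_validation():
    vc = VarianceComponents(0.0, 1.0, 0.0, 1.0)
    a = generate_two_way_table(5, 2, vc, seed=7)
    b = generate_two_way_table(5, 2, vc, seed=7)
    np.testing.assert_array_equal(a.values, b.values)
    with pytest.raises(ConfigurationError):
        VarianceComponents(0.0, -1.0, 0.0, 1.0)
    with pytest.raises(ConfigurationError):
        generate_two_way_table(1, 2, vc, seed=0)


def test_invalid_configuration_errors(tiny_design, alpha_band):
    with pytest.raises(ConfigurationError):
        CouplingSpec(band=alpha_band, edges=((0, 1, 1.5, 0.1),))  # strength > 1
    with pytest.raises(ConfigurationError):
        CouplingSpec(band=alpha_band, edges=((0, 0, 0.5, 0.1),))  # self edge
    with pytest.raises(ConfigurationError):
        CouplingSpec(band=alpha_band, edges=((0, 1, 0.5, 4.0),))  # lag > pi
    spec = CouplingSpec(band=BandDefinition("toohigh", 100.0, 200.0),
                        edges=((0, 1, 0.5, 0.1),))
    with pytest.raises(ConfigurationError):
        generate_recording(tiny_design, spec, 1.0, seed=0)
    with pytest.raises(ConfigurationError):
        generate_recording(tiny_design,
                           CouplingSpec(band=alpha_band,
                                        edges=((0, 5, 0.5, 0.1),)),
                           1.0, seed=0)  # channel outside montage
    with pytest.raises(ConfigurationError):
        StudyDesign(n_participants=1)
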