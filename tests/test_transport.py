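"""Monte Carlo transport tests: sampling laws against quadrature,
delta tracking against an independent ray-marching oracle, closed-form
kerma in the thin-slab limit, batch statistics and determinism."""

import math

import numpy as np
import pytest

from mammodose.materials import (builtin_materials, linear_attenuation,
                                 mass_attenuation, mass_energy_absorption)
from mammodose.phantom import (ADIPOSE, AIR, GLANDULAR, SKIN, PhantomSpec,
                               VoxelPhantom, build_phantom)
from mammodose.spectrum import BeamConfig, EnergySpectrum
from mammodose.transport import (COMPARTMENTS, TallyResult, TransportConfig,
                                 relative_error, run_transport,
                                 sample_compton, sample_interaction,
                                 sample_source)

MEC2 = 511.0


def _mono_spectrum(e_center=20.0):
    return EnergySpectrum(np.array([e_center - 0.05]), np.array([1.0]))


def _slab_phantom(reg, label=GLANDULAR, thickness_cm=0.05,
                  radius_cm=2.0, voxel_mm=0.5):
    """Homogeneous thin slab covering the whole footprint box."""
    spec = PhantomSpec(thickness_cm=thickness_cm, glandular_fraction=0.5,
                       skin_mm=0.1, footprint_radius_cm=radius_cm,
                       voxel_mm=voxel_mm)
    h = voxel_mm / 10.0
    shape = (int(round(2 * radius_cm / h)), int(round(radius_cm / h)),
             int(round(thickness_cm / h)))
    labels = np.full(shape, label, dtype=np.uint8)
    mats = {AIR: reg["air"], SKIN: reg["skin"],
            GLANDULAR: reg["glandular"], ADIPOSE: reg["adipose"]}
    return VoxelPhantom(spec, labels, voxel_mm, (-radius_cm, 0.0, 0.0), mats)


# ---------------------------------------------------------------------------
# source sampling
# ---------------------------------------------------------------------------

def test_single_bin_source_energies_stay_in_bin():
    rng = np.random.default_rng(7)
    _, _, e = sample_source(_mono_spectrum(20.0), BeamConfig(), 5000, rng)
    assert np.all((e >= 19.95) & (e <= 20.05))


def test_source_histogram_matches_bin_probabilities(rh_tube_spectrum):
    rng = np.random.default_rng(11)
    n = 100_000
    _, _, e = sample_source(rh_tube_spectrum, BeamConfig(), n, rng)
    idx = np.floor((e - 1.0) / 0.1).astype(int)
    counts = np.bincount(idx, minlength=rh_tube_spectrum.fluence.size)
    p = rh_tube_spectrum.fluence / rh_tube_spectrum.total_fluence
    expected = n * p
    sigma = np.sqrt(n * p * (1 - p))
    live = expected > 10
    outside = np.abs(counts - expected)[live] > 3 * sigma[live]
    assert outside.mean() < 0.01


def test_source_is_deterministic_given_seed(rh_tube_spectrum):
    a = sample_source(rh_tube_spectrum, BeamConfig(), 1000,
                      np.random.default_rng(3))
    b = sample_source(rh_tube_spectrum, BeamConfig(), 1000,
                      np.random.default_rng(3))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_empty_spectrum_rejected():
    empty = EnergySpectrum(np.array([10.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        sample_source(empty, BeamConfig(), 10, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Compton sampling
# ---------------------------------------------------------------------------

def test_compton_energy_bounds_are_the_closed_form_limits():
    rng = np.random.default_rng(5)
    e0 = 28.0
    e_out, mu = sample_compton(np.full(20_000, e0), rng)
    backscatter = e0 / (1 + 2 * e0 / MEC2)
    assert np.all(e_out <= e0 + 1e-12)           # forward limit E' = E
    assert np.all(e_out >= backscatter - 1e-12)  # theta = pi limit
    # the Compton relation ties the two outputs together exactly
    np.testing.assert_allclose(e_out, e0 / (1 + e0 / MEC2 * (1 - mu)),
                               rtol=1e-12)


def test_compton_mean_cosine_matches_quadrature():
    """Mean scattering cosine at 20 keV vs numerical integration of the
    Klein-Nishina distribution."""
    e0 = 20.0
    k = e0 / MEC2
    mu_grid, w = np.polynomial.legendre.leggauss(200)
    r = 1.0 / (1.0 + k * (1.0 - mu_grid))
    f = r * r * (r + 1.0 / r - (1.0 - mu_grid ** 2))
    want = np.sum(mu_grid * f * w) / np.sum(f * w)

    rng = np.random.default_rng(101)
    n = 1_000_000
    _, mu = sample_compton(np.full(n, e0), rng)
    se = mu.std() / math.sqrt(n)
    assert abs(mu.mean() - want) < 3 * se


# ---------------------------------------------------------------------------
# interaction channel sampling
# ---------------------------------------------------------------------------

def test_channel_frequencies_match_partial_coefficients(registry):
    rng = np.random.default_rng(23)
    mat = registry["glandular"]
    n = 100_000
    codes = sample_interaction(mat, np.full(n, 20.0), rng)
    tot = mass_attenuation(mat, 20.0)
    for code, ch in enumerate(("photoelectric", "incoherent", "coherent")):
        p = mass_attenuation(mat, 20.0, ch) / tot
        se = math.sqrt(n * p * (1 - p))
        assert abs((codes == code).sum() - n * p) < 3 * se


def test_coherent_disabled_renormalizes_to_photoelectric(registry):
    rng = np.random.default_rng(29)
    codes = sample_interaction(registry["tungsten"], np.full(2000, 5.0), rng,
                               coherent=False)
    assert not (codes == 2).any()
    assert (codes == 0).mean() > 0.97   # photoelectric dominates high-Z, 5 keV


def test_scalar_interaction_returns_channel_name(registry):
    out = sample_interaction(registry["glandular"], 20.0,
                             np.random.default_rng(1))
    assert out in ("photoelectric", "incoherent", "coherent")


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def test_air_only_phantom_deposits_nothing_in_tissue(registry):
    ph = _slab_phantom(registry, label=AIR, thickness_cm=1.0)
    beam = BeamConfig(paddle_mm=0.0)
    tal = run_transport(ph, _mono_spectrum(20.0), beam,
                        TransportConfig(histories=2000, batches=2, seed=4,
                                        support_mm=0.0),
                        point_positions=[])
    assert tal.compartment_totals["glandular"] == 0.0
    assert tal.compartment_totals["adipose"] == 0.0


def test_thin_slab_dose_matches_kerma_closed_form(registry):
    """Monoenergetic broad beam on a 0.5 mm glandular slab: deposit per
    photon approaches E * mu_en (thin-slab collision kerma)."""
    ph = _slab_phantom(registry, thickness_cm=0.05)
    beam = BeamConfig(paddle_mm=0.0, source_breast_cm=500.0)
    tal = run_transport(ph, _mono_spectrum(20.0), beam,
                        TransportConfig(histories=400_000, batches=10, seed=9,
                                        support_mm=0.0),
                        point_positions=[])
    per_photon = tal.batch_edep.sum() / tal.histories
    muen_lin = mass_energy_absorption(registry["glandular"], 20.0) \
        * registry["glandular"].density
    want = 20.0 * muen_lin * 0.05
    assert per_photon == pytest.approx(want, rel=0.02)


def test_delta_tracking_agrees_with_ray_marching_oracle(registry):
    """Glandular deposit on a small two-material phantom: delta tracking
    vs an independent per-photon voxel-boundary ray-marching MC."""
    spec = PhantomSpec(thickness_cm=1.0, glandular_fraction=0.5,
                       skin_mm=0.1, footprint_radius_cm=0.5, voxel_mm=1.0)
    shape = (10, 5, 10)
    labels = np.full(shape, ADIPOSE, dtype=np.uint8)
    labels[:5] = GLANDULAR              # left half glandular
    mats = {AIR: registry["air"], SKIN: registry["skin"],
            GLANDULAR: registry["glandular"], ADIPOSE: registry["adipose"]}
    ph = VoxelPhantom(spec, labels, 1.0, (-0.5, 0.0, 0.0), mats)
    beam = BeamConfig(paddle_mm=0.0)
    spect = _mono_spectrum(20.0)

    n = 20_000
    tal = run_transport(ph, spect, beam,
                        TransportConfig(histories=n, batches=10, seed=31,
                                        support_mm=0.0),
                        point_positions=[])
    frac_delta = tal.compartment_totals["glandular"] / tal.batch_source_kev.sum()
    re_delta = relative_error(tal)["glandular"]

    frac_oracle, se_oracle = _ray_march_oracle(ph, spect, beam, n, seed=77)
    sigma = math.hypot(re_delta * frac_delta, se_oracle)
    assert abs(frac_delta - frac_oracle) < 3 * sigma


def _ray_march_oracle(ph, spect, beam, n, seed):
    """Independent MC: exact voxel-boundary traversal with inverse-CDF
    free paths (no majorant, no delta tracking)."""
    rng = np.random.default_rng(seed)
    pos, dirs, energies = sample_source(
        spect, beam, n, rng,
        target_box=((-0.5, 0.5), (0.0, 0.5)), z_plane=1.0)
    h = 0.1
    lo = np.array([-0.5, 0.0, 0.0])
    hi = np.array([0.5, 0.5, 1.0])
    mu_of = {GLANDULAR: lambda e: linear_attenuation(ph.materials[GLANDULAR], e),
             ADIPOSE: lambda e: linear_attenuation(ph.materials[ADIPOSE], e)}
    gland_dep = np.zeros(n)
    emitted = energies.copy()
    for i in range(n):
        p = pos[i].copy()
        d = dirs[i].copy()
        # advance to the slab top
        t_in = (1.0 - p[2]) / d[2]
        p += d * (t_in + 1e-9)
        e = energies[i]
        while True:
            if np.any(p <= lo) or np.any(p >= hi) or e < 1.0:
                break
            idx = np.minimum(((p - lo) / h).astype(int), [9, 4, 9])
            lab = int(ph.labels[tuple(idx)])
            mu = float(mu_of[lab](e))
            # distance to the next voxel face along d
            with np.errstate(divide="ignore"):
                t_faces = np.where(
                    d > 0, (lo + (idx + 1) * h - p) / d,
                    np.where(d < 0, (lo + idx * h - p) / d, np.inf))
            t_next = max(float(t_faces.min()), 1e-9)
            s = -math.log(rng.random()) / mu
            if s > t_next:
                p += d * (t_next + 1e-9)
                continue
            p += d * s
            u = rng.random()
            mat = ph.materials[lab]
            p_pe = mass_attenuation(mat, e, "photoelectric") \
                / mass_attenuation(mat, e)
            p_inc = mass_attenuation(mat, e, "incoherent") \
                / mass_attenuation(mat, e)
            if u < p_pe:
                if lab == GLANDULAR:
                    gland_dep[i] += e
                break
            if u < p_pe + p_inc:
                e_new, mu_sc = sample_compton(e, rng)
                if lab == GLANDULAR:
                    gland_dep[i] += e - e_new
                if e_new < 1.0:
                    if lab == GLANDULAR:
                        gland_dep[i] += e_new
                    break
                e = e_new
                d = _rotate_single(d, mu_sc, rng)
            else:
                mu_c = _thomson_single(rng)
                d = _rotate_single(d, mu_c, rng)
    frac = gland_dep.sum() / emitted.sum()
    se = gland_dep.std() * math.sqrt(n) / emitted.sum()
    return frac, se


def _thomson_single(rng):
    while True:
        m = rng.uniform(-1, 1)
        if rng.random() * 2 < 1 + m * m:
            return m


def _rotate_single(d, mu, rng):
    sin_t = math.sqrt(max(0.0, 1 - mu * mu))
    phi = rng.uniform(0, 2 * math.pi)
    a = np.array([1.0, 0.0, 0.0]) if abs(d[2]) > 0.99 \
        else np.array([0.0, 0.0, 1.0])
    u = np.cross(a, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    out = mu * d + sin_t * (math.cos(phi) * u + math.sin(phi) * v)
    return out / np.linalg.norm(out)


# ---------------------------------------------------------------------------
# tallies, statistics, determinism
# ---------------------------------------------------------------------------

def test_energy_conservation_per_batch(registry, rh_tube_spectrum,
                                       phantom_4cm_50):
    tal = run_transport(phantom_4cm_50, rh_tube_spectrum,
                        BeamConfig(extra_filter="Rh"),
                        TransportConfig(histories=20_000, batches=4, seed=2))
    dep = tal.batch_edep.sum(axis=1)
    assert np.all(dep > 0)
    assert np.all(dep < tal.batch_source_kev)   # some photons escape
    assert np.all(tal.batch_edep >= 0)


def test_seed_determinism_bit_exact(registry, rh_tube_spectrum,
                                    phantom_4cm_50):
    cfg = TransportConfig(histories=10_000, batches=4, seed=42)
    beam = BeamConfig(extra_filter="Rh")
    a = run_transport(phantom_4cm_50, rh_tube_spectrum, beam, cfg)
    b = run_transport(phantom_4cm_50, rh_tube_spectrum, beam, cfg)
    np.testing.assert_array_equal(a.batch_edep, b.batch_edep)
    np.testing.assert_array_equal(a.point_edep, b.point_edep)
    np.testing.assert_array_equal(a.batch_source_kev, b.batch_source_kev)


def test_variance_shrinks_with_history_count(registry, rh_tube_spectrum,
                                             phantom_4cm_50):
    beam = BeamConfig(extra_filter="Rh")
    small = run_transport(phantom_4cm_50, rh_tube_spectrum, beam,
                          TransportConfig(histories=20_000, batches=10,
                                          seed=6))
    big = run_transport(phantom_4cm_50, rh_tube_spectrum, beam,
                        TransportConfig(histories=80_000, batches=10,
                                        seed=6))
    r_small = relative_error(small)["glandular"]
    r_big = relative_error(big)["glandular"]
    assert 0.25 < r_big / r_small < 0.85    # ~1/2 expected for 4x histories


def test_relative_error_arithmetic():
    batch = np.zeros((4, len(COMPARTMENTS)))
    batch[:, 2] = [1.0, 2.0, 3.0, 4.0]
    tal = TallyResult(batch, np.zeros((4, 1)), np.full(4, 100.0), 400, 0)
    re = relative_error(tal)
    mean = 2.5
    se = np.std([1, 2, 3, 4], ddof=1) / 2.0
    assert re["glandular"] == pytest.approx(se / mean)
    assert re["air"] is None                 # zero-mean tally flagged
    batch2 = np.zeros((3, len(COMPARTMENTS)))
    batch2[:, 2] = 5.0
    tal2 = TallyResult(batch2, np.zeros((3, 1)), np.full(3, 10.0), 300, 0)
    assert relative_error(tal2)["glandular"] == 0.0


def test_tally_json_round_trip(registry, rh_tube_spectrum, phantom_4cm_50):
    tal = run_transport(phantom_4cm_50, rh_tube_spectrum,
                        BeamConfig(extra_filter="Rh"),
                        TransportConfig(histories=5_000, batches=2, seed=8))
    again = TallyResult.from_json(tal.to_json())
    np.testing.assert_array_equal(again.batch_edep, tal.batch_edep)
    assert again.histories == tal.histories
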