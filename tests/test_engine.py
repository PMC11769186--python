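"""Transport physics: sampling distributions, boundary optics, conservation."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from oxisim.engine import (
    DetectorSpec,
    EngineSettings,
    PhotonState,
    boundary_interact,
    fresnel_reflectance,
    launch,
    ring_overlap_fraction,
    roulette,
    sample_step,
    scatter,
    transport,
    transport_reference,
)
from oxisim.tissue import PhysiologicalState, build_stack

from conftest import homogeneous_slab

RNG = lambda seed: np.random.default_rng(seed)


class _ZeroRng:
    """Stub generator whose uniform draw is always 0 (i.e. xi = 1)."""

    def random(self):
        return 0.0


class _OneRng:
    """Stub generator drawing just below 1: forces Fresnel transmission."""

    def random(self):
        return 1.0 - 1e-12


# --- launch ----------------------------------------------------------------


def test_launch_matched_boundary_keeps_full_weight():
    p = launch(RNG(0), n_ambient=1.4, n_tissue=1.4)
    assert p.weight == 1.0
    assert np.allclose(p.direction, [0, 0, 1])


def test_launch_deducts_normal_incidence_specular_loss():
    p = launch(RNG(0), n_ambient=1.0, n_tissue=1.4)
    assert p.weight == pytest.approx(1 - 0.027777777777777766, rel=1e-12)
    assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-12)


# --- free-path sampling ----------------------------------------------------


def test_sample_step_xi_one_gives_zero():
    assert sample_step(2.0, _ZeroRng()) == 0.0


def test_sample_step_rejects_nonpositive_mu_t():
    with pytest.raises(ValueError):
        sample_step(0.0, RNG(0))


def test_sample_step_exponential_mean():
    mu_t = 3.7
    rng = RNG(42)
    n = 1_000_000
    xi = 1.0 - rng.random(n)
    samples = -np.log(xi) / mu_t  # same transform the sampler applies
    draws = np.array([sample_step(mu_t, RNG(i)) for i in range(2000)])
    assert np.all(draws >= 0)
    # exponential-distribution oracle: mean 1/mu_t, SE = 1/(mu_t*sqrt(n))
    se = 1.0 / (mu_t * math.sqrt(len(draws)))
    assert abs(draws.mean() - 1.0 / mu_t) < 3 * se
    assert abs(samples.mean() - 1.0 / mu_t) < 3 / (mu_t * math.sqrt(n))


# --- Henyey-Greenstein scattering ------------------------------------------


def test_scatter_isotropic_limit_uniform_cosine():
    rng = RNG(7)
    down = np.array([0.0, 0.0, 1.0])
    cosines = np.array([scatter(down, 0.0, rng)[2] for _ in range(100_000)])
    assert stats.kstest(cosines, stats.uniform(loc=-1, scale=2).cdf).pvalue > 1e-3


def test_scatter_mean_cosine_equals_g():
    g = 0.9
    rng = RNG(11)
    down = np.array([0.0, 0.0, 1.0])
    cosines = np.array([scatter(down, g, rng)[2] for _ in range(100_000)])
    se = cosines.std(ddof=1) / math.sqrt(len(cosines))
    assert abs(cosines.mean() - g) < 3 * se


def test_scatter_preserves_unit_norm():
    rng = RNG(3)
    for _ in range(200):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        out = scatter(d, rng.uniform(-0.9, 0.95), rng)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)


# --- boundary optics --------------------------------------------------------


def _photon(direction):
    d = np.asarray(direction, float)
    return PhotonState(position=np.zeros(3), direction=d / np.linalg.norm(d))


def test_matched_interface_transmits_unchanged():
    p = _photon([0.3, 0.1, 0.9])
    out = boundary_interact(p, [0, 0, 1], 1.4, 1.4, _ZeroRng())
    assert np.allclose(out.direction, p.direction)


def test_total_internal_reflection_beyond_critical_angle():
    # n 1.4 -> 1.0, incidence ~60 deg > critical ~45.6 deg
    p = _photon([math.sin(math.radians(60)), 0, math.cos(math.radians(60))])
    for seed in range(5):
        out = boundary_interact(p, [0, 0, 1], 1.4, 1.0, RNG(seed))
        assert out.direction[2] == pytest.approx(-p.direction[2])


def test_normal_incidence_reflection_probability():
    rng = RNG(5)
    p = _photon([0, 0, 1])
    n = 100_000
    reflected = sum(
        boundary_interact(p, [0, 0, 1], 1.0, 1.4, rng).direction[2] < 0
        for _ in range(n)
    )
    prob = 0.027777777777777766
    se = math.sqrt(prob * (1 - prob) / n)
    assert abs(reflected / n - prob) < 3 * se


def test_snell_refraction_bends_toward_normal():
    p = _photon([math.sin(0.5), 0, math.cos(0.5)])
    out = boundary_interact(p, [0, 0, 1], 1.0, 1.4, _OneRng())
    # stub rng forces transmission; check Snell's law on the sines
    sin_out = math.hypot(out.direction[0], out.direction[1])
    assert sin_out == pytest.approx(math.sin(0.5) / 1.4, rel=1e-12)


def test_fresnel_closed_form_normal_incidence():
    refl, cos_t = fresnel_reflectance(1.0, 1.4, 1.0)
    assert refl == pytest.approx(((1.4 - 1.0) / 2.4) ** 2, rel=1e-12)
    assert cos_t == 1.0


# --- roulette ---------------------------------------------------------------


def test_roulette_above_threshold_unchanged():
    p = dataclasses.replace(_photon([0, 0, 1]), weight=0.5)
    assert roulette(p, 1e-4, 0.1, RNG(0)) == p


def test_roulette_is_unbiased():
    rng = RNG(9)
    w0 = 5e-5
    n = 200_000
    total = 0.0
    survivors = 0
    for _ in range(n):
        p = dataclasses.replace(_photon([0, 0, 1]), weight=w0)
        out = roulette(p, 1e-4, 0.1, rng)
        total += out.weight
        survivors += out.alive
        if not out.alive:
            assert out.weight == 0.0  # terminated packets contribute nothing
    # expected post-roulette weight equals w0; SE from Bernoulli variance
    se = (w0 / 0.1) * math.sqrt(0.1 * 0.9 / n)
    assert abs(total / n - w0) < 3 * se
    assert 0.09 < survivors / n < 0.11


# --- full transport ---------------------------------------------------------


def test_ballistic_transmission_matches_beer_lambert(table):
    # matched-index purely absorbing slab: T = exp(-mu_a * d)
    mu_a, d = 1.3, 1.0
    cfg = homogeneous_slab(mu_a, 0.0, thickness=d, n=1.4, ambient_n=1.4)
    stack = build_stack(cfg, 660, PhysiologicalState(0.9), table)
    res = transport(stack, seed=12, launched_target=100_000)
    assert res.total_transmittance == pytest.approx(math.exp(-mu_a * d), rel=0.01)
    assert res.specular_weight == 0.0


def test_no_absorption_conserves_escaping_weight(table):
    cfg = homogeneous_slab(0.0, 2.0, g=0.3, thickness=5.0, n=1.4, ambient_n=1.4)
    stack = build_stack(cfg, 660, PhysiologicalState(0.9), table)
    res = transport(
        stack,
        seed=3,
        launched_target=20_000,
        settings=EngineSettings(cutoff_radius=1e6),  # no lateral truncation
    )
    escaped = res.diffuse_reflected_weight + res.transmitted_weight
    # no absorption sink and matched boundaries: everything escapes
    assert escaped == pytest.approx(res.launched_weight, rel=1e-9)
    assert res.total_diffuse_reflectance + res.total_transmittance == pytest.approx(
        1.0, rel=1e-9
    )


def test_energy_ledger_closes(light_slab, table):
    stack = build_stack(light_slab, 660, PhysiologicalState(0.8, "systole"), table)
    res = transport(stack, seed=21, launched_target=50_000)
    total = (
        res.specular_weight
        + res.diffuse_reflected_weight
        + res.transmitted_weight
        + res.absorbed_weight
    )
    assert total == pytest.approx(res.launched_weight, rel=1e-9)
    assert 0 <= res.reflectance <= 1
    assert res.detected_weight <= res.diffuse_reflected_weight


def test_same_seed_is_bit_identical(light_slab, table):
    stack = build_stack(light_slab, 940, PhysiologicalState(0.9), table)
    a = transport(stack, seed=77, launched_target=20_000)
    b = transport(stack, seed=77, launched_target=20_000)
    assert a == b  # dataclass equality compares every float exactly


def test_different_seeds_agree_within_sampling_error(light_slab, table):
    stack = build_stack(light_slab, 940, PhysiologicalState(0.9), table)
    runs = [transport(stack, seed=s, launched_target=100_000) for s in (1, 2, 3)]
    refls = [r.total_diffuse_reflectance for r in runs]
    # binomial-scale error bound on a ~0.45 fraction at 1e5 packets
    assert max(refls) - min(refls) < 6 * math.sqrt(0.5 * 0.5 / 100_000)


def test_detected_target_stop_reaches_target(light_slab, table):
    stack = build_stack(light_slab, 940, PhysiologicalState(0.9), table)
    res = transport(stack, seed=5, detected_target=2_000)
    assert res.detected_count >= 2_000
    assert res.launched_count > res.detected_count


def test_ring_and_disc_tallies_agree(table):
    """The azimuthally averaged tally estimates the same quantity as the
    literal disc tally, with far lower variance."""
    cfg = homogeneous_slab(0.05, 4.0, g=0.5, thickness=3.0, n=1.4)
    stack = build_stack(cfg, 660, PhysiologicalState(0.9), table)
    det = DetectorSpec(center_offset=1.5, radius=1.0)
    ring = transport(
        stack, det, seed=8, launched_target=150_000, settings=EngineSettings(tally="ring")
    )
    disc = transport(
        stack, det, seed=9, launched_target=150_000, settings=EngineSettings(tally="disc")
    )
    p = disc.reflectance
    se = math.sqrt(p / 150_000)  # dominant (disc) binomial-scale error
    assert abs(ring.reflectance - disc.reflectance) < 5 * se


def test_reference_and_compiled_transport_agree(table):
    cfg = homogeneous_slab(0.3, 3.0, g=0.6, thickness=2.0)
    stack = build_stack(cfg, 660, PhysiologicalState(0.9), table)
    ref = transport_reference(stack, seed=14, launched_target=4_000)
    fast = transport(stack, seed=15, launched_target=400_000)
    for attr in ("total_diffuse_reflectance", "total_transmittance"):
        a, b = getattr(ref, attr), getattr(fast, attr)
        se = math.sqrt(max(a, 1e-6) / 4_000)
        assert abs(a - b) < 4 * se
    total = (
        ref.specular_weight
        + ref.diffuse_reflected_weight
        + ref.transmitted_weight
        + ref.absorbed_weight
    )
    assert total == pytest.approx(ref.launched_weight, rel=1e-9)


def test_bone_cylinder_transport_runs(light_config, table):
    stack = build_stack(light_config, 940, PhysiologicalState(0.9), table)
    assert stack.bone is not None
    res = transport(stack, seed=4, launched_target=20_000)
    total = (
        res.specular_weight
        + res.diffuse_reflected_weight
        + res.transmitted_weight
        + res.absorbed_weight
    )
    assert total == pytest.approx(res.launched_weight, rel=1e-9)


def test_transport_argument_validation(light_slab, table):
    stack = build_stack(light_slab, 660, PhysiologicalState(0.9), table)
    with pytest.raises(ValueError):
        transport(stack, seed=1)
    with pytest.raises(ValueError):
        transport(stack, seed=1, detected_target=100, launched_target=100)
    with pytest.raises(ValueError):
        transport(stack, seed=1, launched_target=0)


def test_ring_overlap_fraction_geometry():
    # full containment, disjoint, and the half-covered crossing point
    assert ring_overlap_fraction(0.2, 0.0, 0.5) == 1.0
    assert ring_overlap_fraction(0.9, 0.0, 0.5) == 0.0
    assert ring_overlap_fraction(5.0, 3.0, 1.0) == 0.0
    assert ring_overlap_fraction(0.3, 3.0, 1.0) == 0.0
    mid = ring_overlap_fraction(3.0, 3.0, 1.0)
    assert 0.0 < mid < 0.5  # subtends acos-based arc fraction
    # integral of the ring fraction over a dense radial grid weighted by
    # 2*pi*r equals the disc area (unbiasedness of the azimuthal average)
    r = np.linspace(0.0, 6.0, 20_000)
    fracs = np.array([ring_overlap_fraction(v, 3.0, 1.0) for v in r])
    area = np.trapezoid(fracs * 2 * np.pi * r, r)
    assert area == pytest.approx(np.pi * 1.0**2, rel=1e-3)
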