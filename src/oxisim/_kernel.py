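"""Compiled photon-transport kernel.

A single numba-jitted loop implements the classic weighted photon-packet
random walk (hop / drop / spin) through a stack of plane-parallel slabs with
an optional embedded cylinder (bone), unpolarised Fresnel reflection and
Snell refraction at refractive-index mismatches, Henyey-Greenstein
scattering, and roulette termination of low-weight packets.

Randomness comes from an inline xorshift128+ generator seeded through
splitmix64, so a run is a pure function of its integer seed and is cheap
enough not to dominate the per-step cost.

Detection at the surface supports two tallies:

* ``ring`` (default): the exit position is azimuthally averaged - a packet
  exiting at radial distance ``r`` from the source contributes its weight
  times the fraction of the circle of radius ``r`` covered by the detector
  disc.  The pencil-beam problem is rotationally symmetric about the source
  axis, so this estimator has the same expectation as the literal disc
  tally but far lower variance at a given packet count.
* ``disc``: literal point-in-disc test on the exit position.

Bookkeeping convention: roulette kills add the lost weight to the absorbed
tally and roulette amplifications subtract from it, and packets terminated
at the lateral cutoff radius are added to the absorbed tally (and also
recorded separately), so that specular + diffuse reflected + transmitted +
absorbed equals the launched weight to floating-point rounding on every run.
"""

import math

import numpy as np
from numba import njit

TALLY_RING = 0
TALLY_DISC = 1
SIDE_TOP = 0
SIDE_BOTTOM = 1
STOP_LAUNCHED = 0
STOP_DETECTED = 1

_EPS = 1e-12
_GEOM_EPS = 1e-9

_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _splitmix64(state):
    """One splitmix64 output and the advanced state (seed expansion)."""
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return z ^ (z >> np.uint64(31)), state


@njit(cache=True, inline="always")
def _rng_next(s0, s1):
    """xorshift128+: uniform double in [0, 1) and the advanced state."""
    x = s0
    y = s1
    s0 = y
    x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    total = (s1 + y) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return float(total >> np.uint64(11)) * _INV_2_53, s0, s1


@njit(cache=True, inline="always")
def _fresnel_unpolarised(n1, n2, cos_i):
    """Unpolarised Fresnel reflectance and transmitted cosine.

    Returns (R, cos_t); R = 1.0 beyond the critical angle.
    """
    if n1 == n2:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _ring_overlap(r, d, a):
    """Fraction of the circle of radius r covered by a disc (radius a, centre d)."""
    if d <= _EPS:
        return 1.0 if r < a else 0.0
    if r <= a - d:
        return 1.0
    if r <= _EPS or r <= d - a or r >= d + a:
        return 0.0
    c = (r * r + d * d - a * a) / (2.0 * r * d)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.acos(c) / math.pi


@njit(cache=True, inline="always")
def _cyl_intersect(x, z, ux, uz, cx, cz, r, inside):
    """Distance along the ray to the bone cylinder surface (inf if none).

    The cylinder axis runs along y at (cx, cz).  ``inside`` selects the exit
    root; otherwise the entry root is returned.
    """
    a = ux * ux + uz * uz
    if a < _EPS:
        return np.inf
    dx = x - cx
    dz = z - cz
    b = 2.0 * (dx * ux + dz * uz)
    c = dx * dx + dz * dz - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return np.inf
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    if inside:
        return t2 if t2 > _GEOM_EPS else np.inf
    if t1 > _GEOM_EPS:
        return t1
    return np.inf


@njit(cache=True, fastmath=True)
def run_transport(
    z0,
    z1,
    mua,
    mus,
    gg,
    nn,
    n_above,
    n_below,
    bone_on,
    bone_cx,
    bone_cz,
    bone_r,
    bone_mua,
    bone_mus,
    bone_g,
    det_offset,
    det_radius,
    det_cos_min,
    det_side,
    tally_mode,
    stop_mode,
    target,
    max_launched,
    roulette_threshold,
    roulette_survival,
    cutoff_radius,
    seed,
):
    """Run photon packets until the stop criterion; return the tally tuple.

    Returns (launched, detected_count, detected_weight, specular,
    diffuse_reflected, transmitted, absorbed, lateral_lost).
    """
    # expand the integer seed into the xorshift128+ state
    v0, carry = _splitmix64(np.uint64(seed))
    v1, _ = _splitmix64(carry)
    s0 = v0 | np.uint64(1)
    s1 = v1 | np.uint64(2)

    n_layers = z0.shape[0]
    cutoff2 = cutoff_radius * cutoff_radius

    launched = 0
    detected_count = 0
    detected_weight = 0.0
    specular = 0.0
    diffuse_reflected = 0.0
    transmitted = 0.0
    absorbed = 0.0
    lateral_lost = 0.0

    while True:
        if stop_mode == STOP_DETECTED:
            if detected_count >= target or launched >= max_launched:
                break
        else:
            if launched >= target:
                break
        launched += 1

        # launch: pencil beam at origin, straight down, minus specular loss
        rsp, _unused = _fresnel_unpolarised(n_above, nn[0], 1.0)
        w = 1.0 - rsp
        specular += rsp
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        in_bone = False
        alive = True

        while alive:
            u, s0, s1 = _rng_next(s0, s1)
            s = -math.log(1.0 - u)  # optical depth to travel
            while s > 0.0 and alive:
                if in_bone:
                    mua_c = bone_mua
                    mus_c = bone_mus
                    g_c = bone_g
                else:
                    mua_c = mua[layer]
                    mus_c = mus[layer]
                    g_c = gg[layer]
                mut = mua_c + mus_c

                # geometric distance to nearest region boundary
                if in_bone:
                    db = _cyl_intersect(x, z, ux, uz, bone_cx, bone_cz, bone_r, True)
                    cyl_hit = True
                else:
                    if uz > _EPS:
                        db = (z1[layer] - z) / uz
                    elif uz < -_EPS:
                        db = (z0[layer] - z) / uz
                    else:
                        db = np.inf
                    cyl_hit = False
                    if bone_on:
                        dc = _cyl_intersect(
                            x, z, ux, uz, bone_cx, bone_cz, bone_r, False
                        )
                        if dc < db:
                            db = dc
                            cyl_hit = True

                step = s / mut if mut > 0.0 else np.inf

                if step == np.inf and db == np.inf:
                    # vacuum layer, horizontal flight: photon never interacts
                    lateral_lost += w
                    absorbed += w
                    alive = False
                    break

                if step < db:
                    # hop to an interaction site
                    x += step * ux
                    y += step * uy
                    z += step * uz
                    s = 0.0
                    # drop
                    absorbed += w * mua_c / mut
                    w *= mus_c / mut
                    # spin: HG polar angle, rejection-sampled azimuth
                    u, s0, s1 = _rng_next(s0, s1)
                    if g_c > 1e-6 or g_c < -1e-6:
                        tmp = (1.0 - g_c * g_c) / (1.0 - g_c + 2.0 * g_c * u)
                        cost = (1.0 + g_c * g_c - tmp * tmp) / (2.0 * g_c)
                        if cost > 1.0:
                            cost = 1.0
                        elif cost < -1.0:
                            cost = -1.0
                    else:
                        cost = 2.0 * u - 1.0
                    sint = math.sqrt(1.0 - cost * cost)
                    # unit vector on the circle without trig calls
                    while True:
                        a1, s0, s1 = _rng_next(s0, s1)
                        a2, s0, s1 = _rng_next(s0, s1)
                        v1 = 2.0 * a1 - 1.0
                        v2 = 2.0 * a2 - 1.0
                        r2 = v1 * v1 + v2 * v2
                        if 0.0 < r2 < 1.0:
                            break
                    cosp = (v1 * v1 - v2 * v2) / r2
                    sinp = 2.0 * v1 * v2 / r2
                    if uz > 0.99999 or uz < -0.99999:
                        ux = sint * cosp
                        uy = sint * sinp
                        uz = cost if uz > 0.0 else -cost
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                        nz = -sint * cosp * den + uz * cost
                        norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                        ux = nx / norm
                        uy = ny / norm
                        uz = nz / norm
                    # roulette
                    if w < roulette_threshold:
                        u, s0, s1 = _rng_next(s0, s1)
                        if u < roulette_survival:
                            w_new = w / roulette_survival
                            absorbed -= w_new - w
                            w = w_new
                        else:
                            absorbed += w
                            alive = False
                            break
                    if x * x + y * y > cutoff2:
                        lateral_lost += w
                        absorbed += w
                        alive = False
                        break
                else:
                    # hop to the boundary; consume the optical depth spent
                    x += db * ux
                    y += db * uy
                    z += db * uz
                    if mut > 0.0:
                        s -= db * mut
                        if s < 0.0:
                            s = 0.0
                    else:
                        s = 0.0
                    if cyl_hit:
                        # bone surface treated as index-matched: toggle region
                        if in_bone:
                            in_bone = False
                            # re-locate the slab containing the exit depth
                            for k in range(n_layers):
                                if z0[k] <= z < z1[k]:
                                    layer = k
                                    break
                        else:
                            in_bone = True
                        continue
                    going_down = uz > 0.0
                    n1 = nn[layer]
                    if going_down:
                        z = z1[layer]
                        n2 = nn[layer + 1] if layer + 1 < n_layers else n_below
                    else:
                        z = z0[layer]
                        n2 = nn[layer - 1] if layer > 0 else n_above
                    if n1 == n2:
                        # matched interface: cross without Fresnel bookkeeping
                        if going_down and layer == n_layers - 1:
                            transmitted += w
                            if det_side == SIDE_BOTTOM and uz >= det_cos_min:
                                detected_weight, detected_count = _detect(
                                    x,
                                    y,
                                    w,
                                    det_offset,
                                    det_radius,
                                    tally_mode,
                                    detected_weight,
                                    detected_count,
                                )
                            alive = False
                        elif (not going_down) and layer == 0:
                            diffuse_reflected += w
                            if det_side == SIDE_TOP and -uz >= det_cos_min:
                                detected_weight, detected_count = _detect(
                                    x,
                                    y,
                                    w,
                                    det_offset,
                                    det_radius,
                                    tally_mode,
                                    detected_weight,
                                    detected_count,
                                )
                            alive = False
                        else:
                            layer = layer + 1 if going_down else layer - 1
                        continue
                    cos_i = uz if going_down else -uz
                    refl, cos_t = _fresnel_unpolarised(n1, n2, cos_i)
                    do_reflect = refl >= 1.0
                    if not do_reflect and refl > 0.0:
                        u, s0, s1 = _rng_next(s0, s1)
                        do_reflect = u < refl
                    if do_reflect:
                        uz = -uz  # internal reflection
                        continue
                    # refract
                    ratio = n1 / n2
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    if going_down and layer == n_layers - 1:
                        transmitted += w
                        if det_side == SIDE_BOTTOM and cos_t >= det_cos_min:
                            detected_weight, detected_count = _detect(
                                x,
                                y,
                                w,
                                det_offset,
                                det_radius,
                                tally_mode,
                                detected_weight,
                                detected_count,
                            )
                        alive = False
                    elif (not going_down) and layer == 0:
                        diffuse_reflected += w
                        if det_side == SIDE_TOP and cos_t >= det_cos_min:
                            detected_weight, detected_count = _detect(
                                x,
                                y,
                                w,
                                det_offset,
                                det_radius,
                                tally_mode,
                                detected_weight,
                                detected_count,
                            )
                        alive = False
                    else:
                        layer = layer + 1 if going_down else layer - 1

    return (
        launched,
        detected_count,
        detected_weight,
        specular,
        diffuse_reflected,
        transmitted,
        absorbed,
        lateral_lost,
    )


@njit(cache=True, inline="always")
def _detect(x, y, w, det_offset, det_radius, tally_mode, detected_weight, detected_count):
    if tally_mode == TALLY_RING:
        r = math.sqrt(x * x + y * y)
        p = _ring_overlap(r, det_offset, det_radius)
        if p > 0.0:
            detected_weight += w * p
            detected_count += 1
    else:
        ddx = x - det_offset
        if ddx * ddx + y * y < det_radius * det_radius:
            detected_weight += w
            detected_count += 1
    return detected_weight, detected_count
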