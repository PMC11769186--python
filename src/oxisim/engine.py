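"""Photon-packet transport through a resolved tissue stack.

The public surface has two levels:

* unit operations (:func:`launch`, :func:`sample_step`, :func:`scatter`,
  :func:`boundary_interact`, :func:`roulette`) expressed on a single
  :class:`PhotonState` — the physics primitives, usable interactively and
  easy to test against their closed-form distributions;
* :func:`transport`, which runs the full weighted random walk for millions
  of packets through a compiled kernel and returns a :class:`TransportResult`.

Both implement the same physics; :func:`transport_reference` is a slow,
pure-Python composition of the unit operations retained as an internal
cross-check of the compiled kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from .tissue import TissueStack

__all__ = [
    "PhotonState",
    "DetectorSpec",
    "EngineSettings",
    "TransportResult",
    "fresnel_reflectance",
    "launch",
    "sample_step",
    "scatter",
    "boundary_interact",
    "roulette",
    "transport",
    "transport_reference",
]

#: Default roulette parameters: packets below the threshold survive with
#: probability 0.1 and are re-weighted by 1/0.1, keeping the walk unbiased.
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


def fresnel_reflectance(n1: float, n2: float, cos_i: float) -> tuple[float, float]:
    """Unpolarised Fresnel reflectance and transmitted-angle cosine.

    Average of the s- and p-polarised reflectances; returns ``(R, cos_t)``
    with ``R = 1`` beyond the critical angle.
    """
    if not 0 <= cos_i <= 1 + 1e-12:
        raise ValueError(f"cos_i must lie in [0, 1], got {cos_i}")
    if n1 == n2:
        return 0.0, cos_i
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@dataclass
class PhotonState:
    """One photon packet: position (mm), unit direction, weight, region."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    layer: int = 0
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit-norm, |u| = {norm}")
        if self.alive and not 0 < self.weight <= 1 + 1e-12:
            # amplified post-roulette weights may exceed 1 transiently
            if self.weight <= 0:
                raise ValueError(f"live packet must have positive weight")


@dataclass(frozen=True)
class DetectorSpec:
    """Surface detector: a disc displaced from the source along +x.

    ``acceptance_cos`` is the minimum exit-direction cosine (relative to the
    surface normal, measured after refraction into the ambient medium) for a
    packet to be counted; 0 accepts every exit within the footprint.
    ``side`` selects reflectance (top) or transmittance (bottom) geometry.
    """

    center_offset: float = 3.0
    radius: float = 1.0
    acceptance_cos: float = 0.0
    side: str = "top"

    def __post_init__(self):
        if self.center_offset < 0:
            raise ValueError("center_offset must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.side not in ("top", "bottom"):
            raise ValueError("side must be 'top' or 'bottom'")


@dataclass(frozen=True)
class EngineSettings:
    """Numerical knobs of the transport kernel."""

    roulette_threshold: float = ROULETTE_THRESHOLD
    roulette_survival: float = ROULETTE_SURVIVAL
    cutoff_radius: float = 15.0
    max_launched: int = 500_000_000
    tally: str = "ring"

    def __post_init__(self):
        if not 0 < self.roulette_survival <= 1:
            raise ValueError("roulette_survival must lie in (0, 1]")
        if self.tally not in ("ring", "disc"):
            raise ValueError("tally must be 'ring' or 'disc'")


@dataclass(frozen=True)
class TransportResult:
    """Weight ledger of one transport run.

    ``absorbed_weight`` includes the net roulette adjustment and the weight
    of packets terminated at the lateral cutoff (the latter also reported in
    ``lateral_lost_weight``), so the four fates partition the launched
    weight exactly:

    ``specular + diffuse_reflected + transmitted + absorbed = launched``.
    """

    launched_count: int
    detected_count: int
    detected_weight: float
    specular_weight: float
    diffuse_reflected_weight: float
    transmitted_weight: float
    absorbed_weight: float
    lateral_lost_weight: float
    seed: int

    def __post_init__(self):
        total = (
            self.specular_weight
            + self.diffuse_reflected_weight
            + self.transmitted_weight
            + self.absorbed_weight
        )
        if self.launched_count > 0:
            if abs(total - self.launched_weight) > 1e-6 * self.launched_weight:
                raise ValueError(
                    f"weight not conserved: {total} vs {self.launched_weight}"
                )
        if self.detected_weight > self.diffuse_reflected_weight + self.transmitted_weight:
            raise ValueError("detected weight exceeds escaping weight")

    @property
    def launched_weight(self) -> float:
        return float(self.launched_count)

    @property
    def reflectance(self) -> float:
        """Detected weight per unit launched weight."""
        return self.detected_weight / self.launched_weight

    @property
    def total_diffuse_reflectance(self) -> float:
        return self.diffuse_reflected_weight / self.launched_weight

    @property
    def total_transmittance(self) -> float:
        return self.transmitted_weight / self.launched_weight


# ---------------------------------------------------------------------------
# unit operations


def launch(rng: np.random.Generator, *, n_ambient: float = 1.0, n_tissue: float = 1.4) -> PhotonState:
    """New packet: pencil beam entering at the origin straight down.

    The packet weight is reduced by the normal-incidence specular
    reflectance of the air-tissue interface.
    """
    r_sp, _ = fresnel_reflectance(n_ambient, n_tissue, 1.0)
    return PhotonState(
        position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]), weight=1.0 - r_sp
    )


def sample_step(mu_t: float, rng: np.random.Generator) -> float:
    """Free path length (mm): ``-ln(xi)/mu_t`` with ``xi ~ U(0, 1]``."""
    if mu_t <= 0:
        raise ValueError(f"mu_t must be positive, got {mu_t}")
    xi = 1.0 - rng.random()  # (0, 1]
    return -math.log(xi) / mu_t


def henyey_greenstein_cos(g: float, rng: np.random.Generator) -> float:
    """Deflection cosine from the Henyey-Greenstein inverse CDF."""
    if not -1 <= g <= 1:
        raise ValueError(f"anisotropy g must lie in [-1, 1], got {g}")
    xi = rng.random()
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return float(np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0))


def scatter(direction: np.ndarray, g: float, rng: np.random.Generator) -> np.ndarray:
    """Deflect a unit direction by a Henyey-Greenstein polar angle and
    uniform azimuth; returns a unit vector."""
    ux, uy, uz = (float(c) for c in direction)
    cost = henyey_greenstein_cos(g, rng)
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * rng.random()
    cosp, sinp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        new = np.array([sint * cosp, sint * sinp, cost if uz > 0 else -cost])
    else:
        den = math.sqrt(1.0 - uz * uz)
        new = np.array(
            [
                sint * (ux * uz * cosp - uy * sinp) / den + ux * cost,
                sint * (uy * uz * cosp + ux * sinp) / den + uy * cost,
                -sint * cosp * den + uz * cost,
            ]
        )
    return new / np.linalg.norm(new)


def boundary_interact(
    photon: PhotonState,
    normal: np.ndarray,
    n1: float,
    n2: float,
    rng: np.random.Generator,
) -> PhotonState:
    """Reflect or refract a packet at an interface.

    ``normal`` is the unit interface normal pointing into medium 2.  With
    probability equal to the unpolarised Fresnel reflectance the packet
    reflects specularly; otherwise it refracts by Snell's law.  Beyond the
    critical angle it always reflects.
    """
    normal = np.asarray(normal, dtype=float)
    u = photon.direction
    cos_i = float(np.dot(u, normal))
    if cos_i < 0:
        raise ValueError("direction must point into medium 2 (dot(u, normal) >= 0)")
    refl, cos_t = fresnel_reflectance(n1, n2, cos_i)
    if refl >= 1.0 or (refl > 0.0 and rng.random() < refl):
        new_dir = u - 2.0 * cos_i * normal
    else:
        if n1 == n2:
            new_dir = u
        else:
            ratio = n1 / n2
            new_dir = ratio * u + (cos_t - ratio * cos_i) * normal
            new_dir = new_dir / np.linalg.norm(new_dir)
    return replace(photon, direction=new_dir)


def roulette(
    photon: PhotonState,
    threshold: float = ROULETTE_THRESHOLD,
    survival_prob: float = ROULETTE_SURVIVAL,
    rng: np.random.Generator | None = None,
) -> PhotonState:
    """Terminate or amplify a low-weight packet, conserving expected weight.

    Packets at or above the threshold pass through unchanged; below it they
    survive with probability ``survival_prob`` and weight divided by it, or
    terminate with weight zero.
    """
    if not photon.alive:
        raise ValueError("roulette applies to live packets only")
    if photon.weight >= threshold:
        return photon
    if rng.random() < survival_prob:
        return replace(photon, weight=photon.weight / survival_prob)
    return replace(photon, weight=0.0, alive=False)


# ---------------------------------------------------------------------------
# full transport


def _stack_arrays(stack: TissueStack):
    z0 = np.array([lay.z_top for lay in stack.layers])
    z1 = np.array([lay.z_bottom for lay in stack.layers])
    mua = np.array([lay.mu_a for lay in stack.layers])
    mus = np.array([lay.mu_s for lay in stack.layers])
    g = np.array([lay.g for lay in stack.layers])
    n = np.array([lay.n for lay in stack.layers])
    if not (np.all(np.isfinite(mua)) and np.all(np.isfinite(mus))):
        bad = [
            lay.name
            for lay in stack.layers
            if not (np.isfinite(lay.mu_a) and np.isfinite(lay.mu_s))
        ]
        raise ValueError(f"non-finite optical properties in layers {bad}")
    return z0, z1, mua, mus, g, n


def transport(
    stack: TissueStack,
    detector: DetectorSpec | None = None,
    *,
    seed: int,
    detected_target: int | None = None,
    launched_target: int | None = None,
    settings: EngineSettings | None = None,
) -> TransportResult:
    """Run the compiled photon walk until a packet target is met.

    Exactly one of ``detected_target`` (stop once that many packets have
    reached the detector footprint) or ``launched_target`` must be given.
    The run is a pure function of (stack, detector, settings, seed): the
    same inputs reproduce the result bit for bit.
    """
    detector = detector or DetectorSpec()
    settings = settings or EngineSettings()
    if (detected_target is None) == (launched_target is None):
        raise ValueError("give exactly one of detected_target / launched_target")
    target = detected_target if detected_target is not None else launched_target
    if target is None or target <= 0:
        raise ValueError("packet target must be a positive integer")
    z0, z1, mua, mus, g, n = _stack_arrays(stack)
    bone = stack.bone
    out = _kernel.run_transport(
        z0,
        z1,
        mua,
        mus,
        g,
        n,
        stack.ambient_n_above,
        stack.ambient_n_below,
        bone is not None,
        bone.center_x if bone is not None else 0.0,
        bone.center_depth if bone is not None else 0.0,
        bone.radius if bone is not None else 0.0,
        bone.mu_a if bone is not None else 0.0,
        bone.mu_s if bone is not None else 0.0,
        bone.g if bone is not None else 0.0,
        detector.center_offset,
        detector.radius,
        detector.acceptance_cos,
        _kernel.SIDE_TOP if detector.side == "top" else _kernel.SIDE_BOTTOM,
        _kernel.TALLY_RING if settings.tally == "ring" else _kernel.TALLY_DISC,
        _kernel.STOP_DETECTED if detected_target is not None else _kernel.STOP_LAUNCHED,
        int(target),
        int(settings.max_launched),
        settings.roulette_threshold,
        settings.roulette_survival,
        settings.cutoff_radius,
        int(seed) & 0x7FFFFFFF,
    )
    (
        launched,
        detected_count,
        detected_weight,
        specular,
        diffuse_reflected,
        transmitted,
        absorbed,
        lateral_lost,
    ) = out
    if detected_target is not None and detected_count < detected_target:
        raise RuntimeError(
            f"launched {launched} packets (max {settings.max_launched}) but "
            f"detected only {detected_count} of {detected_target}"
        )
    return TransportResult(
        launched_count=int(launched),
        detected_count=int(detected_count),
        detected_weight=float(detected_weight),
        specular_weight=float(specular),
        diffuse_reflected_weight=float(diffuse_reflected),
        transmitted_weight=float(transmitted),
        absorbed_weight=float(absorbed),
        lateral_lost_weight=float(lateral_lost),
        seed=int(seed),
    )


def transport_reference(
    stack: TissueStack,
    detector: DetectorSpec | None = None,
    *,
    seed: int,
    launched_target: int,
    settings: EngineSettings | None = None,
) -> TransportResult:
    """Pure-Python transport composed from the unit operations.

    Slab-only (no bone), launched-target stop, ring tally.  Orders of
    magnitude slower than :func:`transport`; kept as an independent
    cross-check of the compiled kernel on small problems.
    """
    detector = detector or DetectorSpec()
    settings = settings or EngineSettings()
    if stack.bone is not None:
        raise NotImplementedError("reference transport is slab-only")
    rng = np.random.default_rng(seed)
    z0, z1, mua, mus, g, n = _stack_arrays(stack)
    n_layers = len(z0)
    cutoff2 = settings.cutoff_radius**2

    detected_count = 0
    detected_weight = 0.0
    specular = 0.0
    diffuse_reflected = 0.0
    transmitted = 0.0
    absorbed = 0.0
    lateral_lost = 0.0

    for _ in range(launched_target):
        p = launch(rng, n_ambient=stack.ambient_n_above, n_tissue=n[0])
        specular += 1.0 - p.weight
        layer = 0
        while p.alive:
            mut = mua[layer] + mus[layer]
            s_opt = -math.log(1.0 - rng.random())
            while s_opt > 0 and p.alive:
                mut = mua[layer] + mus[layer]
                uz = p.direction[2]
                if uz > 1e-12:
                    db = (z1[layer] - p.position[2]) / uz
                elif uz < -1e-12:
                    db = (z0[layer] - p.position[2]) / uz
                else:
                    db = math.inf
                step = s_opt / mut if mut > 0 else math.inf
                if step < db:
                    p.position = p.position + step * p.direction
                    s_opt = 0.0
                    absorbed += p.weight * mua[layer] / mut
                    p.weight *= mus[layer] / mut
                    p.direction = scatter(p.direction, g[layer], rng)
                    if p.weight < settings.roulette_threshold:
                        w_before = p.weight
                        p = roulette(
                            p,
                            settings.roulette_threshold,
                            settings.roulette_survival,
                            rng,
                        )
                        absorbed += w_before - p.weight
                    if p.alive and (
                        p.position[0] ** 2 + p.position[1] ** 2 > cutoff2
                    ):
                        lateral_lost += p.weight
                        absorbed += p.weight
                        p.alive = False
                else:
                    p.position = p.position + db * p.direction
                    if mut > 0:
                        s_opt = max(0.0, s_opt - db * mut)
                    else:
                        s_opt = 0.0
                    going_down = uz > 0
                    n1 = n[layer]
                    if going_down:
                        p.position[2] = z1[layer]
                        n2 = n[layer + 1] if layer + 1 < n_layers else stack.ambient_n_below
                        normal = np.array([0.0, 0.0, 1.0])
                    else:
                        p.position[2] = z0[layer]
                        n2 = n[layer - 1] if layer > 0 else stack.ambient_n_above
                        normal = np.array([0.0, 0.0, -1.0])
                    before = p.direction[2]
                    p = boundary_interact(p, normal, n1, n2, rng)
                    reflected = (p.direction[2] > 0) != (before > 0)
                    if reflected:
                        continue
                    if going_down and layer == n_layers - 1:
                        transmitted += p.weight
                        if detector.side == "bottom":
                            detected_weight, detected_count = _ring_tally(
                                p, detector, detected_weight, detected_count
                            )
                        p.alive = False
                    elif (not going_down) and layer == 0:
                        diffuse_reflected += p.weight
                        if detector.side == "top":
                            detected_weight, detected_count = _ring_tally(
                                p, detector, detected_weight, detected_count
                            )
                        p.alive = False
                    else:
                        layer += 1 if going_down else -1
    return TransportResult(
        launched_count=launched_target,
        detected_count=detected_count,
        detected_weight=detected_weight,
        specular_weight=specular,
        diffuse_reflected_weight=diffuse_reflected,
        transmitted_weight=transmitted,
        absorbed_weight=absorbed,
        lateral_lost_weight=lateral_lost,
        seed=seed,
    )


def _ring_tally(p, detector, detected_weight, detected_count):
    r = math.hypot(p.position[0], p.position[1])
    frac = ring_overlap_fraction(r, detector.center_offset, detector.radius)
    if frac > 0:
        detected_weight += p.weight * frac
        detected_count += 1
    return detected_weight, detected_count


def ring_overlap_fraction(r: float, offset: float, radius: float) -> float:
    """Fraction of the circle of exit radius ``r`` covered by the detector disc.

    The pencil-beam geometry is rotationally symmetric about the source
    axis, so averaging the detector footprint over azimuth is an unbiased,
    lower-variance tally of detection at a disc displaced ``offset`` from
    the source.
    """
    if offset <= 1e-12:
        return 1.0 if r < radius else 0.0
    if r <= radius - offset:
        return 1.0
    if r <= 1e-12 or r <= offset - radius or r >= offset + radius:
        return 0.0
    c = (r * r + offset * offset - radius * radius) / (2.0 * r * offset)
    return math.acos(min(1.0, max(-1.0, c))) / math.pi
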