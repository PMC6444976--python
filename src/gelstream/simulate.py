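"""Stochastic sawtooth trajectory simulation of DNA streams.

Fragments are injected continuously at the left edge of a square gel
chamber and driven by the alternating field protocol.  Each half-cycle a
particle first sits through its reorientation dead time (zero net
displacement), then moves in a straight line at mu_i*E_i along the active
field direction.  Optional isotropic diffusion adds a Gaussian kick per
half-cycle.  A particle terminates at its first crossing of the collection
edge (x = width); its exit y position feeds the stream profiles that the
analysis chain consumes.

Coordinates: x in [0, width] rightward toward the collection edge, y in
[0, height] along the collection line, origin at the top-left injection
side; angles counterclockwise from +x, degrees at interfaces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .deflection import FieldProtocol, migration_angle
from .mobility import FragmentSpec, MobilityModel

UM_PER_CM = 1.0e4


@dataclass(frozen=True)
class ChamberSpec:
    """Separation chamber geometry (defaults: 10 x 10 mm, 110 um band)."""

    width_cm: float = 1.0
    height_cm: float = 1.0
    injection_y_cm: float = 0.0
    injection_band_width_um: float = 110.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("chamber dimensions must be positive")
        if not (0.0 < self.injection_band_width_um / UM_PER_CM < self.height_cm):
            raise ValueError("injection band width must be positive and << chamber height")
        if not (0.0 <= self.injection_y_cm <= self.height_cm):
            raise ValueError("injection_y_cm must lie within [0, height]")


@dataclass
class ParticleEnsemble:
    """Exit samples and optional trajectory log for one fragment."""

    fragment: FragmentSpec
    start_y_cm: np.ndarray
    exit_y_cm: np.ndarray
    exit_x_cm: np.ndarray
    exit_time_s: np.ndarray
    collected: np.ndarray  # exited through the collection edge x = width
    rng_seed: int
    trajectory: np.ndarray | None = None  # (n_log_points, 2) of particle 0

    @property
    def n_particles(self) -> int:
        return self.start_y_cm.size

    @property
    def exit_angles_deg(self) -> np.ndarray:
        """atan2(net dy, net dx) per particle, degrees."""
        return np.degrees(np.arctan2(self.exit_y_cm - self.start_y_cm, self.exit_x_cm))


@dataclass(frozen=True)
class BroadeningResult:
    """Per-period transverse excursion and its share of the injection band."""

    L_fr_um: float
    fraction_of_injection: float


def band_broadening_excursion(
    protocol: FieldProtocol,
    mobility_2: float,
    chamber: ChamberSpec | None = None,
) -> BroadeningResult:
    """Transverse sawtooth excursion per switching period.

    L_fr = 0.5 * (mu2 * E2 / f) * (tan(theta1) * cos(theta2) + sin(theta2)),
    reported in um; the fraction is taken against the chamber's injection
    band width (default 110 um).
    """
    if protocol.f_Hz <= 0:
        raise ValueError("band broadening excursion requires f > 0")
    t1 = math.radians(protocol.theta1_deg)
    t2 = math.radians(protocol.theta2_deg)
    if abs(math.cos(t1)) < 1e-12:
        raise ValueError("theta1 = 90 deg makes tan(theta1) singular")
    L_fr_cm = (
        0.5
        * mobility_2
        * protocol.E2_V_per_cm
        / protocol.f_Hz
        * (math.tan(t1) * math.cos(t2) + math.sin(t2))
    )
    L_fr_um = abs(L_fr_cm) * UM_PER_CM
    width = chamber.injection_band_width_um if chamber is not None else 110.0
    return BroadeningResult(L_fr_um, L_fr_um / width)


def _segment_schedule(protocol, mu1, mu2, fragment):
    """Per-period segment table: (dt, vx, vy) for dead/move in each field."""
    L = fragment.contour_length_cm
    f = protocol.f_Hz
    T1 = protocol.duty / f
    T2 = (1.0 - protocol.duty) / f
    segs = []
    for (T, mu, E, theta) in (
        (T1, mu1, protocol.E1_V_per_cm, protocol.theta1_deg),
        (T2, mu2, protocol.E2_V_per_cm, protocol.theta2_deg),
    ):
        speed = mu * E
        tau = min(L / speed, T)
        th = math.radians(theta)
        if tau > 0:
            segs.append((tau, 0.0, 0.0))
        if T - tau > 0:
            segs.append((T - tau, speed * math.cos(th), speed * math.sin(th)))
    return segs


def simulate_streams(
    protocol: FieldProtocol,
    fragments: list[FragmentSpec],
    chamber: ChamberSpec,
    model: MobilityModel,
    n_particles: int,
    seed: int,
    diffusion_coeff: float = 0.0,
    *,
    random_phase: bool | None = None,
    log_trajectory: bool = False,
    max_time_s: float = 1.0e5,
) -> dict[int, ParticleEnsemble]:
    """Simulate particle streams for each fragment; keyed by length_bp.

    Particles start at x = 0, y ~ injection_y + top-hat of the injection
    band width, with (by default, for n > 1) a random phase within the
    switching period to suppress phase locking.  Determinism: a fixed seed
    reproduces exit samples bit for bit.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if diffusion_coeff < 0:
        raise ValueError("diffusion_coeff must be >= 0")
    if random_phase is None:
        random_phase = n_particles > 1
    rng_root = np.random.default_rng(seed)
    out: dict[int, ParticleEnsemble] = {}
    for frag in fragments:
        child_seed = int(rng_root.integers(0, 2**31 - 1))
        out[frag.length_bp] = _simulate_fragment(
            protocol, frag, chamber, model, n_particles, child_seed,
            diffusion_coeff, random_phase, log_trajectory, max_time_s,
        )
    return out


def _simulate_fragment(
    protocol, fragment, chamber, model, n, seed, D, random_phase, log_trajectory, max_time_s
):
    rng = np.random.default_rng(seed)
    half_w = 0.5 * chamber.injection_band_width_um / UM_PER_CM
    y0 = chamber.injection_y_cm + rng.uniform(-half_w, half_w, size=n)
    x = np.zeros(n)
    y = y0.copy()
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    exit_x = np.zeros(n)
    exit_y = np.zeros(n)
    exit_t = np.zeros(n)
    collected = np.zeros(n, dtype=bool)
    traj = [(0.0, float(y[0]))] if log_trajectory else None

    mu1 = model.mobility(protocol.E1_V_per_cm, fragment)
    mu2 = model.mobility(protocol.E2_V_per_cm, fragment)
    W, H = chamber.width_cm, chamber.height_cm

    if protocol.f_Hz == 0.0:
        res = migration_angle(protocol, fragment, model)
        if res.no_net_motion and D == 0.0:
            raise RuntimeError(
                "no transport: both effective velocities are zero and diffusion is off"
            )
        d1, d2 = protocol.duty, 1.0 - protocol.duty
        t1 = math.radians(protocol.theta1_deg)
        t2 = math.radians(protocol.theta2_deg)
        vx = (d1 * mu1 * protocol.E1_V_per_cm * math.cos(t1)
              + d2 * mu2 * protocol.E2_V_per_cm * math.cos(t2))
        vy = (d1 * mu1 * protocol.E1_V_per_cm * math.sin(t1)
              + d2 * mu2 * protocol.E2_V_per_cm * math.sin(t2))
        dt = W / max(abs(vx), abs(vy), 1e-30) / 64.0
        segs = [(dt, vx, vy)]
        period = None
    else:
        segs = _segment_schedule(protocol, mu1, mu2, fragment)
        moving = any(vx != 0.0 or vy != 0.0 for _, vx, vy in segs)
        if not moving and D == 0.0:
            raise RuntimeError(
                "no transport: both effective velocities are zero and diffusion is off"
            )
        period = 1.0 / protocol.f_Hz
        if random_phase:
            # Continuous injection across the x = 0 plane: a particle enters
            # mid-cycle with probability proportional to its instantaneous
            # forward x-flux, then finishes the current period, after which
            # all particles advance period-aligned.  Flux weighting (rather
            # than time-uniform phase) matches steady injection at a fixed
            # plane and keeps the mean exit angle consistent with the
            # analytic migration angle.
            seg_dx = np.array([dt * vx for dt, vx, _ in segs])
            w = np.clip(seg_dx, 0.0, None)
            if w.sum() > 0:
                j = rng.choice(len(segs), size=n, p=w / w.sum())
                u = rng.uniform(0.0, 1.0, size=n)
            else:  # no forward drift: fall back to time-uniform phase
                dts = np.array([dt for dt, _, _ in segs])
                j = rng.choice(len(segs), size=n, p=dts / dts.sum())
                u = rng.uniform(0.0, 1.0, size=n)
            sdx = np.zeros(len(segs))
            sdy = np.zeros(len(segs))
            sdt = np.zeros(len(segs))
            for k in range(len(segs) - 2, -1, -1):
                dt, vx, vy = segs[k + 1]
                sdx[k] = sdx[k + 1] + dt * vx
                sdy[k] = sdy[k + 1] + dt * vy
                sdt[k] = sdt[k + 1] + dt
            for k, (dt, vx, vy) in enumerate(segs):
                mk = j == k
                if not mk.any():
                    continue
                tk = (1.0 - u[mk]) * dt
                x[mk] += vx * tk
                y[mk] += vy * tk
                t[mk] += tk
            x += sdx[j]
            y += sdy[j]
            t += sdt[j]

    # per-period drift and within-period path extent, for bulk fast-forward
    if period is not None:
        drift_x = sum(dt * vx for dt, vx, _ in segs)
        drift_y = sum(dt * vy for dt, _, vy in segs)
        path_x = sum(abs(dt * vx) for dt, vx, _ in segs)
        path_y = sum(abs(dt * vy) for dt, _, vy in segs)

    def _step(dt, vx, vy, idx):
        """Advance idx particles one segment; detect first boundary crossing."""
        ox, oy = x[idx], y[idx]
        nx = ox + vx * dt
        ny = oy + vy * dt
        if D > 0.0:
            sig = math.sqrt(2.0 * D * dt)
            nx = nx + rng.normal(0.0, sig, size=idx.size)
            ny = ny + rng.normal(0.0, sig, size=idx.size)
        dx = nx - ox
        dy = ny - oy
        frac_x = np.where(dx > 0, (W - ox) / np.where(dx == 0, 1.0, dx), np.inf)
        frac_y = np.where(dy > 0, (H - oy) / np.where(dy == 0, 1.0, dy), np.inf)
        frac = np.minimum(frac_x, frac_y)
        hit = frac <= 1.0
        if hit.any():
            g = idx[hit]
            fr = frac[hit]
            exit_x[g] = ox[hit] + fr * dx[hit]
            exit_y[g] = oy[hit] + fr * dy[hit]
            exit_t[g] = t[g] + fr * dt
            collected[g] = frac_x[hit] <= frac_y[hit]
            alive[g] = False
        keep = ~hit
        g = idx[keep]
        x[g] = nx[keep]
        y[g] = ny[keep]
        t[g] += dt

    while alive.any():
        idx = np.flatnonzero(alive)
        if period is not None:
            # fast-forward whole periods while no particle can reach a boundary
            k = 0
            if drift_x > 0 or drift_y > 0:
                xmax = float(x[idx].max())
                ymax = float(y[idx].max())
                k = 2**30
                if drift_x > 0:
                    k = min(k, int((W - xmax - path_x) / drift_x))
                elif xmax + path_x >= W:
                    k = 0
                if drift_y > 0:
                    k = min(k, int((H - ymax - path_y) / drift_y))
                elif ymax + path_y >= H:
                    k = 0
                if D > 0.0 and k > 0:
                    sig = math.sqrt(2.0 * D * k * period)
                    head_x = max(W - xmax - path_x - 7.0 * sig, 0.0)
                    head_y = max(H - ymax - path_y - 7.0 * sig, 0.0)
                    if drift_x > 0:
                        k = min(k, int(head_x / drift_x))
                    if drift_y > 0:
                        k = min(k, int(head_y / drift_y))
            if k >= 2:
                x[idx] += k * drift_x
                y[idx] += k * drift_y
                if D > 0.0:
                    sig = math.sqrt(2.0 * D * k * period)
                    x[idx] += rng.normal(0.0, sig, size=idx.size)
                    y[idx] += rng.normal(0.0, sig, size=idx.size)
                t[idx] += k * period
            else:
                for dt, vx, vy in segs:
                    idx = np.flatnonzero(alive)
                    if idx.size == 0:
                        break
                    _step(dt, vx, vy, idx)
        else:
            dt, vx, vy = segs[0]
            _step(dt, vx, vy, idx)
        if log_trajectory:
            p0 = (float(x[0]), float(y[0])) if alive[0] else (float(exit_x[0]), float(exit_y[0]))
            if traj[-1] != p0:
                traj.append(p0)
        live_t = t[alive]
        if live_t.size and live_t.min() > max_time_s:
            raise RuntimeError("simulation exceeded max_time_s before all particles exited")
    return ParticleEnsemble(
        fragment=fragment,
        start_y_cm=y0,
        exit_y_cm=exit_y,
        exit_x_cm=exit_x,
        exit_time_s=exit_t,
        collected=collected,
        rng_seed=seed,
        trajectory=np.asarray(traj) if log_trajectory else None,
    )


def single_trajectory(
    protocol: FieldProtocol,
    fragment: FragmentSpec,
    model: MobilityModel,
    n_periods: int = 1,
    points_per_segment: int = 32,
) -> np.ndarray:
    """Noiseless single-particle path sampled within n_periods; (m, 2) cm.

    Starts at the beginning of a field-1 half-cycle at the origin; used to
    measure the per-period transverse sawtooth excursion.
    """
    if protocol.f_Hz <= 0:
        raise ValueError("single_trajectory requires f > 0")
    mu1 = model.mobility(protocol.E1_V_per_cm, fragment)
    mu2 = model.mobility(protocol.E2_V_per_cm, fragment)
    segs = _segment_schedule(protocol, mu1, mu2, fragment)
    pts = [(0.0, 0.0)]
    x = y = 0.0
    for _ in range(n_periods):
        for dt, vx, vy in segs:
            for k in range(1, points_per_segment + 1):
                s = dt * k / points_per_segment
                pts.append((x + vx * s, y + vy * s))
            x += vx * dt
            y += vy * dt
    return np.asarray(pts)


def sawtooth_excursion_um(
    protocol: FieldProtocol, fragment: FragmentSpec, model: MobilityModel
) -> float:
    """Measured peak y-deviation from the strong-field line over one period.

    Geometric counterpart of the closed-form L_fr: the largest vertical
    distance between the sampled one-period path and the straight line at
    theta1 through its start.
    """
    path = single_trajectory(protocol, fragment, model, n_periods=1)
    slope = math.tan(math.radians(protocol.theta1_deg))
    dev = path[:, 1] - slope * path[:, 0]
    return float((dev.max() - dev.min()) * UM_PER_CM)


def exit_profile(exit_samples_um, bin_width_um: float = 10.0):
    """Histogram of exit y positions as a StreamProfile (count-normalized)."""
    from .profiles import StreamProfile

    samples = np.asarray(exit_samples_um, dtype=float)
    if samples.size < 1:
        raise ValueError("need at least one exit sample")
    lo = math.floor(samples.min() / bin_width_um) * bin_width_um - bin_width_um
    hi = math.ceil(samples.max() / bin_width_um) * bin_width_um + bin_width_um
    edges = np.arange(lo, hi + bin_width_um, bin_width_um)
    counts, edges = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return StreamProfile(
        positions_um=centers,
        intensities=counts.astype(float) / samples.size,
        source="simulated",
    )


def render_image(
    stream_centers_um,
    stream_sigmas_um,
    *,
    amplitudes=None,
    angles_deg=None,
    image_shape=(256, 256),
    extent_um=(10000.0, 10000.0),
    psf_sigma_px: float = 1.0,
    background: float = 200.0,
    background_gradient: float = 0.05,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Synthetic 16-bit fluorescence micrograph of separated streams.

    Streams are Gaussian-blurred intensity ridges whose centers at the
    right (collection) edge are ``stream_centers_um`` with Gaussian widths
    ``stream_sigmas_um``; if ``angles_deg`` is given each ridge runs from
    the image origin at that angle, otherwise ridges are horizontal bands.
    A constant-plus-gradient background and Poisson shot noise are added.
    Returns (image, ground_truth) where the sidecar records the true
    centers/widths at the collection line and the pixel pitch.
    """
    ny, nx = image_shape
    if ny < 1 or nx < 1:
        raise ValueError("image_shape must be positive")
    if psf_sigma_px < 0:
        raise ValueError("psf_sigma_px must be >= 0")
    centers = np.asarray(stream_centers_um, dtype=float)
    sigmas = np.asarray(stream_sigmas_um, dtype=float)
    if centers.shape != sigmas.shape:
        raise ValueError("centers and sigmas must have equal length")
    if amplitudes is None:
        amplitudes = np.full(centers.shape, 8000.0)
    amplitudes = np.asarray(amplitudes, dtype=float)
    um_per_px_y = extent_um[0] / ny
    um_per_px_x = extent_um[1] / nx
    yy = (np.arange(ny) + 0.5) * um_per_px_y
    xx = (np.arange(nx) + 0.5) * um_per_px_x
    img = np.zeros((ny, nx), dtype=float)
    for k, (c, s, a) in enumerate(zip(centers, sigmas, amplitudes)):
        if angles_deg is None:
            ridge_c = np.full(nx, c)
        else:
            slope = math.tan(math.radians(np.asarray(angles_deg, dtype=float)[k]))
            ridge_c = c - slope * (extent_um[1] - xx)  # hits c at the right edge
        img += a * np.exp(-0.5 * ((yy[:, None] - ridge_c[None, :]) / s) ** 2)
    if psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, psf_sigma_px)
    img += background + background_gradient * background * (xx[None, :] / extent_um[1])
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if img.max() > 65535:
        warnings.warn("intensity overflow: clipping to 16-bit range")
        img = np.clip(img, 0, 65535)
    ground_truth = {
        "centers_um": centers.tolist(),
        "sigmas_um": sigmas.tolist(),
        "um_per_px_y": um_per_px_y,
        "um_per_px_x": um_per_px_x,
        "collection_x_px": nx - 1,
    }
    return img.astype(np.uint16), ground_truth
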