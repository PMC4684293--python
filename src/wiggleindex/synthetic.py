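"""Ground-truth synthetic data: rendered well videos and WI time courses.

Two generators, two purposes:

* :func:`render_well_sequence` draws a bright liquid-filled well on a dark
  plate background with dark elongated larvae, and animates them with a
  bout-structured gyration model.  It exercises the imaging pipeline with
  known motion amplitude, flicker and noise.
* :func:`simulate_timecourse` draws per-well WI time courses with
  fast-acting or slow-acting decay shapes, exercising the response
  statistics with known onset times and plateaus.

Motion model
------------
The temporal-dispersion statistic the pipeline computes (sigma_S) is, by
construction, blind to stationary oscillation: a larva wiggling in place at
constant intensity produces rolling-window SDs that are the same in every
window and therefore zero second-order dispersion.  What registers is
*non-stationary* activity — bouts of movement that start, stop and relocate
the animal.  Larvae behave exactly this way (brief lunges and gyrations
separated by rest), so each synthetic larva performs one or two motion
bouts per clip: it jitters around its pose, turns, and lunges to a nearby
resting pose.  The ``amplitude`` knob scales the jitter excursion and the
lunge distance; amplitude 0 is a perfectly static well.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .io import DataError, FrameStack, PlateLayout

__all__ = [
    "SceneSpec",
    "DecaySpec",
    "TIME_GRID",
    "render_well_sequence",
    "render_plate_video",
    "simulate_timecourse",
    "mini_scene",
]

#: Sampling schedule of the assay, minutes after insecticide addition
#: (0 = immediately before addition).
TIME_GRID = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 120.0, 240.0)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class SceneSpec:
    """One synthetic well video.

    Geometry is chosen to mimic one well of a 24-well plate filmed from
    above at the assay's working magnification: a ~15 mm well imaged at
    120 px across, holding 25 third-instar larvae of ~5 mm (32 px) length,
    which appear dark against the bright back-lit liquid.

    ``amplitude`` (px) controls motility: it scales the in-bout jitter, the
    turn angle, and the lunge ("relocation") distance of every bout.  The
    lognormal-free defaults keep all randomness reproducible from ``seed``.

    ``flicker_amplitude`` adds a spatially uniform per-frame intensity
    offset (illumination flicker); ``noise_sd`` adds i.i.d. Gaussian pixel
    noise.  Frames are rounded to whole 8-bit intensities and clipped to
    [0, 255], as a camera would.
    """

    well_size: int = 120
    n_blobs: int = 25
    blob_semi_major: float = 16.0
    blob_semi_minor: float = 3.0
    amplitude: float = 0.0
    background: float = 20.0
    well_intensity: float = 250.0
    blob_intensity: float = 10.0
    flicker_amplitude: float = 0.0
    flicker_freq_hz: float = 2.0
    noise_sd: float = 0.0
    n_frames: int = 250
    frame_rate: float = 25.0
    seed: int = 0
    edge_softness: float = 0.45
    def __post_init__(self) -> None:
        if self.n_blobs < 0 or self.n_frames < 1:
            raise DataError("n_blobs and n_frames must be positive")
        if self.amplitude < 0:
            raise DataError("amplitude must be >= 0")

    def ground_truth(self) -> dict:
        """Serializable record of the parameters that generated the scene."""
        return asdict(self)


def mini_scene(**overrides) -> SceneSpec:
    """Small fast preset (48 px well, 5 larvae, 30 frames) for quick tests.

    Pair with ``WIParams(window_size=12)`` so the rolling windows fit.
    """
    base = dict(
        well_size=48,
        n_blobs=5,
        blob_semi_major=6.0,
        blob_semi_minor=2.0,
        n_frames=30,
    )
    base.update(overrides)
    return SceneSpec(**base)


def _sharpened_sine(phase: np.ndarray, exponent: float = 0.25) -> np.ndarray:
    """Lunge-like waveform: a sine raised to a small odd power.

    Larval movements are jerky — rapid strokes with dwell at the extremes —
    which a pure harmonic underrepresents; flattening the sine toward a
    square wave captures the dwell while staying smooth and seed-free.
    """
    s = np.sin(phase)
    return np.sign(s) * np.abs(s) ** exponent


def _blob_tracks(spec: SceneSpec, rng: np.random.Generator):
    """Per-frame centre/orientation tracks for every blob.

    Each blob rests, then performs 1–2 bouts at random times: during a bout
    it jitters (sharpened-sine oscillation of its centre), turns, and
    drifts to a new resting pose a few * amplitude pixels away (lunge speed
    grows with amplitude, so vigorous animals relocate crisply).  Bout
    times, directions and frequencies are drawn independently of the
    amplitude, so scenes that differ only in amplitude share their bout
    structure — amplitude is a pure motion-scale knob.
    """
    a = spec.amplitude
    n, n_frames = spec.n_blobs, spec.n_frames
    cy = cx = (spec.well_size - 1) / 2.0
    rad = spec.well_size / 2.0 - 2.0
    rmax = rad - 6.0
    if spec.blob_semi_major >= 2 * rmax:
        raise DataError(
            f"blobs of semi-major {spec.blob_semi_major} px cannot fit a "
            f"{spec.well_size} px well"
        )
    if n * spec.blob_semi_major * spec.blob_semi_minor * np.pi > 2.5 * np.pi * rad**2:
        raise DataError(f"{n} blobs oversubscribe a {spec.well_size} px well")
    T = n_frames / spec.frame_rate
    t = np.arange(n_frames) / spec.frame_rate

    th0 = rng.uniform(0, 2 * np.pi, n)
    r0 = rmax * np.sqrt(rng.uniform(0, 1, n))
    by = cy + r0 * np.sin(th0)
    bx = cx + r0 * np.cos(th0)
    ori = rng.uniform(0, np.pi, n)

    BY = np.tile(by[:, None], (1, n_frames))
    BX = np.tile(bx[:, None], (1, n_frames))
    TH = np.tile(ori[:, None], (1, n_frames))

    jit = (min(a, 1.0) + 0.05 * a) if a > 0 else 0.0
    rot = 0.2 * np.sqrt(min(a, 4.0)) if a > 0 else 0.0
    speed = 4.0 + 4.0 * a  # lunge px/s

    for b in range(n):
        n_bouts = 1 + int(rng.uniform() < 0.5)
        starts = np.sort(rng.uniform(0, T, n_bouts))
        cury, curx, curth = by[b], bx[b], ori[b]
        for s in starts:
            fy, fx = rng.uniform(1.0, 2.5, 2)
            fr = rng.uniform(0.3, 0.8)
            py, px, pr = rng.uniform(0, 2 * np.pi, 3)
            mag = rng.uniform(1.8, 3.2) * a**0.8
            ang = rng.uniform(0, 2 * np.pi)
            dth = rng.normal(0, 0.3) * np.sqrt(a)
            if a == 0:
                continue
            dy, dx = mag * np.sin(ang), mag * np.cos(ang)
            ny, nx = cury + dy, curx + dx
            if np.hypot(ny - cy, nx - cx) > rmax:
                ny, nx = cury - dy, curx - dx  # lunge away from the wall
                drr = np.hypot(ny - cy, nx - cx)
                if drr > rmax:
                    ny = cy + (ny - cy) * rmax / drr
                    nx = cx + (nx - cx) * rmax / drr
            dist = float(np.hypot(ny - cury, nx - curx))
            L = float(np.clip(dist / speed, 0.2, 1.5))
            nth = curth + dth
            sel = t >= s
            inb = sel & (t < s + L)
            frac = np.clip((t - s) / L, 0.0, 1.0)
            BY[b, sel] = cury + (ny - cury) * frac[sel]
            BX[b, sel] = curx + (nx - curx) * frac[sel]
            TH[b, sel] = curth + (nth - curth) * frac[sel]
            BY[b, inb] += jit * _sharpened_sine(2 * np.pi * fy * t[inb] + py)
            BX[b, inb] += jit * _sharpened_sine(2 * np.pi * fx * t[inb] + px)
            TH[b, inb] += rot * _sharpened_sine(2 * np.pi * fr * t[inb] + pr)
            cury, curx, curth = ny, nx, nth
    return BY, BX, TH


def _render_frames(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    H = W = spec.well_size
    cy = cx = (W - 1) / 2.0
    rad = W / 2.0 - 2.0
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    rr = np.hypot(yy - cy, xx - cx)
    base = spec.background + (spec.well_intensity - spec.background) * _smoothstep(
        (rad - rr) / 1.5 + 0.5
    )
    BY, BX, TH = _blob_tracks(spec, rng)
    sa, sb = spec.blob_semi_major, spec.blob_semi_minor
    edge = spec.edge_softness
    t = np.arange(spec.n_frames) / spec.frame_rate
    frames = np.empty((spec.n_frames, H, W))
    for k in range(spec.n_frames):
        img = base.copy()
        for b in range(spec.n_blobs):
            cyb, cxb, ang = BY[b, k], BX[b, k], TH[b, k]
            ext = sa + edge + 1
            y0, y1 = int(max(0, cyb - ext)), int(min(H, cyb + ext + 1))
            x0, x1 = int(max(0, cxb - ext)), int(min(W, cxb + ext + 1))
            if y0 >= y1 or x0 >= x1:
                continue
            ys, xs = np.mgrid[y0:y1, x0:x1].astype(float)
            u = np.cos(ang) * (xs - cxb) + np.sin(ang) * (ys - cyb)
            v = -np.sin(ang) * (xs - cxb) + np.cos(ang) * (ys - cyb)
            rho = np.sqrt((u / sa) ** 2 + (v / sb) ** 2)
            alpha = _smoothstep((1.0 - rho) * (sb / edge) + 0.5)
            img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - alpha) + spec.blob_intensity * alpha
        if spec.flicker_amplitude:
            img = img + spec.flicker_amplitude * np.sin(
                2 * np.pi * spec.flicker_freq_hz * t[k]
            )
        if spec.noise_sd:
            img = img + rng.normal(0, spec.noise_sd, img.shape)
        frames[k] = np.clip(np.round(img), 0, 255)
    return frames


def render_well_sequence(spec: SceneSpec) -> FrameStack:
    """Render one synthetic well video; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    frames = _render_frames(spec, rng)
    return FrameStack(
        frames=frames,
        frame_rate=spec.frame_rate,
        source_id=f"synthetic-well-a{spec.amplitude:g}-s{spec.seed}",
    )


def render_plate_video(
    specs: dict[str, SceneSpec],
    layout: PlateLayout,
    plate_background: float = 20.0,
    plate_flicker_amplitude: float = 0.0,
    flicker_freq_hz: float = 2.0,
) -> FrameStack:
    """Compose per-well renders into one multi-well video.

    ``specs`` maps well ids of ``layout`` to scene specs whose well size
    matches that well's box.  Without plate-wide flicker, cropping the
    result with :func:`wiggleindex.io.crop_wells` recovers each individual
    render pixel-for-pixel.  ``plate_flicker_amplitude`` adds a global
    per-frame offset across the whole plate after composition (then
    re-rounds), emulating illumination flicker shared by all wells.
    """
    boxes = {w.well_id: w for w in layout.wells}
    missing = set(boxes) ^ set(specs)
    if missing:
        raise DataError(f"layout wells and specs disagree on: {sorted(missing)}")
    for i, w1 in enumerate(layout.wells):
        for w2 in layout.wells[i + 1 :]:
            if (
                w1.row_start < w2.row_stop
                and w2.row_start < w1.row_stop
                and w1.col_start < w2.col_stop
                and w2.col_start < w1.col_stop
            ):
                raise DataError(f"overlapping well boxes {w1.well_id}, {w2.well_id}")
    n_frames = {s.n_frames for s in specs.values()}
    rates = {s.frame_rate for s in specs.values()}
    if len(n_frames) != 1 or len(rates) != 1:
        raise DataError("all wells must share n_frames and frame_rate")
    H = max(w.row_stop for w in layout.wells)
    W = max(w.col_stop for w in layout.wells)
    (nf,), (rate,) = n_frames, rates
    frames = np.full((nf, H, W), float(plate_background))
    for wid, spec in specs.items():
        box = boxes[wid]
        if box.shape != (spec.well_size, spec.well_size):
            raise DataError(
                f"well {wid}: box shape {box.shape} != scene size {spec.well_size}"
            )
        frames[:, box.row_start : box.row_stop, box.col_start : box.col_stop] = (
            render_well_sequence(spec).frames
        )
    if plate_flicker_amplitude:
        t = np.arange(nf) / rate
        offs = plate_flicker_amplitude * np.sin(2 * np.pi * flicker_freq_hz * t)
        frames = np.clip(np.round(frames + offs[:, None, None]), 0, 255)
    return FrameStack(frames=frames, frame_rate=rate, source_id="synthetic-plate")


# ---------------------------------------------------------------------------
# WI time-course simulation


@dataclass(frozen=True)
class DecaySpec:
    """An ensemble of per-well WI time courses for one treatment group.

    Profiles mirror the two response classes seen in insecticide assays:

    ``fast``
        Motility collapses shortly after dosing (default onset 5 min) to a
        plateau whose depth tracks the dose — set ``plateau_frac`` per dose.
    ``slow``
        Motility holds at baseline until a delayed onset (default 45 min),
        then declines to a dose-independent plateau.
    ``none``
        Untreated control; constant at baseline apart from noise.

    ``noise_sd_frac`` is the SD of additive Gaussian noise as a fraction of
    the baseline WI, applied to every sampled point (including t = 0) and
    truncated at 0 so WI stays non-negative.
    """

    group: str = "control"
    profile: str = "none"  # fast | slow | none
    baseline_wi: float = 10.0
    onset_min: float | None = None
    plateau_frac: float | None = None
    tau_min: float | None = None
    noise_sd_frac: float = 0.05
    n_wells: int = 10
    time_grid: tuple[float, ...] = TIME_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("fast", "slow", "none"):
            raise DataError(f"unknown profile {self.profile!r}")
        if self.baseline_wi <= 0:
            raise DataError("baseline_wi must be > 0")
        if self.plateau_frac is not None and not (0 <= self.plateau_frac <= 1):
            raise DataError("plateau_frac must lie in [0, 1]")

    def _resolved(self) -> tuple[float, float, float]:
        if self.profile == "fast":
            onset = 5.0 if self.onset_min is None else self.onset_min
            plateau = 0.3 if self.plateau_frac is None else self.plateau_frac
            tau = 5.0 if self.tau_min is None else self.tau_min
        else:  # slow
            onset = 45.0 if self.onset_min is None else self.onset_min
            plateau = 0.4 if self.plateau_frac is None else self.plateau_frac
            tau = 30.0 if self.tau_min is None else self.tau_min
        return onset, plateau, tau


def _mean_curve(spec: DecaySpec, times: np.ndarray) -> np.ndarray:
    if spec.profile == "none":
        return np.full_like(times, spec.baseline_wi)
    onset, plateau_frac, tau = spec._resolved()
    base, plat = spec.baseline_wi, spec.baseline_wi * plateau_frac
    vals = np.full_like(times, base)
    post = times >= onset
    # half the drop lands instantly at onset, the rest decays exponentially,
    # so detection at the onset sample itself is possible in the noiseless case
    vals[post] = plat + (base - plat) * 0.5 * np.exp(-(times[post] - onset) / tau)
    return vals


def simulate_timecourse(spec: DecaySpec):
    """Draw ``n_wells`` per-well WI time courses on the spec's time grid.

    Returns a list of :class:`wiggleindex.stats.TimeCourse`.  Deterministic
    per seed; distinct seeds give independent noise.
    """
    from .stats import TimeCourse

    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.time_grid, dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] != 0:
        raise DataError("time grid must start at 0 and strictly increase")
    mean = _mean_curve(spec, times)
    sd = spec.noise_sd_frac * spec.baseline_wi
    out = []
    for w in range(spec.n_wells):
        wi = mean + (rng.normal(0, sd, times.size) if sd > 0 else 0.0)
        wi = np.clip(wi, 0.0, None)
        out.append(
            TimeCourse(
                well_id=f"{spec.group}-w{w + 1}",
                group=spec.group,
                times=times.copy(),
                wi_values=wi,
            )
        )
    return out
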