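"""Synthetic data generators for the myosin-head tracking analysis.

The generative model mirrors the statistical structure the downstream
inference assumes: a tethered-diffusion *detached* state emitting Gaussian
positions (SD 12.5 nm), transient *weak-binding* sites emitting tighter
Gaussians (SD 4.7 nm) with exponential dwells of a few hundred
microseconds, and an optional ATP-gated *strong-binding* site whose dwell
is the ATP waiting time, ``1 / (rate_slope * [ATP] + rate_intercept)``.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import FluorescenceTrace, ImageStack, Trajectory


@dataclass
class WeakSite:
    """A transient actin-binding position.

    position is relative to the detached mean (nm); access_weight is the
    probability that an encounter lands on this site; mean_dwell is the
    mean of the exponential dwell distribution (us).
    """

    position: float
    access_weight: float
    mean_dwell: float

    def __post_init__(self) -> None:
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be positive")
        if not 0.0 <= self.access_weight <= 1.0:
            raise ValueError("access_weight must lie in [0, 1]")


@dataclass
class KineticScheme:
    """Generative model for a single myosin head in the origami filament.

    Parameters
    ----------
    detached_mean, detached_sd : float
        Mean and SD (nm) of the Gaussian emission of the detached
        (tethered-diffusion) state.  SD default 12.5 nm.
    bound_sd : float
        Shared emission SD of every binding state (nm), default 4.7.
    sites : list of WeakSite
        Transient binding sites; access weights must sum to 1 when
        non-empty.
    strong_site_index : int, optional
        Index into ``sites`` of the strong-binding site.  Dwells at that
        site are exponential with mean ``1 / (rate_slope * atp_conc +
        rate_intercept)`` seconds (the ATP waiting time) instead of the
        site's ``mean_dwell``.
    atp_conc : float
        ATP concentration in nM.
    rate_slope, rate_intercept : float
        The ATP-binding rate line, s^-1 nM^-1 and s^-1.
    encounter_rate : float
        Rate (s^-1) at which the detached head encounters actin and enters
        a weak-binding site; per-frame entry probability is
        ``1 - exp(-encounter_rate * dt)``.  Not constrained by the imaging
        data, so exposed as a free parameter.
    substeps : list of (displacement nm, mean latency us), optional
        Lever-arm sub-step phases appended after strong binding; default
        off (the camera data do not resolve the second step).
    frame_interval : float
        Camera frame spacing, us (default 40, i.e. 25,000 fps).
    duration : float
        Record length in us; the default 400,000 us (10,000 frames)
        matches the analysis window.
    lateral_sd : float, optional
        When set, a second (lateral) Gaussian coordinate is emitted to
        exercise axis projection.
    """

    detached_mean: float = 0.0
    detached_sd: float = 12.5
    bound_sd: float = 4.7
    sites: List[WeakSite] = field(default_factory=list)
    strong_site_index: Optional[int] = None
    atp_conc: float = 2000.0
    rate_slope: float = 0.0038
    rate_intercept: float = 0.17
    encounter_rate: float = 1000.0
    substeps: Optional[List[Tuple[float, float]]] = None
    frame_interval: float = 40.0
    duration: float = 400_000.0
    lateral_sd: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.detached_sd <= 0 or self.bound_sd <= 0:
            raise ValueError("emission SDs must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.encounter_rate < 0:
            raise ValueError("encounter_rate must be non-negative")
        sites = [
            s if isinstance(s, WeakSite) else WeakSite(**s) for s in self.sites
        ]
        self.sites = sites
        if sites:
            w = sum(s.access_weight for s in sites)
            if not np.isclose(w, 1.0, atol=1e-6):
                raise ValueError("site access weights must sum to 1")
        if self.strong_site_index is not None:
            if not 0 <= self.strong_site_index < len(self.sites):
                raise ValueError("strong_site_index out of range")
            if self.strong_binding_rate() <= 0:
                raise ValueError("strong-binding rate must be positive")

    def strong_binding_rate(self) -> float:
        """ATP-binding rate (s^-1) predicted by the rate line."""
        return self.rate_slope * self.atp_conc + self.rate_intercept

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @classmethod
    def from_config(cls, path: str | Path) -> "KineticScheme":
        """Load a scheme from a JSON or YAML file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "substeps" in data and data["substeps"] is not None:
            data["substeps"] = [tuple(s) for s in data["substeps"]]
        return cls(**data)


def simulate_trajectory(scheme: KineticScheme, seed: Optional[int] = None) -> Trajectory:
    """Simulate a 1D head trajectory under an alternating-renewal scheme.

    From the detached state the head enters weak binding at site ``k``
    with per-frame probability ``(1 - exp(-encounter_rate * dt)) *
    access_weight[k]``.  Dwells are drawn in continuous time from the
    site's exponential distribution and discretised by rounding to whole
    frames with a minimum of one frame (the observability floor).
    Emissions are independent per-frame Gaussians.

    Returns a :class:`Trajectory` with ground-truth ``labels`` (0 =
    detached, k+1 = site k) and, in ``meta``, the continuous dwell draws
    per site (``true_dwells_us``) for oracle use.
    """
    if seed is None:
        seed = scheme.seed
    rng = np.random.default_rng(seed)
    n = scheme.n_frames
    if n < 1:
        raise ValueError("duration must cover at least one frame")
    dt = scheme.frame_interval
    labels = np.zeros(n, dtype=int)
    n_sites = len(scheme.sites)
    true_dwells: dict = {k: [] for k in range(n_sites)}

    if n_sites:
        p_enter = 1.0 - np.exp(-scheme.encounter_rate * dt * 1e-6)
        weights = np.array([s.access_weight for s in scheme.sites])
        strong = scheme.strong_site_index
        strong_mean_us = (
            1e6 / scheme.strong_binding_rate() if strong is not None else None
        )
        i = 0
        while i < n:
            if rng.random() >= p_enter:
                i += 1  # stays detached this frame
                continue
            k = int(rng.choice(n_sites, p=weights))
            mean = strong_mean_us if k == strong else scheme.sites[k].mean_dwell
            dwell = rng.exponential(mean)
            true_dwells[k].append(dwell)
            n_dwell = max(1, int(round(dwell / dt)))
            labels[i : i + n_dwell] = k + 1
            i += n_dwell

    means = np.array(
        [scheme.detached_mean]
        + [scheme.detached_mean + s.position for s in scheme.sites]
    )
    sds = np.array([scheme.detached_sd] + [scheme.bound_sd] * n_sites)
    positions = means[labels] + sds[labels] * rng.standard_normal(n)
    lateral = None
    if scheme.lateral_sd is not None:
        lateral = scheme.lateral_sd * rng.standard_normal(n)

    times = np.arange(n) * dt
    meta = {
        "true_dwells_us": {k: np.asarray(v) for k, v in true_dwells.items()},
        "scheme_seed": seed,
    }
    return Trajectory(times, positions, dt, labels=labels, lateral=lateral, meta=meta)


def simulate_spot_stack(
    center_track: np.ndarray,
    pixel_size: float,
    psf_sigma: float,
    photon_rate: float,
    background: float,
    seed: Optional[int] = None,
    shape: Tuple[int, int] = (32, 32),
    frame_interval: float = 40.0,
    poisson_noise: bool = True,
) -> ImageStack:
    """Render a diffraction-limited spot as a stack of camera frames.

    ``center_track`` is ``(n, 2)`` spot centres in nm in the lab frame
    (x, y); they are mapped to pixels as ``px = nm / pixel_size`` with
    pixel centres at integer coordinates, shifted so the track mean sits
    at the field centre.  Each frame is a Poisson realisation of an
    isotropic Gaussian PSF with total intensity ``photon_rate``
    counts/frame plus a uniform ``background`` counts/pixel.

    Raises if any centre leaves the field of view.
    """
    if pixel_size <= 0 or psf_sigma <= 0:
        raise ValueError("pixel_size and psf_sigma must be positive")
    if photon_rate < 0 or background < 0:
        raise ValueError("photon_rate and background must be non-negative")
    centers_nm = np.atleast_2d(np.asarray(center_track, dtype=float))
    ny, nx = shape
    centers_px = centers_nm / pixel_size
    # integer-pixel shift so sub-pixel structure of the track is preserved
    offset = np.round(np.array([(nx - 1) / 2.0, (ny - 1) / 2.0]) - centers_px.mean(axis=0))
    centers_px = centers_px + offset
    if (
        centers_px[:, 0].min() < 1
        or centers_px[:, 0].max() > nx - 2
        or centers_px[:, 1].min() < 1
        or centers_px[:, 1].max() > ny - 2
    ):
        raise ValueError("track leaves the field of view")

    rng = np.random.default_rng(seed)
    xs = np.arange(nx)
    ys = np.arange(ny)
    sig_px = psf_sigma / pixel_size
    frames = np.empty((len(centers_px), ny, nx))
    for i, (cx, cy) in enumerate(centers_px):
        gx = np.exp(-0.5 * ((xs - cx) / sig_px) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sig_px) ** 2)
        psf = np.outer(gy, gx)
        psf /= 2.0 * np.pi * sig_px**2  # unit-integral PSF sampled at pixel centres
        expected = photon_rate * psf + background
        frames[i] = rng.poisson(expected) if poisson_noise else expected
    return ImageStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        true_centers=centers_px,
    )


def simulate_atp_trace(
    event_rate: float,
    on_mean: float,
    frame_rate: float = 1000.0,
    duration: float = 100.0,
    spike_amplitude: float = 50.0,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
    baseline: float = 0.0,
) -> FluorescenceTrace:
    """Simulate a fluorescent-ATP intensity time course.

    Spikes mark ATP binding events: dark gaps between a spike's end and
    the next spike's start are exponential with mean ``1 / event_rate``
    seconds and on-times are exponential with mean ``on_mean`` seconds.
    Ground-truth event (start, duration) pairs are attached to the trace;
    when ``on_mean`` is not small relative to the mean gap, an
    overlap-risk warning flag is set.
    """
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    if event_rate < 0 or on_mean < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    events = []
    if event_rate > 0:
        t = rng.exponential(1.0 / event_rate)
        while t < duration:
            on = rng.exponential(on_mean) if on_mean > 0 else 0.0
            events.append((t, on))
            t += on + rng.exponential(1.0 / event_rate)
    n = int(round(duration * frame_rate))
    times = (np.arange(n) + 0.5) / frame_rate
    intensity = np.full(n, baseline, dtype=float)
    for start, on in events:
        i0 = int(np.ceil((start - 0.5 / frame_rate) * frame_rate))
        i1 = int(np.ceil((start + on - 0.5 / frame_rate) * frame_rate))
        intensity[max(i0, 0) : max(i1, i0 + 1)] += spike_amplitude
    if noise_sd > 0:
        intensity += noise_sd * rng.standard_normal(n)
    overlap = event_rate > 0 and on_mean >= 1.0 / event_rate
    return FluorescenceTrace(
        times=times,
        intensity=intensity,
        frame_rate=frame_rate,
        true_events=np.asarray(events, dtype=float).reshape(-1, 2),
        overlap_warning=bool(overlap),
    )


def five_site_scheme(
    positions: Sequence[float] = (-26.0, -12.9, -1.1, 9.9, 22.8),
    weights: Sequence[float] = (0.014, 0.184, 0.493, 0.245, 0.064),
    dwells: Sequence[float] = (322.0, 237.0, 160.0, 238.0, 513.0),
    **kwargs,
) -> KineticScheme:
    """Convenience scheme with the five weak-binding sites of the
    lever-arm-less S1 analysis (positions nm, access weights, dwells us)."""
    sites = [
        WeakSite(position=p, access_weight=w, mean_dwell=d)
        for p, w, d in zip(positions, weights, dwells)
    ]
    return KineticScheme(sites=sites, **kwargs)
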