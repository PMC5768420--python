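"""Synthetic data generators for every pipeline input.

Emulates (i) angular phalloidin-intensity profiles and rendered cell images
with prescribed arc structure — several narrow peripheral arcs for a
segmented lamellipodium (SL), one broad arc for a broad lamellipodium (BL) —
on a sampling circle of radius 8 µm; (ii) FM4-64 accumulation traces
following a single-exponential rise sampled every 2 min for 40 min; and
(iii) image-level populations bridging the switch model's per-cell phenotype
calls to profiles the LO pipeline can classify.  Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .endo_kinetics import UptakeTrace
from .morphometrics import AngularProfile
from .switch_model import CellRecord

__all__ = [
    "CellSpec",
    "ImagedCell",
    "gen_profile",
    "render_image",
    "gen_uptake_trace",
    "population_from_ensemble",
    "sample_spec_for_phenotype",
]

TWO_PI = 2.0 * math.pi

#: SL arcs each span less than 1/3 of the periphery; BL a single broad arc.
SL_SPAN_RANGE = (0.05 * TWO_PI, 0.30 * TWO_PI)
BL_SPAN_RANGE = (0.35 * TWO_PI, 0.80 * TWO_PI)


@dataclass(frozen=True)
class CellSpec:
    """Generative description of one synthetic phalloidin-stained cell."""

    phenotype: str                     # "SL" | "BL"
    spans: tuple                       # radians per arc
    starts: tuple = ()                 # radians; filled by the generator if empty
    arc_intensity: float = 3.0         # a.u., in background units
    background: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    radius_um: float = 8.0

    def __post_init__(self):
        if self.phenotype not in ("SL", "BL"):
            raise ValueError("phenotype must be 'SL' or 'BL'")
        if self.phenotype == "SL":
            if not (1 <= len(self.spans) <= 5):
                raise ValueError("an SL cell carries 1-5 narrow arcs")
            if any(s >= TWO_PI / 3 for s in self.spans):
                raise ValueError("SL arc spans must each be < 2*pi/3")
        else:
            if len(self.spans) != 1:
                raise ValueError("a BL cell carries exactly one broad arc")
            if not (TWO_PI / 3 < self.spans[0] <= 0.85 * TWO_PI):
                raise ValueError("BL span must lie in (2*pi/3, 0.85*2*pi]")
        if self.arc_intensity <= self.background:
            raise ValueError("arc_intensity must exceed background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ImagedCell:
    """A model cell joined with its rendered profile (generative truth kept)."""

    record: CellRecord
    spec: CellSpec
    profile: AngularProfile


def _place_arcs(spans, n, rng):
    """Random non-overlapping arc placement with >= 1 sample gap.

    Stick-breaking: the slack left after all spans and minimum gaps is split
    among the gaps by a Dirichlet draw, the arc order is shuffled, and the
    whole arrangement gets a uniform random rotation.  Feasible whenever the
    spans plus minimum gaps fit the circle.
    """
    min_gap = TWO_PI / n
    spans = list(spans)
    slack = TWO_PI - sum(spans) - len(spans) * min_gap
    if slack <= 0:
        raise ValueError("total arc span too large for non-overlapping placement "
                         f"(total span {sum(spans):.2f} rad over {len(spans)} arcs)")
    extra = slack * rng.dirichlet(np.ones(len(spans)))
    order = rng.permutation(len(spans))
    placed, pos = [], float(rng.uniform(0.0, TWO_PI))
    for i in range(len(spans)):
        w = spans[order[i]]
        placed.append((pos % TWO_PI, w))
        pos += w + min_gap + extra[i]
    return placed


def gen_profile(spec: CellSpec, n: int = 360) -> tuple[AngularProfile, CellSpec]:
    """Render a spec to an angular profile (background + arcs + noise).

    Returns the profile together with the spec completed with the arc start
    angles actually used, so the generative truth is fully recorded.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.starts and len(spec.starts) == len(spec.spans):
        placed = list(zip(spec.starts, spec.spans))
    else:
        placed = _place_arcs(spec.spans, n, rng)
    theta = TWO_PI * np.arange(n) / n
    intensities = np.full(n, spec.background, float)
    for start, span in placed:
        rel = (theta - start) % TWO_PI
        intensities[rel < span] = spec.arc_intensity
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=n)
    intensities = np.maximum(intensities, 0.0)
    full_spec = CellSpec(
        phenotype=spec.phenotype, spans=tuple(w for _, w in placed),
        starts=tuple(s for s, _ in placed), arc_intensity=spec.arc_intensity,
        background=spec.background, noise_sd=spec.noise_sd, seed=spec.seed,
        radius_um=spec.radius_um)
    return AngularProfile(radius_um=spec.radius_um, intensities=intensities), full_spec


def render_image(spec: CellSpec, image_size: int = 256,
                 pixel_size_um: float = 0.1,
                 arc_width_um: float = 1.2,
                 soma_radius_um: float = 5.0) -> np.ndarray:
    """Rasterize a cell: dim soma disk plus bright annular arcs, anti-aliased.

    The arcs sit on the 8 µm sampling circle so that ``oval_profile`` of the
    rendered image reproduces the generating angular structure.  Returns a
    float image in arbitrary units (background = spec.background).
    """
    r_px = spec.radius_um / pixel_size_um
    c = (image_size - 1) / 2.0
    margin = r_px + arc_width_um / pixel_size_um
    if margin > c:
        raise ValueError(f"canvas {image_size} px too small for the 8 µm circle")
    rng = np.random.default_rng(spec.seed)
    if spec.starts and len(spec.starts) == len(spec.spans):
        placed = list(zip(spec.starts, spec.spans))
    else:
        placed = _place_arcs(spec.spans, 360, rng)

    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    dx = xx - c
    dy = c - yy                      # y-flip: math frame, ccw from +x
    rr = np.hypot(dx, dy)
    ang = np.arctan2(dy, dx) % TWO_PI

    img = np.full((image_size, image_size), spec.background, float)
    soma_px = soma_radius_um / pixel_size_um
    img += 0.3 * (spec.arc_intensity - spec.background) * _soft_mask(soma_px - rr)
    half_w = 0.5 * arc_width_um / pixel_size_um
    radial = _soft_mask(half_w - np.abs(rr - r_px))
    for start, span in placed:
        rel = (ang - start) % TWO_PI
        ang_mask = _soft_mask((span - rel) * rr) * _soft_mask(rel * rr + 0.5)
        img += (spec.arc_intensity - spec.background) * radial * ang_mask
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.maximum(img, 0.0)


def _soft_mask(signed_dist):
    """1 inside, 0 outside, linear ramp over one pixel (anti-aliasing)."""
    return np.clip(signed_dist + 0.5, 0.0, 1.0)


def gen_uptake_trace(F_max: float, t_half: float, noise_sd: float = 0.0,
                     seed: int | None = None, t_end: float = 40.0,
                     dt: float = 2.0, condition_label: str = "") -> UptakeTrace:
    """Sample ``F_max (1 - 2^(-t/t_half))`` every ``dt`` min up to ``t_end``.

    With noise, Gaussian deviations are added to every sample except t = 0,
    which stays exactly 0 (traces are normalized to the t = 0 value).
    """
    if not (F_max > 0 and t_half > 0):
        raise ValueError("F_max and t_half must be > 0")
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = F_max * (1.0 - np.power(2.0, -t / t_half))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
        y[0] = 0.0
    return UptakeTrace(times=t, intensities=y, condition_label=condition_label)


def sample_spec_for_phenotype(phenotype: str, seed: int,
                              arc_intensity: float = 3.0, background: float = 1.0,
                              noise_sd: float = 0.0) -> CellSpec:
    """Draw a random CellSpec consistent with a phenotype class.

    SL: 2-5 arcs with spans i.i.d. uniform in (0.05, 0.30) of the periphery,
    redrawn until a non-overlapping placement is feasible; BL: a single arc
    uniform in (0.35, 0.80) of the periphery.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    if phenotype == "SL":
        for _ in range(200):
            n_arcs = int(rng.integers(2, 6))
            spans = tuple(rng.uniform(*SL_SPAN_RANGE, size=n_arcs))
            if sum(spans) < 0.9 * TWO_PI:
                break
        else:
            raise RuntimeError("failed to draw a feasible SL spec")
    elif phenotype == "BL":
        spans = (float(rng.uniform(*BL_SPAN_RANGE)),)
    else:
        raise ValueError("phenotype must be 'SL' or 'BL'")
    return CellSpec(phenotype=phenotype, spans=spans,
                    arc_intensity=arc_intensity, background=background,
                    noise_sd=noise_sd, seed=seed)


def population_from_ensemble(cells, noise_sd: float = 0.1,
                             arc_intensity: float = 3.0, background: float = 1.0,
                             seed: int = 0, n_angles: int = 360) -> list[ImagedCell]:
    """Give every model cell a rendered angular profile matching its phenotype.

    ``noise_sd`` is expressed as a fraction of ``arc_intensity``.  Each cell's
    profile seed derives from ``(seed, cell_id)``, so records are reproducible
    one by one regardless of population size.
    """
    out = []
    for rec in cells:
        cell_seed = int(np.random.SeedSequence(seed, spawn_key=(rec.cell_id, 1)).generate_state(1)[0] % (2**31))
        spec = sample_spec_for_phenotype(
            rec.phenotype, cell_seed, arc_intensity=arc_intensity,
            background=background, noise_sd=noise_sd * arc_intensity)
        profile, full_spec = gen_profile(spec, n=n_angles)
        out.append(ImagedCell(record=rec, spec=full_spec, profile=profile))
    return out


def provenance(seed: int, config: dict | None = None) -> dict:
    """Provenance stamp written next to generated data sets."""
    import hashlib

    from . import __version__

    blob = json.dumps(config, sort_keys=True).encode() if config else b""
    return {"seed": seed, "version": __version__,
            "config_sha256": hashlib.sha256(blob).hexdigest()}
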