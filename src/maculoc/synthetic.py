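"""Ground-truthed synthetic fundus image generator.

Renders the anatomy the detection pipeline relies on, with exact ground
truth by construction:

* a circular field of view (FOV) on a dark surround;
* a bright optic disc with soft radial falloff, its true diameter
  defaulting to 0.126 × FOV width;
* a dark macula whose center sits exactly 2.5 true disc diameters from the
  disc center on the temporal side, slightly inferior;
* vessels converging on the disc, bundled on the nasal side: a near-
  vertical trunk through the disc plus two parabolic arcades arching
  temporal-ward well clear of the macula;
* gentle vignetting and a fine choroidal texture (always on — real retinas
  are never flat fields);
* optional illumination gradient, sensor noise and bright exudate-like
  lesions for degraded acquisition conditions.

All randomness (texture, noise, suite variation) is driven by the spec
seed; the same spec renders bit-identical images.  Right-lateral images
are rendered as the exact mirror of the equivalent left-lateral spec, so
laterality symmetry holds to the pixel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from .errors import InvalidSpecError

log = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_fundus", "generate_suite"]

#: true disc diameter as a fraction of FOV width
DISC_FRACTION = 0.126
#: radial macula offset from the disc center, in true disc diameters
MACULA_OFFSET_DD = 2.5
#: vertical (inferior) component of that offset, in true disc diameters
MACULA_DROP_DD = 0.165


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one rendered fundus; every default is the nominal
    study condition, not a free dial."""

    width: int = 768
    height: int = 584
    laterality: str = "left"            # side of the disc the macula is on
    fov_center: tuple[float, float] | None = None   # default: image center
    fov_radius: float | None = None     # default: 0.48 × height
    od_center: tuple[float, float] | None = None    # default: macula at FOV center
    od_brightness: float = 110.0        # additive peak over the retinal base
    disc_diameter: float | None = None  # D_true; default DISC_FRACTION × FOV width
    macula_offset_dd: float = MACULA_OFFSET_DD
    macula_drop_dd: float = MACULA_DROP_DD
    macula_depth: float = 45.0          # subtractive darkness of the foveal pit
    macula_radius: float | None = None  # Gaussian pit scale; default 0.35 × D_true
    vessel_width: float | None = None   # default: 0.05 × D_true
    vessel_contrast: float = 40.0       # green-channel darkening of vessels
    #: darkening of the small perifoveal branches bounding the macula; a bit
    #: deeper than the fovea itself, as vessels usually are
    perifoveal_contrast: float = 48.0
    vignette: float = 0.06              # radial shading amplitude (fraction)
    texture_sigma: float = 4.0          # fine choroidal texture, gray levels
    gradient: float = 0.0               # left-right illumination ramp, ± levels
    noise_sigma: float = 0.0            # additive Gaussian sensor noise
    n_lesions: int = 0                  # bright exudate-like blobs
    lesion_radius_d: float = 0.2        # lesion radius in units of D_true
    seed: int = 0

    def resolved(self) -> "SyntheticSpec":
        """Fill in every derived default."""
        fc = self.fov_center or (self.width / 2.0, self.height / 2.0)
        R = self.fov_radius if self.fov_radius is not None else 0.48 * self.height
        D = (self.disc_diameter if self.disc_diameter is not None
             else DISC_FRACTION * 2.0 * R)
        drop = self.macula_drop_dd * D
        dx = float(np.sqrt((self.macula_offset_dd * D) ** 2 - drop ** 2))
        if self.od_center is None:
            s = 1.0 if self.laterality == "left" else -1.0
            od = (fc[0] + s * dx, fc[1] - drop)
        else:
            od = self.od_center
        mrad = (self.macula_radius if self.macula_radius is not None
                else 0.35 * D)
        vw = self.vessel_width if self.vessel_width is not None else 0.05 * D
        return dataclasses.replace(
            self, fov_center=fc, fov_radius=R, od_center=od,
            disc_diameter=D, macula_radius=mrad, vessel_width=vw)

    def macula_center(self) -> tuple[float, float]:
        spec = self.resolved()
        D = spec.disc_diameter
        drop = spec.macula_drop_dd * D
        dx = float(np.sqrt((spec.macula_offset_dd * D) ** 2 - drop ** 2))
        s = -1.0 if spec.laterality == "left" else 1.0
        return (spec.od_center[0] + s * dx, spec.od_center[1] + drop)


@dataclass(frozen=True)
class SyntheticTruth:
    macula: tuple[float, float]
    od: tuple[float, float]
    D_true: float
    laterality: str
    background_mask: np.ndarray   # plain retina: FOV minus disc/macula/vessels
    vessel_mask: np.ndarray


_BASE = np.array([150.0, 78.0, 30.0])          # retinal base RGB
_OD_GAIN = np.array([1.0, 1.0, 0.5])
_MACULA_GAIN = np.array([1.0, 1.0, 0.4])
_VESSEL_DROP = np.array([12.0, 1.0, 8.0])      # green scaled by vessel_contrast
_TEXTURE_GAIN = np.array([1.0, 1.0, 0.5])


def _stamp_curve(mask: np.ndarray, xs, ys, radius: float) -> None:
    h, w = mask.shape
    for x, y in zip(xs, ys):
        rr, cc = draw.disk((y, x), max(1.0, radius), shape=(h, w))
        mask[rr, cc] = True


def _render_left(spec: SyntheticSpec, rng: np.random.Generator):
    """Render a left-lateral (macula left of disc) image."""
    h, w = spec.height, spec.width
    fcx, fcy = spec.fov_center
    R = spec.fov_radius
    D = spec.disc_diameter
    odx, ody = spec.od_center
    mx, my = spec.macula_center()

    yy, xx = np.mgrid[0:h, 0:w]
    rho_f = np.hypot(xx - fcx, yy - fcy)
    fov = rho_f <= R
    if np.hypot(mx - fcx, my - fcy) + spec.macula_radius > R:
        raise InvalidSpecError("macula (with its extent) falls outside the FOV")
    if np.hypot(odx - fcx, ody - fcy) + D / 2 > R:
        raise InvalidSpecError("optic disc falls outside the FOV")

    canvas = np.full((h, w, 3), 8.0)
    canvas[fov] = _BASE

    shade = 1.0 - spec.vignette * (rho_f / R) ** 2
    canvas[fov] *= shade[fov, None]

    # macular luteal pigment masks the choroidal texture, so the fine grain
    # fades toward the fovea
    rho_m = np.hypot(xx - mx, yy - my)
    macula_profile = np.exp(-((rho_m / spec.macula_radius) ** 2))
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
    texture *= spec.texture_sigma / max(texture.std(), 1e-9)
    texture *= 1.0 - 0.9 * np.exp(-((rho_m / (1.6 * spec.macula_radius)) ** 2))
    canvas[fov] += texture[fov, None] * _TEXTURE_GAIN

    rho_od = np.hypot(xx - odx, yy - ody)
    canvas += (spec.od_brightness * np.exp(-(rho_od / (0.5 * D)) ** 4))[..., None] \
        * _OD_GAIN * fov[..., None]

    canvas -= (spec.macula_depth * macula_profile)[..., None] \
        * _MACULA_GAIN * fov[..., None]

    # vessels: nasal trunk through the disc + two arcades arching temporal-ward
    vessels = np.zeros((h, w), dtype=bool)
    t = np.linspace(0.0, 1.0, 400)
    s_n = 1.0  # nasal side is +x for a left-lateral image
    trunk_x = odx + s_n * (0.22 * D + 0.08 * D * np.sin(2 * np.pi * t))
    trunk_y = ody + (2 * t - 1) * 1.8 * D
    _stamp_curve(vessels, trunk_x, trunk_y, spec.vessel_width / 2)
    for sign in (-1.0, 1.0):
        ax = odx + s_n * 0.22 * D - s_n * 2.4 * D * t ** 2
        ay = ody + sign * 1.8 * D * (1.0 - 0.35 * t)
        _stamp_curve(vessels, ax, ay, 0.8 * spec.vessel_width / 2)
    vessels &= fov
    canvas -= vessels[..., None] * _VESSEL_DROP * np.array(
        [1.0, spec.vessel_contrast, 1.0])

    # small perifoveal branches bounding the foveal avascular zone on the
    # temporal, nasal and inferior sides, just outside one disc-diameter
    # unit (FOV width / 12) from the fovea — slightly darker than the pit,
    # as retinal vessels usually are
    dd_unit = 2.0 * R / 12.0
    peri = np.zeros((h, w), dtype=bool)
    seg = np.linspace(-0.8 * dd_unit, 0.8 * dd_unit, 200)
    for sx in (-1.0, 1.0):
        _stamp_curve(peri, np.full_like(seg, mx + sx * 1.15 * dd_unit),
                     my + seg, 0.03 * D)
    _stamp_curve(peri, mx + seg, np.full_like(seg, my + 1.15 * dd_unit), 0.03 * D)
    peri &= fov
    canvas -= peri[..., None] * spec.perifoveal_contrast * np.array([1.0, 1.0, 0.3])
    vessels = vessels | peri

    lesion_zone = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_lesions):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.2, 0.8) * R
        lx, ly = fcx + rad * np.cos(ang), fcy + rad * np.sin(ang)
        rho_l = np.hypot(xx - lx, yy - ly)
        profile = np.exp(-(rho_l / (spec.lesion_radius_d * D)) ** 4)
        canvas += profile[..., None] * np.array([95.0, 90.0, 30.0]) * fov[..., None]
        lesion_zone |= (profile > 0.05) & fov

    if spec.gradient:
        ramp = spec.gradient * (xx - fcx) / R
        canvas += ramp[..., None] * fov[..., None]
    if spec.noise_sigma:
        canvas += rng.normal(0.0, spec.noise_sigma, (h, w))[..., None] * fov[..., None]

    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    vessels_wide = ndi.binary_dilation(vessels, iterations=2)
    background = (fov & (rho_od > 0.8 * D) & (rho_m > 1.4 * spec.macula_radius)
                  & ~vessels_wide & ~lesion_zone)

    # nasal-vs-temporal vessel asymmetry inside the disc, by construction
    in_disc = rho_od <= 0.5 * D
    nasal = int((vessels & in_disc & (xx > odx)).sum())
    temporal_px = int((vessels & in_disc & (xx < odx)).sum())
    if nasal <= temporal_px:
        raise InvalidSpecError("vessel asymmetry inside the disc not achieved")

    truth = SyntheticTruth(macula=(mx, my), od=(odx, ody), D_true=D,
                           laterality=spec.laterality,
                           background_mask=background, vessel_mask=vessels)
    return image, truth


def generate_fundus(spec: SyntheticSpec):
    """Render one synthetic fundus; returns ``(image, SyntheticTruth)``.

    Deterministic given the spec (including its seed).  A right-lateral
    image is the exact horizontal mirror of the equivalent left-lateral
    render.
    """
    spec = spec.resolved()
    if spec.laterality not in ("left", "right"):
        raise InvalidSpecError(f"laterality must be left/right, got {spec.laterality!r}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.laterality == "left":
        return _render_left(spec, rng)

    # mirror the spec into left orientation, render, then flip back
    w = spec.width
    mirrored = dataclasses.replace(
        spec, laterality="left",
        fov_center=(w - 1 - spec.fov_center[0], spec.fov_center[1]),
        od_center=(w - 1 - spec.od_center[0], spec.od_center[1]),
    )
    image, truth = _render_left(mirrored, rng)
    flip = lambda xy: (w - 1 - xy[0], xy[1])
    return image[:, ::-1].copy(), SyntheticTruth(
        macula=flip(truth.macula), od=flip(truth.od), D_true=truth.D_true,
        laterality="right",
        background_mask=truth.background_mask[:, ::-1].copy(),
        vessel_mask=truth.vessel_mask[:, ::-1].copy(),
    )


_DIFFICULTY = {
    "clean":   dict(gradient=0.0, noise_sigma=0.0, n_lesions=0),
    "nominal": dict(gradient=12.0, noise_sigma=5.0, n_lesions=0),
    "hard":    dict(gradient=34.0, noise_sigma=10.0, n_lesions=3,
                    macula_depth=14.0, od_brightness=45.0),
}


def generate_suite(n: int, difficulty: str = "nominal", seed: int = 0,
                   out_dir: str | Path | None = None):
    """Generate ``n`` varied images with ground truth.

    Laterality alternates; image size, disc placement and (for noisy
    difficulties) degradations vary per image, each driven by an RNG
    stream derived from ``(seed, index)`` so suites are reproducible and
    extensible.  With ``out_dir`` set, writes ``img_###.png``, a
    ``gt.csv`` in the evaluation dialect and a ``spec.json`` per image.

    Returns a list of ``(spec, image, truth)`` triples.
    """
    if n < 1:
        raise InvalidSpecError("suite size must be >= 1")
    if difficulty not in _DIFFICULTY:
        raise InvalidSpecError(f"unknown difficulty {difficulty!r}")
    preset = _DIFFICULTY[difficulty]

    out = []
    rows = []
    for i in range(n):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        img_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        h = int(rng.integers(560, 641))
        w = int(round(1.31 * h))
        R = 0.48 * h
        fc = (w / 2.0, h / 2.0)
        laterality = "left" if i % 2 == 0 else "right"
        D = DISC_FRACTION * 2.0 * R
        drop = MACULA_DROP_DD * D
        dx = float(np.sqrt((MACULA_OFFSET_DD * D) ** 2 - drop ** 2))
        s = 1.0 if laterality == "left" else -1.0
        jx, jy = rng.uniform(-0.05, 0.05, 2) * R
        od = (fc[0] + s * dx + jx, fc[1] - drop + jy)
        params = dict(preset)
        if difficulty == "hard":
            # tiered severity: every third image has a washed-out disc dimmer
            # than the lesions, which defeats brightness-based disc
            # localization; the rest are merely degraded
            if i % 3 == 2:
                params["od_brightness"] = 20.0
            else:
                params["od_brightness"] = float(rng.uniform(35.0, 60.0))
            params["gradient"] = float(rng.uniform(28.0, 42.0))
        spec = SyntheticSpec(width=w, height=h, laterality=laterality,
                             fov_radius=R, od_center=od, seed=img_seed,
                             **params)
        image, truth = generate_fundus(spec)
        out.append((spec, image, truth))
        name = f"img_{i:03d}.png"
        rows.append(dict(file=name, x=truth.macula[0], y=truth.macula[1],
                         od_x=truth.od[0], od_y=truth.od[1]))

    if out_dir is not None:
        import imageio.v3 as iio
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for i, (spec, image, _) in enumerate(out):
            iio.imwrite(out_path / f"img_{i:03d}.png", image)
            meta = dataclasses.asdict(spec)
            with open(out_path / f"img_{i:03d}.spec.json", "w") as fh:
                json.dump(meta, fh, indent=2, default=float)
        pd.DataFrame(rows).to_csv(out_path / "gt.csv", index=False)
    return out
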