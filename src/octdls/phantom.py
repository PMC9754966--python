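"""Synthetic OCT phantom: layered retina volumes with DLS and drusen lesions.

The generator emulates the structural cues that distinguish nonexudative
macular neovascularization (neMNV) from ordinary drusen on swept-source OCT:

* a hyperreflective retinal pigment epithelium (RPE) band resting on Bruch's
  membrane;
* **drusen** — dome-shaped sub-RPE deposits wider than 63 um, elevating the
  RPE *without* separating it from Bruch's membrane;
* the **double-layer sign (DLS)** — a shallow, irregular, broad elevation of
  the RPE off Bruch's membrane with a visible hyporeflective separation,
  the structural correlate of type 1 neMNV;
* optional **geographic atrophy (GA)** — loss of the RPE band with
  choroidal hypertransmission beneath it;
* multiplicative gamma speckle followed by a light axial blur.

Every eye carries pixel-exact ground-truth label masks (0 background, 1 DLS,
2 drusen) and a binary eye-level neMNV label, so the full segmentation +
en-face classification pipeline can be exercised and scored without any
clinical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, gaussian_filter1d

__all__ = [
    "DrusenParams",
    "DLSParams",
    "GAParams",
    "PhantomConfig",
    "BScanVolume",
    "LabelMaskVolume",
    "EyeGeometry",
    "EyeRecord",
    "generate_eye",
    "generate_cohort",
    "write_volume",
    "read_volume",
]

BACKGROUND, DLS, DRUSEN = 0, 1, 2

# Stage mix of the reference 100-eye test cohort: 20/33 positives and 44/67
# negatives had intermediate AMD, the remainder late AMD with GA.
DEFAULT_STAGE_MIX = (20 / 33, 44 / 67)


@dataclass(frozen=True)
class DrusenParams:
    """Dome-shaped sub-RPE deposits; only drusen wider than 63 um count."""

    count_range: tuple[int, int] = (3, 7)
    diameter_um_range: tuple[float, float] = (250.0, 800.0)
    height_um_range: tuple[float, float] = (70.0, 130.0)
    dome_profile: float = 0.5  # exponent of (1 - r^2); 0.5 = hemispheric shoulders

    def validate(self) -> None:
        if self.diameter_um_range[0] <= 63.0:
            raise ValueError("drusen diameters must exceed 63 um")
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError("invalid drusen count range")
        if self.dome_profile <= 0:
            raise ValueError("dome_profile must be positive")


@dataclass(frozen=True)
class DLSParams:
    """Shallow irregular broad RPE elevation with RPE-Bruch separation."""

    footprint_um_range: tuple[float, float] = (1200.0, 2500.0)
    height_um_range: tuple[float, float] = (40.0, 100.0)
    irregularity_amplitude: float = 0.35
    interior_reflectivity: float = 0.12

    def validate(self, drusen: DrusenParams) -> None:
        if self.footprint_um_range[0] <= 0:
            raise ValueError("DLS footprint must be positive")
        if not 0.0 <= self.interior_reflectivity <= 1.0:
            raise ValueError("interior_reflectivity must lie in [0, 1]")
        # Shallowness: the steepest allowed DLS must still be flatter than the
        # flattest allowed druse, or the two lesion morphologies blur together.
        dls_aspect = self.height_um_range[1] / self.footprint_um_range[0]
        drusen_aspect = drusen.height_um_range[0] / drusen.diameter_um_range[1]
        if not dls_aspect < drusen_aspect:
            raise ValueError(
                "DLS height/footprint aspect must be smaller than drusen's "
                f"({dls_aspect:.3f} >= {drusen_aspect:.3f})"
            )


@dataclass(frozen=True)
class GAParams:
    """Geographic atrophy: RPE loss with choroidal hypertransmission."""

    present: bool = False
    extent_um_range: tuple[float, float] = (500.0, 1600.0)
    hypertransmission_gain: float = 1.9

    def validate(self) -> None:
        if self.hypertransmission_gain < 1.0:
            raise ValueError("hypertransmission_gain must be >= 1")


@dataclass(frozen=True)
class PhantomConfig:
    """Scan geometry, optical appearance and lesion statistics of one phantom eye.

    Defaults follow a 6 x 6-mm swept-source scan pattern: 500 B-scans of
    500 A-scans x 1536 axial pixels, 12 um between A-scans and between
    B-scan positions.  The axial pitch is taken as 1.95 um/px (a 3-mm
    window over 1536 px), a stated modelling assumption rather than a
    device fact.  `desk()` gives a proportionally reduced geometry that is
    tractable on a single CPU.
    """

    n_ascans: int = 500
    n_bscans: int = 500
    depth_px: int = 1536
    lateral_um_per_px: float = 12.0
    bscan_um_per_px: float = 12.0
    axial_um_per_px: float = 1.95
    rpe_depth_px: int | None = None  # None -> 55% of depth
    # mean gray level of each modeled band, in [0, 1]
    layer_reflectivities: dict[str, float] = field(
        default_factory=lambda: {
            "vitreous": 0.04,
            "retina": 0.35,
            "rpe": 0.92,
            "bruch": 0.55,
            "choroid": 0.22,
        }
    )
    drusen_interior_reflectivity: float = 0.50
    speckle_shape: float = 8.0  # gamma shape of multiplicative speckle; 0 = off
    drusen: DrusenParams = field(default_factory=DrusenParams)
    dls: DLSParams = field(default_factory=DLSParams)
    ga: GAParams = field(default_factory=GAParams)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ascans", "n_bscans", "depth_px"):
            if getattr(self, name) < 32:
                raise ValueError(f"{name} must be >= 32")
        for name in ("lateral_um_per_px", "bscan_um_per_px", "axial_um_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        refl = self.layer_reflectivities
        for k, v in refl.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"layer reflectivity {k}={v} outside [0, 1]")
        if not (refl["rpe"] > refl["retina"] and refl["rpe"] > refl["choroid"]):
            raise ValueError("RPE must be the brightest band (retina centering relies on it)")
        self.drusen.validate()
        self.dls.validate(self.drusen)
        self.ga.validate()

    # -- geometry helpers ---------------------------------------------------
    @property
    def width_um(self) -> float:
        return self.n_ascans * self.lateral_um_per_px

    @property
    def rpe_depth(self) -> int:
        return self.rpe_depth_px if self.rpe_depth_px is not None else int(0.55 * self.depth_px)

    @classmethod
    def full(cls, seed: int = 0, **kw) -> "PhantomConfig":
        """Native acquisition geometry (memory-hungry; ~1.5 GB per eye)."""
        return cls(seed=seed, **kw)

    @classmethod
    def desk(cls, seed: int = 0, easy: bool = False, **kw) -> "PhantomConfig":
        """Reduced geometry (64 B-scans x 256 depth x 128 A-scans) over the
        same 6 x 6-mm footprint, for CPU-scale experiments.

        The axial pitch is 2.5 um/px (a ~0.64-mm window around the outer
        retina) rather than a proportional squeeze of the full 3-mm window:
        this keeps lesion thickness, measured in pixels relative to the
        segmenter's patch size, in the same regime the full-scale recipe
        operates in.  ``easy=True`` switches speckle off for a high-contrast
        benchmark on which segmentation performance reflects the model, not
        the noise.
        """
        kw.setdefault("n_ascans", 128)
        kw.setdefault("n_bscans", 64)
        kw.setdefault("depth_px", 256)
        kw.setdefault("lateral_um_per_px", 6000.0 / 128)
        kw.setdefault("bscan_um_per_px", 6000.0 / 64)
        kw.setdefault("axial_um_per_px", 2.5)
        kw.setdefault("rpe_depth_px", 158)
        if easy:
            # high-contrast, speckle-free benchmark: widen the reflectivity
            # separation between every pair of adjacent structures
            kw.setdefault("speckle_shape", 0.0)
            kw.setdefault(
                "layer_reflectivities",
                {"vitreous": 0.02, "retina": 0.40, "rpe": 1.0, "bruch": 0.62, "choroid": 0.16},
            )
            kw.setdefault("drusen_interior_reflectivity", 0.62)
            kw.setdefault("dls", DLSParams(interior_reflectivity=0.06))
        return cls(seed=seed, **kw)


@dataclass
class BScanVolume:
    """One eye's B-scan stack: voxels[b-scan, depth, a-scan] in [0, 1]."""

    voxels: np.ndarray
    lateral_um_per_px: float
    axial_um_per_px: float
    bscan_um_per_px: float
    eye_id: str = "eye"

    def __post_init__(self):
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (b-scan, depth, a-scan)")
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("voxel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMaskVolume:
    """Per-voxel class labels aligned to a BScanVolume: 0 bg, 1 DLS, 2 drusen."""

    labels: np.ndarray

    def __post_init__(self):
        if not np.isin(self.labels, (BACKGROUND, DLS, DRUSEN)).all():
            raise ValueError("mask labels must be in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class EyeGeometry:
    """Continuous surfaces used to render an eye (for auditing label soundness)."""

    bruch_px: np.ndarray        # (n_bscans, n_ascans) Bruch's membrane depth
    rpe_top_px: np.ndarray      # (n_bscans, n_ascans) top of the RPE band
    rpe_thickness_px: int
    druse_elevation_px: np.ndarray
    dls_separation_px: np.ndarray
    ga_region: np.ndarray       # boolean en-face footprint of atrophy


@dataclass
class EyeRecord:
    volume: BScanVolume
    masks: LabelMaskVolume
    mnv_label: bool
    amd_stage: str
    seed: int
    geometry: EyeGeometry | None = None

    def __post_init__(self):
        if self.volume.shape != self.masks.shape:
            raise ValueError("volume and masks must share a shape")
        has_dls = bool((self.masks.labels == DLS).any())
        if self.mnv_label != has_dls:
            raise ValueError("mnv_label must equal presence of DLS voxels")


# ---------------------------------------------------------------------------
# lesion field construction
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    s = f.std()
    return f / s if s > 0 else f


def _ellipse_r2(nb: int, na: int, b0: float, a0: float, rb: float, ra: float) -> np.ndarray:
    bb = (np.arange(nb)[:, None] - b0) / rb
    aa = (np.arange(na)[None, :] - a0) / ra
    return bb**2 + aa**2


def _place_center(
    rng: np.random.Generator,
    nb: int,
    na: int,
    rb: float,
    ra: float,
    occupied: np.ndarray,
    tries: int = 60,
) -> tuple[float, float] | None:
    """Random lesion centre whose elliptical footprint avoids `occupied`."""
    for _ in range(tries):
        b0 = rng.uniform(rb, nb - 1 - rb) if nb - 1 > 2 * rb else (nb - 1) / 2
        a0 = rng.uniform(ra, na - 1 - ra) if na - 1 > 2 * ra else (na - 1) / 2
        foot = _ellipse_r2(nb, na, b0, a0, rb + 1, ra + 1) <= 1.0
        if not (foot & occupied).any():
            occupied |= foot
            return b0, a0
    return None


def _build_lesion_fields(
    config: PhantomConfig,
    mnv_positive: bool,
    n_dls: int,
    ga_present: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (druse elevation, DLS separation, GA footprint) en-face fields in px."""
    nb, na = config.n_bscans, config.n_ascans
    lat, bsp, ax = config.lateral_um_per_px, config.bscan_um_per_px, config.axial_um_per_px
    druse = np.zeros((nb, na))
    sep = np.zeros((nb, na))
    occupied = np.zeros((nb, na), dtype=bool)

    ga_region = np.zeros((nb, na), dtype=bool)
    if ga_present:
        ext = rng.uniform(*config.ga.extent_um_range)
        if ext > config.width_um:
            raise ValueError(f"GA extent {ext:.0f} um exceeds scan width {config.width_um:.0f} um")
        rb, ra = ext / 2 / bsp, ext / 2 / lat
        c = _place_center(rng, nb, na, rb, ra, occupied)
        if c is not None:
            ga_region = _ellipse_r2(nb, na, *c, rb, ra) <= 1.0

    for _ in range(n_dls):
        foot = rng.uniform(*config.dls.footprint_um_range)
        if foot > config.width_um:
            raise ValueError(
                f"DLS footprint {foot:.0f} um exceeds scan width {config.width_um:.0f} um"
            )
        height = rng.uniform(*config.dls.height_um_range) / ax
        height = max(height, 2.0)  # guarantee at least one interior voxel row
        ra = foot / 2 / lat
        rb = foot / 2 / bsp * rng.uniform(0.7, 1.0)
        c = _place_center(rng, nb, na, rb, ra, occupied)
        if c is None:
            continue
        r2 = _ellipse_r2(nb, na, *c, rb, ra)
        base = np.clip(1.0 - r2, 0.0, None) ** 0.5
        rough = 1.0 + config.dls.irregularity_amplitude * _smooth_field(
            rng, (nb, na), sigma=max(2.0, ra / 6)
        )
        sep += height * base * np.clip(rough, 0.25, 1.75)

    n_drusen = int(rng.integers(config.drusen.count_range[0], config.drusen.count_range[1] + 1))
    for _ in range(n_drusen):
        diam = rng.uniform(*config.drusen.diameter_um_range)
        if diam > config.width_um:
            raise ValueError(
                f"druse diameter {diam:.0f} um exceeds scan width {config.width_um:.0f} um"
            )
        height = rng.uniform(*config.drusen.height_um_range) / ax
        height = max(height, 2.0)
        ra = diam / 2 / lat
        rb = diam / 2 / bsp
        c = _place_center(rng, nb, na, rb, ra, occupied)
        if c is None:
            continue
        r2 = _ellipse_r2(nb, na, *c, rb, ra)
        druse += height * np.clip(1.0 - r2, 0.0, None) ** config.drusen.dome_profile

    if mnv_positive and not (sep >= 1.0).any():
        raise RuntimeError("failed to place a DLS lesion in an MNV-positive eye")
    return druse, sep, ga_region


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_eye(
    config: PhantomConfig,
    druse: np.ndarray,
    sep: np.ndarray,
    ga_region: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, EyeGeometry]:
    nb, na, depth = config.n_bscans, config.n_ascans, config.depth_px
    ax = config.axial_um_per_px
    refl = config.layer_reflectivities

    t_rpe = max(2, round(20.0 / ax))
    t_bruch = max(1, round(10.0 / ax))
    # nominal 300-um retina, compressed if the axial window cannot hold it
    t_retina = max(8, min(round(300.0 / ax), round(0.35 * depth)))

    # Bruch's membrane: gently curved surface with mild smooth undulation.
    amp = 0.012 * depth
    bb = np.arange(nb)[:, None] / max(nb - 1, 1)
    aa = np.arange(na)[None, :] / max(na - 1, 1)
    bruch = (
        config.rpe_depth
        + amp * np.sin(2 * np.pi * (0.7 * aa + 0.4 * bb))
        + 0.5 * amp * _smooth_field(rng, (nb, na), sigma=max(4.0, na / 16))
    )
    rpe_top = bruch - t_rpe - druse - sep

    z = np.arange(depth, dtype=np.float64)[:, None]  # (depth, 1) broadcast vs (na,)
    voxels = np.empty((nb, depth, na), dtype=np.float32)
    labels = np.zeros((nb, depth, na), dtype=np.uint8)
    decay = np.exp(-np.arange(depth) * ax / 350.0)  # choroidal attenuation, ~350 um

    for b in range(nb):
        B, R = bruch[b], rpe_top[b]
        ilm = R - t_retina
        img = np.full((depth, na), refl["vitreous"])
        img[(z >= ilm) & (z < R)] = refl["retina"]
        rpe_level = np.where(ga_region[b], refl["retina"], refl["rpe"])
        rpe_zone = (z >= R) & (z < R + t_rpe)
        img = np.where(rpe_zone, rpe_level[None, :], img)
        interior = (z >= R + t_rpe) & (z < B)
        druse_zone = interior & (druse[b] > 0)[None, :]
        dls_zone = interior & (sep[b] > 0)[None, :]
        img[druse_zone] = config.drusen_interior_reflectivity
        img[dls_zone] = config.dls.interior_reflectivity
        img[(z >= B) & (z < B + t_bruch)] = refl["bruch"]
        chor = (z >= B + t_bruch)
        gain = np.where(ga_region[b], config.ga.hypertransmission_gain, 1.0)
        depth_below = np.clip(z - B - t_bruch, 0, None).astype(int)
        chor_img = refl["choroid"] * gain[None, :] * decay[np.minimum(depth_below, depth - 1)]
        img = np.where(chor, chor_img, img)

        labels[b][dls_zone] = DLS
        labels[b][druse_zone] = DRUSEN

        if config.speckle_shape > 0:
            k = config.speckle_shape
            img = img * rng.gamma(k, 1.0 / k, size=img.shape)
            img = gaussian_filter1d(img, sigma=0.8, axis=0)
        voxels[b] = np.clip(img, 0.0, 1.0)

    geometry = EyeGeometry(
        bruch_px=bruch,
        rpe_top_px=rpe_top,
        rpe_thickness_px=t_rpe,
        druse_elevation_px=druse,
        dls_separation_px=sep,
        ga_region=ga_region,
    )
    return voxels, labels, geometry


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_eye(
    config: PhantomConfig,
    mnv_positive: bool,
    amd_stage: str = "intermediate",
    n_dls: int | None = None,
    eye_id: str | None = None,
) -> EyeRecord:
    """Generate one phantom eye, deterministic in (config.seed, mnv_positive, amd_stage).

    MNV-positive eyes receive one or two DLS lesions (plus drusen); negative
    eyes receive drusen only.  ``amd_stage='late'`` adds a geographic-atrophy
    region regardless of ``config.ga.present``.
    """
    if amd_stage not in ("intermediate", "late"):
        raise ValueError(f"unknown amd_stage {amd_stage!r}")
    if n_dls is not None and n_dls > 0 and not mnv_positive:
        raise ValueError("DLS lesions requested for an MNV-negative eye")
    stage_code = 0 if amd_stage == "intermediate" else 1
    rng = np.random.default_rng(
        np.random.SeedSequence((int(config.seed), int(mnv_positive), stage_code))
    )
    if n_dls is None:
        n_dls = int(rng.integers(1, 3)) if mnv_positive else 0
    ga_present = config.ga.present or amd_stage == "late"

    druse, sep, ga_region = _build_lesion_fields(config, mnv_positive, n_dls, ga_present, rng)
    voxels, labels, geometry = _render_eye(config, druse, sep, ga_region, rng)

    if eye_id is None:
        eye_id = f"phantom-s{config.seed}-{'pos' if mnv_positive else 'neg'}-{amd_stage}"
    volume = BScanVolume(
        voxels,
        lateral_um_per_px=config.lateral_um_per_px,
        axial_um_per_px=config.axial_um_per_px,
        bscan_um_per_px=config.bscan_um_per_px,
        eye_id=eye_id,
    )
    return EyeRecord(
        volume=volume,
        masks=LabelMaskVolume(labels),
        mnv_label=bool((labels == DLS).any()),
        amd_stage=amd_stage,
        seed=config.seed,
        geometry=geometry,
    )


def generate_cohort(
    n_mnv: int,
    n_control: int,
    stage_mix: tuple[float, float] = DEFAULT_STAGE_MIX,
    config: PhantomConfig | None = None,
) -> list[EyeRecord]:
    """Generate a cohort of `n_mnv` positive and `n_control` negative eyes.

    `stage_mix` gives the intermediate-AMD fraction among positives and
    negatives (the default mirrors the reference test cohort: 20/33 and
    44/67).  Each eye gets an independent seed derived from `config.seed`.
    """
    if n_mnv < 0 or n_control < 0:
        raise ValueError("cohort counts must be nonnegative")
    if config is None:
        config = PhantomConfig()
    eyes: list[EyeRecord] = []
    idx = 0
    for positive, n, frac_int in (
        (True, n_mnv, stage_mix[0]),
        (False, n_control, stage_mix[1]),
    ):
        n_int = round(n * frac_int)
        for j in range(n):
            stage = "intermediate" if j < n_int else "late"
            eye_seed = int(
                np.random.SeedSequence((int(config.seed), idx)).generate_state(1)[0] % 2**31
            )
            cfg = replace(config, seed=eye_seed)
            eyes.append(
                generate_eye(
                    cfg,
                    mnv_positive=positive,
                    amd_stage=stage,
                    eye_id=f"cohort{config.seed}-{idx:03d}-{'pos' if positive else 'neg'}",
                )
            )
            idx += 1
    return eyes


_PALETTE = [0, 0, 0, 60, 120, 255, 255, 210, 40]  # bg black, DLS blue, drusen yellow


def write_volume(record: EyeRecord, directory: str | Path, bit_depth: int = 16) -> dict:
    """Write an eye to `directory`: multi-page TIFF voxels, per-slice paletted
    PNG masks (palette index = class id) and a JSON sidecar manifest.

    Returns the manifest.  Reading the directory back with `read_volume`
    reproduces the voxel grid to stored precision and the masks exactly.
    """
    import tifffile

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        scale = 2**bit_depth - 1
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        quant = np.round(record.volume.voxels * scale).astype(dtype)
        tiff_path = directory / "volume.tif"
        tifffile.imwrite(tiff_path, quant)

        mask_dir = directory / "masks"
        mask_dir.mkdir(exist_ok=True)
        mask_files = []
        for b in range(record.masks.shape[0]):
            im = Image.fromarray(record.masks.labels[b], mode="P")
            im.putpalette(_PALETTE)
            name = f"mask_{b:04d}.png"
            im.save(mask_dir / name)
            mask_files.append(f"masks/{name}")

        manifest = {
            "eye_id": record.volume.eye_id,
            "shape": list(record.volume.shape),
            "calibration": {
                "lateral_um_per_px": record.volume.lateral_um_per_px,
                "axial_um_per_px": record.volume.axial_um_per_px,
                "bscan_um_per_px": record.volume.bscan_um_per_px,
            },
            "mnv_label": record.mnv_label,
            "amd_stage": record.amd_stage,
            "seed": record.seed,
            "bit_depth": bit_depth,
            "volume_file": "volume.tif",
            "mask_files": mask_files,
            "n_pages": record.volume.shape[0],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing eye to {directory}: {exc}") from exc
    return manifest


def read_volume(directory: str | Path) -> EyeRecord:
    """Read an eye previously written by `write_volume`."""
    import tifffile

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    quant = tifffile.imread(directory / manifest["volume_file"])
    scale = 2 ** manifest["bit_depth"] - 1
    voxels = (quant.astype(np.float32) / scale).astype(np.float32)
    labels = np.stack(
        [np.asarray(Image.open(directory / f), dtype=np.uint8) for f in manifest["mask_files"]]
    )
    cal = manifest["calibration"]
    volume = BScanVolume(
        voxels,
        lateral_um_per_px=cal["lateral_um_per_px"],
        axial_um_per_px=cal["axial_um_per_px"],
        bscan_um_per_px=cal["bscan_um_per_px"],
        eye_id=manifest["eye_id"],
    )
    return EyeRecord(
        volume=volume,
        masks=LabelMaskVolume(labels),
        mnv_label=manifest["mnv_label"],
        amd_stage=manifest["amd_stage"],
        seed=manifest["seed"],
    )
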