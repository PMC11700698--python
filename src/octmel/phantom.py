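"""Synthetic longitudinal OCT phantoms of mouse-ear skin.

Generates 3-D OCT intensity volumes (stacks of B-scans) for "induced" subjects,
in which a melanoma-like lesion appears at a configurable onset week and grows
laterally week by week, and for "control" subjects, which never develop a
lesion.  Every volume carries voxel-level ground truth (lesion mask, per-slice
lesion flags, the true surface) so that downstream estimators can be validated
against known answers.

The image model is deliberately first-order:

* depth attenuation follows the single-scattering Beer-Lambert law
  ``I(z) = I0 * exp(-2 * mu * z)`` below the skin surface, with ``mu`` the
  tissue attenuation coefficient in 1/mm (the factor 2 accounts for the round
  trip of the probe beam);
* fully developed speckle is multiplicative, unit-mean exponential;
* the lesion is a growing elliptical footprint in the (lateral, slice) plane
  that raises backscatter (``hyperreflective_gain``), changes attenuation
  (``mu_lesion``), elevates the surface, and adds band-limited "disarray"
  texture.

All randomness flows from one master seed through a hierarchical
``numpy.random.SeedSequence`` split (cohort -> subject -> volume -> slice), so
identical (spec, seed) inputs reproduce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

GROUP_INDUCED = "induced"
GROUP_CONTROL = "control"

#: columns of the sidecar table written next to phantom TIFF stacks
SIDECAR_COLUMNS = [
    "subject_id",
    "group",
    "week",
    "path",
    "axial_um_per_px",
    "lateral_um_per_px",
    "slice_um",
    "n_slices",
    "intensity_scale",
    "mask_path",
]


class InvalidSpecError(ValueError):
    """Raised when a PhantomSpec violates its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk volume does not match its sidecar metadata."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one subject's longitudinal volumes.

    Defaults reproduce the nominal full-scale geometry (1024 axial px, 813
    lateral px, 400 slices over a 4 x 4 x 2 mm^3 field).  Tests and desk-scale
    experiments use :meth:`reduced`.
    """

    depth_px: int = 1024
    lateral_px: int = 813
    n_slices: int = 400
    axial_um_per_px: float = 2000.0 / 1024.0
    lateral_um_per_px: float = 4000.0 / 813.0
    slice_um: float = 4000.0 / 400.0
    #: amplitude (px) of the smooth random surface height profile
    surface_profile: float = 6.0
    #: mean axial position of the surface, as a fraction of depth_px
    surface_depth_frac: float = 0.125
    epidermis_thickness_um: float = 50.0
    #: attenuation coefficient of healthy dermis, 1/mm
    mu_normal: float = 2.0
    #: attenuation coefficient inside the lesion, 1/mm
    mu_lesion: float = 3.0
    #: axial extent of the lesion below the surface, um
    lesion_depth_um: float = 300.0
    #: week at which the lesion first appears; None for control subjects
    lesion_onset_week: int | None = None
    #: lateral radius increase per week, px/week
    lesion_growth_rate: float = 76.0
    #: slice-direction radius increase per week, slices/week
    lesion_growth_rate_slices: float = 100.0
    #: nucleation radius at the onset week (px lateral, slices)
    lesion_seed_radius_px: float = 19.0
    lesion_seed_radius_slices: float = 25.0
    #: multiplicative backscatter factor inside the lesion (>= 1)
    hyperreflective_gain: float = 1.8
    #: amplitude of band-limited texture modulation inside the lesion
    disarray_strength: float = 0.3
    #: surface elevation inside the lesion footprint, px/week after onset
    lesion_elevation_px_per_week: float = 1.5
    #: 'exponential' for fully developed speckle, 'none' to disable
    speckle_model: str = "exponential"
    #: additive background level above the surface
    noise_floor: float = 0.01
    #: peak backscatter at the surface (arbitrary intensity units)
    i0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_px < 64 or self.lateral_px < 64:
            raise InvalidSpecError("depth_px and lateral_px must be >= 64")
        if self.n_slices < 1:
            raise InvalidSpecError("n_slices must be >= 1")
        if self.mu_normal <= 0:
            raise InvalidSpecError("mu_normal must be > 0")
        if self.lesion_onset_week is not None and self.hyperreflective_gain < 1:
            raise InvalidSpecError("hyperreflective_gain must be >= 1 for lesions")
        if self.speckle_model not in ("exponential", "none"):
            raise InvalidSpecError(f"unknown speckle_model {self.speckle_model!r}")

    @property
    def is_induced(self) -> bool:
        return self.lesion_onset_week is not None

    def lesion_radii(self, week: int) -> tuple[float, float]:
        """(lateral px, slice) radii of the lesion footprint at ``week``.

        The lesion nucleates with a small seed radius at the onset week (so a
        lesion is present from the onset on) and grows linearly thereafter.
        """
        if self.lesion_onset_week is None or week < self.lesion_onset_week:
            return 0.0, 0.0
        dw = float(week - self.lesion_onset_week)
        return (self.lesion_seed_radius_px + self.lesion_growth_rate * dw,
                self.lesion_seed_radius_slices + self.lesion_growth_rate_slices * dw)

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def reduced(cls, **kw) -> "PhantomSpec":
        """Desk-scale geometry: 256 x 256 x 16 over the same physical field."""
        base = dict(
            depth_px=256,
            lateral_px=256,
            n_slices=16,
            axial_um_per_px=2000.0 / 256.0,
            lateral_um_per_px=4000.0 / 256.0,
            slice_um=4000.0 / 16.0,
            surface_profile=3.0,
            lesion_growth_rate=24.0,
            lesion_growth_rate_slices=4.0,
            lesion_seed_radius_px=6.0,
            lesion_seed_radius_slices=1.0,
        )
        base.update(kw)
        return cls(**base)


class BScan(NamedTuple):
    """One generated cross-section with its ground truth."""

    image: np.ndarray  # (depth, lateral) float32, >= 0
    lesion_mask: np.ndarray  # (depth, lateral) bool
    surface: np.ndarray  # (lateral,) int, true surface row per A-line


@dataclass
class OCTVolume:
    """A 3-D stack of B-scans with subject/group/week metadata.

    ``voxels`` is indexed (depth, lateral, slice).
    """

    voxels: np.ndarray
    subject_id: str
    group: str
    week: int
    spacing: tuple[float, float, float]  # (axial um, lateral um, slice um)
    lesion_mask: np.ndarray | None = None
    surface: np.ndarray | None = None  # (lateral, slice) true surface rows

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (depth, lateral, slice)")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be finite and >= 0")
        if self.group not in (GROUP_INDUCED, GROUP_CONTROL):
            raise ValueError(f"unknown group {self.group!r}")
        if self.week < 0:
            raise ValueError("week must be >= 0")
        if self.lesion_mask is not None and self.lesion_mask.shape != self.voxels.shape:
            raise ValueError("lesion_mask shape must match voxels")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    def bscan(self, slice_index: int) -> np.ndarray:
        return self.voxels[:, :, slice_index]

    def slice_lesion_flags(self) -> np.ndarray:
        """Per-slice boolean: True iff the mask has >= 1 voxel in that slice."""
        if self.lesion_mask is None:
            return np.zeros(self.n_slices, dtype=bool)
        return self.lesion_mask.any(axis=(0, 1))


@dataclass
class Cohort:
    """Volumes spanning subjects x weeks plus the design table."""

    volumes: list[OCTVolume]
    design: pd.DataFrame  # columns subject_id, group, week

    def __post_init__(self) -> None:
        pairs = list(zip(self.design["subject_id"], self.design["week"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (subject_id, week) pairs in design")

    def get(self, subject_id: str, week: int) -> OCTVolume:
        for v in self.volumes:
            if v.subject_id == subject_id and v.week == week:
                return v
        raise KeyError((subject_id, week))

    @property
    def subjects(self) -> pd.DataFrame:
        return self.design[["subject_id", "group"]].drop_duplicates().reset_index(drop=True)


# ----------------------------------------------------------------------------
# B-scan synthesis
# ----------------------------------------------------------------------------

def _smooth_profile(rng: np.random.Generator, n: int, amplitude: float,
                    n_harmonics: int = 4) -> np.ndarray:
    """Smooth zero-mean random curve of length n built from low harmonics."""
    x = np.linspace(0.0, 2.0 * np.pi, n)
    out = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        a, b = rng.normal(size=2)
        out += (a * np.cos(k * x) + b * np.sin(k * x)) / k
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= amplitude / peak
    return out


def _lesion_halfwidth(spec: PhantomSpec, week: int, slice_index: int) -> float:
    """Lateral half-width (px) of the lesion footprint in this slice."""
    r_lat, r_sli = spec.lesion_radii(week)
    if r_lat <= 0:
        return 0.0
    ds = slice_index - (spec.n_slices - 1) / 2.0
    if r_sli <= 0:
        frac = 1.0 if abs(ds) < 0.5 else -1.0
    else:
        frac = 1.0 - (ds / r_sli) ** 2
    if frac <= 0:
        return 0.0
    return r_lat * np.sqrt(frac)


def generate_bscan(spec: PhantomSpec, week: int, slice_index: int,
                   rng: np.random.Generator) -> BScan:
    """Synthesize one cross-sectional image plus its ground truth.

    The image is built as: a smooth random surface boundary; zero-mean noise
    plus ``noise_floor`` above the surface; Beer-Lambert decay
    ``I0*exp(-2*mu*z)`` below it with lesion parameters inside the lesion
    footprint; multiplicative speckle last.
    """
    if slice_index < 0 or slice_index >= spec.n_slices:
        raise InvalidSpecError(
            f"slice_index {slice_index} out of range [0, {spec.n_slices})")
    depth, lateral = spec.depth_px, spec.lateral_px
    axial_mm = spec.axial_um_per_px / 1000.0

    base_row = spec.surface_depth_frac * depth
    surface = base_row + _smooth_profile(rng, lateral, spec.surface_profile)

    # lesion footprint in this slice, centred laterally
    halfwidth = _lesion_halfwidth(spec, week, slice_index)
    cols = np.arange(lateral)
    in_footprint = np.abs(cols - (lateral - 1) / 2.0) <= halfwidth
    if in_footprint.any() and spec.lesion_onset_week is not None:
        dw = week - spec.lesion_onset_week
        elev = spec.lesion_elevation_px_per_week * dw
        # smooth elevation ramp across the footprint edge
        dist = np.abs(cols - (lateral - 1) / 2.0)
        ramp = np.clip((halfwidth - dist) / max(halfwidth, 1.0), 0.0, 1.0)
        surface = surface - elev * ramp
    surface_rows = np.clip(np.round(surface).astype(int), 0, depth - 1)

    rows = np.arange(depth)[:, None]
    below = rows >= surface_rows[None, :]
    z_mm = (rows - surface_rows[None, :]) * axial_mm  # depth below surface

    lesion_depth_px = spec.lesion_depth_um / spec.axial_um_per_px
    mask = below & in_footprint[None, :] & (rows - surface_rows[None, :] < lesion_depth_px)

    mu = np.where(mask, spec.mu_lesion, spec.mu_normal)
    gain = np.where(mask, spec.hyperreflective_gain, 1.0)
    signal = spec.i0 * gain * np.exp(-2.0 * mu * np.clip(z_mm, 0.0, None))

    if mask.any() and spec.disarray_strength > 0:
        texture = rng.standard_normal((depth, lateral))
        texture = ndimage.gaussian_filter(texture, sigma=3.0)
        sd = texture.std()
        if sd > 0:
            texture /= sd
        signal = np.where(mask, signal * np.clip(1.0 + spec.disarray_strength * texture, 0.1, None), signal)
    elif spec.disarray_strength > 0:
        # keep the random stream position independent of lesion presence
        rng.standard_normal((depth, lateral))

    if spec.speckle_model == "exponential":
        signal = signal * rng.exponential(1.0, size=(depth, lateral))
    background = np.clip(
        spec.noise_floor + rng.normal(0.0, spec.noise_floor / 3.0, size=(depth, lateral)),
        0.0, None)
    image = np.where(below, signal, background).astype(np.float32)
    return BScan(image=image, lesion_mask=mask, surface=surface_rows)


def generate_volume(spec: PhantomSpec, subject_id: str, week: int,
                    seed_seq: np.random.SeedSequence) -> OCTVolume:
    """Generate one volume; each slice draws from its own child stream."""
    slice_seqs = seed_seq.spawn(spec.n_slices)
    voxels = np.empty((spec.depth_px, spec.lateral_px, spec.n_slices), dtype=np.float32)
    mask = np.zeros_like(voxels, dtype=bool)
    surf = np.empty((spec.lateral_px, spec.n_slices), dtype=int)
    for s in range(spec.n_slices):
        b = generate_bscan(spec, week, s, np.random.default_rng(slice_seqs[s]))
        voxels[:, :, s] = b.image
        mask[:, :, s] = b.lesion_mask
        surf[:, s] = b.surface
    group = GROUP_INDUCED if spec.is_induced else GROUP_CONTROL
    return OCTVolume(
        voxels=voxels, subject_id=subject_id, group=group, week=week,
        spacing=(spec.axial_um_per_px, spec.lateral_um_per_px, spec.slice_um),
        lesion_mask=mask, surface=surf)


def _jitter(rng: np.random.Generator, amount: float) -> float:
    return 1.0 + rng.uniform(-amount, amount)


def generate_cohort(induced_spec: PhantomSpec, control_spec: PhantomSpec,
                    n_induced: int, n_control: int, weeks: Sequence[int],
                    master_seed: int, subject_jitter: float = 0.1) -> Cohort:
    """Generate a longitudinal cohort of induced and control subjects.

    Per-subject biological variability is emulated by jittering ``mu_normal``,
    ``hyperreflective_gain``, ``lesion_growth_rate`` and ``surface_profile``
    by up to ``subject_jitter`` (relative), drawn from the master seed.
    """
    if n_induced < 1 or n_control < 1:
        raise ValueError("need >= 1 subject per group")
    weeks = list(weeks)
    if not weeks or any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("weeks must be non-empty and strictly increasing")
    if induced_spec.lesion_onset_week is None:
        raise ValueError("induced_spec must have a lesion_onset_week")
    control_spec = control_spec.replace(lesion_onset_week=None)

    root = np.random.SeedSequence(master_seed)
    subject_seqs = root.spawn(n_induced + n_control)
    volumes: list[OCTVolume] = []
    rows = []
    names = [f"I{i + 1:02d}" for i in range(n_induced)] + \
            [f"C{i + 1:02d}" for i in range(n_control)]
    if len(names) != len(set(names)):
        raise ValueError("duplicate subject ids")
    templates = [induced_spec] * n_induced + [control_spec] * n_control
    for name, template, sseq in zip(names, templates, subject_seqs):
        jr = np.random.default_rng(sseq.spawn(1)[0])
        spec = template.replace(
            mu_normal=template.mu_normal * _jitter(jr, subject_jitter),
            hyperreflective_gain=1.0 + (template.hyperreflective_gain - 1.0)
            * _jitter(jr, subject_jitter),
            lesion_growth_rate=template.lesion_growth_rate * _jitter(jr, subject_jitter),
            surface_profile=template.surface_profile * _jitter(jr, subject_jitter),
        )
        week_seqs = sseq.spawn(len(weeks) + 1)[1:]
        for week, wseq in zip(weeks, week_seqs):
            volumes.append(generate_volume(spec, name, week, wseq))
            rows.append({"subject_id": name, "group": volumes[-1].group, "week": week})
    design = pd.DataFrame(rows)
    return Cohort(volumes=volumes, design=design)


# ----------------------------------------------------------------------------
# Disk round-trip: multi-page TIFF + sidecar CSV
# ----------------------------------------------------------------------------

def write_volume(directory: Path | str, volume: OCTVolume,
                 sidecar_name: str = "index.csv", write_mask: bool = True) -> Path:
    """Write a volume as a 16-bit multi-page TIFF and append its sidecar row.

    Intensities are scaled by ``intensity_scale`` (recorded in the sidecar) so
    that the volume maximum maps to 65535; the declared quantization is
    therefore ``1/intensity_scale``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{volume.subject_id}_w{volume.week:02d}"
    path = directory / f"{stem}.tif"
    vmax = float(volume.voxels.max())
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    pages = np.round(np.transpose(volume.voxels, (2, 0, 1)) * scale).astype(np.uint16)
    tifffile.imwrite(path, pages)
    mask_path = ""
    if write_mask and volume.lesion_mask is not None:
        mask_path = f"{stem}_mask.tif"
        tifffile.imwrite(directory / mask_path,
                         np.transpose(volume.lesion_mask, (2, 0, 1)).astype(np.uint8))
    row = pd.DataFrame([{
        "subject_id": volume.subject_id,
        "group": volume.group,
        "week": volume.week,
        "path": path.name,
        "axial_um_per_px": volume.spacing[0],
        "lateral_um_per_px": volume.spacing[1],
        "slice_um": volume.spacing[2],
        "n_slices": volume.n_slices,
        "intensity_scale": scale,
        "mask_path": mask_path,
    }])
    sidecar = directory / sidecar_name
    if sidecar.exists():
        table = pd.concat([pd.read_csv(sidecar), row], ignore_index=True)
    else:
        table = row
    table.to_csv(sidecar, index=False)
    return path


def read_volume(directory: Path | str, subject_id: str, week: int,
                sidecar_name: str = "index.csv") -> OCTVolume:
    """Read a volume back; inverse of :func:`write_volume` up to quantization."""
    directory = Path(directory)
    sidecar = directory / sidecar_name
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    table = pd.read_csv(sidecar)
    sel = table[(table["subject_id"] == subject_id) & (table["week"] == week)]
    if len(sel) == 0:
        raise FormatError(f"no sidecar entry for {subject_id} week {week}")
    meta = sel.iloc[0]
    pages = tifffile.imread(directory / meta["path"])
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != int(meta["n_slices"]):
        raise FormatError(
            f"page count {pages.shape[0]} != sidecar n_slices {meta['n_slices']}")
    voxels = np.transpose(pages.astype(np.float32) / float(meta["intensity_scale"]),
                          (1, 2, 0))
    mask = None
    mp = meta.get("mask_path", "")
    if isinstance(mp, str) and mp:
        mpages = tifffile.imread(directory / mp)
        if mpages.ndim == 2:
            mpages = mpages[None]
        mask = np.transpose(mpages.astype(bool), (1, 2, 0))
        if mask.shape != voxels.shape:
            raise FormatError("mask shape does not match voxels")
    return OCTVolume(
        voxels=voxels, subject_id=subject_id, group=str(meta["group"]),
        week=int(meta["week"]),
        spacing=(float(meta["axial_um_per_px"]), float(meta["lateral_um_per_px"]),
                 float(meta["slice_um"])),
        lesion_mask=mask)


def write_cohort(directory: Path | str, cohort: Cohort,
                 sidecar_name: str = "index.csv") -> Path:
    directory = Path(directory)
    for v in cohort.volumes:
        write_volume(directory, v, sidecar_name=sidecar_name)
    return directory / sidecar_name
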