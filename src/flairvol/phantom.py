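"""Seeded synthetic FLAIR-like brain phantoms and whole cohorts.

Real FLAIR volumes from the clinical cohort this toolkit targets are not
publicly distributable, so every downstream stage (ROI cropping, 3D/2D CNN
training, evaluation) is exercised on simulated volumes instead.  A phantom
is the minimal geometry that carries the three imaging signatures of
subcortical ischemic vascular disease as they appear on FLAIR:

* an ellipsoidal "brain" of mid-intensity white matter with a brighter
  cortical shell, on an exactly-zero background (as after skull stripping);
* dark ellipsoidal ventricles whose size scales with disease severity
  (an atrophy proxy);
* hyperintense periventricular white-matter lesions (WMH) covering a
  class-dependent fraction of the periventricular shell, plus small
  quasi-spherical lacunar infarcts with a dark (CSF-like) core and a
  hyperintense rim.

Severity of all three signatures increases over the four diagnostic classes
HC < NCI < VaMCI < VaD, which is what makes the cohort learnably separable.
Everything is a pure function of (spec, seed): the same spec and seed give a
bit-identical volume.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

CLASSES = ("HC", "NCI", "VaMCI", "VaD")

# Tissue intensity scale (arbitrary units, FLAIR-like contrast ordering:
# CSF dark, white matter mid, gray matter brighter, lesions brightest).
WM_BASELINE = 0.60
GM_INTENSITY = 0.75
CSF_INTENSITY = 0.15
LACUNE_CORE = 0.15
BRAIN_FLOOR = 0.02  # brain voxels never drop to exactly zero after noise

# Per-class severity defaults: (n_lacunes, wmh_fraction, ventricle_scale).
# The ordering HC <= NCI <= VaMCI <= VaD in every field is the contract;
# the particular values are documented fixtures, not clinically calibrated.
CLASS_SEVERITY = {
    "HC": (0, 0.00, 1.00),
    "NCI": (1, 0.02, 1.05),
    "VaMCI": (3, 0.08, 1.15),
    "VaD": (6, 0.20, 1.30),
}

# Default cohort composition: 52 VaD + 82 VaMCI + 83 NCI patients and 46
# matched healthy controls (217 patients, 263 subjects in total).
DEFAULT_COUNTS = {"HC": 46, "NCI": 83, "VaMCI": 82, "VaD": 52}

PRESETS = {
    "test": {"grid_shape": (64, 64, 32), "spacing": (4.0, 4.0, 4.0)},
    "paper": {"grid_shape": (256, 256, 66), "spacing": (1.0, 1.0, 2.0)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject volume."""

    class_label: str
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    n_lacunes: int = 0
    wmh_fraction: float = 0.0
    ventricle_scale: float = 1.0
    lesion_contrast: float = 1.6
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}, got {self.class_label!r}")
        if len(self.grid_shape) != 3 or any(int(g) < 8 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 extents all >= 8, got {self.grid_shape}")
        if self.n_lacunes < 0:
            raise ValueError("n_lacunes must be nonnegative")
        if not 0.0 <= self.wmh_fraction < 1.0:
            raise ValueError("wmh_fraction must lie in [0, 1)")
        if self.ventricle_scale < 1.0:
            raise ValueError("ventricle_scale must be >= 1")
        if self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must exceed 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def default_spec(class_label: str, preset: str = "test", seed: int = 0, **overrides) -> PhantomSpec:
    """Severity defaults for a class at a grid preset ('test' or 'paper')."""
    n_lac, wmh, vent = CLASS_SEVERITY[class_label]
    kwargs = dict(
        class_label=class_label,
        grid_shape=tuple(PRESETS[preset]["grid_shape"]),
        n_lacunes=n_lac,
        wmh_fraction=wmh,
        ventricle_scale=vent,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@dataclass
class LabeledVolume:
    """A volume plus its diagnostic label and provenance."""

    data: np.ndarray
    label: str
    subject_id: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: PhantomSpec | str | None = None


def _ellipsoid(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def phantom_fields(spec: PhantomSpec) -> dict:
    """Build the phantom and return the volume together with tissue masks.

    Returned dict keys: ``volume`` (float32), ``brain``, ``white_matter``,
    ``ventricles``, ``wmh``, ``lacunes`` (boolean masks).  The volume is
    exactly zero outside ``brain``.
    """
    shape = tuple(int(g) for g in spec.grid_shape)
    rng = np.random.default_rng(spec.seed)
    m, n, l = shape
    center = ((m - 1) / 2.0, (n - 1) / 2.0, (l - 1) / 2.0)

    # mild per-subject anatomical variability so ROIs and lesion layouts differ
    jitter = 1.0 + rng.uniform(-0.04, 0.04, size=3)
    brain_axes = (0.42 * m * jitter[0], 0.45 * n * jitter[1], 0.42 * l * jitter[2])
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, brain_axes))
    brain = r2 <= 1.0
    if not brain.any():
        raise ValueError("degenerate geometry: empty brain mask")
    cortex = brain & (r2 > 0.72)  # outer shell reads as gray matter

    vent_axes = np.array([0.09 * m, 0.16 * n, 0.22 * l]) * spec.ventricle_scale
    lateral = 0.10 * m
    vent = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = (center[0] + side * lateral, center[1], center[2])
        vent |= _ellipsoid(shape, c, vent_axes)
    vent &= brain

    white = brain & ~cortex & ~vent

    vol = np.zeros(shape, dtype=np.float64)
    vol[brain] = WM_BASELINE
    vol[cortex] = GM_INTENSITY
    vol[vent] = CSF_INTENSITY

    # periventricular shell: white matter within a few voxels of a ventricle
    shell_width = max(2.0, 0.06 * min(m, n))
    dist_vent = ndimage.distance_transform_edt(~vent)
    shell = white & (dist_vent <= shell_width)

    wmh = np.zeros(shape, dtype=bool)
    if spec.wmh_fraction > 0 and shell.any():
        # blobby selection: threshold a smoothed random field at the quantile
        # that keeps exactly the requested fraction of shell voxels
        fieldv = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        vals = fieldv[shell]
        k = max(1, int(round(spec.wmh_fraction * vals.size)))
        thr = np.partition(vals, -k)[-k]
        wmh = shell & (fieldv >= thr)
        vol[wmh] = spec.lesion_contrast * WM_BASELINE

    lacunes = np.zeros(shape, dtype=bool)
    if spec.n_lacunes > 0:
        core_r = max(1.0, 0.025 * min(m, n))
        rim_r = core_r + max(1.0, 0.015 * min(m, n))
        deep = white & (r2 <= 0.68) & (dist_vent > shell_width)
        candidates = np.argwhere(deep)
        if candidates.size == 0:
            raise ValueError(
                f"cannot place {spec.n_lacunes} lacunes: no deep white matter in grid {shape}"
            )
        placed: list[np.ndarray] = []
        tries = 0
        max_tries = 200 * spec.n_lacunes
        while len(placed) < spec.n_lacunes:
            if tries >= max_tries:
                raise ValueError(
                    f"cannot place {spec.n_lacunes} lacunes in grid {shape}: "
                    f"only {len(placed)} fitted after {tries} attempts"
                )
            tries += 1
            c = candidates[rng.integers(len(candidates))]
            if any(np.linalg.norm(c - p) < 2.0 * rim_r for p in placed):
                continue
            placed.append(c)
        for c in placed:
            ball_rim = _ellipsoid(shape, c, (rim_r,) * 3) & brain & ~vent
            ball_core = _ellipsoid(shape, c, (core_r,) * 3) & brain & ~vent
            vol[ball_rim] = spec.lesion_contrast * WM_BASELINE  # hyperintense rim
            vol[ball_core] = LACUNE_CORE  # dark CSF-filled cavity
            lacunes |= ball_rim

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=shape)
        vol[brain] += noise[brain]
        np.maximum(vol, BRAIN_FLOOR, out=vol, where=brain)
    vol[~brain] = 0.0

    return {
        "volume": vol.astype(np.float32),
        "brain": brain,
        "white_matter": white,
        "ventricles": vent,
        "wmh": wmh,
        "lacunes": lacunes,
    }


def generate_phantom(spec: PhantomSpec, subject_id: str = "phantom") -> LabeledVolume:
    """Generate one labeled synthetic FLAIR volume (deterministic in spec+seed)."""
    fields = phantom_fields(spec)
    return LabeledVolume(
        data=fields["volume"],
        label=spec.class_label,
        subject_id=subject_id,
        provenance=spec,
    )


@dataclass
class CohortManifest:
    """Tabular index of a generated cohort: one row per subject volume."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def per_class_counts(self) -> dict:
        return self.table["label"].value_counts().to_dict()

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path, dtype={"subject_id": str, "label": str, "path": str, "seed": np.int64}))


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def generate_cohort(
    out_dir,
    per_class_counts: dict | None = None,
    master_seed: int = 0,
    preset: str = "test",
    phantom_defaults: dict | None = None,
    overwrite: bool = False,
) -> CohortManifest:
    """Write one NIfTI per subject plus a ``manifest.csv`` into ``out_dir``.

    Default composition mirrors the study cohort (52 VaD, 82 VaMCI, 83 NCI,
    46 HC).  Subjects are generated in a fixed class/index order with seeds
    derived from ``master_seed``, so two runs with the same seed produce
    byte-identical manifests and voxel-identical volumes.
    """
    counts = dict(DEFAULT_COUNTS if per_class_counts is None else per_class_counts)
    for label, c in counts.items():
        if label not in CLASSES:
            raise ValueError(f"unknown class {label!r}")
        if c < 0:
            raise ValueError(f"negative count for class {label}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = PRESETS[preset]["spacing"]
    affine = np.diag(list(spacing) + [1.0])

    rows = []
    index = 0
    for label in CLASSES:
        for i in range(counts.get(label, 0)):
            seed = subject_seed(master_seed, index)
            spec = default_spec(label, preset=preset, seed=seed, **(phantom_defaults or {}))
            sid = f"{label}{i:03d}"
            lv = generate_phantom(spec, subject_id=sid)
            path = out_dir / f"{sid}.nii.gz"
            img = nib.Nifti1Image(lv.data, affine)
            img.header.set_zooms(spacing)
            nib.save(img, path)
            rows.append({"subject_id": sid, "label": label, "path": str(path), "seed": seed})
            index += 1
    manifest = CohortManifest(pd.DataFrame(rows, columns=["subject_id", "label", "path", "seed"]))
    manifest.save(out_dir / "manifest.csv")
    return manifest
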