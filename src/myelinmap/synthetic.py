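"""Synthetic cohorts and digital phantoms.

Everything the analysis pipeline consumes can be generated here with known
ground truth:

* tabular cohorts of per-subject, per-region R1 observations drawn from
  the published growth curves with additive Gaussian measurement noise,
  emulating a pediatric population aged 3-72 months;
* 3-D digital phantoms — geometric stand-ins for the anatomical ROIs —
  with paired inversion-time volumes simulated through the MP2RAGE signal
  model, optional smooth transmit/receive bias fields (+-10% is the
  variation typically expected in the brain at 3 T) and additive Gaussian
  noise on the two inversion images.

Geometric primitives rather than anatomical atlases keep the ground truth
exact and the generator dependency-free; Gaussian (not Rician) noise is
used because at the simulated SNR the magnitude bias is negligible.
All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from . import regions as _regions
from .growth import GrowthParams, RegionObservation, predict_r1, reference_growth_params
from .mp2rage import simulate_signals, uni_combine
from .protocol import ProtocolParameters

__all__ = [
    "CohortSpec",
    "PhantomSpec",
    "Structure",
    "PhantomVolumes",
    "GeometryError",
    "generate_cohort",
    "generate_phantom",
    "default_phantom_structures",
    "write_volume",
    "read_volume",
    "check_same_geometry",
]


class ConfigError(ValueError):
    pass


class GeometryError(ValueError):
    """Paired volumes do not share shape/affine."""


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a tabular cohort.

    Defaults emulate the study population: 94 subjects aged 3-72 months,
    measurement noise 0.03 1/s per region (ROI SDs of real maps run
    0.01-0.05 1/s), male fraction 60/94.  ``age_bin_weights`` optionally
    reweights six-month age bins to mimic a non-uniform age distribution.
    """

    n_subjects: int = 94
    age_range: tuple[float, float] = (3.0, 72.0)
    age_bin_weights: tuple[float, ...] | None = None
    region_truth: dict[str, GrowthParams] | None = None
    noise_sd: float | dict[str, float] = 0.03
    sex_ratio: float = 60.0 / 94.0
    seed: int = 0

    def resolved_truth(self) -> dict[str, GrowthParams]:
        return dict(self.region_truth) if self.region_truth else reference_growth_params()

    def noise_for(self, truth: dict[str, GrowthParams]) -> dict[str, float]:
        if isinstance(self.noise_sd, dict):
            unknown = set(self.noise_sd) - set(truth)
            if unknown:
                raise ConfigError(
                    f"noise_sd given for regions without truth curves: {sorted(unknown)}"
                )
            table = {k: float(self.noise_sd.get(k, 0.0)) for k in truth}
        else:
            table = {k: float(self.noise_sd) for k in truth}
        if any(v < 0 for v in table.values()):
            raise ConfigError("noise_sd must be non-negative")
        return table


def _sample_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if not 0 <= lo < hi:
        raise ConfigError("age_range must satisfy 0 <= lo < hi")
    if spec.age_bin_weights is None:
        return rng.uniform(lo, hi, spec.n_subjects)
    weights = np.asarray(spec.age_bin_weights, dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ConfigError("age_bin_weights must be non-negative and not all zero")
    edges = np.linspace(lo, hi, len(weights) + 1)
    bins = rng.choice(len(weights), size=spec.n_subjects, p=weights / weights.sum())
    return rng.uniform(edges[bins], edges[bins + 1])


def generate_cohort(spec: CohortSpec) -> list[RegionObservation]:
    """Draw a cohort: per subject an age and sex, per region
    r1_mean = curve(age) + N(0, noise_sd) with r1_sd set to the noise SD."""
    if spec.n_subjects <= 0:
        raise ConfigError("n_subjects must be positive")
    truth = spec.resolved_truth()
    noise = spec.noise_for(truth)
    rng = np.random.default_rng(spec.seed)
    ages = _sample_ages(spec, rng)
    sexes = np.where(rng.uniform(size=spec.n_subjects) < spec.sex_ratio, "male", "female")
    observations: list[RegionObservation] = []
    for i in range(spec.n_subjects):
        for key in sorted(truth):
            region, side = _regions.split_key(key)
            sd = noise[key]
            r1 = predict_r1(truth[key], ages[i]) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            observations.append(
                RegionObservation(
                    subject_id=f"S{i + 1:04d}",
                    age=float(ages[i]),
                    region=region,
                    side=side,
                    r1_mean=float(r1),
                    r1_sd=sd,
                    sex=str(sexes[i]),
                    group="negative",
                )
            )
    return observations


@dataclass(frozen=True)
class Structure:
    """Geometric primitive standing in for one anatomical ROI.

    ``center`` and ``radii`` are in voxel units; ``shape`` is
    ``"ellipsoid"`` or ``"box"`` (half-widths given by ``radii``).
    """

    region: str
    side: str
    shape: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        rel = [(idx[d] - self.center[d]) / self.radii[d] for d in range(3)]
        if self.shape == "ellipsoid":
            return rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0
        if self.shape == "box":
            return (np.abs(rel[0]) <= 1) & (np.abs(rel[1]) <= 1) & (np.abs(rel[2]) <= 1)
        raise ConfigError(f"unknown structure shape {self.shape!r}")


def default_phantom_structures(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
) -> list[Structure]:
    """Bilateral ROI ellipsoids laid out roughly like an axial brain:
    anterior = +y, right = +x (RAS).  Coordinates are defined on a 64^3
    grid and rescaled proportionally for other grid shapes."""
    E = "ellipsoid"
    out = [
        Structure("plic", "right", E, (38, 29, 32), (2.5, 4.0, 3.0)),
        Structure("plic", "left", E, (26, 29, 32), (2.5, 4.0, 3.0)),
        Structure("alic", "right", E, (39, 37, 32), (2.0, 3.0, 2.5)),
        Structure("alic", "left", E, (25, 37, 32), (2.0, 3.0, 2.5)),
        Structure("genu", _regions.MIDLINE, E, (32, 44, 32), (4.0, 2.0, 2.5)),
        Structure("splenium", _regions.MIDLINE, E, (32, 19, 32), (4.5, 2.0, 2.5)),
        Structure("caudate", "right", E, (36, 40, 32), (2.0, 3.0, 2.5)),
        Structure("caudate", "left", E, (28, 40, 32), (2.0, 3.0, 2.5)),
        Structure("putamen", "right", E, (43, 33, 32), (2.5, 4.0, 3.0)),
        Structure("putamen", "left", E, (21, 33, 32), (2.5, 4.0, 3.0)),
        Structure("thalamus", "right", E, (35.5, 23, 32), (2.0, 2.5, 3.0)),
        Structure("thalamus", "left", E, (28.5, 23, 32), (2.0, 2.5, 3.0)),
        Structure("central_wm", "right", E, (40, 32, 44), (4.0, 5.0, 3.0)),
        Structure("central_wm", "left", E, (24, 32, 44), (4.0, 5.0, 3.0)),
        Structure("frontal_wm", "right", E, (38, 43, 44), (3.0, 3.5, 3.0)),
        Structure("frontal_wm", "left", E, (26, 43, 44), (3.0, 3.5, 3.0)),
        Structure("pons", _regions.MIDLINE, E, (32, 24, 16), (4.0, 3.0, 3.5)),
    ]
    scale = tuple(n / 64.0 for n in grid_shape)
    if scale != (1.0, 1.0, 1.0):
        out = [
            Structure(
                s.region,
                s.side,
                s.shape,
                tuple(c * f for c, f in zip(s.center, scale)),
                tuple(max(r * f, 0.75) for r, f in zip(s.radii, scale)),
            )
            for s in out
        ]
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a 3-D phantom at one age.

    The brain is an ellipsoid of ``background_t1`` (unmyelinated-tissue
    like); ROI structures take the T1 implied by their growth curve at
    ``age``.  ``transmit_bias`` / ``receive_bias`` are peak fractional
    amplitudes of smooth multiplicative fields; ``noise_sd`` is additive
    Gaussian noise on the two inversion-time images, in units of the
    equilibrium signal ``m0``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    age: float = 24.0
    structures: tuple[Structure, ...] | None = None
    region_truth: dict[str, GrowthParams] | None = None
    background_t1: float = 2.0
    m0: float = 1.0
    transmit_bias: float = 0.0
    receive_bias: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class PhantomVolumes:
    """Outputs of the phantom generator; all volumes share one geometry."""

    labels: nib.Nifti1Image
    t1_true: nib.Nifti1Image
    r1_true: nib.Nifti1Image
    ti1: nib.Nifti1Image
    ti2: nib.Nifti1Image
    uni: nib.Nifti1Image
    transmit_field: nib.Nifti1Image
    receive_field: nib.Nifti1Image
    label_table: pd.DataFrame


def _phantom_affine(spec: PhantomSpec) -> np.ndarray:
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -spec.voxel_size * (np.asarray(spec.grid_shape) - 1) / 2.0
    return affine


def _smooth_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative field 1 + amplitude * g with g a smooth low-frequency
    pattern in [-1, 1] (product of half-period sinusoids, random phases)."""
    if amplitude == 0.0:
        return np.ones(shape)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    phases = rng.uniform(0, 2 * np.pi, 3)
    g = np.ones(shape)
    for axis, (u, phase) in enumerate(zip(coords, phases)):
        profile = np.sin(np.pi * u / 2.0 + phase)
        g = g * profile.reshape([-1 if a == axis else 1 for a in range(3)])
    return 1.0 + amplitude * g


def generate_phantom(spec: PhantomSpec, protocol: ProtocolParameters) -> PhantomVolumes:
    """Build label/truth volumes and simulate the paired inversion-time
    images plus their uniform-ratio combination."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    affine = _phantom_affine(spec)
    truth = dict(spec.region_truth) if spec.region_truth else reference_growth_params()
    structures = (
        list(spec.structures)
        if spec.structures is not None
        else default_phantom_structures(shape)
    )

    # brain ellipsoid fills most of the grid; outside it is air (no signal)
    brain = Structure(
        "background", _regions.MIDLINE, "ellipsoid",
        tuple((n - 1) / 2.0 for n in shape),
        tuple(0.45 * n for n in shape),
    )
    labels = np.zeros(shape, dtype=np.int16)
    t1 = np.full(shape, spec.background_t1, dtype=float)
    brain_mask = brain.mask(shape)
    labels[brain_mask] = 1
    rows = [{"label_value": 1, "region": "background", "side": _regions.MIDLINE}]

    claimed = np.zeros(shape, dtype=bool)
    for value, struct in enumerate(structures, start=2):
        key = _regions.region_key(struct.region, struct.side)
        curve = truth.get(key)
        if curve is None and struct.side != _regions.MIDLINE:
            curve = truth.get(_regions.region_key(struct.region, "right"))
        if curve is None:
            raise ConfigError(f"no growth curve available for structure {key}")
        mask = struct.mask(shape)
        if not mask.any():
            raise ConfigError(f"structure {key} lies outside the grid")
        if (mask & claimed).any():
            warnings.warn(
                f"structure {key} overlaps an earlier structure; "
                "last listed wins",
                stacklevel=2,
            )
        labels[mask] = value
        t1[mask] = 1.0 / predict_r1(curve, spec.age)
        claimed |= mask
        rows.append({"label_value": value, "region": struct.region, "side": struct.side})

    transmit = _smooth_field(shape, spec.transmit_bias, rng)
    receive = _smooth_field(shape, spec.receive_bias, rng)

    s1, s2 = simulate_signals(protocol, t1, b1_scale=transmit, m0=spec.m0)
    air = ~brain_mask
    s1[air] = 0.0
    s2[air] = 0.0
    s1 = s1 * receive
    s2 = s2 * receive
    if spec.noise_sd > 0:
        s1 = s1 + rng.normal(0.0, spec.noise_sd, shape)
        s2 = s2 + rng.normal(0.0, spec.noise_sd, shape)
    uni = uni_combine(s1, s2)

    t1_out = np.where(brain_mask, t1, 0.0)
    with np.errstate(divide="ignore"):
        r1_out = np.where(brain_mask, 1.0 / t1, 0.0)

    def img(data, dtype=np.float64):
        return nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)

    return PhantomVolumes(
        labels=nib.Nifti1Image(labels, affine),
        t1_true=img(t1_out),
        r1_true=img(r1_out),
        ti1=img(s1),
        ti2=img(s2),
        uni=img(uni),
        transmit_field=img(transmit),
        receive_field=img(receive),
        label_table=pd.DataFrame(rows, columns=["label_value", "region", "side"]),
    )


def write_volume(volume: nib.Nifti1Image, path) -> None:
    nib.save(volume, str(path))


def read_volume(path) -> nib.Nifti1Image:
    return nib.load(str(path))


def check_same_geometry(a: nib.Nifti1Image, b: nib.Nifti1Image) -> None:
    """Raise :class:`GeometryError` unless the two volumes share shape and
    affine (RAS+ convention)."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise GeometryError("affine mismatch between paired volumes")
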